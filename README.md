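# morbidlca

Multimorbidity subgroup discovery for critical-care cohorts from
administrative diagnosis data.

Intensive-care patients typically carry several chronic conditions at
once, and particular *combinations* of conditions — not single diagnoses —
drive vulnerability to organ dysfunction, sepsis, and death. `morbidlca`
implements the full analysis pipeline for discovering such multimorbidity
subgroups from ICD-9-CM coded hospital data:

1. **Code mapping** — normalize ICD-9-CM codes and collapse each patient's
   diagnoses onto the 30 Elixhauser chronic-morbidity categories
   (Quan-style coding, bundled as a replaceable plain-text table).
2. **Phenotyping** — administrative (Angus-style) flags: infection, acute
   organ dysfunction, and sepsis = infection ∧ organ dysfunction (or an
   explicit septicemia/septic-shock code).
3. **Latent class analysis** — a finite mixture over the 30 binary
   indicators plus age bracket and admission type,
   P(x) = Σ_k π_k Π_j ρ_{kj,x_j}, fitted by multi-start EM; the number of
   classes chosen by lowest BIC (AIC tie-break) subject to a minimum
   subgroup size (default 5% of the cohort).
4. **Characterization** — per-subgroup prevalence/outcome tables,
   chi-square and ANOVA contrasts, one-vs-rest logistic-regression AUC,
   and disease co-occurrence networks: relative-risk edges
   RR_ij = C_ij·N/(P_i·P_j) with exact-test filtering at cohort level,
   normalized pair counts C_ij/N_subgroup within subgroups.
5. **Synthetic cohorts** — a seeded generator with a built-in six-class
   structure (cardiopulmonary, young, hepatic/addiction, complicated
   diabetics, uncomplicated diabetics, cardiac) that emits ICD-9 codes per
   active category, so the entire pipeline runs end-to-end with no
   access-restricted clinical data.

See `docs/methods.md` for the model, its assumptions, and all numerical
choices.

## Worked example

```python
import morbidlca as m

# a 10,000-patient synthetic cohort from the bundled six-class config
cfg = m.default_config()
cohort = m.generate_cohort(cfg, n=10_000, seed=7)

# map the emitted ICD-9 diagnosis table onto Elixhauser indicators + flags
table = m.load_code_table()
wide = m.phenotype_cohort(cohort.diagnoses, table,
                          patient_ids=cohort.cohort["patient_id"])

# fit the six-class latent class model
data = m.prepare_dataset(
    wide[list(m.ELIXHAUSER_CATEGORIES)].to_numpy(),
    m.ELIXHAUSER_CATEGORIES,
    cohort.cohort["age"].to_numpy(),
    cohort.cohort["elective"].to_numpy(),
)
model, resp = m.em_fit(data, K=6, n_restarts=10, seed=1)
perm = m.align_classes(model, cfg)  # resolve label switching

for g, name in enumerate(cfg.class_names):
    print(f"{name:24s} pi = {model.pi[perm[g]]:.3f}")
```

prints (generating proportions 0.061 / 0.235 / 0.098 / 0.094 / 0.248 /
0.264):

```
cardiopulmonary          pi = 0.055
young                    pi = 0.239
hepatic_addiction        pi = 0.104
complicated_diabetics    pi = 0.086
uncomplicated_diabetics  pi = 0.240
cardiac                  pi = 0.276
```

i.e. the fitted mixture recovers the generating subgroup sizes to within
about a percentage point at this cohort size (tighter at the full
36,390-patient scale the recovery harness uses). `resp.gamma` holds each patient's posterior
class membership; `m.summarize_subgroups`, `m.compare_subgroups` and
`m.build_network` take it from there.

The same pipeline is scriptable from the shell:

```sh
morbidlca --config analysis.yaml all   # simulate -> map -> select -> network -> summarize
```

Each stage writes flat CSV/JSON/GraphML artifacts plus a run manifest with
config, input and output hashes and per-stage seeds, so any stage can be
re-run or swapped independently.

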