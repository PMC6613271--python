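"""Seeded synthetic ICU cohort generator with a six-class latent structure.

The generator draws exactly the statistical structure the latent class
model assumes: a categorical class per patient, then conditionally
independent Bernoulli morbidity indicators, a truncated-normal age, a
Bernoulli admission type, and outcome flags with sepsis nested inside organ
dysfunction (matching the administrative definition, under which sepsis
implies organ dysfunction).  Active morbidity categories emit ICD-9 codes
into a long-format diagnosis table so the code-mapping stage is exercised
end-to-end; the emission codes are chosen to map back to exactly their own
category, making the code -> indicator round trip exact.

The bundled default configuration encodes the canonical six-subgroup
structure (cardiopulmonary, young, hepatic/addiction, complicated
diabetics, uncomplicated diabetics, cardiac) that the recovery tests and
the acceptance harness measure against.  True class labels are returned in
a sidecar array, never in the analysis inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import codemap
from .codemap import ELIXHAUSER_CATEGORIES, N_CATEGORIES

N_CLASSES = 6


@dataclass
class GeneratorConfig:
    """Full parameterization of the six-class synthetic cohort."""

    class_names: tuple[str, ...]
    mixing: np.ndarray  # (6,)
    prevalence: np.ndarray  # (6, 30) class-conditional Bernoulli probs
    age_mean: np.ndarray  # (6,) years
    age_sd: np.ndarray  # (6,) years
    age_min: float
    elective_prob: np.ndarray  # (6,)
    organ_dysfunction_rate: np.ndarray  # (6,) marginal per class
    sepsis_rate: np.ndarray  # (6,) marginal per class, <= organ dysfunction
    mortality_given_organ_dysfunction: np.ndarray  # (6,) marginal among OD
    mortality_given_sepsis: np.ndarray  # (6,)
    mortality_baseline: np.ndarray  # (6,) among patients without OD
    sofa_mean: np.ndarray
    sofa_sd: float
    oasis_mean: np.ndarray
    oasis_sd: float
    emission_codes: dict[str, list[str]]
    outcome_emission: dict[str, list[str]] = field(default_factory=dict)
    male_prob: float = 0.578
    correlation_jitter: float = 0.0
    n: int = 36390
    seed: int = 12345

    def prevalence_matrix(self) -> np.ndarray:
        """(6, 30) class-conditional prevalences, for class alignment."""
        return self.prevalence

    def validate(self, table: codemap.CodeTable | None = None) -> None:
        """Check all structural invariants; raise ValueError on violation."""
        if len(self.class_names) != N_CLASSES:
            raise ValueError("exactly six classes are required")
        if not np.isclose(self.mixing.sum(), 1.0, atol=1e-9):
            raise ValueError("mixing proportions must sum to 1")
        probs = [
            self.mixing, self.prevalence, self.elective_prob,
            self.organ_dysfunction_rate, self.sepsis_rate,
            self.mortality_given_organ_dysfunction,
            self.mortality_given_sepsis, self.mortality_baseline,
        ]
        for p in probs:
            arr = np.asarray(p)
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError("all probabilities must lie in [0, 1]")
        if self.prevalence.shape != (N_CLASSES, N_CATEGORIES):
            raise ValueError("prevalence must be 6 x 30")
        if (self.sepsis_rate > self.organ_dysfunction_rate + 1e-12).any():
            raise ValueError("sepsis rate cannot exceed organ-dysfunction rate")
        # the implied mortality among OD-without-sepsis patients must be a
        # valid probability for each class
        m_only = self._mortality_od_without_sepsis()
        if (m_only < -1e-12).any() or (m_only > 1 + 1e-12).any():
            raise ValueError(
                "mortality_given_organ_dysfunction incompatible with "
                "mortality_given_sepsis at the stated sepsis/OD rates"
            )
        if table is None:
            table = codemap.load_code_table()
        for j, cat in enumerate(ELIXHAUSER_CATEGORIES):
            codes = self.emission_codes.get(cat, [])
            if not codes:
                raise ValueError(f"no emission code for category {cat}")
            for code in codes:
                vec = codemap.map_elixhauser({codemap.normalize_icd9(code)}, table)
                if vec[j] != 1 or vec.sum() != 1:
                    raise ValueError(
                        f"emission code {code} for {cat} does not map back "
                        "to exactly its own category"
                    )

    def _mortality_od_without_sepsis(self) -> np.ndarray:
        """Solve the OD-without-sepsis mortality from the marginals.

        mortality_given_organ_dysfunction is the marginal rate among all OD
        patients; since sepsis is a sub-event with its own rate, the rate
        among OD-without-sepsis patients follows by mixture decomposition.
        """
        od, sep = self.organ_dysfunction_rate, self.sepsis_rate
        num = self.mortality_given_organ_dysfunction * od - (
            self.mortality_given_sepsis * sep
        )
        den = od - sep
        out = np.where(
            den > 1e-12, num / np.maximum(den, 1e-12),
            self.mortality_given_organ_dysfunction,
        )
        return out


def _as_array(x, dtype=float) -> np.ndarray:
    return np.asarray(x, dtype=dtype)


def load_config(path: str | Path) -> GeneratorConfig:
    """Load a generator config from YAML (see the bundled default file)."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> GeneratorConfig:
    prev = np.array(
        [raw["prevalence"][cat] for cat in ELIXHAUSER_CATEGORIES], dtype=float
    ).T  # categories are rows in the file; classes are rows in memory
    rates = raw["outcome_rates"]
    sev = raw["severity"]
    cfg = GeneratorConfig(
        class_names=tuple(raw["class_names"]),
        mixing=_as_array(raw["mixing"]),
        prevalence=prev,
        age_mean=_as_array(raw["age"]["mean"]),
        age_sd=_as_array(raw["age"]["sd"]),
        age_min=float(raw["age"]["min"]),
        elective_prob=_as_array(raw["elective_prob"]),
        organ_dysfunction_rate=_as_array(rates["organ_dysfunction"]),
        sepsis_rate=_as_array(rates["sepsis"]),
        mortality_given_organ_dysfunction=_as_array(
            rates["mortality_given_organ_dysfunction"]
        ),
        mortality_given_sepsis=_as_array(rates["mortality_given_sepsis"]),
        mortality_baseline=_as_array(rates["mortality_baseline"]),
        sofa_mean=_as_array(sev["sofa_mean"]),
        sofa_sd=float(sev["sofa_sd"]),
        oasis_mean=_as_array(sev["oasis_mean"]),
        oasis_sd=float(sev["oasis_sd"]),
        emission_codes={k: list(v) for k, v in raw["emission_codes"].items()},
        outcome_emission={
            k: list(v) for k, v in raw.get("outcome_emission", {}).items()
        },
        n=int(raw.get("n", 36390)),
        seed=int(raw.get("seed", 12345)),
    )
    return cfg


def default_config() -> GeneratorConfig:
    """The bundled, versioned six-class configuration."""
    ref = resources.files("morbidlca.data").joinpath("default_generator.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)


@dataclass
class SyntheticCohort:
    """Generated cohort + diagnosis tables with sidecar ground truth."""

    cohort: pd.DataFrame  # patient_id, age, sex, elective, outcomes, scores
    diagnoses: pd.DataFrame  # patient_id, icd9_code, seq_num
    true_class: np.ndarray  # (N,) generating class index (sidecar only)
    indicators: np.ndarray  # (N, 30) drawn morbidity indicators (sidecar)


def generate_cohort(
    config: GeneratorConfig,
    n: int | None = None,
    seed: int | None = None,
    table: codemap.CodeTable | None = None,
) -> SyntheticCohort:
    """Draw a cohort of ``n`` patients from the latent six-class model.

    Fully reproducible given (config, n, seed).  ``n`` and ``seed`` default
    to the config values.
    """
    config.validate(table=table)
    n = config.n if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    if n == 0:
        cohort = pd.DataFrame(
            columns=["patient_id", "age", "sex", "elective",
                     "organ_dysfunction", "sepsis", "mortality",
                     "sofa", "oasis"]
        )
        diagnoses = pd.DataFrame(columns=["patient_id", "icd9_code", "seq_num"])
        return SyntheticCohort(cohort, diagnoses,
                               np.empty(0, dtype=int),
                               np.empty((0, N_CATEGORIES), dtype=np.int8))

    z = rng.choice(N_CLASSES, size=n, p=config.mixing)
    indicators = (
        rng.random((n, N_CATEGORIES)) < config.prevalence[z]
    ).astype(np.int8)

    if config.correlation_jitter > 0:
        # optional residual within-class dependence: with probability q,
        # copy each even-indexed indicator from its left neighbour
        q = config.correlation_jitter
        copy = rng.random((n, N_CATEGORIES // 2)) < q
        even = np.arange(0, N_CATEGORIES - 1, 2)
        for c, col in enumerate(even):
            sel = copy[:, c]
            indicators[sel, col + 1] = indicators[sel, col]

    mu, sd = config.age_mean[z], config.age_sd[z]
    a = (config.age_min - mu) / sd
    age = truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)

    elective = (rng.random(n) < config.elective_prob[z]).astype(np.int8)
    sex_male = (rng.random(n) < config.male_prob).astype(np.int8)

    od = rng.random(n) < config.organ_dysfunction_rate[z]
    with np.errstate(invalid="ignore", divide="ignore"):
        sep_given_od = np.where(
            config.organ_dysfunction_rate > 0,
            config.sepsis_rate / np.maximum(config.organ_dysfunction_rate, 1e-12),
            0.0,
        )
    sepsis = od & (rng.random(n) < sep_given_od[z])

    m_od_only = config._mortality_od_without_sepsis()
    p_death = np.where(
        sepsis, config.mortality_given_sepsis[z],
        np.where(od, m_od_only[z], config.mortality_baseline[z]),
    )
    mortality = (rng.random(n) < p_death).astype(np.int8)

    sofa = np.clip(np.rint(rng.normal(config.sofa_mean[z], config.sofa_sd)), 0, 24)
    oasis = np.clip(np.rint(rng.normal(config.oasis_mean[z], config.oasis_sd)), 0, 90)

    width = max(6, len(str(n)))
    patient_id = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    cohort = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age": age,
            "sex": np.where(sex_male == 1, "M", "F"),
            "elective": elective,
            "organ_dysfunction": od.astype(np.int8),
            "sepsis": sepsis.astype(np.int8),
            "mortality": mortality,
            "sofa": sofa.astype(int),
            "oasis": oasis.astype(int),
        }
    )

    emission = [config.emission_codes[cat] for cat in ELIXHAUSER_CATEGORIES]
    od_codes = config.outcome_emission.get("organ_dysfunction", [])
    infection_codes = config.outcome_emission.get("infection", [])
    pid_col: list[str] = []
    code_col: list[str] = []
    seq_col: list[int] = []
    for i in range(n):
        codes: list[str] = []
        active = np.flatnonzero(indicators[i])
        for j in active:
            codes.append(emission[j][int(rng.integers(len(emission[j])))])
        if od[i]:
            codes.extend(od_codes[:1])
        if sepsis[i]:
            codes.extend(infection_codes[:1])
        pid_col.extend([patient_id[i]] * len(codes))
        code_col.extend(codes)
        seq_col.extend(range(1, len(codes) + 1))
    diagnoses = pd.DataFrame(
        {"patient_id": pid_col, "icd9_code": code_col, "seq_num": seq_col}
    )
    return SyntheticCohort(cohort, diagnoses, z, indicators)
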