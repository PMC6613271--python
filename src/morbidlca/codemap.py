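"""ICD-9-CM normalization, Elixhauser morbidity mapping, and administrative
sepsis phenotyping.

Diagnoses from administrative hospital data arrive as ICD-9-CM code strings
in varying dialects (with or without the decimal point, mixed case for
V/E codes).  This module canonicalizes them, collapses each patient's code
set onto the 30 Elixhauser chronic-morbidity categories, and derives the
administrative infection / acute-organ-dysfunction / sepsis flags in the
style of the Angus criteria: sepsis is the conjunction of a bacterial or
fungal infection code with an acute organ-dysfunction code, or an explicit
septicemia/septic-shock code.

The default code table bundles a Quan-style Elixhauser ICD-9-CM mapping and
Angus-style infection and organ-dysfunction lists as a plain-text TSV; both
are user-replaceable so the mapping can be swapped for site-specific
variants without touching code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ICD9_SHAPE = re.compile(r"^(V\d{2,4}|E\d{3,4}|\d{3,5})$")

#: canonical order of the 30 Elixhauser categories used everywhere downstream
ELIXHAUSER_CATEGORIES: tuple[str, ...] = (
    "congestive_heart_failure",
    "cardiac_arrhythmias",
    "valvular_disease",
    "pulmonary_circulation",
    "peripheral_vascular",
    "hypertension_uncomplicated",
    "hypertension_complicated",
    "paralysis",
    "other_neurological",
    "chronic_pulmonary",
    "diabetes_uncomplicated",
    "diabetes_complicated",
    "hypothyroidism",
    "renal_failure",
    "liver_disease",
    "peptic_ulcer",
    "aids_hiv",
    "lymphoma",
    "metastatic_cancer",
    "solid_tumor",
    "rheumatoid_arthritis",
    "coagulopathy",
    "obesity",
    "weight_loss",
    "fluid_electrolyte",
    "blood_loss_anemia",
    "deficiency_anemia",
    "alcohol_abuse",
    "drug_abuse",
    "depression",
)

N_CATEGORIES = len(ELIXHAUSER_CATEGORIES)


class InvalidICD9Error(ValueError):
    """Raised when a string cannot be interpreted as an ICD-9-CM code."""


def normalize_icd9(raw_code: str) -> str:
    """Canonicalize an ICD-9-CM code string.

    Strips whitespace and the decimal point and uppercases V/E prefixes, so
    ``"428.0"``, ``" 4280 "`` and ``"4280"`` all become ``"4280"``.
    Idempotent by construction.

    Raises
    ------
    InvalidICD9Error
        If the input is empty or not shaped like an ICD-9-CM code
        (3-5 digits, or a V/E code).
    """
    if raw_code is None:
        raise InvalidICD9Error("ICD-9 code is None")
    code = str(raw_code).strip().replace(".", "").upper()
    if not code:
        raise InvalidICD9Error(f"empty ICD-9 code from input {raw_code!r}")
    if not _ICD9_SHAPE.match(code):
        raise InvalidICD9Error(f"not an ICD-9-CM shaped code: {raw_code!r}")
    return code


@dataclass(frozen=True)
class _MatchSet:
    """Exact codes plus prefixes, with a fast containment test."""

    exact: frozenset[str]
    prefixes: tuple[str, ...]

    def matches(self, code: str) -> bool:
        if code in self.exact:
            return True
        return bool(self.prefixes) and code.startswith(self.prefixes)


@dataclass(frozen=True)
class CodeTable:
    """The 30-category Elixhauser mapping plus the administrative sepsis lists.

    ``category_names`` fixes the indicator order of every
    :class:`MorbidityVector` produced from this table.
    """

    category_names: tuple[str, ...]
    category_sets: dict[str, _MatchSet]
    infection: _MatchSet
    organ_dysfunction: _MatchSet
    explicit_sepsis: _MatchSet
    mech_vent_procedures: _MatchSet = field(
        default_factory=lambda: _MatchSet(frozenset(), ())
    )

    def __post_init__(self):
        if len(self.category_names) != N_CATEGORIES:
            raise ValueError(
                f"expected exactly {N_CATEGORIES} Elixhauser categories, "
                f"got {len(self.category_names)}"
            )


def _build_matchset(df: pd.DataFrame) -> _MatchSet:
    exact = frozenset(df.loc[df["match_type"] == "exact", "code"])
    prefixes = tuple(sorted(df.loc[df["match_type"] == "prefix", "code"]))
    return _MatchSet(exact, prefixes)


def load_code_table(path: str | Path | None = None) -> CodeTable:
    """Load a code table TSV (columns: category, code, match_type, list).

    With no argument, loads the bundled default table.  Codes in the file
    are normalized on load, so a user-supplied table may use dotted codes.
    """
    if path is None:
        ref = resources.files("morbidlca.data").joinpath("icd9_codetable.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"category", "code", "match_type", "list"}
    if not required.issubset(df.columns):
        raise ValueError(f"code table must have columns {sorted(required)}")
    bad = set(df["match_type"]) - {"exact", "prefix"}
    if bad:
        raise ValueError(f"unknown match_type values: {sorted(bad)}")
    df["code"] = df["code"].map(normalize_icd9)

    elix = df[df["list"] == "elixhauser"]
    names = tuple(c for c in ELIXHAUSER_CATEGORIES if c in set(elix["category"]))
    if len(names) != N_CATEGORIES:
        # a replacement table may rename categories; keep file order then
        names = tuple(dict.fromkeys(elix["category"]))
    sets = {
        cat: _build_matchset(elix[elix["category"] == cat]) for cat in names
    }
    return CodeTable(
        category_names=names,
        category_sets=sets,
        infection=_build_matchset(df[df["list"] == "infection"]),
        organ_dysfunction=_build_matchset(df[df["list"] == "organ_dysfunction"]),
        explicit_sepsis=_build_matchset(df[df["list"] == "explicit_sepsis"]),
        mech_vent_procedures=_build_matchset(df[df["list"] == "mech_vent"]),
    )


def map_elixhauser(codes: set[str], table: CodeTable) -> np.ndarray:
    """Map a patient's normalized code set onto the 30 binary indicators.

    Indicator j is set iff any code matches category j exactly or by a
    declared prefix.  Codes matching no category are ignored (administrative
    data is noisy); their count is logged at debug level.  A code listed
    under several categories in the table (e.g. alcoholic cardiomyopathy,
    alcoholic cirrhosis) activates each of them.
    """
    vec = np.zeros(N_CATEGORIES, dtype=np.int8)
    unmapped = 0
    for code in codes:
        hit = False
        for j, cat in enumerate(table.category_names):
            if table.category_sets[cat].matches(code):
                vec[j] = 1
                hit = True
        if not hit:
            unmapped += 1
    if unmapped:
        logger.debug("%d codes mapped to no Elixhauser category", unmapped)
    return vec


def flag_infection(codes: set[str], table: CodeTable) -> bool:
    """True iff any code denotes a bacterial or fungal infection."""
    return any(table.infection.matches(c) for c in codes)


def flag_organ_dysfunction(
    codes: set[str],
    table: CodeTable,
    procedure_codes: set[str] | None = None,
) -> bool:
    """True iff any code denotes acute organ dysfunction.

    ``procedure_codes``, when provided, are checked against the
    mechanical-ventilation procedure list (part of the administrative
    organ-dysfunction definition); when absent that criterion is skipped.
    """
    if any(table.organ_dysfunction.matches(c) for c in codes):
        return True
    if procedure_codes is not None:
        return any(table.mech_vent_procedures.matches(c) for c in procedure_codes)
    return False


def flag_sepsis(
    infection: bool,
    organ_dysfunction: bool,
    codes: set[str],
    table: CodeTable,
) -> bool:
    """Administrative sepsis: infection AND organ dysfunction, or an
    explicit septicemia / septic-shock code."""
    if infection and organ_dysfunction:
        return True
    return any(table.explicit_sepsis.matches(c) for c in codes)


def read_diagnoses(path: str | Path) -> pd.DataFrame:
    """Read a long-format diagnosis CSV (patient_id, icd9_code, seq_num).

    Extra columns are ignored; codes are normalized; rows whose code is not
    ICD-9-shaped are dropped with a logged count.
    """
    df = pd.read_csv(path, dtype={"icd9_code": str})
    required = {"patient_id", "icd9_code", "seq_num"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"diagnosis table missing columns {sorted(missing)}")

    def _safe(c):
        try:
            return normalize_icd9(c)
        except InvalidICD9Error:
            return None

    df = df.copy()
    df["icd9_code"] = df["icd9_code"].map(_safe)
    n_bad = int(df["icd9_code"].isna().sum())
    if n_bad:
        logger.warning("dropped %d rows with malformed ICD-9 codes", n_bad)
        df = df.dropna(subset=["icd9_code"])
    if (df["seq_num"] < 1).any():
        raise ValueError("seq_num must be >= 1")
    return df[["patient_id", "icd9_code", "seq_num"]]


def phenotype_cohort(
    diagnoses: pd.DataFrame,
    table: CodeTable | None = None,
    patient_ids: pd.Index | list | None = None,
    procedures: pd.DataFrame | None = None,
    drg_suppression: dict[str, list[str]] | None = None,
    drg_column: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the wide per-patient phenotype table.

    Returns one row per patient with the 30 Elixhauser indicator columns
    (named by category) plus ``infection``, ``organ_dysfunction`` and
    ``sepsis`` flags.  ``patient_ids`` can supply the full cohort (patients
    with no diagnosis rows get all-zero rows).

    ``drg_suppression`` is an optional exclusion hook mapping a DRG code to
    the Elixhauser categories it suppresses (the admission-reason filter);
    ``drg_column`` gives each patient's DRG.  No default map is shipped.
    """
    if table is None:
        table = load_code_table()
    groups = diagnoses.groupby("patient_id")["icd9_code"].agg(set)
    if patient_ids is not None:
        groups = groups.reindex(pd.Index(patient_ids), fill_value=frozenset())
        groups = groups.map(set)

    proc_groups = None
    if procedures is not None:
        proc_groups = procedures.groupby("patient_id")["proc_code"].agg(set)
    else:
        logger.info(
            "no procedure codes supplied; mechanical-ventilation criterion "
            "for organ dysfunction skipped"
        )

    rows = np.zeros((len(groups), N_CATEGORIES), dtype=np.int8)
    inf = np.zeros(len(groups), dtype=bool)
    od = np.zeros(len(groups), dtype=bool)
    sep = np.zeros(len(groups), dtype=bool)
    for i, (pid, codes) in enumerate(groups.items()):
        rows[i] = map_elixhauser(codes, table)
        proc = None
        if proc_groups is not None:
            proc = proc_groups.get(pid, set())
        inf[i] = flag_infection(codes, table)
        od[i] = flag_organ_dysfunction(codes, table, procedure_codes=proc)
        sep[i] = flag_sepsis(inf[i], od[i], codes, table)

    out = pd.DataFrame(rows, index=groups.index, columns=list(table.category_names))
    out["infection"] = inf.astype(np.int8)
    out["organ_dysfunction"] = od.astype(np.int8)
    out["sepsis"] = sep.astype(np.int8)
    out.index.name = "patient_id"

    if drg_suppression and drg_column is not None:
        drg = drg_column.reindex(out.index)
        n_suppressed = 0
        for code, cats in drg_suppression.items():
            mask = drg == code
            for cat in cats:
                if cat in out.columns:
                    n_suppressed += int(out.loc[mask, cat].sum())
                    out.loc[mask, cat] = 0
        logger.info("DRG hook suppressed %d indicator cells", n_suppressed)
    return out
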