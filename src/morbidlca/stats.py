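"""Subgroup characterization and verification statistics.

Covers the descriptive and inferential layer around the latent classes:
per-subgroup prevalence/outcome tables with t-based confidence intervals
for mean age, chi-square and one-way ANOVA contrasts across subgroups,
one-vs-rest logistic-regression AUC as a discriminability check on the
subgroup labels, and the preliminary k-means clustering of disease
prevalence profiles over age brackets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .codemap import ELIXHAUSER_CATEGORIES
from .lca import AGE_BRACKET_LABELS, age_to_bracket

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = ("organ_dysfunction", "sepsis", "mortality")
SEVERITY_COLUMNS = ("sofa", "oasis")


def _rate(mask_num: np.ndarray, mask_den: np.ndarray) -> float:
    den = int(mask_den.sum())
    return float(mask_num[mask_den].mean()) if den else np.nan


def summarize_subgroups(
    membership: np.ndarray,
    data: pd.DataFrame,
    category_names: tuple[str, ...] = ELIXHAUSER_CATEGORIES,
) -> pd.DataFrame:
    """Tabulate each subgroup: size, morbidity prevalence, age, outcomes.

    ``data`` is the wide cohort table with the indicator columns plus
    ``age``, ``elective`` and the outcome flags; optional ``sofa``/``oasis``
    columns are summarized when present.  Empty subgroups are reported with
    count 0 and NaN rates.  Conditional mortality uses the conditioning
    event as denominator.
    """
    membership = np.asarray(membership)
    if len(membership) != len(data):
        raise ValueError("membership length must match cohort rows")
    labels = np.unique(membership)
    rows = []
    N = len(data)
    for g in labels:
        mask = membership == g
        sub = data.loc[mask]
        n = int(mask.sum())
        row: dict[str, float] = {"subgroup": g, "n": n, "fraction": n / N}
        for cat in category_names:
            row[f"prev_{cat}"] = float(sub[cat].mean()) if n else np.nan
        if n:
            age = sub["age"].to_numpy(dtype=float)
            row["age_mean"] = float(age.mean())
            if n > 1:
                half = sps.t.ppf(0.975, n - 1) * age.std(ddof=1) / np.sqrt(n)
            else:
                half = np.nan
            row["age_ci_low"] = row["age_mean"] - half
            row["age_ci_high"] = row["age_mean"] + half
            row["elective_frac"] = float(sub["elective"].mean())
            od = sub["organ_dysfunction"].to_numpy(dtype=bool)
            sep = sub["sepsis"].to_numpy(dtype=bool)
            dead = sub["mortality"].to_numpy(dtype=bool)
            row["organ_dysfunction_rate"] = float(od.mean())
            row["sepsis_rate"] = float(sep.mean())
            row["mortality_rate"] = float(dead.mean())
            row["mortality_given_organ_dysfunction"] = _rate(dead, od)
            row["mortality_given_sepsis"] = _rate(dead, sep)
            for col in SEVERITY_COLUMNS:
                if col in sub.columns:
                    row[f"{col}_mean"] = float(sub[col].mean())
                    row[f"{col}_median"] = float(sub[col].median())
        else:
            logger.warning("subgroup %s is empty; rates undefined", g)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("subgroup")
    return out


def compare_subgroups(
    membership: np.ndarray,
    data: pd.DataFrame,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Chi-square tests for categorical and one-way ANOVA for continuous
    variables across subgroups.

    For each chi-square table the minimum expected cell count is reported
    (the usual validity heuristic); for each ANOVA a variance-ratio flag
    (max/min group sd > 2) is reported as a descriptive diagnostic, not a
    gate.  Single-level variables are skipped with a note.
    """
    membership = np.asarray(membership)
    if len(np.unique(membership)) < 2:
        raise ValueError("need at least two non-empty subgroups")
    if categorical is None:
        categorical = [
            c
            for c in data.columns
            if c in ELIXHAUSER_CATEGORIES
            or c in ("elective", "organ_dysfunction", "sepsis", "mortality")
        ]
    if continuous is None:
        continuous = [c for c in ("age", "sofa", "oasis") if c in data.columns]

    rows = []
    for var in categorical:
        tab = pd.crosstab(membership, data[var])
        if tab.shape[1] < 2:
            rows.append(
                {"variable": var, "kind": "categorical", "note": "single level"}
            )
            continue
        # plain Pearson statistic (no Yates correction), so 2x2 tables agree
        # with the closed-form formula
        stat, p, dof, expected = sps.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append(
            {
                "variable": var,
                "kind": "categorical",
                "statistic": float(stat),
                "df": int(dof),
                "p_value": float(p),
                "min_expected_count": float(expected.min()),
                "note": "",
            }
        )
    for var in continuous:
        groups = [
            data.loc[membership == g, var].to_numpy(dtype=float)
            for g in np.unique(membership)
        ]
        groups = [g[~np.isnan(g)] for g in groups]
        if any(len(g) < 2 for g in groups):
            rows.append({"variable": var, "kind": "continuous", "note": "group too small"})
            continue
        stat, p = sps.f_oneway(*groups)
        sds = np.array([g.std(ddof=1) for g in groups])
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "statistic": float(stat),
                "df": len(groups) - 1,
                "p_value": float(p),
                "variance_ratio_flag": bool(sds.max() > 2 * max(sds.min(), 1e-12)),
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def validate_subgroups_auc(
    membership: np.ndarray,
    features: pd.DataFrame | np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
) -> pd.Series:
    """One-vs-rest logistic regression AUC per subgroup.

    Each subgroup is discriminated from the rest using the same variables
    the latent class model consumed, with stratified cross-validated
    out-of-fold predictions.  Subgroups smaller than the fold count get a
    reduced fold count with a warning.
    """
    membership = np.asarray(membership)
    X = np.asarray(features, dtype=float)
    aucs = {}
    for g in np.unique(membership):
        y = (membership == g).astype(int)
        pos = int(y.sum())
        folds = min(n_folds, pos, len(y) - pos)
        if folds < 2:
            logger.warning("subgroup %s too small for cross-validation", g)
            aucs[g] = np.nan
            continue
        if folds < n_folds:
            logger.warning(
                "subgroup %s: reducing folds from %d to %d", g, n_folds, folds
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = np.zeros(len(y))
        for train, test in skf.split(X, y):
            clf = LogisticRegression(max_iter=1000)
            clf.fit(X[train], y[train])
            scores[test] = clf.predict_proba(X[test])[:, 1]
        aucs[g] = float(roc_auc_score(y, scores))
    return pd.Series(aucs, name="auc")


def age_bracket_profile(
    indicators: pd.DataFrame | np.ndarray,
    age: np.ndarray,
    category_names: tuple[str, ...] = ELIXHAUSER_CATEGORIES,
) -> pd.DataFrame:
    """Disease prevalence per Elixhauser category within each age bracket.

    Returns a (30 categories x 5 brackets) DataFrame of fractions.
    """
    ind = np.asarray(indicators)
    brackets = age_to_bracket(np.asarray(age, dtype=float))
    prof = np.full((len(category_names), len(AGE_BRACKET_LABELS)), np.nan)
    for b in range(len(AGE_BRACKET_LABELS)):
        mask = brackets == b
        if mask.any():
            prof[:, b] = ind[mask].mean(axis=0)
    return pd.DataFrame(prof, index=list(category_names), columns=AGE_BRACKET_LABELS)


def kmeans_age_profiles(
    profile: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """Cluster disease prevalence-over-age profiles with k-means.

    Euclidean distance on the bracket-prevalence rows; multi-start with the
    lowest within-cluster sum of squares kept.  Returns one label per
    category row.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(profile, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of categories")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)
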