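"""Disease co-occurrence networks over the Elixhauser categories.

Two edge weightings are supported, matching the two uses of the network:

* ``rr`` mode (whole-cohort discovery): the edge statistic is the relative
  risk of co-occurrence RR_ij = C_ij * N / (P_i * P_j) — the observed pair
  count over the count expected under independence — and edges are filtered
  by a significance test on the 2x2 co-occurrence table.
* ``normalized`` mode (within-subgroup description): the edge weight is the
  pair count normalized to the subgroup size, C_ij / N_subgroup, with no
  significance filter.  RR is avoided there because it understates the
  co-occurrence of highly prevalent diseases.

The default significance test is Fisher's exact test (two-sided); a
chi-square alternative without continuity correction is available as a
config switch, as is optional Benjamini-Hochberg correction (off by
default, matching the plain p < alpha threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkEdge:
    cat_a: str
    cat_b: str
    count: int
    weight: float
    p_value: float | None
    retained: bool


@dataclass
class ComorbidityNetwork:
    """Nodes with prevalence, edges with RR or normalized weight."""

    category_names: tuple[str, ...]
    mode: str
    n: int
    prevalence: np.ndarray  # (30,) fractions in [0, 1]
    edges: list[NetworkEdge]

    def to_edge_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cat_a": [e.cat_a for e in self.edges],
                "cat_b": [e.cat_b for e in self.edges],
                "count": [e.count for e in self.edges],
                "weight": [e.weight for e in self.edges],
                "p_value": [e.p_value for e in self.edges],
                "retained": [e.retained for e in self.edges],
            }
        )

    def to_graph(self, retained_only: bool = True) -> nx.Graph:
        g = nx.Graph(mode=self.mode, n=self.n)
        for name, prev in zip(self.category_names, self.prevalence):
            g.add_node(name, prevalence=float(prev))
        for e in self.edges:
            if retained_only and not e.retained:
                continue
            attrs = {"weight": e.weight, "count": e.count, "mode": self.mode}
            if e.p_value is not None:
                attrs["p_value"] = e.p_value
            g.add_edge(e.cat_a, e.cat_b, **attrs)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)

    def write_edge_csv(self, path) -> None:
        self.to_edge_dataframe().to_csv(path, index=False)


def cooccurrence_counts(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column counts P_i and pair counts C_ij from an N x 30 binary matrix.

    C is symmetric with C_ii = P_i.
    """
    matrix = np.asarray(matrix)
    if matrix.size and not np.isin(matrix, (0, 1)).all():
        raise ValueError("indicator matrix must be binary")
    m = matrix.astype(np.int64)
    C = m.T @ m
    return np.diag(C).copy(), C


def relative_risk(C_ij: int, P_i: int, P_j: int, N: int) -> float:
    """RR_ij = C_ij * N / (P_i * P_j); 0 when either marginal is 0."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if C_ij > min(P_i, P_j):
        raise ValueError("pair count exceeds a marginal count")
    if P_i == 0 or P_j == 0:
        return 0.0
    return float(C_ij) * N / (float(P_i) * float(P_j))


def edge_significance(
    C_ij: int, P_i: int, P_j: int, N: int, test: str = "fisher"
) -> float:
    """Two-sided p-value for association on the 2x2 co-occurrence table.

    The table is [[C_ij, P_i - C_ij], [P_j - C_ij, N - P_i - P_j + C_ij]].
    ``test`` is ``"fisher"`` (exact, default) or ``"chi2"`` (Pearson without
    continuity correction).
    """
    a = C_ij
    b = P_i - C_ij
    c = P_j - C_ij
    d = N - P_i - P_j + C_ij
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts: negative cell in 2x2 table")
    table = np.array([[a, b], [c, d]])
    if test == "fisher":
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    if test == "chi2":
        if table.sum() == 0:
            return 1.0
        # expected-zero rows/columns carry no information
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return 1.0
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(p)
    raise ValueError(f"unknown significance test {test!r}")


def build_network(
    matrix: np.ndarray,
    category_names: tuple[str, ...] | list[str],
    mode: str = "rr",
    alpha: float = 0.05,
    scope_size: int | None = None,
    test: str = "fisher",
    bh_correct: bool = False,
) -> ComorbidityNetwork:
    """Build the co-occurrence network for one population scope.

    ``matrix`` must already be restricted to the intended population (whole
    cohort or one subgroup); ``scope_size`` defaults to its row count.
    In ``rr`` mode edges with p < alpha are retained with weight RR; in
    ``normalized`` mode every positive-count edge is retained with weight
    C_ij / scope_size and no test is run.  Zero-count pairs are never
    emitted; pairs are stored once in lexicographic category order.
    """
    if mode not in ("rr", "normalized"):
        raise ValueError(f"unknown network mode {mode!r}")
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != len(category_names):
        raise ValueError("matrix columns must match category names")
    N = matrix.shape[0] if scope_size is None else int(scope_size)
    P, C = cooccurrence_counts(matrix)
    prevalence = P / N if N > 0 else np.zeros_like(P, dtype=float)

    order = np.argsort(np.asarray(category_names))
    edges: list[NetworkEdge] = []
    pvals: list[float] = []
    raw: list[tuple[str, str, int, float]] = []
    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            cij = int(C[i, j])
            if cij == 0:
                continue
            if mode == "rr":
                w = relative_risk(cij, int(P[i]), int(P[j]), N)
                pvals.append(edge_significance(cij, int(P[i]), int(P[j]), N, test))
            else:
                w = cij / N
            raw.append((category_names[i], category_names[j], cij, w))

    if mode == "rr":
        pv = np.asarray(pvals)
        if bh_correct and len(pv):
            from statsmodels.stats.multitest import multipletests

            retained = multipletests(pv, alpha=alpha, method="fdr_bh")[0]
            logger.info("Benjamini-Hochberg correction applied to %d edges", len(pv))
        elif alpha >= 1.0:
            retained = np.ones(len(pv), dtype=bool)  # vacuous filter
        else:
            retained = pv < alpha
        for (a, b, cij, w), p, keep in zip(raw, pv, retained):
            edges.append(NetworkEdge(a, b, cij, w, float(p), bool(keep)))
    else:
        for a, b, cij, w in raw:
            edges.append(NetworkEdge(a, b, cij, w, None, True))

    return ComorbidityNetwork(
        category_names=tuple(category_names),
        mode=mode,
        n=N,
        prevalence=prevalence,
        edges=edges,
    )
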