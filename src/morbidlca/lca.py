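"""Latent class analysis for categorical cohort data, fitted by EM.

The model is a finite mixture over J categorical variables assuming
conditional independence given an unobserved class (the classical latent
class model).  For patient i with observed levels x_i = (x_i1, ..., x_iJ):

    P(x_i) = sum_k  pi_k  prod_j  rho_{k j x_ij}

where pi are the K mixing proportions and rho_{kj.} is the class-conditional
level distribution of variable j.  Here the variables are the 30 binary
Elixhauser morbidity indicators, a 5-level age bracket, and the binary
admission type (elective vs non-elective).

Fitting uses expectation-maximization with multiple random restarts:
responsibilities are initialized row-wise from a flat Dirichlet, followed by
an M-step.  The E- and M-steps are computed on a one-hot encoding so each
iteration is two dense matrix products, which keeps cohort-scale fits
(N ~ 36k, J = 32) in the seconds range.  All randomness flows from a single
seed through ``numpy.random.SeedSequence`` spawning, so fits are exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: left edges of the age brackets (years); right-open, last bracket unbounded
AGE_BRACKET_EDGES = (16.0, 25.0, 45.0, 65.0, 85.0)
AGE_BRACKET_LABELS = ("16-24", "25-44", "45-64", "65-84", "85+")

PROB_FLOOR = 1e-6


@dataclass(frozen=True)
class CategoricalDataset:
    """N patients by J categorical variables, stored as level indices."""

    variable_names: tuple[str, ...]
    n_levels: np.ndarray  # (J,) ints
    values: np.ndarray  # (N, J) ints, values[i, j] in [0, n_levels[j])

    def __post_init__(self):
        J = len(self.variable_names)
        if self.values.ndim != 2 or self.values.shape[1] != J:
            raise ValueError("values must be N x J")
        if len(self.n_levels) != J:
            raise ValueError("n_levels must have one entry per variable")
        if self.values.size and (
            (self.values < 0).any() or (self.values >= self.n_levels).any()
        ):
            raise ValueError("value out of range for its variable")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def one_hot(self) -> np.ndarray:
        """(N, sum_j C_j) dense 0/1 encoding, variables in block order."""
        offsets = np.concatenate([[0], np.cumsum(self.n_levels)])
        out = np.zeros((self.n, offsets[-1]), dtype=np.float64)
        rows = np.arange(self.n)
        for j in range(self.n_variables):
            out[rows, offsets[j] + self.values[:, j]] = 1.0
        return out


def age_to_bracket(age: np.ndarray) -> np.ndarray:
    """Map ages in years to the 5 bracket indices (16-24 ... 85+)."""
    age = np.asarray(age, dtype=float)
    if (age < AGE_BRACKET_EDGES[0]).any():
        raise ValueError("ages below 16 are outside the cohort definition")
    return (np.searchsorted(AGE_BRACKET_EDGES, age, side="right") - 1).astype(np.int64)


def prepare_dataset(
    indicators: np.ndarray,
    category_names: tuple[str, ...] | list[str],
    age: np.ndarray,
    elective: np.ndarray,
) -> CategoricalDataset:
    """Assemble the LCA input: 30 binary indicators + age bracket + admission.

    Rows with any missing value are dropped with a logged count (the model
    has no missing-data mechanism).
    """
    indicators = np.asarray(indicators)
    age = np.asarray(age, dtype=float)
    elective = np.asarray(elective)
    mask = (
        ~np.isnan(age)
        & ~np.isnan(indicators.astype(float)).any(axis=1)
        & ~np.isnan(elective.astype(float))
    )
    if (~mask).any():
        logger.warning("dropping %d rows with missing covariates", int((~mask).sum()))
        indicators, age, elective = indicators[mask], age[mask], elective[mask]
    values = np.column_stack(
        [
            indicators.astype(np.int64),
            age_to_bracket(age),
            elective.astype(np.int64),
        ]
    )
    names = tuple(category_names) + ("age_bracket", "admission_type")
    n_levels = np.array([2] * len(category_names) + [len(AGE_BRACKET_LABELS), 2])
    return CategoricalDataset(names, n_levels, values)


@dataclass
class LCAModel:
    """A fitted latent class model.

    ``rho`` is stored per variable as a (K, C_j) array, aligned with the
    dataset's variable order.
    """

    K: int
    pi: np.ndarray  # (K,)
    rho: list[np.ndarray]  # J arrays of shape (K, C_j)
    loglik: float = np.nan
    n_params: int = 0
    aic: float = np.nan
    bic: float = np.nan
    n_restarts: int = 0
    seed: int | None = None
    converged: bool = False
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    all_traces: list = field(default_factory=list, repr=False)

    @property
    def n_variables(self) -> int:
        return len(self.rho)

    def _check(self, data: CategoricalDataset) -> None:
        if data.n_variables != self.n_variables:
            raise ValueError("model/data variable count mismatch")
        for j, r in enumerate(self.rho):
            if r.shape != (self.K, data.n_levels[j]):
                raise ValueError(f"rho shape mismatch at variable {j}")

    def _log_components(self) -> np.ndarray:
        """log rho flattened to (sum_j C_j, K) for the one-hot product."""
        return np.log(np.concatenate([r.T for r in self.rho], axis=0))

    def permuted(self, perm: np.ndarray) -> "LCAModel":
        """Return a copy with classes reordered as ``perm`` (new k = old perm[k])."""
        perm = np.asarray(perm)
        return LCAModel(
            K=self.K,
            pi=self.pi[perm].copy(),
            rho=[r[perm].copy() for r in self.rho],
            loglik=self.loglik,
            n_params=self.n_params,
            aic=self.aic,
            bic=self.bic,
            n_restarts=self.n_restarts,
            seed=self.seed,
            converged=self.converged,
            n_iter=self.n_iter,
            loglik_trace=self.loglik_trace,
        )


@dataclass(frozen=True)
class Responsibilities:
    """Posterior class-membership probabilities and hard labels."""

    gamma: np.ndarray  # (N, K), rows sum to 1
    hard_assignment: np.ndarray  # (N,) argmax, lowest index on ties


def n_free_parameters(K: int, n_levels: np.ndarray) -> int:
    """d = (K - 1) + K * sum_j (C_j - 1)."""
    return (K - 1) + K * int(np.sum(np.asarray(n_levels) - 1))


def information_criteria(loglik: float, d: int, N: int) -> tuple[float, float]:
    """AIC = -2 LL + 2d;  BIC = -2 LL + d ln N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    aic = -2.0 * loglik + 2.0 * d
    bic = -2.0 * loglik + d * np.log(N)
    return aic, bic


def _log_joint(model: LCAModel, one_hot: np.ndarray) -> np.ndarray:
    """(N, K) array of log pi_k + sum_j log rho_{kj x_ij}."""
    return one_hot @ model._log_components() + np.log(model.pi)


def log_likelihood(model: LCAModel, data: CategoricalDataset) -> float:
    """Observed-data log-likelihood, computed in log space."""
    model._check(data)
    if data.n == 0:
        return 0.0
    return float(logsumexp(_log_joint(model, data.one_hot()), axis=1).sum())


def posterior(model: LCAModel, data: CategoricalDataset) -> Responsibilities:
    """Posterior responsibilities gamma_ik and hard argmax labels."""
    model._check(data)
    lj = _log_joint(model, data.one_hot())
    gamma = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
    return Responsibilities(gamma=gamma, hard_assignment=np.argmax(gamma, axis=1))


def _m_step(
    gamma: np.ndarray,
    one_hot: np.ndarray,
    n_levels: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Closed-form M-step with probability flooring to avoid log(0).

    ``gamma`` has one row per unique response pattern; ``weights`` carries
    each pattern's multiplicity (weighted EM over unique patterns is exact
    and much cheaper than per-patient EM on large cohorts).
    """
    gw = gamma * weights[:, None]
    pi = gw.sum(axis=0) / weights.sum()
    pi = np.maximum(pi, PROB_FLOOR)
    pi /= pi.sum()
    counts = gw.T @ one_hot  # (K, sum C_j)
    offsets = np.concatenate([[0], np.cumsum(n_levels)])
    rho = []
    for j, C in enumerate(n_levels):
        block = counts[:, offsets[j]: offsets[j + 1]]
        block = np.maximum(block, 0.0) + 0.0
        denom = block.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            r = np.where(denom > 0, block / np.maximum(denom, 1e-300), 1.0 / C)
        r = np.maximum(r, PROB_FLOOR)
        r /= r.sum(axis=1, keepdims=True)
        rho.append(r)
    return pi, rho


def _single_em(
    one_hot: np.ndarray,
    n_levels: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    weights: np.ndarray,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, bool]:
    n_patterns = one_hot.shape[0]
    gamma0 = rng.dirichlet(np.ones(K), size=n_patterns)
    pi, rho = _m_step(gamma0, one_hot, n_levels, weights)
    log_pi = np.log(pi)
    trace = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        logrho_flat = np.log(np.concatenate([r.T for r in rho], axis=0))
        lj = one_hot @ logrho_flat + log_pi
        # manual log-sum-exp: K is tiny, so this beats the library call
        mx = lj.max(axis=1, keepdims=True)
        norm = mx + np.log(np.exp(lj - mx).sum(axis=1, keepdims=True))
        ll = float((norm[:, 0] * weights).sum())
        trace.append(ll)
        gamma = np.exp(lj - norm)
        pi, rho = _m_step(gamma, one_hot, n_levels, weights)
        log_pi = np.log(pi)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = ll
    return pi, rho, np.array(trace), converged


def em_fit(
    data: CategoricalDataset,
    K: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> tuple[LCAModel, Responsibilities]:
    """Fit a K-class latent class model, keeping the best of ``n_restarts``.

    Each restart draws its own substream from ``seed``; the best final
    log-likelihood wins.  The returned model's ``loglik_trace`` holds the
    winning restart's EM trace (non-decreasing up to floating-point noise).
    If no restart converges within ``max_iter`` the best model is still
    returned with ``converged=False`` and a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if data.n <= K:
        raise ValueError("need more patients than classes")
    n_levels = np.asarray(data.n_levels)
    # EM over unique response patterns with multiplicity weights: exact,
    # and typically 2-3x cheaper on cohort-scale categorical data
    uniq, counts = np.unique(data.values, axis=0, return_counts=True)
    compact = CategoricalDataset(data.variable_names, n_levels, uniq)
    one_hot = compact.one_hot()
    weights = counts.astype(np.float64)
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    all_traces = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        pi, rho, trace, conv = _single_em(
            one_hot, n_levels, K, rng, max_iter, tol, weights
        )
        all_traces.append(trace)
        if best is None or trace[-1] > best[2][-1]:
            best = (pi, rho, trace, conv)
    pi, rho, trace, conv = best
    if not conv:
        logger.warning("no EM restart converged within %d iterations", max_iter)
    d = n_free_parameters(K, n_levels)
    model = LCAModel(
        K=K, pi=pi, rho=rho, n_params=d, n_restarts=n_restarts, seed=seed,
        converged=conv, n_iter=len(trace), loglik_trace=trace,
        all_traces=all_traces,
    )
    model.loglik = log_likelihood(model, data)
    model.aic, model.bic = information_criteria(model.loglik, d, data.n)
    return model, posterior(model, data)
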