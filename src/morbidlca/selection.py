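"""Model-order selection and class alignment.

The number of latent classes is chosen by a joint rule: fit each candidate
K, discard candidates whose smallest subgroup (by hard assignment) falls
below a minimum fraction of the cohort, then pick the lowest BIC among the
survivors, breaking ties by AIC.  When BIC and AIC disagree about the best
surviving candidate, BIC wins and the disagreement is logged.

Class labels of a mixture are only identified up to permutation ("label
switching"); :func:`align_classes` resolves it by optimal assignment on the
L1 distance between class-conditional probability profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .lca import CategoricalDataset, LCAModel, Responsibilities, em_fit

logger = logging.getLogger(__name__)


@dataclass
class Candidate:
    K: int
    model: LCAModel
    responsibilities: Responsibilities
    smallest_class_frac: float
    rejected: bool = False
    rejection_reason: str | None = None


@dataclass
class SelectionReport:
    candidates: list[Candidate]
    chosen_K: int | None
    min_class_frac: float
    rejection_reasons: dict[int, str] = field(default_factory=dict)

    @property
    def chosen(self) -> Candidate | None:
        for c in self.candidates:
            if c.K == self.chosen_K:
                return c
        return None

    def table(self):
        """Per-K summary (K, loglik, AIC, BIC, smallest class fraction)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "K": [c.K for c in self.candidates],
                "loglik": [c.model.loglik for c in self.candidates],
                "aic": [c.model.aic for c in self.candidates],
                "bic": [c.model.bic for c in self.candidates],
                "smallest_class_frac": [
                    c.smallest_class_frac for c in self.candidates
                ],
                "rejected": [c.rejected for c in self.candidates],
            }
        )


def select_k(
    data: CategoricalDataset,
    k_min: int = 2,
    k_max: int = 8,
    min_class_frac: float = 0.05,
    n_restarts: int = 20,
    seed: int = 0,
) -> SelectionReport:
    """Fit K = k_min..k_max and choose by lowest BIC subject to the
    minimum-subgroup-size constraint.

    Every candidate K gets an independent seed substream derived from
    ``seed``, so the report is reproducible.  If every candidate violates
    the size floor, ``chosen_K`` is None and the reasons are recorded.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    if not (0 <= min_class_frac < 1):
        raise ValueError("min_class_frac must be in [0, 1)")
    streams = np.random.SeedSequence(seed).spawn(k_max - k_min + 1)
    candidates: list[Candidate] = []
    for K, ss in zip(range(k_min, k_max + 1), streams):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        model, resp = em_fit(data, K, n_restarts=n_restarts, seed=sub_seed)
        sizes = np.bincount(resp.hard_assignment, minlength=K)
        frac = float(sizes.min()) / data.n
        candidates.append(Candidate(K, model, resp, frac))

    reasons: dict[int, str] = {}
    for c in candidates:
        if c.smallest_class_frac < min_class_frac:
            c.rejected = True
            c.rejection_reason = (
                f"smallest class fraction {c.smallest_class_frac:.4f} "
                f"< {min_class_frac}"
            )
            reasons[c.K] = c.rejection_reason

    survivors = [c for c in candidates if not c.rejected]
    chosen_K = None
    if survivors:
        by_bic = min(survivors, key=lambda c: (c.model.bic, c.K))
        by_aic = min(survivors, key=lambda c: (c.model.aic, c.K))
        if by_aic.K != by_bic.K:
            logger.info(
                "AIC prefers K=%d but BIC prefers K=%d; choosing by BIC",
                by_aic.K, by_bic.K,
            )
        chosen_K = by_bic.K
    else:
        logger.warning("all candidate K rejected by the class-size floor")

    # soft sanity check: best-of-restarts loglik should not decrease in K
    lls = [c.model.loglik for c in candidates]
    if any(lls[i + 1] < lls[i] - 1e-6 for i in range(len(lls) - 1)):
        logger.info(
            "log-likelihood not monotone in K; multi-start may have missed "
            "an optimum for some K"
        )
    return SelectionReport(candidates, chosen_K, min_class_frac, reasons)


def _profile_matrix(obj, binary_only: bool = False) -> np.ndarray:
    """(K, P) matrix of class-conditional probabilities for alignment.

    Accepts an :class:`LCAModel` (concatenates all rho blocks) or any object
    with a ``prevalence_matrix`` attribute/method such as a generator
    config (classes x categories Bernoulli means, mapped to the binary
    blocks only).
    """
    if isinstance(obj, LCAModel):
        if binary_only:
            blocks = [r[:, 1:2] for r in obj.rho if r.shape[1] == 2]
        else:
            blocks = obj.rho
        return np.concatenate(blocks, axis=1)
    prev = getattr(obj, "prevalence_matrix", None)
    if prev is None:
        raise TypeError(f"cannot extract class profiles from {type(obj)!r}")
    prev = prev() if callable(prev) else prev
    return np.asarray(prev, dtype=float)


def align_classes(estimated, reference) -> np.ndarray:
    """Match estimated classes to reference classes by optimal assignment.

    Returns ``perm`` with ``perm[g]`` = index of the estimated class matched
    to reference class g, minimizing the total L1 distance between matched
    class-conditional probability profiles (Hungarian algorithm).  When the
    reference is a generator config, only the binary morbidity blocks are
    compared (the config states Bernoulli prevalences, not bracket
    distributions).

    ``align_classes(a, b)`` and ``align_classes(b, a)`` are inverse
    permutations of each other.
    """
    both_models = isinstance(reference, LCAModel) and isinstance(estimated, LCAModel)
    est = _profile_matrix(estimated, binary_only=not both_models)
    ref = _profile_matrix(reference, binary_only=not both_models)
    if not both_models:
        # config references state morbidity prevalences only; the dataset
        # orders the morbidity indicators first, so truncate trailing
        # binary covariates (admission type)
        est = est[:, : ref.shape[1]]
        ref = ref[:, : est.shape[1]]
    if est.shape[0] != ref.shape[0]:
        raise ValueError("class counts differ; cannot align")
    if est.shape[1] != ref.shape[1]:
        raise ValueError("profile dimensions differ; cannot align")
    cost = np.abs(ref[:, None, :] - est[None, :, :]).sum(axis=2)
    ref_idx, est_idx = linear_sum_assignment(cost)
    perm = np.empty(est.shape[0], dtype=np.int64)
    perm[ref_idx] = est_idx
    return perm
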