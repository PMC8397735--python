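"""Variance-maximizing training/test split of the snapshot epochs.

Rather than splitting the snapshot epochs at random, candidate training
subsets are kept only if their forcing covariance dominates that of the full
set — i.e. every eigenvalue of the subset covariance (sorted descending) is
at least the corresponding eigenvalue of the full covariance. Epochs are then
ranked by how often they appear in accepted candidates, and the top fraction
forms the training set. This pushes the training set to the edges of the
forcing phase space, so the fitted regressions interpolate (rather than
extrapolate) on held-out epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["SelectionConfig", "SelectionResult", "candidate_check", "select_training"]


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the resampling split.

    train_fraction in (0, 1]; k = round(train_fraction * n) with 0.5 rounding
    up (0.8 * 72 = 57.6 -> 58). n_iterations is the number of random subsets
    drawn; method="exhaustive" instead enumerates every k-subset (small n
    only), which makes n_iterations irrelevant.
    """

    train_fraction: float = 0.8
    n_iterations: int = 10_000
    seed: int = 0
    method: str = "random"  # "random" | "exhaustive"

    def __post_init__(self):
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.method not in ("random", "exhaustive"):
            raise ValueError("method must be 'random' or 'exhaustive'")

    def train_size(self, n_total: int) -> int:
        # round-half-up
        return int(np.floor(self.train_fraction * n_total + 0.5))


@dataclass
class SelectionResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    appearance_counts: np.ndarray
    candidate_count: int
    config: SelectionConfig = field(repr=False, default=None)

    def __post_init__(self):
        overlap = np.intersect1d(self.train_indices, self.test_indices)
        if overlap.size:
            raise ValueError("train and test indices overlap")


def candidate_check(sample_cov: np.ndarray, full_cov: np.ndarray, *, rtol: float = 1e-12) -> bool:
    """True iff the sample covariance spectrum dominates the full spectrum.

    Both eigenvalue lists are sorted descending; the check passes iff every
    sample eigenvalue is >= the corresponding full eigenvalue (equality
    passes: the full set dominates itself).
    """
    sample_cov = np.asarray(sample_cov, dtype=float)
    full_cov = np.asarray(full_cov, dtype=float)
    if sample_cov.shape != full_cov.shape or sample_cov.ndim != 2:
        raise ValueError("covariance matrices must be square and of equal dimension")
    for name, m in (("sample_cov", sample_cov), ("full_cov", full_cov)):
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError(f"{name} is not symmetric to 1e-10")
    ev_sample = np.sort(np.linalg.eigvalsh(sample_cov))[::-1]
    ev_full = np.sort(np.linalg.eigvalsh(full_cov))[::-1]
    scale = max(abs(ev_full[0]), abs(ev_sample[0]), 1e-300)
    return bool(np.all(ev_sample >= ev_full - rtol * scale))


def select_training(
    forcing_block: np.ndarray,
    config: SelectionConfig,
    epochs: np.ndarray | None = None,
) -> SelectionResult:
    """Split n epochs into training/test by the eigenvalue-dominance ranking.

    forcing_block is the (n, p) matrix of continuous forcing values at the
    snapshot epochs (not necessarily normalized; covariance is scale-aware
    but the verdicts are identical either way per subset). ``epochs`` (ka BP)
    is used only to break ranking ties toward the older epoch; without it,
    ties go to the lower row index.

    Deterministic given ``config.seed``.
    """
    X = np.asarray(forcing_block, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} epochs, got {n}")
    k = config.train_size(n)

    if k == n:
        return SelectionResult(
            train_indices=np.arange(n),
            test_indices=np.array([], dtype=int),
            appearance_counts=np.ones(n, dtype=int),
            candidate_count=1,
            config=config,
        )

    full_cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    ev_full = np.sort(np.linalg.eigvalsh(full_cov))[::-1]
    scale = max(abs(ev_full[0]), 1e-300)

    counts = np.zeros(n, dtype=np.int64)
    n_candidates = 0

    if config.method == "exhaustive":
        subsets = (np.array(c) for c in combinations(range(n), k))
    else:
        rng = np.random.default_rng(config.seed)
        subsets = (rng.choice(n, size=k, replace=False) for _ in range(config.n_iterations))

    for idx in subsets:
        sub_cov = np.atleast_2d(np.cov(X[idx], rowvar=False, ddof=1))
        ev_s = np.sort(np.linalg.eigvalsh(sub_cov))[::-1]
        if np.all(ev_s >= ev_full - 1e-12 * scale):
            counts[idx] += 1
            n_candidates += 1

    if n_candidates == 0:
        raise RuntimeError(
            "no candidate training subsets found; increase n_iterations or "
            "lower train_fraction"
        )

    # rank by count descending; ties to the older epoch (larger ka BP),
    # falling back to lower index
    if epochs is not None:
        tiebreak = -np.asarray(epochs, dtype=float)
    else:
        tiebreak = np.arange(n, dtype=float)
    order = np.lexsort((tiebreak, -counts))
    train = np.sort(order[:k])
    test = np.sort(order[k:])
    return SelectionResult(
        train_indices=train,
        test_indices=test,
        appearance_counts=counts,
        candidate_count=n_candidates,
        config=config,
    )
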