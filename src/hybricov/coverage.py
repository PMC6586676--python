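"""Maternal-lineage and sex determination from sequencing coverage.

Maternal lineage is called by competitive mitochondrial mapping: the same
reads are mapped to each candidate species' mitogenome and the reference
with markedly higher mean coverage (fold ratio at least ``min_fold``)
indicates the maternal species.

Karyotypic sex comes from the X:autosome coverage ratio. With one X
chromosome a male's X-linked depth is about half his autosomal depth
(ratio ~0.5); a female's is about equal (~1.0). The ratio is estimated by
repeatedly resampling sites from each partition, averaging depth within
a replicate, and summarizing the replicate ratios by empirical quantiles
(5%, 25%, 75%, 95%). The call is male when the 5–95% band lies below the
decision boundary (default 0.75, the midpoint between the two cluster
centers), female when above, ambiguous when it straddles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "CoverageProfile",
    "MitoCoverageComparison",
    "RatioEstimate",
    "maternal_lineage",
    "x_autosome_ratio",
    "sex_call",
    "SexClassifier",
]


@dataclass
class CoverageProfile:
    """Per-site depths split into X-linked and autosomal partitions.

    ``x_weights`` / ``auto_weights`` optionally weight each entry (e.g.
    scaffold mean depths weighted by scaffold length when only per-
    scaffold summaries are available); unweighted entries are per-site
    depths sampled uniformly.
    """

    x_depths: np.ndarray
    auto_depths: np.ndarray
    x_weights: Optional[np.ndarray] = None
    auto_weights: Optional[np.ndarray] = None
    provenance: str = "input"

    def __post_init__(self) -> None:
        self.x_depths = np.asarray(self.x_depths, dtype=float)
        self.auto_depths = np.asarray(self.auto_depths, dtype=float)
        if self.x_depths.size == 0 or self.auto_depths.size == 0:
            raise ValueError("both X and autosomal partitions must be nonempty")


@dataclass(frozen=True)
class MitoCoverageComparison:
    coverage_a: float
    coverage_b: float
    fold_ratio: float
    call: str  # "A", "B" or "ambiguous"


@dataclass(frozen=True)
class RatioEstimate:
    ratios: np.ndarray
    point: float
    q05: float
    q25: float
    q75: float
    q95: float

    def interval(self) -> tuple[float, float]:
        return self.q05, self.q95


def maternal_lineage(
    cov_a: float, cov_b: float, min_fold: float = 2.0
) -> MitoCoverageComparison:
    """Call the maternal species from competitive mitogenome coverages.

    Scale-invariant: only the fold ratio max/min matters. Both coverages
    zero is an error; a single zero gives an infinite fold ratio and a
    confident call.
    """
    if cov_a < 0 or cov_b < 0:
        raise ValueError("coverages must be nonnegative")
    if cov_a == 0 and cov_b == 0:
        raise ValueError("both mitochondrial coverages are zero")
    lo, hi = sorted((cov_a, cov_b))
    fold = np.inf if lo == 0 else hi / lo
    call = "ambiguous" if fold < min_fold else ("A" if cov_a > cov_b else "B")
    return MitoCoverageComparison(cov_a, cov_b, float(fold), call)


def _resample_means(
    values: np.ndarray,
    weights: Optional[np.ndarray],
    n_reps: int,
    sites_per_rep: int,
    rng: np.random.Generator,
) -> np.ndarray:
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    idx = rng.choice(values.size, size=(n_reps, sites_per_rep), replace=True, p=p)
    return values[idx].mean(axis=1)


def x_autosome_ratio(
    profile: CoverageProfile,
    n_reps: int = 100,
    sites_per_rep: int = 10_000,
    seed=None,
) -> RatioEstimate:
    """Resampled X:autosome mean-depth ratio with empirical quantiles.

    Each replicate draws ``sites_per_rep`` sites with replacement from
    each partition and forms the ratio of mean depths; the point estimate
    is the mean of the replicate ratios. Defaults (10^4 sites x 100
    replicates) are a desk-scale version of genome-wide resampling.
    """
    if n_reps < 1 or sites_per_rep < 1:
        raise ValueError("n_reps and sites_per_rep must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_means = _resample_means(profile.x_depths, profile.x_weights, n_reps, sites_per_rep, rng)
    a_means = _resample_means(
        profile.auto_depths, profile.auto_weights, n_reps, sites_per_rep, rng
    )
    if np.any(a_means == 0):
        raise ValueError("a resampling replicate had zero autosomal depth; use more sites")
    ratios = x_means / a_means
    q05, q25, q75, q95 = np.quantile(ratios, [0.05, 0.25, 0.75, 0.95])
    return RatioEstimate(
        ratios=ratios,
        point=float(ratios.mean()),
        q05=float(q05),
        q25=float(q25),
        q75=float(q75),
        q95=float(q95),
    )


def sex_call(estimate: RatioEstimate, boundary: float = 0.75) -> str:
    """Male / female / ambiguous from the 5-95% ratio interval."""
    if estimate.q95 < boundary:
        return "male"
    if estimate.q05 > boundary:
        return "female"
    return "ambiguous"


class SexClassifier(BaseEstimator):
    """Sex determination from an X/autosome coverage profile.

    ``fit`` computes the resampled ratio estimate (``estimate_``,
    ``ratio_``) and the call (``sex_``); ``predict`` maps one or more
    profiles to labels.
    """

    def __init__(
        self,
        n_reps: int = 100,
        sites_per_rep: int = 10_000,
        boundary: float = 0.75,
        random_state: Optional[int] = None,
    ):
        self.n_reps = n_reps
        self.sites_per_rep = sites_per_rep
        self.boundary = boundary
        self.random_state = random_state

    def fit(self, X: CoverageProfile, y=None):
        self.estimate_ = x_autosome_ratio(
            X, n_reps=self.n_reps, sites_per_rep=self.sites_per_rep, seed=self.random_state
        )
        self.ratio_ = self.estimate_.point
        self.sex_ = sex_call(self.estimate_, boundary=self.boundary)
        return self

    def predict(self, X) -> list[str]:
        profiles = [X] if isinstance(X, CoverageProfile) else list(X)
        rng = np.random.default_rng(self.random_state)
        calls = []
        for prof in profiles:
            est = x_autosome_ratio(
                prof, n_reps=self.n_reps, sites_per_rep=self.sites_per_rep, seed=rng
            )
            calls.append(sex_call(est, boundary=self.boundary))
        return calls
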