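"""Alpha-diversity estimation from per-sample OTU count vectors.

Inputs begin at OTU abundance vectors (reads per OTU for one sample) —
clustering reads into OTUs is upstream of this package. Implemented
estimators:

* Good's coverage, 100·(1 − f1/N): the estimated percent probability that
  one more read would fall in an already-observed OTU;
* Chao1 minimum-richness, bias-corrected S_obs + f1(f1−1)/(2(f2+1)) by
  default or classic S_obs + f1²/(2 f2), with the log-normal confidence
  interval of the estimator literature;
* Shannon's H (natural log by default) with a normal-approximation CI using
  the standard variance with a small-sample correction term.

A fixed-depth subsample (multivariate hypergeometric draw without
replacement) makes reports comparable across samples of unequal depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "OTUVector",
    "DiversityReport",
    "goods_coverage",
    "chao1",
    "shannon",
    "subsample",
    "diversity_report",
]


@dataclass(frozen=True)
class OTUVector:
    """Reads per observed OTU for a single sample (all counts ≥ 1)."""

    sample_name: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("OTU vector must contain at least one OTU")
        if any(c < 1 or int(c) != c for c in self.counts):
            raise ValueError("OTU counts must be positive integers")

    @property
    def n_reads(self) -> int:
        return int(sum(self.counts))

    @property
    def s_obs(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class DiversityReport:
    """Per-sample alpha-diversity summary.

    ``chao1_form`` records which estimator variant (and hence which
    variance formula) produced the interval.
    """

    sample_name: str
    reads: int
    coverage: float
    s_obs: int
    chao1: float
    chao1_ci: tuple[float, float]
    shannon: float
    shannon_ci: tuple[float, float]
    max_otu_percent: float
    chao1_form: str
    depth: int | None = None
    seed: int | None = None


def goods_coverage(v: OTUVector) -> float:
    """Good's coverage as a percent: 100·(1 − singletons/reads)."""
    f1 = sum(1 for c in v.counts if c == 1)
    return 100.0 * (1.0 - f1 / v.n_reads)


def _chao1_variance(s_obs: int, f1: int, f2: int, estimate: float, bias_corrected: bool) -> float:
    # variance formulas from the estimator's literature, per form and f2 case
    if f1 == 0:
        return 0.0
    if bias_corrected:
        if f2 > 0:
            return (
                f1 * (f1 - 1) / (2.0 * (f2 + 1))
                + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
                + f1**2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
            )
        return (
            f1 * (f1 - 1) / 2.0
            + f1 * (2 * f1 - 1) ** 2 / 4.0
            - f1**4 / (4.0 * estimate)
        )
    r = f1 / f2  # classic form requires f2 > 0
    return f2 * (r**2 / 2.0 + r**3 + r**4 / 4.0)


def chao1(
    v: OTUVector, bias_corrected: bool = True, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Chao1 richness estimate with a log-normal confidence interval.

    Bias-corrected (default): S_obs + f1(f1−1)/(2(f2+1)), defined for all
    inputs. Classic: S_obs + f1²/(2 f2), which requires doubletons. The CI
    places a log-normal distribution on T = estimate − S_obs:
    K = exp(z·sqrt(ln(1 + var/T²))), CI = [S_obs + T/K, S_obs + T·K];
    T = 0 collapses the interval to [S_obs, S_obs].
    """
    f1 = sum(1 for c in v.counts if c == 1)
    f2 = sum(1 for c in v.counts if c == 2)
    s_obs = v.s_obs
    if bias_corrected:
        estimate = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        if f2 == 0:
            raise ValueError(
                "classic Chao1 is undefined with no doubletons; "
                "use the bias-corrected form"
            )
        estimate = s_obs + f1 * f1 / (2.0 * f2)
    t = estimate - s_obs
    if t <= 0:
        return estimate, (float(s_obs), float(s_obs))
    var = _chao1_variance(s_obs, f1, f2, estimate, bias_corrected)
    z = sps.norm.ppf((1.0 + conf) / 2.0)
    k = math.exp(z * math.sqrt(math.log(1.0 + var / (t * t))))
    return estimate, (s_obs + t / k, s_obs + t * k)


def shannon(
    v: OTUVector, conf: float = 0.95, base: float = math.e
) -> tuple[float, tuple[float, float]]:
    """Shannon diversity H with a normal-approximation confidence interval.

    H = −Σ pᵢ log pᵢ. The variance is
    (Σ pᵢ (ln pᵢ)² − H²)/N + (S_obs − 1)/(2N²), computed in nats and
    rescaled when a different log base is requested.
    """
    counts = np.asarray(v.counts, dtype=float)
    n = counts.sum()
    p = counts / n
    log_p = np.log(p)
    h_nats = float(-(p * log_p).sum())
    var_nats = float(((p * log_p**2).sum() - h_nats**2) / n) + (v.s_obs - 1) / (
        2.0 * n * n
    )
    var_nats = max(var_nats, 0.0)
    z = sps.norm.ppf((1.0 + conf) / 2.0)
    scale = 1.0 / math.log(base)
    h = h_nats * scale
    half = z * math.sqrt(var_nats) * scale
    return h, (max(0.0, h - half), h + half)


def subsample(v: OTUVector, depth: int, seed: int = 0) -> OTUVector:
    """Draw ``depth`` reads without replacement (rarefy to a fixed depth).

    A multivariate hypergeometric draw; OTUs reduced to zero are dropped.
    Deterministic for a fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth > v.n_reads:
        raise ValueError(
            f"depth {depth} exceeds total reads {v.n_reads} of sample "
            f"{v.sample_name!r}"
        )
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(list(v.counts), depth)
    return OTUVector(
        sample_name=v.sample_name,
        counts=tuple(int(c) for c in drawn if c > 0),
    )


def diversity_report(
    v: OTUVector,
    depth: int | None = None,
    seed: int = 0,
    bias_corrected: bool = True,
    conf: float = 0.95,
    base: float = math.e,
) -> DiversityReport:
    """Full alpha-diversity summary for one sample.

    When ``depth`` is given the vector is subsampled first and every metric
    is computed on the subsample; the report then records depth and seed so
    it can be reproduced bit-for-bit.
    """
    w = subsample(v, depth, seed) if depth is not None else v
    chao, chao_ci = chao1(w, bias_corrected=bias_corrected, conf=conf)
    h, h_ci = shannon(w, conf=conf, base=base)
    return DiversityReport(
        sample_name=v.sample_name,
        reads=w.n_reads,
        coverage=goods_coverage(w),
        s_obs=w.s_obs,
        chao1=chao,
        chao1_ci=chao_ci,
        shannon=h,
        shannon_ci=h_ci,
        max_otu_percent=100.0 * max(w.counts) / w.n_reads,
        chao1_form="bias_corrected" if bias_corrected else "classic",
        depth=depth,
        seed=seed if depth is not None else None,
    )
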