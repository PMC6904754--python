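"""Cross-modality agreement statistics: Bland-Altman and Wilcoxon rank-sum.

Bland-Altman agreement is computed on per-placenta percent differences
100*(MRI - CT)/mean by default (the absolute-difference scale is available
via ``scale="absolute"``), with limits of agreement at bias +/- 1.96 sample
SD.  Two-group comparisons use the Wilcoxon rank-sum (Mann-Whitney) test,
exact by enumeration for small tie-free samples and normal-approximate with
midranks, tie-corrected variance and continuity correction otherwise.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .fbv_pipeline import FBVEstimate
from .core_io import PipelineError

logger = logging.getLogger(__name__)

#: pooled sample size up to which the tie-free exact distribution is used
EXACT_MAX_N = 20


class RankSumMethod(str, enum.Enum):
    EXACT = "EXACT"
    NORMAL_APPROX = "NORMAL_APPROX"


@dataclasses.dataclass
class PairedEstimates:
    """FBV pairs matched by (subject, FPU) across two modalities."""

    keys: list[tuple[str, int]]
    mri: np.ndarray
    ct: np.ndarray
    n_unpaired: int = 0

    def __post_init__(self) -> None:
        self.mri = np.asarray(self.mri, dtype=np.float64)
        self.ct = np.asarray(self.ct, dtype=np.float64)
        if not (len(self.keys) == len(self.mri) == len(self.ct)):
            raise PipelineError("keys, mri and ct must have equal lengths")


@dataclasses.dataclass
class BlandAltmanResult:
    """Per-pair differences with bias and +/- 1.96 SD limits of agreement."""

    diffs: np.ndarray
    mean_bias: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    fraction_within: float
    scale: str = "percent"


@dataclasses.dataclass
class RankSumResult:
    """Wilcoxon rank-sum outcome: statistic, method, p-value and star tier."""

    statistic: float  # rank sum of the first sample
    u_statistic: float
    method: RankSumMethod
    p_two_sided: float
    stars: int


def pair_estimates(
    mri_estimates: Sequence[FBVEstimate], ct_estimates: Sequence[FBVEstimate]
) -> PairedEstimates:
    """Match MRI and CT estimates by (subject, FPU); log the unpaired count."""
    mri_by_key = {(e.subject_id, e.fpu_index): e.fbv for e in mri_estimates}
    ct_by_key = {(e.subject_id, e.fpu_index): e.fbv for e in ct_estimates}
    shared = sorted(set(mri_by_key) & set(ct_by_key))
    n_unpaired = len(set(mri_by_key) ^ set(ct_by_key))
    if n_unpaired:
        logger.warning("excluding %d unpaired FPU estimates", n_unpaired)
    return PairedEstimates(
        keys=list(shared),
        mri=np.array([mri_by_key[k] for k in shared]),
        ct=np.array([ct_by_key[k] for k in shared]),
        n_unpaired=n_unpaired,
    )


def bland_altman(pairs: PairedEstimates, scale: str = "percent") -> BlandAltmanResult:
    """Bland-Altman agreement of MRI against CT FBV.

    ``scale="percent"`` (default) uses per-pair percent differences
    100*(mri - ct)/((mri + ct)/2); ``scale="absolute"`` uses mri - ct.
    ``fraction_within`` is the share of pairs inside the closed interval
    [lower, upper].
    """
    if len(pairs.keys) < 2:
        raise PipelineError(">= 2 pairs required for Bland-Altman analysis")
    if scale == "percent":
        means = (pairs.mri + pairs.ct) / 2.0
        if np.any(means == 0):
            raise PipelineError("a pair with mri + ct = 0 has no percent difference")
        diffs = 100.0 * (pairs.mri - pairs.ct) / means
    elif scale == "absolute":
        diffs = pairs.mri - pairs.ct
    else:
        raise PipelineError(f"scale must be 'percent' or 'absolute', got {scale!r}")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((diffs >= lower) & (diffs <= upper)))
    return BlandAltmanResult(
        diffs=diffs, mean_bias=bias, sd_diff=sd,
        lower_limit=lower, upper_limit=upper,
        fraction_within=within, scale=scale,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled sample is small
    (n_x + n_y <= 20) and tie-free; otherwise the normal approximation with
    midranks, tie-corrected variance, and continuity correction.  The
    reported ``statistic`` is the rank sum of ``x`` in the pooled ranking.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise PipelineError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= EXACT_MAX_N:
        method = RankSumMethod.EXACT
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = RankSumMethod.NORMAL_APPROX
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u = float(res.statistic)
    w = u + x.size * (x.size + 1) / 2.0
    p = float(min(res.pvalue, 1.0))
    return RankSumResult(
        statistic=w, u_statistic=u, method=method,
        p_two_sided=p, stars=significance_stars(p),
    )


def significance_stars(p: float) -> int:
    """Star tiers: 3 if p < 0.0005, 2 if p < 0.005, 1 if p < 0.05, else 0."""
    if not 0.0 < p <= 1.0:
        raise PipelineError(f"p must lie in (0, 1], got {p}")
    if p < 0.0005:
        return 3
    if p < 0.005:
        return 2
    if p < 0.05:
        return 1
    return 0
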