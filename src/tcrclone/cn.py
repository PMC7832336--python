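"""Log2 tumor/normal ratios, absolute copy number, and tumor purity.

Copy number is assigned from the depth-normalized log2 tumor/normal ratio
with fixed cutoffs:

    log2 < -1.1          -> CN 0  (biallelic loss)
    -1.1 <= log2 < -0.25 -> CN 1  (monoallelic loss)
    -0.25 <= log2 < 0.2  -> CN 2  (neutral)
    0.2 <= log2 <= 0.7   -> CN 3
    log2 > 0.7           -> CN 4

Boundaries are owned by the higher copy number (half-open upward; 0.7 goes
to CN 3).  Tumor content is estimated as twice the median somatic VAF of a
diploid tumor, clipped to 1.  For a two-population mixture of tumor at
purity p and diploid normal, the tumor-intrinsic copy number behind an
observed ratio r is  (2*2^r - 2*(1-p)) / p, which the purity adjustment
inverts (floored at 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .segmentation import Segment

#: (upper_bound_exclusive_or_none, cn); scanned in order.
CN_THRESHOLDS = (-1.1, -0.25, 0.2, 0.7)


def compute_log2_ratio(
    tumor_mean_depth: float,
    normal_mean_depth: float,
    tumor_lib_depth: float,
    normal_lib_depth: float,
    epsilon: float = 0.01,
) -> float:
    """Library-normalized log2(tumor/normal) with a pseudocount.

    Depths are first scaled by each library's reference depth (mean depth
    over a copy-neutral region), then ``epsilon`` (in normalized-depth
    units) keeps the ratio finite on biallelic losses.
    """
    if tumor_lib_depth <= 0 or normal_lib_depth <= 0:
        raise ValueError("library depths must be positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    t = tumor_mean_depth / tumor_lib_depth + epsilon
    n = normal_mean_depth / normal_lib_depth + epsilon
    return math.log2(t / n)


def call_cn(log2_ratio: float) -> int:
    """Map a segment log2 ratio to absolute copy number (0-4)."""
    if log2_ratio is None or math.isnan(log2_ratio):
        raise ValueError("log2 ratio is NaN")
    if log2_ratio < CN_THRESHOLDS[0]:
        return 0
    if log2_ratio < CN_THRESHOLDS[1]:
        return 1
    if log2_ratio < CN_THRESHOLDS[2]:
        return 2
    if log2_ratio <= CN_THRESHOLDS[3]:
        return 3
    return 4


def purity_adjust_cn(log2_ratio: float, purity: float) -> float:
    """Tumor-intrinsic copy number under a tumor/diploid-normal mixture.

    Inverts  2^r = (p*c + (1-p)*2) / 2  for c, floored at 0.  At purity 1
    this is just 2*2^r.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    c = (2.0 * 2.0**log2_ratio - 2.0 * (1.0 - purity)) / purity
    return max(0.0, c)


def adjusted_log2(log2_ratio: float, purity: float, epsilon: float = 0.01) -> float:
    """Log2 ratio the tumor would show at purity 1 (for thresholding)."""
    c = purity_adjust_cn(log2_ratio, purity)
    return math.log2((c + epsilon) / (2.0 + epsilon))


def estimate_tumor_content(vafs: Sequence[float]) -> float:
    """Tumor purity of a diploid sample: min(1, 2 * median(VAF))."""
    arr = np.asarray(list(vafs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one VAF")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("VAFs must lie in [0, 1]")
    return min(1.0, 2.0 * float(np.median(arr)))


def purity_category(purity: float) -> str:
    """Adequacy band for a purity estimate: low / moderate / adequate."""
    if purity <= 0.20:
        return "low"
    if purity <= 0.40:
        return "moderate"
    return "adequate"


@dataclass
class PuritySpec:
    """A VAF list together with the purity estimate derived from it."""

    vafs: list[float]
    estimate: float = None  # type: ignore[assignment]

    def __post_init__(self):
        est = estimate_tumor_content(self.vafs)
        if self.estimate is None:
            self.estimate = est
        elif abs(self.estimate - est) > 1e-9:
            raise ValueError("estimate inconsistent with 2*median(vafs)")

    @property
    def category(self) -> str:
        return purity_category(self.estimate)


@dataclass
class RatioSegment:
    """A segment with its log2 ratio, raw CN call, and flatness slope.

    ``cn`` is always the raw threshold call on ``log2_ratio``;
    ``cn_purity_adjusted`` (when purity is known) carries the real-valued
    tumor-intrinsic copy number.  ``slope_per_10kb`` is the within-segment
    least-squares slope of the binned coverage ratio, expressed in log2
    units per 10 kb at the diploid scale, used by the flat-vs-slopy
    classification.
    """

    segment: Segment
    log2_ratio: float
    cn: int
    cn_purity_adjusted: Optional[float] = None
    slope_per_10kb: float = 0.0

    def __post_init__(self):
        if self.cn != call_cn(self.log2_ratio):
            raise ValueError("cn inconsistent with threshold map")
        if self.cn_purity_adjusted is not None and self.cn_purity_adjusted < 0:
            raise ValueError("adjusted CN must be >= 0")

    def to_dict(self) -> dict:
        s = self.segment
        return {
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "start_bin": s.start_bin,
            "end_bin": s.end_bin,
            "n_bins": s.n_bins,
            "mean_value": s.mean_value,
            "log2_ratio": self.log2_ratio,
            "cn": self.cn,
            "cn_purity_adjusted": self.cn_purity_adjusted,
            "slope_per_10kb": self.slope_per_10kb,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RatioSegment":
        seg = Segment(
            start_bin=d["start_bin"],
            end_bin=d["end_bin"],
            start_bp=d["start_bp"],
            end_bp=d["end_bp"],
            mean_value=d["mean_value"],
            n_bins=d["n_bins"],
        )
        return cls(
            segment=seg,
            log2_ratio=d["log2_ratio"],
            cn=d["cn"],
            cn_purity_adjusted=d.get("cn_purity_adjusted"),
            slope_per_10kb=d.get("slope_per_10kb", 0.0),
        )


def read_vaf_tsv(path: str | Path) -> list[float]:
    """Read somatic VAFs from a 1-column TSV (header lines starting with #
    are skipped)."""
    vafs: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line.split("\t")[0])
            except ValueError as exc:
                raise ValueError(f"VAF TSV line {lineno}: {exc}") from exc
            if not 0 <= v <= 1:
                raise ValueError(f"VAF TSV line {lineno}: {v} outside [0, 1]")
            vafs.append(v)
    if not vafs:
        raise ValueError("VAF TSV contains no values")
    return vafs
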