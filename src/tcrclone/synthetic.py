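"""Synthetic matched tumor-normal coverage with known receptor rearrangements.

The generator composes three cell populations over one receptor locus:

* a clonal (tumor) population at fraction ``f``, every cell carrying the
  same V(D)J deletion on one or both alleles — the flat monoclonal loss;
* a polyclonal background in which each allele independently carries a
  deletion with probability ``fraction_rearranged``, its V and J endpoints
  drawn from usage weights — their aggregate is the slopy staircase that
  declines toward the J cluster;
* Poisson sequencing noise: each bin's total base coverage is Poisson with
  mean ``mean_depth * bin_width * c(x) / 2`` (i.e. the bin aggregates
  per-base Poisson draws, as averaging samtools-depth output does).

The expected diploid-equivalent copy number at position x is

    c(x) = f * c_tumor(x) + (1 - f) * c_bg(x)
    c_tumor(x) = 2 - [x in allele1_del] - [x in allele2_del]
    c_bg(x)    = 2 * (1 - fraction_rearranged * P_del(x))
    P_del(x)   = sum_{p,q} w(V_p) * w(J_q) * 1[end(V_p) < x < start(J_q)]

No GC or mappability structure is simulated: the pipeline operates on
matched tumor/normal ratios, so first-order systematic bias cancels.
Abstract locus templates (TRB-, TRG- and TRA/TRD-like geometry) are
provided so unit tests need no real coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clonality import (
    BIALLELIC,
    INDETERMINATE,
    MONOALLELIC,
    MONOCLONAL,
    NO_LOSS,
    POLYCLONAL,
    ClonalityCall,
)
from .coverage import CoverageTrack, n_bins
from .loci import GenomicInterval, LocusDefinition


@dataclass
class PolyclonalSpec:
    """Aggregate V-J deletion model of the non-clonal background.

    ``fraction_rearranged`` is the share of background alleles carrying a
    V-J deletion.  The default 0.7 models a bulk sample that is mostly but
    not purely T cells (NK/B/myeloid cells keep germline loci).  Usage
    weights default to uniform; skew them to model restricted repertoires.
    """

    fraction_rearranged: float = 0.7
    v_usage: Optional[Sequence[float]] = None
    j_usage: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not 0.0 <= self.fraction_rearranged <= 1.0:
            raise ValueError("fraction_rearranged must be in [0, 1]")
        for w in (self.v_usage, self.j_usage):
            if w is not None:
                arr = np.asarray(w, dtype=float)
                if np.any(arr < 0) or arr.sum() <= 0:
                    raise ValueError("usage weights must be >= 0 with positive sum")

    def weights(self, locus: LocusDefinition) -> tuple[np.ndarray, np.ndarray]:
        nv, nj = len(locus.v_segments), len(locus.j_segments)
        wv = (
            np.full(nv, 1.0 / nv)
            if self.v_usage is None
            else np.asarray(self.v_usage, dtype=float)
        )
        wj = (
            np.full(nj, 1.0 / nj)
            if self.j_usage is None
            else np.asarray(self.j_usage, dtype=float)
        )
        if len(wv) != nv or len(wj) != nj:
            raise ValueError("usage weights must match segment counts")
        return wv / wv.sum(), wj / wj.sum()


@dataclass
class CloneSimSpec:
    """Ground-truth description of one simulated matched pair."""

    locus: LocusDefinition
    tumor_fraction: float
    allele1_deletion: Optional[GenomicInterval] = None
    allele2_deletion: Optional[GenomicInterval] = None
    background: PolyclonalSpec = field(default_factory=PolyclonalSpec)
    mean_depth: float = 30.0  # haploid-pair (diploid) per-base depth
    bin_size: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for d in (self.allele1_deletion, self.allele2_deletion):
            if d is None:
                continue
            if not self.locus.extent.contains(d):
                raise ValueError("deletion outside locus extent")
            if not any(v.end <= d.start for v in self.locus.v_segments) and not any(
                s.end <= d.start for s in self.locus.d_segments
            ):
                raise ValueError("deletion must start after a V (or D) segment end")
            if not any(j.start >= d.end for j in self.locus.j_segments):
                raise ValueError("deletion must end before a J segment start")

    @property
    def deletions(self) -> list[GenomicInterval]:
        return [d for d in (self.allele1_deletion, self.allele2_deletion) if d]

    def truth_call(self, sample_id: str = "truth") -> ClonalityCall:
        """Ground-truth per-locus verdict implied by the spec."""
        if self.tumor_fraction > 0 and self.deletions:
            if (
                self.allele1_deletion
                and self.allele2_deletion
                and self.allele1_deletion.overlaps(self.allele2_deletion)
            ):
                allelic = BIALLELIC
            else:
                allelic = MONOALLELIC
            return ClonalityCall(
                locus=self.locus.name,
                category=MONOCLONAL,
                allelic=allelic,
                sample_id=sample_id,
            )
        if self.background.fraction_rearranged > 0:
            return ClonalityCall(
                locus=self.locus.name,
                category=POLYCLONAL,
                allelic=INDETERMINATE,
                sample_id=sample_id,
            )
        return ClonalityCall(
            locus=self.locus.name,
            category=NO_LOSS,
            allelic=INDETERMINATE,
            sample_id=sample_id,
        )


# ---------------------------------------------------------------------------
# expected copy number


def background_deletion_probability(
    locus: LocusDefinition,
    background: PolyclonalSpec,
    x: np.ndarray,
) -> np.ndarray:
    """P_del(x): probability a rearranged allele has deleted position x.

    Factorizes as (total V weight with end < x) * (total J weight with
    start > x) because V and J choice are independent.
    """
    x = np.asarray(x, dtype=float)
    wv, wj = background.weights(locus)
    v_ends = np.array([v.end for v in locus.v_segments], dtype=float)
    j_starts = np.array([j.start for j in locus.j_segments], dtype=float)
    order_v = np.argsort(v_ends)
    cum_v = np.concatenate([[0.0], np.cumsum(wv[order_v])])
    pv = cum_v[np.searchsorted(v_ends[order_v], x, side="left")]
    order_j = np.argsort(j_starts)
    cum_j_from_right = np.concatenate([[0.0], np.cumsum(wj[order_j][::-1])])[::-1]
    pj = cum_j_from_right[np.searchsorted(j_starts[order_j], x, side="right")]
    return pv * pj


def copy_number_at(spec: CloneSimSpec, x: np.ndarray) -> np.ndarray:
    """Pointwise expected diploid-equivalent copy number c(x)."""
    x = np.asarray(x, dtype=float)
    f = spec.tumor_fraction
    c_tumor = np.full_like(x, 2.0)
    for d in spec.deletions:
        c_tumor -= ((x >= d.start) & (x < d.end)).astype(float)
    p_del = background_deletion_probability(spec.locus, spec.background, x)
    c_bg = 2.0 * (1.0 - spec.background.fraction_rearranged * p_del)
    return f * c_tumor + (1.0 - f) * c_bg


def _bin_edges(spec: CloneSimSpec) -> tuple[np.ndarray, np.ndarray]:
    ext = spec.locus.extent
    nb = n_bins(ext, spec.bin_size)
    starts = ext.start + spec.bin_size * np.arange(nb)
    ends = np.minimum(starts + spec.bin_size, ext.end)
    return starts.astype(float), ends.astype(float)


def expected_copy_profile(spec: CloneSimSpec) -> np.ndarray:
    """Per-bin expected copy number.

    Clonal deletions contribute their exact overlap fraction per bin; the
    background staircase is evaluated at bin midpoints (V/D/J elements are
    much smaller than a bin, so the approximation is sub-bin).
    """
    starts, ends = _bin_edges(spec)
    widths = ends - starts
    f = spec.tumor_fraction
    c_tumor = np.full(len(starts), 2.0)
    for d in spec.deletions:
        overlap = np.clip(np.minimum(ends, d.end) - np.maximum(starts, d.start), 0, None)
        c_tumor -= overlap / widths
    mid = (starts + ends) / 2.0
    p_del = background_deletion_probability(spec.locus, spec.background, mid)
    c_bg = 2.0 * (1.0 - spec.background.fraction_rearranged * p_del)
    return f * c_tumor + (1.0 - f) * c_bg


# ---------------------------------------------------------------------------
# sampling


def simulate_sample(
    spec: CloneSimSpec,
) -> tuple[CoverageTrack, CoverageTrack, ClonalityCall]:
    """Draw a matched tumor/normal pair plus its ground-truth call.

    Tumor bin coverage ~ Poisson(mean_depth * width * c/2) / width; the
    matched normal is diploid everywhere.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    starts, ends = _bin_edges(spec)
    widths = ends - starts
    c = expected_copy_profile(spec)
    lam_t = spec.mean_depth * widths * c / 2.0
    lam_n = spec.mean_depth * widths
    tumor_vals = rng.poisson(lam_t) / widths
    normal_vals = rng.poisson(lam_n) / widths
    ext = spec.locus.extent
    tumor = CoverageTrack(ext, spec.bin_size, tumor_vals)
    normal = CoverageTrack(ext, spec.bin_size, normal_vals)
    return tumor, normal, spec.truth_call()


def simulate_vafs(spec: CloneSimSpec, n_variants: int, seed: int) -> list[float]:
    """Somatic VAFs at heterozygous clonal sites: Binomial(depth, f/2)/depth.

    Site depths are Poisson around ``spec.mean_depth``; the median VAF
    converges to f/2 as n grows, so 2*median recovers tumor content.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    depths = np.maximum(rng.poisson(spec.mean_depth, size=n_variants), 1)
    alts = rng.binomial(depths, spec.tumor_fraction / 2.0)
    return list(alts / depths)


# ---------------------------------------------------------------------------
# abstract locus templates (geometry realistic, coordinates arbitrary)


def trb_like_locus() -> LocusDefinition:
    """500 kb locus, 50 V / 2 D / 13 J: TRB-like geometry.

    The V array spans most of the locus; the D-J region is compact (~1.6 kb)
    so incomplete D-J deletions are invisible at whole-locus bin sizes.
    """
    chrom = "chrSimB"
    v = [GenomicInterval(chrom, 5_000 + i * 9_500, 5_500 + i * 9_500) for i in range(50)]
    d = [
        GenomicInterval(chrom, 471_700, 471_720),
        GenomicInterval(chrom, 472_600, 472_620),
    ]
    j = [GenomicInterval(chrom, 472_000 + k * 80, 472_040 + k * 80) for k in range(6)]
    j += [GenomicInterval(chrom, 472_800 + k * 80, 472_840 + k * 80) for k in range(7)]
    return LocusDefinition(
        name="TRB",
        extent=GenomicInterval(chrom, 0, 500_000),
        v_segments=v,
        d_segments=d,
        j_segments=sorted(j, key=lambda s: s.start),
        orientation="forward",
    )


def trg_like_locus() -> LocusDefinition:
    """160 kb locus, 14 V / 0 D / 5 J: TRG-like geometry."""
    chrom = "chrSimG"
    v = [
        GenomicInterval(chrom, 5_000 + i * 10_350, 5_500 + i * 10_350)
        for i in range(14)
    ]
    j = [GenomicInterval(chrom, 142_000 + k * 400, 142_060 + k * 400) for k in range(5)]
    return LocusDefinition(
        name="TRG",
        extent=GenomicInterval(chrom, 0, 160_000),
        v_segments=v,
        j_segments=j,
        orientation="forward",
    )


def tra_trd_like_loci() -> tuple[LocusDefinition, LocusDefinition]:
    """TRA-like 500 kb locus with a TRD-like locus nested inside it."""
    chrom = "chrSimA"
    tra_v = [
        GenomicInterval(chrom, 5_000 + i * 8_200, 5_500 + i * 8_200) for i in range(41)
    ]
    tra_j = [
        GenomicInterval(chrom, 400_000 + k * 800, 400_060 + k * 800) for k in range(50)
    ]
    tra = LocusDefinition(
        name="TRA",
        extent=GenomicInterval(chrom, 0, 500_000),
        v_segments=tra_v,
        j_segments=tra_j,
        orientation="forward",
        nested_locus="TRD",
    )
    trd_v = [
        GenomicInterval(chrom, 345_000 + i * 7_000, 345_500 + i * 7_000)
        for i in range(3)
    ]
    trd_d = [
        GenomicInterval(chrom, 370_000, 370_020),
        GenomicInterval(chrom, 372_000, 372_020),
    ]
    trd_j = [
        GenomicInterval(chrom, 374_000 + k * 250, 374_060 + k * 250) for k in range(4)
    ]
    trd = LocusDefinition(
        name="TRD",
        extent=GenomicInterval(chrom, 340_000, 396_000),
        v_segments=trd_v,
        d_segments=trd_d,
        j_segments=trd_j,
        orientation="forward",
    )
    return tra, trd
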