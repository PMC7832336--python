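"""Monoclonal / polyclonal / no-loss classification of receptor loci.

A clonal (neoplastic) T- or B-cell population carries one identical V(D)J
deletion per rearranged allele in every cell, which shows up in coverage as
a *flat*, sharply stepped segment of loss.  A polyclonal background instead
aggregates many different V-J deletions into a *slopy* staircase that
declines toward the J cluster.  The classifier encodes exactly that
distinction:

(a) MONOCLONAL — a contiguous run of flat segments at copy number <= 1,
    at least ``min_flat_width_bp`` wide in total, forms a *trough*: the
    segments flanking the run sit at least ``min_step_log2`` above the
    run members they touch, on both sides.  A clonal deletion recovers on
    both sides (at the J cluster at the latest); a staircase step or its
    terminal plateau drops on one side only.  Tested for every sub-run,
    so a flat loss sitting inside a slopy polyclonal background still
    triggers.
(b) POLYCLONAL — nothing qualifies under (a), but >= ``min_slopy_run``
    consecutive segments have negative means strictly decreasing toward
    the J cluster.
(c) NO_LOSS otherwise.

Allelic status of a monoclonal call is biallelic when a qualifying segment
sits at CN 0, monoallelic at CN 1, and indeterminate when the decisive
segment's ratio lies within ``indeterminate_band`` of the CN0/CN1 cutoff.

When tumor purity is known (``params.purity``), the copy-number and step
tests run on purity-adjusted copy numbers, since dilution by normal cells
compresses raw ratios toward 0 and would otherwise hide low-purity clones;
allelic status then comes from the trough's boundary drops (copies lost
per tumor cell) rather than the absolute adjusted level, which assumes a
diploid background.

Incomplete D-J rearrangements delete only a few hundred bp to a few kb and
are invisible at whole-locus scale; ``detect_dj_microdeletion`` re-segments
the D-J window at fine bins to recover them.  TRD is nested inside TRA, so
a monoclonal TRA call whose entire evidence is focal to the TRD extent is
reattributed to TRD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cn import RatioSegment, adjusted_log2, call_cn, purity_adjust_cn
from .coverage import CoverageTrack
from .loci import LocusDefinition
from .segmentation import Segment, Signal, segment_pcf, winsorize

logger = logging.getLogger(__name__)

MONOCLONAL = "monoclonal"
POLYCLONAL = "polyclonal"
NO_LOSS = "no_loss"

MONOALLELIC = "monoallelic"
BIALLELIC = "biallelic"
INDETERMINATE = "indeterminate"

TCR_LOCI = ("TRA", "TRB", "TRG", "TRD")


@dataclass
class ClonalityParams:
    """Tunable thresholds of the pipeline (units noted per field)."""

    bin_size: int = 100  # bp, whole-locus segmentation
    zoom_bin_size: int = 25  # bp, D-J re-segmentation
    gamma: float = 40.0  # PCF penalty (scale-free)
    kmin: int = 5  # min segment length, bins
    kmin_zoom: int = 8  # min segment length in the zoomed D-J window
    tau: float = 2.5  # winsorization band, sigma units
    half_window: int = 25  # winsorization window half-width, bins
    epsilon: float = 0.01  # ratio pseudocount, normalized-depth units
    min_flat_width_bp: int = 2000  # min width of a qualifying flat loss
    max_flat_slope: float = 0.05  # max |slope| of a flat segment, log2/10kb
    min_step_log2: float = 0.25  # min drop vs a flank, log2 (raw mode)
    min_step_copies: float = 0.5  # min drop vs a flank, copies (purity mode)
    min_slopy_run: int = 3  # consecutive segments for a slopy call
    min_dj_width_bp: int = 300  # min width of a zoomed D-J hit
    zoom_flank_bp: int = 2000  # context added around the D-J window
    indeterminate_band: float = 0.05  # log2 half-width around the CN0/1 cutoff
    purity: Optional[float] = None  # tumor content; enables adjusted calling
    tumor_lib_depth: Optional[float] = None  # library normalizer (None: median)
    normal_lib_depth: Optional[float] = None

    def __post_init__(self):
        if self.purity is not None and not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.bin_size % self.zoom_bin_size != 0:
            raise ValueError("bin_size must be a multiple of zoom_bin_size")


@dataclass
class ClonalityCall:
    """Per-locus verdict with its supporting segments."""

    locus: str
    category: str
    allelic: str
    evidence: list[RatioSegment] = field(default_factory=list)
    zoom_hit: Optional[RatioSegment] = None
    attributed_from: Optional[str] = None
    sample_id: Optional[str] = None

    def __post_init__(self):
        if self.category not in (MONOCLONAL, POLYCLONAL, NO_LOSS):
            raise ValueError(f"bad category {self.category!r}")
        if self.allelic not in (MONOALLELIC, BIALLELIC, INDETERMINATE):
            raise ValueError(f"bad allelic status {self.allelic!r}")
        if self.category != MONOCLONAL and self.allelic != INDETERMINATE:
            raise ValueError("allelic status applies only to monoclonal calls")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "locus": self.locus,
            "category": self.category,
            "allelic": self.allelic,
            "evidence": [rs.to_dict() for rs in self.evidence],
            "zoom_hit": self.zoom_hit.to_dict() if self.zoom_hit else None,
            "attributed_from": self.attributed_from,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClonalityCall":
        return cls(
            locus=d["locus"],
            category=d["category"],
            allelic=d["allelic"],
            evidence=[RatioSegment.from_dict(e) for e in d["evidence"]],
            zoom_hit=RatioSegment.from_dict(d["zoom_hit"]) if d.get("zoom_hit") else None,
            attributed_from=d.get("attributed_from"),
            sample_id=d.get("sample_id"),
        )


@dataclass
class SampleCall:
    """All locus calls of one sample plus the headline clonality flag."""

    sample_id: str
    calls: list[ClonalityCall]
    clonal_t_cell_process: bool

    def call_for(self, locus: str) -> ClonalityCall:
        for c in self.calls:
            if c.locus == locus:
                return c
        raise KeyError(locus)


# ---------------------------------------------------------------------------
# signal construction


def copy_ratio_signal(
    tumor: CoverageTrack,
    normal: CoverageTrack,
    params: ClonalityParams,
) -> Signal:
    """Per-bin diploid-equivalent copy estimate 2*(t/tlib)/(n/nlib).

    Segmentation runs in copy-ratio space rather than log2 space: for
    count data the noise variance scales *with* coverage, so deleted
    regions are quiet in copy space (as they are in the raw read-depth
    plots the method segments) while a log transform would amplify their
    noise and shatter deep losses into spurious pieces.  Log2 ratios are
    derived per segment afterwards for CN thresholding.
    """
    if not tumor.same_bins(normal):
        raise ValueError("tumor and normal tracks must share identical bins")
    tlib = params.tumor_lib_depth or tumor.median_depth()
    nlib = params.normal_lib_depth or normal.median_depth()
    if tlib <= 0 or nlib <= 0:
        raise ValueError("library depths must be positive")
    eps = params.epsilon
    vals = 2.0 * (tumor.values / tlib + eps) / (normal.values / nlib + eps)
    return Signal(tumor.bin_starts(), vals, tumor.bin_size)


def make_ratio_segments(
    signal: Signal,
    segments: list[Segment],
    params: ClonalityParams,
) -> list[RatioSegment]:
    """Annotate copy-space segments with log2 ratio, CN, adjusted CN, slope.

    The segment log2 ratio is log2(mean_copy / 2) — the log of the mean,
    which is unbiased at low depth where the mean of logs is not.  Slopes
    are fitted in copy space and converted to log2 units at the segment's
    own level so the flatness threshold keeps its meaning.
    """
    out = []
    for seg in segments:
        chunk = signal.values[seg.start_bin : seg.end_bin]
        mean_c = float(np.mean(chunk))
        log2r = math.log2(max(mean_c, 1e-6) / 2.0)
        slope = _slope_per_10kb(chunk, signal.bin_size) / _DIPLOID_LOG_SCALE
        adj = (
            purity_adjust_cn(log2r, params.purity)
            if params.purity is not None
            else None
        )
        out.append(
            RatioSegment(
                segment=seg,
                log2_ratio=log2r,
                cn=call_cn(log2r),
                cn_purity_adjusted=adj,
                slope_per_10kb=slope,
            )
        )
    return out


#: d(copy)/d(log2) at the diploid level.  Slopes are fitted in copy space
#: and expressed in log2-per-10kb *at diploid scale*: a 0.05 threshold then
#: equals 0.069 copies/10kb everywhere.  Converting at the segment's own
#: level instead would declare a deep trough "slopy" over a copy-space tilt
#: of a few hundredths of a copy, which no coverage plot would show.
_DIPLOID_LOG_SCALE = 2.0 * math.log(2.0)


def _slope_per_10kb(values: np.ndarray, bin_size: int) -> float:
    if len(values) < 2:
        return 0.0
    x = np.arange(len(values), dtype=float)
    b, _ = np.polyfit(x, values, 1)
    return float(b) / bin_size * 1e4


def _slope_se_per_10kb(values: np.ndarray, bin_size: int) -> float:
    """Standard error of the within-segment slope (same units)."""
    n = len(values)
    if n < 3:
        return math.inf
    x = np.arange(n, dtype=float)
    b, a = np.polyfit(x, values, 1)
    resid = values - (a + b * x)
    s2 = float(np.sum(resid**2)) / (n - 2)
    sxx = float(np.sum((x - x.mean()) ** 2))
    return math.sqrt(s2 / sxx) / bin_size * 1e4


# ---------------------------------------------------------------------------
# classification


def _effective_cn(rs: RatioSegment, params: ClonalityParams) -> int:
    """Integer CN used by the classifier (purity-adjusted when available)."""
    if params.purity is None:
        return rs.cn
    return call_cn(adjusted_log2(rs.log2_ratio, params.purity, params.epsilon))


def _effective_log2(rs: RatioSegment, params: ClonalityParams) -> float:
    if params.purity is None:
        return rs.log2_ratio
    return adjusted_log2(rs.log2_ratio, params.purity, params.epsilon)


def _boundary_drop_ok(
    boundary: RatioSegment,
    edge_member: RatioSegment,
    params: ClonalityParams,
) -> bool:
    """Is the flanking segment a full step above the run segment it touches?

    A clonal deletion enters with a sharp drop and exits with a sharp rise,
    so the step is tested locally at each end of the candidate run (robust
    to a residual background tilt across the run's interior).  Raw mode
    compares in log2; purity mode compares the copy-space drop rescaled by
    tumor content (a clone at purity p shifts coverage by only p copies per
    deleted allele), unfloored so drops between two deep losses register.
    """
    if params.purity is None:
        drop = boundary.log2_ratio - edge_member.log2_ratio
        return drop >= params.min_step_log2
    drop = (
        boundary.segment.mean_value - edge_member.segment.mean_value
    ) / params.purity
    return drop >= params.min_step_copies


def _is_flat(rs: RatioSegment, signal_values: Optional[np.ndarray], params) -> bool:
    """Flatness: |slope| below threshold, judged against its own noise.

    A slope estimate over a short segment is noise-dominated, so a segment
    counts as slopy only when its slope exceeds the threshold *and* is
    statistically distinguishable from zero (2 SE); otherwise the step and
    width criteria carry the decision.
    """
    if abs(rs.slope_per_10kb) <= params.max_flat_slope:
        return True
    if signal_values is None:
        return False
    bin_size = (rs.segment.end_bp - rs.segment.start_bp) // max(rs.segment.n_bins, 1)
    se = _slope_se_per_10kb(
        signal_values[rs.segment.start_bin : rs.segment.end_bin], bin_size
    ) / _DIPLOID_LOG_SCALE
    return abs(rs.slope_per_10kb) <= 2.0 * se


def _qualifying_loss_runs(
    ratio_segments: list[RatioSegment],
    params: ClonalityParams,
    min_width_bp: Optional[int] = None,
    signal_values: Optional[np.ndarray] = None,
) -> list[list[RatioSegment]]:
    """Contiguous runs of flat low-CN segments that form a genuine trough.

    A clonal deletion may be split by the segmenter along residual
    background structure, so candidates are *runs* of consecutive segments
    that each have (effective) CN <= 1 and are internally flat.  Every
    contiguous sub-run is tested locally: it qualifies when it is wide
    enough in total and the two segments immediately flanking it sit a
    full step above the run members they touch, on *both* sides.  A
    clonal deletion is a trough that recovers on both sides relative to
    its local context (which may itself be a polyclonal plateau), whereas
    a polyclonal staircase step or its terminal plateau drops only on one
    side.  Runs touching the edge of the tiled region never qualify —
    V(D)J deletions are bounded by V and J segments, so a genuine loss
    always has context on both sides.
    """
    min_width = min_width_bp if min_width_bp is not None else params.min_flat_width_bp
    n = len(ratio_segments)
    eligible = [
        _effective_cn(rs, params) <= 1 and _is_flat(rs, signal_values, params)
        for rs in ratio_segments
    ]
    spans: list[tuple[int, int]] = []
    for i in range(1, n - 1):
        if not eligible[i]:
            continue
        if not _boundary_drop_ok(ratio_segments[i - 1], ratio_segments[i], params):
            continue
        for j in range(i, n - 1):
            if not eligible[j]:
                break
            width = (
                ratio_segments[j].segment.end_bp - ratio_segments[i].segment.start_bp
            )
            if width < min_width:
                continue
            if _boundary_drop_ok(ratio_segments[j + 1], ratio_segments[j], params):
                spans.append((i, j))
    return [ratio_segments[i : j + 1] for i, j in _minimal_spans(spans)]


def _qualifying_run_spans(
    ratio_segments: list[RatioSegment],
    params: ClonalityParams,
    min_width_bp: Optional[int] = None,
    signal_values: Optional[np.ndarray] = None,
) -> list[tuple[int, int]]:
    """Index spans (i, j inclusive) of the qualifying trough runs."""
    runs = _qualifying_loss_runs(ratio_segments, params, min_width_bp, signal_values)
    by_id = {id(rs): k for k, rs in enumerate(ratio_segments)}
    return [(by_id[id(r[0])], by_id[id(r[-1])]) for r in runs]


def _minimal_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop spans that strictly contain another qualifying span: the
    tightest run is the deletion; wider ones merely absorb its shoulders."""
    out = []
    for i, j in spans:
        contains_other = any(
            (oi, oj) != (i, j) and i <= oi and oj <= j for (oi, oj) in spans
        )
        if not contains_other:
            out.append((i, j))
    return out


def _qualifying_flat_losses(
    ratio_segments: list[RatioSegment],
    params: ClonalityParams,
    min_width_bp: Optional[int] = None,
    signal_values: Optional[np.ndarray] = None,
) -> list[RatioSegment]:
    """All segments belonging to a qualifying trough run (see above)."""
    seen: set[int] = set()
    out: list[RatioSegment] = []
    for run in _qualifying_loss_runs(
        ratio_segments, params, min_width_bp, signal_values
    ):
        for rs in run:
            if id(rs) not in seen:
                seen.add(id(rs))
                out.append(rs)
    out.sort(key=lambda rs: rs.segment.start_bin)
    return out


def _slopy_run(
    ratio_segments: list[RatioSegment],
    locus: LocusDefinition,
    params: ClonalityParams,
) -> list[RatioSegment]:
    """Longest run of negative-mean segments strictly declining toward J."""
    ordered = list(ratio_segments)
    if locus.j_side() == "left":
        ordered = ordered[::-1]
    best: list[RatioSegment] = []
    run: list[RatioSegment] = []
    for rs in ordered:
        if rs.log2_ratio < 0 and (not run or rs.log2_ratio < run[-1].log2_ratio):
            run.append(rs)
        else:
            if len(run) > len(best):
                best = run
            run = [rs] if rs.log2_ratio < 0 else []
    if len(run) > len(best):
        best = run
    return best if len(best) >= params.min_slopy_run else []


def _allelic_status(
    qualifying: list[RatioSegment], params: ClonalityParams
) -> str:
    decisive = min(qualifying, key=lambda rs: _effective_log2(rs, params))
    eff = _effective_log2(decisive, params)
    if abs(eff - (-1.1)) <= params.indeterminate_band:
        return INDETERMINATE
    if any(_effective_cn(rs, params) == 0 for rs in qualifying):
        return BIALLELIC
    return MONOALLELIC


def _allelic_from_boundary_drops(
    ratio_segments: list[RatioSegment],
    spans: list[tuple[int, int]],
    params: ClonalityParams,
) -> str:
    """Copies lost by the clone, read off the trough's boundary steps.

    At tumor content p a deletion of k copies drops coverage by k*p copies
    relative to its *local* context, so (flank - trough)/p estimates k
    regardless of how deep the surrounding polyclonal background already
    is — unlike the absolute purity-adjusted CN, which assumes a diploid
    background.  The larger of the two boundary drops is used (one side of
    a deletion may coincide with the background's own bottom).
    """
    best = 0.0
    for i, j in spans:
        left = (
            ratio_segments[i - 1].segment.mean_value
            - ratio_segments[i].segment.mean_value
        ) / params.purity
        right = (
            ratio_segments[j + 1].segment.mean_value
            - ratio_segments[j].segment.mean_value
        ) / params.purity
        best = max(best, left, right)
    lost = min(best, 2.0)
    if lost >= 1.65:
        return BIALLELIC
    if lost <= 1.35:
        return MONOALLELIC
    return INDETERMINATE


def _check_tiling(ratio_segments: list[RatioSegment]) -> None:
    if not ratio_segments:
        raise ValueError("no segments supplied")
    for a, b in zip(ratio_segments[:-1], ratio_segments[1:]):
        if a.segment.end_bin != b.segment.start_bin:
            raise ValueError("segments do not tile the locus contiguously")


def classify_locus(
    ratio_segments: list[RatioSegment],
    locus: LocusDefinition,
    params: Optional[ClonalityParams] = None,
    signal_values: Optional[np.ndarray] = None,
) -> ClonalityCall:
    """Classify one locus from its tiled ratio segments."""
    params = params or ClonalityParams()
    _check_tiling(ratio_segments)

    spans = _qualifying_run_spans(ratio_segments, params, signal_values=signal_values)
    if spans:
        flat = sorted(
            {k for i, j in spans for k in range(i, j + 1)}
        )
        flat_segs = [ratio_segments[k] for k in flat]
        if params.purity is not None:
            allelic = _allelic_from_boundary_drops(ratio_segments, spans, params)
        else:
            allelic = _allelic_status(flat_segs, params)
        return ClonalityCall(
            locus=locus.name,
            category=MONOCLONAL,
            allelic=allelic,
            evidence=flat_segs,
        )
    run = _slopy_run(ratio_segments, locus, params)
    if run:
        return ClonalityCall(
            locus=locus.name,
            category=POLYCLONAL,
            allelic=INDETERMINATE,
            evidence=run,
        )
    return ClonalityCall(
        locus=locus.name, category=NO_LOSS, allelic=INDETERMINATE, evidence=[]
    )


# ---------------------------------------------------------------------------
# zoomed D-J re-segmentation


def detect_dj_microdeletion(
    tumor: CoverageTrack,
    normal: CoverageTrack,
    locus: LocusDefinition,
    params: Optional[ClonalityParams] = None,
) -> Optional[RatioSegment]:
    """Re-segment the D-J window at fine bins; return a qualifying loss.

    Only meaningful for loci whose recombination includes a D-to-J joining
    step (TRB, TRD, IGH).  The window spans the D and J clusters plus
    ``zoom_flank_bp`` of context; a flat loss segment at least
    ``min_dj_width_bp`` wide (same CN/step tests as the whole-locus rule)
    is returned, or None.  Sub-threshold candidates are logged.
    """
    params = params or ClonalityParams()
    if not locus.has_d_segments:
        raise ValueError(f"locus {locus.name} has no D segments")
    djs = locus.d_segments + locus.j_segments
    win_start = max(locus.extent.start, min(s.start for s in djs) - params.zoom_flank_bp)
    win_end = min(locus.extent.end, max(s.end for s in djs) + params.zoom_flank_bp)

    if tumor.bin_size > params.zoom_bin_size:
        raise ValueError(
            f"zoom requires tracks binned at <= {params.zoom_bin_size} bp"
        )
    t_win = tumor.slice_bp(win_start, win_end)
    n_win = normal.slice_bp(win_start, win_end)
    factor = params.zoom_bin_size // tumor.bin_size
    if factor > 1:
        t_win, n_win = t_win.rebin(factor), n_win.rebin(factor)

    sig = copy_ratio_signal(t_win, n_win, params)
    hw = min(params.half_window, (len(sig) - 1) // 2)
    if hw >= 1 and len(sig) > 2 * hw:
        sig = winsorize(sig, params.tau, hw)
    segs = segment_pcf(sig, params.gamma, params.kmin_zoom)
    ratio_segs = make_ratio_segments(sig, segs, params)

    hits = _qualifying_flat_losses(
        ratio_segs,
        params,
        min_width_bp=params.min_dj_width_bp,
        signal_values=sig.values,
    )
    if hits:
        return min(hits, key=lambda rs: _effective_log2(rs, params))
    sub = _qualifying_flat_losses(
        ratio_segs, params, min_width_bp=1, signal_values=sig.values
    )
    for rs in sub:
        logger.debug(
            "%s D-J candidate %d-%d (%d bp) below min width %d bp",
            locus.name,
            rs.segment.start_bp,
            rs.segment.end_bp,
            rs.segment.width_bp,
            params.min_dj_width_bp,
        )
    return None


# ---------------------------------------------------------------------------
# nested TRD attribution


def attribute_nested_trd(
    tra_call: ClonalityCall,
    locus_tra: LocusDefinition,
    locus_trd: Optional[LocusDefinition],
    params: Optional[ClonalityParams] = None,
    all_segments: Optional[list[RatioSegment]] = None,
) -> tuple[ClonalityCall, Optional[ClonalityCall]]:
    """Reattribute a focal monoclonal TRA event to the nested TRD locus.

    If every qualifying evidence segment of a monoclonal TRA call lies
    entirely within the TRD extent, the event is really a TRD loss seen
    through TRA; a monoclonal TRD call is emitted and the TRA call is
    downgraded (polyclonal if its slopy criterion independently holds,
    else no loss).
    """
    params = params or ClonalityParams()
    if locus_tra.nested_locus is None:
        return tra_call, None
    if locus_trd is None:
        raise ValueError("TRA declares a nested locus but no TRD definition given")
    if tra_call.category != MONOCLONAL or not tra_call.evidence:
        return tra_call, None

    trd_iv = locus_trd.extent
    focal = all(
        trd_iv.start <= rs.segment.start_bp and rs.segment.end_bp <= trd_iv.end
        for rs in tra_call.evidence
    )
    if not focal:
        return tra_call, None

    trd_call = ClonalityCall(
        locus=locus_trd.name,
        category=MONOCLONAL,
        allelic=tra_call.allelic,
        evidence=list(tra_call.evidence),
        attributed_from=locus_tra.name,
        sample_id=tra_call.sample_id,
    )
    # downgraded TRA: polyclonal if the slopy criterion independently holds
    run = _slopy_run(all_segments, locus_tra, params) if all_segments else []
    if run:
        new_tra = ClonalityCall(
            locus=tra_call.locus,
            category=POLYCLONAL,
            allelic=INDETERMINATE,
            evidence=run,
            sample_id=tra_call.sample_id,
        )
    else:
        new_tra = ClonalityCall(
            locus=tra_call.locus,
            category=NO_LOSS,
            allelic=INDETERMINATE,
            evidence=[],
            sample_id=tra_call.sample_id,
        )
    return new_tra, trd_call


# ---------------------------------------------------------------------------
# orchestration


def call_locus(
    tumor: CoverageTrack,
    normal: CoverageTrack,
    locus: LocusDefinition,
    params: Optional[ClonalityParams] = None,
) -> tuple[ClonalityCall, list[RatioSegment], Signal]:
    """Whole-locus pipeline for one locus (no zoom, no TRD attribution)."""
    params = params or ClonalityParams()
    if tumor.bin_size < params.bin_size:
        factor = params.bin_size // tumor.bin_size
        t, n = tumor.rebin(factor), normal.rebin(factor)
    else:
        t, n = tumor, normal
    sig = copy_ratio_signal(t, n, params)
    hw = min(params.half_window, (len(sig) - 1) // 2)
    if hw >= 1 and len(sig) > 2 * hw:
        sig = winsorize(sig, params.tau, hw)
    segs = segment_pcf(sig, params.gamma, params.kmin)
    ratio_segs = make_ratio_segments(sig, segs, params)
    call = classify_locus(ratio_segs, locus, params, signal_values=sig.values)
    return call, ratio_segs, sig


def call_sample(
    tumor_tracks: dict[str, CoverageTrack],
    normal_tracks: dict[str, CoverageTrack],
    loci: list[LocusDefinition],
    params: Optional[ClonalityParams] = None,
    sample_id: str = "sample",
) -> SampleCall:
    """Full per-sample pipeline over all requested loci.

    Winsorize -> segment -> ratio/CN -> classify; always re-checks the D-J
    window of D-bearing loci at fine bins (such deletions are easily missed
    at whole-locus scale); reattributes focal TRA events to nested TRD.
    The sample is flagged as a clonal T-cell process when at least one TCR
    locus is monoclonal.
    """
    params = params or ClonalityParams()
    by_name = {l.name: l for l in loci}
    calls: dict[str, ClonalityCall] = {}
    segs_by_locus: dict[str, list[RatioSegment]] = {}

    for locus in loci:
        if locus.name not in tumor_tracks:
            raise ValueError(f"missing tumor track for {locus.name}")
        if locus.name not in normal_tracks:
            raise ValueError(
                f"missing matched normal track for {locus.name}: "
                "the method is matched-pair by construction"
            )
        tumor, normal = tumor_tracks[locus.name], normal_tracks[locus.name]
        call, ratio_segs, _ = call_locus(tumor, normal, locus, params)
        segs_by_locus[locus.name] = ratio_segs
        call.sample_id = sample_id

        if locus.has_d_segments and tumor.bin_size <= params.zoom_bin_size:
            hit = detect_dj_microdeletion(tumor, normal, locus, params)
            if hit is not None:
                logger.debug("%s: D-J zoom hit at %d-%d", locus.name,
                             hit.segment.start_bp, hit.segment.end_bp)
                if call.category != MONOCLONAL:
                    call = ClonalityCall(
                        locus=locus.name,
                        category=MONOCLONAL,
                        allelic=_allelic_status([hit], params),
                        evidence=[hit],
                        zoom_hit=hit,
                        sample_id=sample_id,
                    )
                else:
                    call.zoom_hit = hit
        calls[locus.name] = call

    if "TRA" in calls and by_name.get("TRA") is not None:
        tra_locus = by_name["TRA"]
        if tra_locus.nested_locus and tra_locus.nested_locus in by_name:
            trd_locus = by_name[tra_locus.nested_locus]
            new_tra, trd_from_tra = attribute_nested_trd(
                calls["TRA"],
                tra_locus,
                trd_locus,
                params,
                all_segments=segs_by_locus.get("TRA"),
            )
            if trd_from_tra is not None:
                calls["TRA"] = new_tra
                existing = calls.get("TRD")
                if existing is None or existing.category != MONOCLONAL:
                    calls["TRD"] = trd_from_tra

    ordered = [calls[l.name] for l in loci if l.name in calls]
    for name in calls:
        if name not in {l.name for l in loci}:
            ordered.append(calls[name])
    clonal = any(
        c.category == MONOCLONAL and c.locus in TCR_LOCI for c in ordered
    )
    return SampleCall(sample_id=sample_id, calls=ordered, clonal_t_cell_process=clonal)
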