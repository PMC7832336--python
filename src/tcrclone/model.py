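"""Model/Results facade over the per-locus pipeline.

``LocusClonalityModel`` wraps one locus of one matched tumor/normal pair;
``fit()`` runs winsorization, piecewise-constant segmentation, ratio/CN
calling and clonality classification, returning a
:class:`LocusClonalityResults` that carries the segments, the call, and
presentation helpers (``summary()``, ``segments_frame()``, ``plot()``).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .clonality import (
    ClonalityCall,
    ClonalityParams,
    call_locus,
    detect_dj_microdeletion,
)
from .cn import RatioSegment
from .coverage import CoverageTrack, track_from_depth_tsv
from .loci import LocusDefinition
from .segmentation import Signal


class LocusClonalityModel:
    """Clonality model for one receptor locus of a matched pair.

    Parameters
    ----------
    tumor, normal
        Binned coverage tracks over the locus extent, identical bins.
        Bins must be at least as fine as ``params.zoom_bin_size`` for the
        D-J microdeletion check to run.
    locus
        Locus definition with V/D/J annotation.
    params
        Pipeline thresholds; defaults follow the package defaults.
    """

    def __init__(
        self,
        tumor: CoverageTrack,
        normal: CoverageTrack,
        locus: LocusDefinition,
        params: Optional[ClonalityParams] = None,
    ):
        if not tumor.same_bins(normal):
            raise ValueError("tumor and normal tracks must share identical bins")
        self.tumor = tumor
        self.normal = normal
        self.locus = locus
        self.params = params or ClonalityParams()

    @classmethod
    def from_depth_tsv(
        cls,
        tumor_path,
        normal_path,
        locus: LocusDefinition,
        params: Optional[ClonalityParams] = None,
        bin_size: Optional[int] = None,
    ) -> "LocusClonalityModel":
        """Build from two samtools-depth TSVs restricted to the locus."""
        params = params or ClonalityParams()
        bs = bin_size or params.zoom_bin_size
        tumor = track_from_depth_tsv(tumor_path, locus.extent, bs)
        normal = track_from_depth_tsv(normal_path, locus.extent, bs)
        return cls(tumor, normal, locus, params)

    def fit(self) -> "LocusClonalityResults":
        call, ratio_segs, signal = call_locus(
            self.tumor, self.normal, self.locus, self.params
        )
        zoom_hit = None
        if (
            self.locus.has_d_segments
            and self.tumor.bin_size <= self.params.zoom_bin_size
        ):
            zoom_hit = detect_dj_microdeletion(
                self.tumor, self.normal, self.locus, self.params
            )
            if zoom_hit is not None and call.category != "monoclonal":
                from .clonality import MONOCLONAL, _allelic_status

                call = ClonalityCall(
                    locus=self.locus.name,
                    category=MONOCLONAL,
                    allelic=_allelic_status([zoom_hit], self.params),
                    evidence=[zoom_hit],
                    zoom_hit=zoom_hit,
                )
            elif zoom_hit is not None:
                call.zoom_hit = zoom_hit
        return LocusClonalityResults(self, call, ratio_segs, signal)


class LocusClonalityResults:
    """Fitted segmentation + clonality verdict for one locus."""

    def __init__(
        self,
        model: LocusClonalityModel,
        call: ClonalityCall,
        ratio_segments: list[RatioSegment],
        signal: Signal,
    ):
        self.model = model
        self.call = call
        self.ratio_segments = ratio_segments
        self.signal = signal

    @property
    def category(self) -> str:
        return self.call.category

    @property
    def allelic(self) -> str:
        return self.call.allelic

    def segments_frame(self) -> pd.DataFrame:
        """Per-segment table: coordinates, log2 ratio, CN, flatness slope."""
        rows = [rs.to_dict() for rs in self.ratio_segments]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        locus = self.model.locus
        lines = [
            f"Locus clonality fit: {locus.name} "
            f"({locus.extent.chrom}:{locus.extent.start}-{locus.extent.end})",
            f"  bins: {len(self.signal)} x {self.signal.bin_size} bp, "
            f"gamma={self.model.params.gamma}, kmin={self.model.params.kmin}",
            f"  segments: {len(self.ratio_segments)}",
            f"  call: {self.call.category} ({self.call.allelic})",
        ]
        if self.call.zoom_hit is not None:
            z = self.call.zoom_hit.segment
            lines.append(
                f"  D-J zoom hit: {z.start_bp}-{z.end_bp} "
                f"(log2 {self.call.zoom_hit.log2_ratio:.2f}, CN {self.call.zoom_hit.cn})"
            )
        lines.append(
            "  "
            + "-" * 68
            + "\n  "
            + f"{'start_bp':>10} {'end_bp':>10} {'width_kb':>9} "
            f"{'log2':>7} {'CN':>3} {'slope/10kb':>11}"
        )
        for rs in self.ratio_segments:
            s = rs.segment
            lines.append(
                f"  {s.start_bp:>10} {s.end_bp:>10} {s.width_bp / 1000:>9.1f} "
                f"{rs.log2_ratio:>7.2f} {rs.cn:>3} {rs.slope_per_10kb:>11.3f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Coverage-ratio plot with segment means, colored by copy number."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = self.signal.positions / 1e3
        ax.plot(x, self.signal.values, ".", ms=2, color="0.7", label="bins")
        cmap = {0: "tab:red", 1: "tab:orange", 2: "tab:gray", 3: "tab:blue", 4: "tab:purple"}
        for rs in self.ratio_segments:
            s = rs.segment
            ax.hlines(
                rs.log2_ratio,
                s.start_bp / 1e3,
                s.end_bp / 1e3,
                color=cmap.get(rs.cn, "k"),
                lw=3,
            )
        ax.set_xlabel(f"{self.model.locus.extent.chrom} position (kb)")
        ax.set_ylabel("log2 tumor/normal")
        ax.set_title(
            f"{self.model.locus.name}: {self.call.category} ({self.call.allelic})"
        )
        return ax
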