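"""Antigen-receptor locus definitions and the flat-file formats around them.

The antigen-receptor loci (TRA/TRB/TRG/TRD and IGH/IGK/IGL) share a common
architecture: an array of variable (V) gene segments, an optional cluster of
diversity (D) segments, and a cluster of joining (J) segments.  Somatic
V(D)J recombination deletes the DNA between the joined segments, which is
what makes clonal rearrangements visible as copy-number loss in WGS
coverage.  TRD is physically nested inside TRA, so a focal TRA loss may in
fact be a TRD event.

Coordinates are 0-based half-open internally.  BED input/output is 0-based
half-open (native BED); samtools-depth TSV positions are 1-based and are
converted exactly once at the parsing boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

KNOWN_LOCI = ("TRA", "TRB", "TRG", "TRD", "IGH", "IGK", "IGL")

#: loci whose recombination starts with a D-to-J joining step; only these
#: can carry the small incomplete D-J deletions that need a zoomed view.
D_BEARING_LOCI = ("TRB", "TRD", "IGH")


class BedParseError(ValueError):
    """Malformed BED line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"BED line {lineno}: {message}")
        self.lineno = lineno


class LocusValidationError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise LocusValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise LocusValidationError(
                f"empty/inverted interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class LocusDefinition:
    """One receptor locus with its ordered V/D/J sub-segment annotation.

    ``orientation`` is the direction in which V-to-J recombination deletes
    intervening sequence along genomic coordinates: ``forward`` when the J
    cluster sits at higher coordinates than the V array, ``reverse``
    otherwise.  The polyclonal "slopy" coverage decline runs toward the J
    cluster in this direction.
    """

    name: str
    extent: GenomicInterval
    v_segments: list[GenomicInterval] = field(default_factory=list)
    d_segments: list[GenomicInterval] = field(default_factory=list)
    j_segments: list[GenomicInterval] = field(default_factory=list)
    orientation: str = "forward"
    nested_locus: Optional[str] = None
    segment_names: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise LocusValidationError(f"bad orientation {self.orientation!r}")
        for role, segs in (
            ("V", self.v_segments),
            ("D", self.d_segments),
            ("J", self.j_segments),
        ):
            prev_end = -1
            for seg in segs:
                if not self.extent.contains(seg):
                    raise LocusValidationError(
                        f"{self.name} {role} segment [{seg.start}, {seg.end}) "
                        f"outside locus extent [{self.extent.start}, {self.extent.end})"
                    )
                if seg.start < prev_end:
                    raise LocusValidationError(
                        f"{self.name} {role} segments unsorted or overlapping"
                    )
                prev_end = seg.end

    @property
    def has_d_segments(self) -> bool:
        return len(self.d_segments) > 0

    def j_side(self) -> str:
        """Which end of the locus the J cluster sits on ('left'/'right')."""
        if self.orientation == "forward":
            return "right"
        return "left"

    def sorted_sub_segments(self) -> list[tuple[str, GenomicInterval]]:
        out = [("V", s) for s in self.v_segments]
        out += [("D", s) for s in self.d_segments]
        out += [("J", s) for s in self.j_segments]
        return sorted(out, key=lambda t: (t[1].start, t[1].end))


@dataclass(frozen=True)
class DepthRecord:
    """Per-base depth at a 0-based position (converted from 1-based input)."""

    chrom: str
    pos: int
    depth: int

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth} at {self.chrom}:{self.pos}")


def _infer_orientation(
    v_segments: list[GenomicInterval], j_segments: list[GenomicInterval]
) -> str:
    if not v_segments or not j_segments:
        return "forward"
    v_mid = sum(s.start for s in v_segments) / len(v_segments)
    j_mid = sum(s.start for s in j_segments) / len(j_segments)
    return "forward" if j_mid >= v_mid else "reverse"


def read_locus_bed(path: str | Path) -> list[LocusDefinition]:
    """Read locus definitions from a 4-column BED.

    The 4th column encodes ``LOCUS`` for the locus extent row or
    ``LOCUS|ROLE|NAME`` (role in V/D/J) for a sub-segment row, e.g.
    ``TRB|V|TRBV5-1``.  Sub-segments must lie within their locus extent.
    When both TRA and TRD are present and TRD's extent is contained in
    TRA's, TRA is marked as carrying the nested TRD locus.
    """
    extents: dict[str, GenomicInterval] = {}
    subs: dict[str, dict[str, list[GenomicInterval]]] = {}
    names: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(lineno, f"expected >=4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(lineno, f"non-integer coordinates: {exc}") from exc
            if end <= start or start < 0:
                raise BedParseError(lineno, f"bad interval [{start}, {end})")
            label = fields[3]
            parts = label.split("|")
            locus = parts[0]
            if locus not in subs:
                subs[locus] = {"V": [], "D": [], "J": []}
                names[locus] = {}
                order.append(locus)
            iv = GenomicInterval(chrom, start, end)
            if len(parts) == 1:
                if locus in extents:
                    raise BedParseError(lineno, f"duplicate extent row for {locus}")
                extents[locus] = iv
            elif len(parts) == 3:
                role = parts[1]
                if role not in ("V", "D", "J"):
                    raise BedParseError(lineno, f"unknown segment role {role!r}")
                subs[locus][role].append(iv)
                names[locus][(iv.start, iv.end)] = parts[2]
            else:
                raise BedParseError(lineno, f"cannot parse name field {label!r}")

    loci: list[LocusDefinition] = []
    for locus in order:
        if locus not in extents:
            raise LocusValidationError(f"locus {locus} has sub-segments but no extent row")
        v = sorted(subs[locus]["V"], key=lambda s: s.start)
        d = sorted(subs[locus]["D"], key=lambda s: s.start)
        j = sorted(subs[locus]["J"], key=lambda s: s.start)
        loci.append(
            LocusDefinition(
                name=locus,
                extent=extents[locus],
                v_segments=v,
                d_segments=d,
                j_segments=j,
                orientation=_infer_orientation(v, j),
                segment_names=names[locus],
            )
        )

    by_name = {l.name: l for l in loci}
    if "TRA" in by_name and "TRD" in by_name:
        tra, trd = by_name["TRA"], by_name["TRD"]
        if tra.extent.contains(trd.extent):
            tra.nested_locus = "TRD"
    return loci


def write_locus_bed(loci: Iterable[LocusDefinition], path: str | Path) -> None:
    """Write locus definitions in the BED dialect read_locus_bed accepts."""
    with open(path, "w") as fh:
        for locus in loci:
            e = locus.extent
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{locus.name}\n")
            for role, segs in (
                ("V", locus.v_segments),
                ("D", locus.d_segments),
                ("J", locus.j_segments),
            ):
                for i, seg in enumerate(segs, start=1):
                    name = locus.segment_names.get(
                        (seg.start, seg.end), f"{locus.name}{role}{i}"
                    )
                    fh.write(
                        f"{seg.chrom}\t{seg.start}\t{seg.end}\t{locus.name}|{role}|{name}\n"
                    )


def load_default_loci() -> list[LocusDefinition]:
    """Locus BED shipped with the package (hg38, approximate template).

    The shipped coordinates are a starting point compiled from public genome
    annotation; sites should supply their own BED matching their reference
    build and preferred (IMGT vs RefSeq) annotation set.
    """
    ref = importlib.resources.files("tcrclone").joinpath("data/loci_hg38.bed")
    with importlib.resources.as_file(ref) as p:
        return read_locus_bed(p)


def read_depth_tsv(
    path: str | Path,
    interval: GenomicInterval,
    densify: bool = False,
) -> list[DepthRecord]:
    """Read a samtools-depth style TSV (chrom, 1-based pos, depth).

    Returns records restricted to ``interval`` with positions converted to
    0-based.  With ``densify=True``, positions of the interval absent from
    the file are emitted with depth 0 so the track is dense.  Positions must
    be sorted within a chromosome; negative depths are rejected.
    """
    records: list[DepthRecord] = []
    last_pos: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"depth TSV line {lineno}: expected 3 columns")
            chrom = fields[0]
            try:
                pos1 = int(fields[1])
                depth = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"depth TSV line {lineno}: {exc}") from exc
            if depth < 0:
                raise ValueError(f"depth TSV line {lineno}: negative depth {depth}")
            if chrom in last_pos and pos1 <= last_pos[chrom]:
                raise ValueError(
                    f"depth TSV line {lineno}: unsorted position {pos1} on {chrom}"
                )
            last_pos[chrom] = pos1
            pos0 = pos1 - 1
            if chrom == interval.chrom and interval.start <= pos0 < interval.end:
                records.append(DepthRecord(chrom, pos0, depth))

    if densify:
        have = {r.pos: r for r in records}
        records = [
            have.get(p, DepthRecord(interval.chrom, p, 0))
            for p in range(interval.start, interval.end)
        ]
    return records


def write_depth_tsv(records: Iterable[DepthRecord], path: str | Path) -> None:
    """Write records as samtools-depth TSV (positions back to 1-based)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.depth}\n")
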