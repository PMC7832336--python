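"""Clonality report serialization (TSV for eyes, JSON for round-trips)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .clonality import ClonalityCall

TSV_COLUMNS = (
    "sample_id",
    "locus",
    "category",
    "allelic",
    "attributed_from",
    "n_evidence_segments",
    "evidence_segments",
    "evidence_log2",
    "evidence_cn",
    "zoom_hit",
)


def _fmt_segments(call: ClonalityCall) -> tuple[str, str, str]:
    coords = ";".join(
        f"{rs.segment.start_bp}-{rs.segment.end_bp}" for rs in call.evidence
    )
    log2s = ";".join(f"{rs.log2_ratio:.4f}" for rs in call.evidence)
    cns = ";".join(str(rs.cn) for rs in call.evidence)
    return coords or ".", log2s or ".", cns or "."


def write_report(
    calls: Sequence[ClonalityCall],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write one row/object per locus call.

    TSV has a fixed, deterministic column order; JSON preserves the full
    call structure and round-trips losslessly via :func:`read_report_json`.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls to write")
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for call in calls:
                coords, log2s, cns = _fmt_segments(call)
                zoom = (
                    f"{call.zoom_hit.segment.start_bp}-{call.zoom_hit.segment.end_bp}"
                    if call.zoom_hit
                    else "."
                )
                row = (
                    call.sample_id or ".",
                    call.locus,
                    call.category,
                    call.allelic,
                    call.attributed_from or ".",
                    str(len(call.evidence)),
                    coords,
                    log2s,
                    cns,
                    zoom,
                )
                fh.write("\t".join(row) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([c.to_dict() for c in calls], fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> list[ClonalityCall]:
    with open(path) as fh:
        data = json.load(fh)
    return [ClonalityCall.from_dict(d) for d in data]
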