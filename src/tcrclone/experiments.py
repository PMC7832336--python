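"""Canned simulation experiments: dilution sensitivity, pattern archetypes,
D-J microdeletion recovery, low-purity detection.

These reproduce, on synthetic data, the sensitivity analyses that motivate
the pipeline: how far a monoclonal rearrangement remains detectable under
in-silico dilution, how its apparent copy number degrades with tumor
content, and whether the three canonical coverage patterns (clonal flat
loss, polyclonal slopy staircase, germline no-loss) classify correctly.

All experiments are fully seeded; child seeds are spawned from the master
seed so replicates are independent but reproducible.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .clonality import MONOCLONAL, ClonalityParams, call_locus, call_sample, detect_dj_microdeletion
from .cn import estimate_tumor_content
from .dilution import mix_tracks, MixtureSpec
from .loci import GenomicInterval
from .synthetic import (
    CloneSimSpec,
    PolyclonalSpec,
    simulate_sample,
    simulate_vafs,
    trb_like_locus,
    trg_like_locus,
)

DEPTH = 30.0  # mean per-base diploid depth used throughout (30x WGS)
SIM_BIN = 25  # bp; fine enough for the D-J zoom

TRG_DELETION = (30_000, 141_500)  # V-J bounded biallelic deletion interval
TRB_VJ_DELETION = (200_000, 471_500)
TRB_DJ_DELETION = (471_720, 473_280)  # 1.56 kb incomplete D-J interval
TRG_LOW_PURITY_DELETION = (20_000, 40_000)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _params(purity: Optional[float] = None) -> ClonalityParams:
    return ClonalityParams(
        purity=purity, tumor_lib_depth=DEPTH, normal_lib_depth=DEPTH
    )


def _trg_spec(
    tumor_fraction: float,
    seed: int,
    deletion: Optional[tuple[int, int]] = None,
    biallelic: bool = True,
    fraction_rearranged: float = 0.0,
) -> CloneSimSpec:
    locus = trg_like_locus()
    iv = (
        GenomicInterval(locus.extent.chrom, *deletion)
        if deletion is not None
        else None
    )
    return CloneSimSpec(
        locus=locus,
        tumor_fraction=tumor_fraction,
        allele1_deletion=iv,
        allele2_deletion=iv if (iv is not None and biallelic) else None,
        background=PolyclonalSpec(fraction_rearranged=fraction_rearranged),
        mean_depth=DEPTH,
        bin_size=SIM_BIN,
        seed=seed,
    )


def dilution_detection(
    seed: int,
    n_replicates: int = 20,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    tumor_purity: float = 0.93,
) -> dict[float, int]:
    """Monoclonal-TRG detection counts across an in-silico dilution series.

    A T-lineage tumor with a biallelic TRG deletion (purity ``tumor_purity``)
    is mixed into an NK-like background (germline TCR loci) at each
    fraction; classification is purity-aware with the known diluted
    content.  Returns {fraction: number of replicates called monoclonal}.
    """
    locus = trg_like_locus()
    counts = {f: 0 for f in fractions}
    for rep_seed in _child_seeds(seed, n_replicates):
        sub = _child_seeds(rep_seed, 4)
        tum_a, _, _ = simulate_sample(_trg_spec(tumor_purity, sub[0], TRG_DELETION))
        tum_b, _, _ = simulate_sample(_trg_spec(0.0, sub[1]))
        _, normal, _ = simulate_sample(_trg_spec(0.0, sub[2]))
        mix_seeds = _child_seeds(sub[3], len(fractions))
        for frac, mseed in zip(fractions, mix_seeds):
            mixed = mix_tracks(
                tum_a,
                tum_b,
                MixtureSpec(a=frac, target_depth=DEPTH),
                seed=mseed,
                a_ref_depth=DEPTH,
                b_ref_depth=DEPTH,
            )
            call, _, _ = call_locus(
                mixed, normal, locus, _params(purity=frac * tumor_purity)
            )
            if call.category == MONOCLONAL:
                counts[frac] += 1
    return counts


def lowest_detected_fraction(
    counts: dict[float, int], n_replicates: int
) -> Optional[float]:
    """Smallest dilution fraction still detected in a majority of replicates,
    requiring detection at every fraction above it (persistence)."""
    lowest = None
    for frac in sorted(counts, reverse=True):
        if counts[frac] > n_replicates / 2:
            lowest = frac
        else:
            break
    return lowest


def diluted_cn_calls(
    seed: int,
    n_replicates: int = 20,
    fraction: float = 0.2,
) -> list[int]:
    """Raw threshold CN of the deletion segment after dilution to ``fraction``.

    A fully clonal biallelic TRG deletion is diluted into a deletion-free
    background; the deepest segment's raw (unadjusted) copy number is
    recorded per replicate.  At 20% the expected log2 ratio is
    log2(0.8) ~ -0.32, i.e. the biallelic loss masquerades as CN 1.
    """
    locus = trg_like_locus()
    out = []
    for rep_seed in _child_seeds(seed, n_replicates):
        sub = _child_seeds(rep_seed, 4)
        tum_a, _, _ = simulate_sample(_trg_spec(1.0, sub[0], TRG_DELETION))
        tum_b, _, _ = simulate_sample(_trg_spec(0.0, sub[1]))
        _, normal, _ = simulate_sample(_trg_spec(0.0, sub[2]))
        mixed = mix_tracks(
            tum_a,
            tum_b,
            MixtureSpec(a=fraction, target_depth=DEPTH),
            seed=sub[3],
            a_ref_depth=DEPTH,
            b_ref_depth=DEPTH,
        )
        _, segs, _ = call_locus(mixed, normal, locus, _params())
        deepest = min(segs, key=lambda rs: rs.log2_ratio)
        out.append(deepest.cn)
    return out


def archetype_calls(kind: str, seed: int, n_replicates: int = 20) -> list[str]:
    """Classify replicates of the three canonical coverage patterns.

    kind: 'clonal' (90% tumor, biallelic V-J deletion in a reactive
    background), 'normal_t' (pure polyclonal T cells), or 'nk' (germline
    loci, no rearrangement at all).
    """
    locus = trb_like_locus()
    settings = {
        "clonal": dict(f=0.9, fr=0.7, deletion=TRB_VJ_DELETION),
        "normal_t": dict(f=0.0, fr=0.7, deletion=None),
        "nk": dict(f=0.0, fr=0.0, deletion=None),
    }
    if kind not in settings:
        raise ValueError(f"unknown archetype {kind!r}")
    s = settings[kind]
    out = []
    for rep_seed in _child_seeds(seed, n_replicates):
        iv = (
            GenomicInterval(locus.extent.chrom, *s["deletion"])
            if s["deletion"]
            else None
        )
        spec = CloneSimSpec(
            locus=locus,
            tumor_fraction=s["f"],
            allele1_deletion=iv,
            allele2_deletion=iv,
            background=PolyclonalSpec(fraction_rearranged=s["fr"]),
            mean_depth=DEPTH,
            bin_size=SIM_BIN,
            seed=rep_seed,
        )
        tumor, normal, _ = simulate_sample(spec)
        result = call_sample(
            {"TRB": tumor}, {"TRB": normal}, [locus], _params()
        )
        out.append(result.call_for("TRB").category)
    return out


def dj_microdeletion_recovery(
    seed: int, n_replicates: int = 10
) -> list[tuple[str, bool]]:
    """Whole-locus category vs zoomed D-J detection for a 1.5 kb deletion.

    Simulates an isolated incomplete D-J rearrangement (monoallelic,
    TRBD1 to just before TRBJ2-7) at 40% tumor fraction.  Returns
    (whole-locus category, zoom hit found) per replicate: the deletion is
    far below the whole-locus minimum flat width, so only the magnified
    D-J re-segmentation should see it.
    """
    locus = trb_like_locus()
    out = []
    for rep_seed in _child_seeds(seed, n_replicates):
        spec = CloneSimSpec(
            locus=locus,
            tumor_fraction=0.4,
            allele1_deletion=GenomicInterval(locus.extent.chrom, *TRB_DJ_DELETION),
            background=PolyclonalSpec(fraction_rearranged=0.0),
            mean_depth=DEPTH,
            bin_size=SIM_BIN,
            seed=rep_seed,
        )
        tumor, normal, _ = simulate_sample(spec)
        params = _params()
        whole, _, _ = call_locus(tumor, normal, locus, params)
        hit = detect_dj_microdeletion(tumor, normal, locus, params)
        out.append((whole.category, hit is not None))
    return out


def low_purity_detection(seed: int, n_replicates: int = 20) -> list[bool]:
    """Detection of a monoallelic 20 kb deletion at 13% tumor content.

    The tumor content is *estimated* from simulated somatic VAFs
    (2 x median), then classification runs purity-aware with that
    estimate — the full low-purity workflow end to end.
    """
    locus = trg_like_locus()
    out = []
    for rep_seed in _child_seeds(seed, n_replicates):
        sub = _child_seeds(rep_seed, 2)
        spec = _trg_spec(
            0.13,
            sub[0],
            TRG_LOW_PURITY_DELETION,
            biallelic=False,
            fraction_rearranged=0.7,
        )
        tumor, normal, _ = simulate_sample(spec)
        purity = estimate_tumor_content(simulate_vafs(spec, 400, sub[1]))
        call, _, _ = call_locus(tumor, normal, locus, _params(purity=purity))
        out.append(call.category == MONOCLONAL)
    return out
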