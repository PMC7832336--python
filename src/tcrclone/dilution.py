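"""In-silico dilution of one sample's coverage into another's.

The paper-style sensitivity experiment mixes a tumor sample A into a
background sample B so the resultant behaves like A at tumor proportion
``a``:  Resultant = a*A + (1-a)*B.  Here the mixing happens on binned
coverage by binomial thinning of each sample's per-bin base counts, which
preserves Poisson sampling character without touching read-level data:

    mixed_count = Binomial(A_count, a * s_A) + Binomial(B_count, (1-a) * s_B)

where s_A, s_B rescale each sample to a common target depth.  The default
target is the mixture's natural depth a*ref_A + (1-a)*ref_B (always
reachable by thinning); pass an explicit ``target_depth`` to hold depth
constant across a dilution series.  Per-bin expectation is exactly
a*A_hat + (1-a)*B_hat.

With real aligned data the same experiment is a one-liner outside this
package: ``samtools view -s`` each BAM at the complementary fractions,
``samtools merge``, then ``samtools depth`` into the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coverage import CoverageTrack


@dataclass(frozen=True)
class MixtureSpec:
    """Mixing proportion and optional common target depth."""

    a: float
    target_depth: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"mixture proportion a={self.a} outside [0, 1]")
        if self.target_depth is not None and self.target_depth <= 0:
            raise ValueError("target_depth must be positive")


def mix_tracks(
    A: CoverageTrack,
    B: CoverageTrack,
    spec: MixtureSpec,
    seed: int,
    a_ref_depth: Optional[float] = None,
    b_ref_depth: Optional[float] = None,
) -> CoverageTrack:
    """Mix two tracks at proportion ``spec.a`` of A by binomial thinning.

    ``a_ref_depth``/``b_ref_depth`` are each sample's copy-neutral reference
    depth (default: the track's own mean).  Pass them explicitly when the
    tracks carry large deletions — rescaling by a deletion-depressed mean
    would silently shift the effective mixing proportion.
    """
    if not A.same_bins(B):
        raise ValueError("tracks must cover identical bins")
    rng = np.random.default_rng(seed)
    ref_a = a_ref_depth if a_ref_depth is not None else A.mean_depth()
    ref_b = b_ref_depth if b_ref_depth is not None else B.mean_depth()
    if spec.target_depth is not None:
        target = spec.target_depth
    else:
        # the mixture's natural depth: always reachable by thinning alone
        target = spec.a * ref_a + (1.0 - spec.a) * ref_b
    s_a = target / ref_a if ref_a > 0 else 0.0
    s_b = target / ref_b if ref_b > 0 else 0.0
    p_a = spec.a * s_a
    p_b = (1.0 - spec.a) * s_b
    tol = 1e-9
    if p_a > 1.0 + tol or p_b > 1.0 + tol:
        raise ValueError(
            "thinning probability exceeds 1; target depth too high for inputs"
        )
    p_a, p_b = min(p_a, 1.0), min(p_b, 1.0)

    counts_a = np.round(A.values * A.bin_size).astype(np.int64)
    counts_b = np.round(B.values * B.bin_size).astype(np.int64)
    mixed = rng.binomial(counts_a, p_a) + rng.binomial(counts_b, p_b)
    return CoverageTrack(A.interval, A.bin_size, mixed / A.bin_size)


def dilution_series(
    A: CoverageTrack,
    B: CoverageTrack,
    fractions: Sequence[float],
    seed: int,
    target_depth: Optional[float] = None,
    a_ref_depth: Optional[float] = None,
    b_ref_depth: Optional[float] = None,
) -> list[tuple[float, CoverageTrack]]:
    """One mixture per fraction, independently seeded.

    Child seeds are spawned deterministically from the master seed so each
    fraction's noise is independent but the whole series reproduces.  Pass
    ``target_depth`` to hold the resultant depth constant across the
    series (recommended: the shallower sample's reference depth).
    """
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(fractions))
    out = []
    for frac, child in zip(fractions, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        spec = MixtureSpec(a=frac, target_depth=target_depth)
        out.append(
            (
                frac,
                mix_tracks(
                    A,
                    B,
                    spec,
                    seed=child_seed,
                    a_ref_depth=a_ref_depth,
                    b_ref_depth=b_ref_depth,
                ),
            )
        )
    return out
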