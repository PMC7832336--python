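# Methods

## The problem

Every T lymphocyte assembles its antigen receptor by V(D)J recombination:
one variable (V), optionally one diversity (D), and one joining (J) gene
segment are fused, and the DNA between them is excised.  A healthy T-cell
population is polyclonal — thousands of clones, each with a different
V(D)J choice — whereas a T-cell lymphoma is a single clone expanded, every
cell carrying the *same* deletion on the same allele(s).  In whole-genome
sequencing coverage of a receptor locus (TRA, TRB, TRG, TRD; analogously
IGH/IGK/IGL for B cells) these two situations look qualitatively
different:

* **monoclonal**: a flat, sharply bounded trough of coverage over the
  shared deleted interval — one copy lost per rearranged allele, so the
  trough sits at copy number 1 (monoallelic) or 0 (biallelic, when the
  deletions on the two alleles overlap);
* **polyclonal**: a "slopy" staircase that declines toward the J cluster,
  because the aggregate of many different V–J deletions removes a larger
  fraction of alleles the closer a position lies to the J genes;
* **no loss**: flat diploid coverage (NK-lineage tumors, non-lymphoid
  tissue).

`tcrclone` classifies each locus into one of these categories from a
matched tumor/normal pair of per-base depth tracks, and resolves the
allelic status of monoclonal calls.

## Pipeline

1. **Binning.**  Per-base depth (samtools-depth TSV) is averaged in
   fixed-width bins: 100 bp for whole-locus analysis, 25 bp for the
   zoomed D–J window.  Binning is a noise/runtime tradeoff only; the bin
   mean keeps the information of the per-base track it summarizes.
2. **Copy-ratio signal.**  Per bin, the diploid-equivalent copy estimate
   `2·(t/t_lib)/(n/n_lib)` is formed, with a pseudocount `epsilon = 0.01`
   in normalized-depth units so biallelic losses stay finite.  Library
   depths default to each track's median bin depth (robust while less
   than half the region is deleted) and should be given explicitly
   (a copy-neutral reference region) when deletions are expected to be
   broad.
3. **Winsorization.**  Each bin is clipped to a running median ± tau·MAD
   band (tau = 2.5 sigma-scaled, window ±25 bins, edges truncated).
   Genuine steps survive (each bin's window median matches its own side);
   isolated spikes are pulled to the local level.
4. **Segmentation (PCF).**  The signal is partitioned into
   piecewise-constant segments by exact minimization of
   `sum (x_i − mean_seg)² + gamma·sigma²·(#breakpoints)` with a minimum
   segment length `kmin`.  `sigma²` is estimated from the MAD of lag-1
   differences (÷√2) — as an upper envelope (90th percentile of 50-bin
   windowed MADs), since count noise is quiet inside deletions and a
   global MAD dominated by a broad loss would over-segment the neutral
   ground.  This makes `gamma` scale-free across depths; defaults
   `gamma = 40`, `kmin = 5` bins follow the established defaults for
   single-sample PCF.  Two solvers share the objective: a vectorized
   O(n²) dynamic program in production and an independently coded plain
   DP as a verification oracle (`segment_pcf_exact`); ties break toward
   fewer, then leftmost, breakpoints.

   Segmentation runs in copy-ratio space, not log space.  For count data
   the variance scales *with* the signal, so a deleted region is quiet in
   copy space — as it is in the raw-read coverage plots the method is
   built on — while a log transform amplifies its noise and fragments
   deep troughs.  Log2 ratios are computed per segment afterwards (log of
   the segment mean, which is unbiased at low counts) for thresholding.
5. **Copy number.**  Each segment's log2 ratio maps to an absolute copy
   number through fixed cutoffs: < −1.1 → 0; [−1.1, −0.25) → 1;
   [−0.25, 0.2) → 2; [0.2, 0.7] → 3; > 0.7 → 4.  Boundaries are owned by
   the higher CN; the convention is configuration, not biology.
6. **Classification.**  A locus is **monoclonal** if some contiguous run
   of segments — each with (effective) CN ≤ 1 and internally flat — forms
   a genuine *trough*: total width ≥ 2 kb, and the segments flanking the
   run sit at least `min_step_log2 = 0.25` above the run members they
   touch, on **both** sides.  Both-sidedness is the discriminator between
   a clonal deletion (coverage recovers past both breakpoints, at the J
   cluster at the latest) and a polyclonal staircase step or terminal
   plateau, which falls on one side only.  Runs rather than single
   segments are tested because the segmenter may legitimately split a
   trough along residual background structure; the tightest qualifying
   runs are kept as evidence.  Failing that, the locus is **polyclonal**
   if ≥ 3 consecutive segments with negative log2 means decline strictly
   monotonically toward the J cluster; otherwise **no loss**.

   *Flatness* is a within-segment least-squares slope bound of 0.05 log2
   per 10 kb, evaluated at diploid scale (0.069 copies/10 kb) so deep
   troughs are not penalized for copy-space tilts no plot would show, and
   waived when the slope is within 2 SE of zero (short segments carry no
   usable slope information).
7. **Allelic status** of a monoclonal call: biallelic if a qualifying
   segment sits at CN 0, monoallelic at CN 1, indeterminate when the
   decisive ratio lies within ±0.05 log2 of the −1.1 cutoff.
8. **D–J zoom.**  Incomplete D-to-J rearrangements delete only ~0.3–3 kb
   and are invisible at whole-locus scale (they fail the 2 kb width
   floor).  For loci with D segments (TRB, TRD, IGH) the window from the
   D cluster to the last J ± 2 kb of context is re-segmented at 25 bp
   bins (`kmin = 8`) and the same trough test is applied with a 300 bp
   width floor.  A hit upgrades a negative whole-locus call to
   monoclonal.  The zoom always runs — such deletions are easily missed —
   and sub-threshold candidates are logged rather than called.
9. **Nested TRD.**  TRD lies inside TRA, so a monoclonal TRA call whose
   entire evidence is contained in the TRD extent is reattributed as a
   TRD event; the TRA call is then downgraded to polyclonal if the slopy
   criterion independently holds, else to no loss.
10. **Sample verdict.**  A sample is flagged as a clonal T-cell process
    when at least one TCR locus is monoclonal.

## Tumor purity

Tumor content is estimated as `min(1, 2 × median(VAF))` over curated
somatic SNVs of a diploid tumor, with adequacy bands ≤ 20% low, 21–40%
moderate, > 40% adequate.  Raw threshold CN is the primary output.  When
purity `p` is supplied, classification switches to purity-aware mode:

* effective CN comes from the purity-corrected ratio, inverting
  `2^r = (p·c + (1−p)·2)/2` (floored at 0);
* the trough step is tested in copy space rescaled by purity
  (`(c_flank − c_run)/p ≥ 0.5` copies), since a clone at content `p`
  shifts coverage by only `p` copies per deleted allele;
* allelic status is read off the trough's boundary drops
  (copies lost = max flank drop / p; ≥ 1.65 biallelic, ≤ 1.35
  monoallelic, else indeterminate).  This differential form is exact for
  any locally smooth background, whereas the absolute adjusted CN assumes
  the non-tumor fraction is diploid at the locus — false for a rearranged
  T-cell background, which would otherwise masquerade as a second lost
  allele.

Purity-aware mode is what makes low-content detection possible at all: a
fully clonal biallelic loss diluted to content `f` shows
`log2(1 − f)` ≈ −0.15 at 10%, far above every raw threshold.  Its known
limitation is the same diploid-background assumption: in a sample that is
almost entirely polyclonal T cells, background staircase steps rescaled
by a very low purity can approach the 0.5-copy step threshold.  Raw mode
is therefore the default, and purity-aware mode is recommended when a
clone is plausibly present and content is below ~50%.

## Parameters

| name | default | units | role |
| --- | --- | --- | --- |
| `bin_size` | 100 | bp | whole-locus bin width |
| `zoom_bin_size` | 25 | bp | D–J window bin width |
| `gamma` | 40 | — | PCF penalty (scale-free via MAD noise estimate) |
| `kmin` / `kmin_zoom` | 5 / 8 | bins | minimum segment length |
| `tau` | 2.5 | sigma | winsorization band |
| `half_window` | 25 | bins | winsorization window half-width |
| `epsilon` | 0.01 | normalized depth | ratio pseudocount |
| `min_flat_width_bp` | 2000 | bp | minimum clonal-trough width |
| `max_flat_slope` | 0.05 | log2/10 kb (diploid scale) | flatness bound |
| `min_step_log2` | 0.25 | log2 | trough boundary step (raw mode) |
| `min_step_copies` | 0.5 | copies/purity | trough boundary step (purity mode) |
| `min_slopy_run` | 3 | segments | slopy staircase length |
| `min_dj_width_bp` | 300 | bp | minimum zoomed D–J hit width |
| `zoom_flank_bp` | 2000 | bp | context around the D–J window |
| `indeterminate_band` | 0.05 | log2 | allelic indeterminacy around −1.1 |

The flat/slopy thresholds (`min_flat_width_bp`, `max_flat_slope`,
`min_step_log2`, `min_slopy_run`) quantify a distinction the source
material only draws by visual pattern; they were chosen so the three
canonical archetypes separate cleanly and are all exposed in the YAML
config.

## Synthetic data generator

`tcrclone.synthetic` draws matched tumor/normal tracks from an explicit
cell-population model: a clonal fraction `f` with fixed per-allele
deletion intervals, plus a polyclonal background in which each allele is
independently rearranged with probability `fraction_rearranged`, its V
and J endpoints drawn from usage weights (uniform by default).  The
expected diploid-equivalent copy number is

    c(x) = f·c_tumor(x) + (1−f)·c_bg(x)
    c_tumor(x) = 2 − [x ∈ del₁] − [x ∈ del₂]
    c_bg(x)   = 2·(1 − fraction_rearranged·P_del(x))
    P_del(x)  = (Σ_{V: end<x} w_V) · (Σ_{J: start>x} w_J)

which produces exactly the slopy staircase toward J.  Bin coverage is
Poisson with mean `mean_depth·bin_width·c/2` (the sum of per-base Poisson
draws an averaged samtools-depth track would give); the matched normal is
diploid throughout.  Defaults: 30× depth, 25 bp bins,
`fraction_rearranged = 0.7` — a bulk background that is mostly but not
purely T cells, since NK/B/myeloid cells keep germline loci (a background
of 100% rearranged alleles would drive the pre-J plateau toward zero
coverage, a corner real bulk samples do not reach).

What the generator deliberately omits: GC and mappability bias (the
matched-pair ratio cancels systematic bias to first order), read-level
artifacts, subclonal structure, and real V/J usage skew (exposed via the
usage weights but defaulting to uniform).  Passing tests therefore
demonstrate the statistical identifiability of the coverage patterns
under Poisson noise, not robustness to alignment artifacts on real data.

Abstract locus templates with realistic geometry ship for testing: a
TRB-like 500 kb locus (50 V, 2 D, 13 J; compact ~1.6 kb D–J region), a
TRG-like 160 kb locus (14 V, 5 J), and a TRA-like 500 kb locus with a
nested TRD-like locus.  The packaged hg38 BED provides real locus extents
with representative V/D/J anchor rows and is meant to be replaced by a
site's own annotation (IMGT vs RefSeq is a user choice).

## In-silico dilution

`mix_tracks` merges two samples' binned coverage at proportion `a` by
binomial thinning — `Binom(A_count, a·s_A) + Binom(B_count, (1−a)·s_B)` —
which preserves Poisson character without read-level data and has
per-bin expectation exactly `a·Â + (1−a)·B̂`.  Rescaling factors are
taken against each sample's *copy-neutral reference depth* (by default
the track mean; pass it explicitly for deletion-heavy loci, where the
track mean is depressed and would silently shift the effective mixing
proportion).  The default target depth is the mixture's natural depth
`a·ref_A + (1−a)·ref_B`, which thinning can always reach; dilution series
hold depth constant by passing an explicit target.  With real BAMs the
same experiment is `samtools view -s` + `merge` + `depth` outside the
package.

The dilution experiment in `tcrclone.experiments` reproduces the
sensitivity analysis this design exists for: a biallelic TRG deletion at
93% purity, mixed into an NK-like background at 10–90%, remains
detectable (purity-aware, purity = a·0.93) down to the 10% point, while
its raw threshold CN at 20% reads 1 rather than 0 — the characteristic
allelic-status degradation of diluted biallelic losses.

## Numerical choices and degenerate inputs

* Noise variance for the PCF penalty is floored at 1e-12 so noiseless
  signals keep a positive penalty; remaining ties resolve toward fewer
  breakpoints, then leftmost.
* Winsorization windows whose values are all equal clip nothing by
  construction; a window with MAD 0 but unequal values (an isolated
  spike among constants) clips to the local median, which is the point
  of the procedure.
* Runs touching the edge of the tiled region never qualify as troughs:
  V(D)J deletions are bounded by V and J segments, so genuine losses
  always have context on both sides.
* Empty signals, non-tiling segment lists, negative depths, unsorted
  depth positions, VAFs outside [0, 1], and purity outside (0, 1] raise
  errors rather than propagate.

## Known limitations

* One clone only: coexisting clones with different rearrangements blur
  into intermediate steps and are not deconvolved.
* ~1 kb V–J deletions sit below the whole-locus width floor and outside
  the D–J window; they surface only in debug logs.
* Purity-aware mode degrades when the background itself is heavily
  rearranged (see above); allelic calls at < 30% content are best treated
  as indeterminate unless the boundary drop is clear.
* The median-depth library normalization fails when more than half the
  analyzed region is deleted — supply reference depths explicitly.
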