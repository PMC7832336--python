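"""Synthetic coverage generator: expected profiles, sampling, VAFs."""

import numpy as np
import pytest

import tcrclone as tc
from tcrclone.synthetic import background_deletion_probability, copy_number_at


def spec_for(locus, f=0.0, dele=None, fr=0.0, seed=0, biallelic=True, **kw):
    iv = tc.GenomicInterval(locus.extent.chrom, *dele) if dele else None
    return tc.CloneSimSpec(
        locus=locus,
        tumor_fraction=f,
        allele1_deletion=iv,
        allele2_deletion=iv if biallelic else None,
        background=tc.PolyclonalSpec(fraction_rearranged=fr),
        mean_depth=kw.pop("mean_depth", 30.0),
        bin_size=kw.pop("bin_size", 25),
        seed=seed,
    )


class TestExpectedCopyProfile:
    def test_germline_everywhere_two_copies(self, trg):
        prof = tc.expected_copy_profile(spec_for(trg))
        assert np.allclose(prof, 2.0)

    def test_fully_clonal_biallelic_deletion(self, trg):
        prof = tc.expected_copy_profile(spec_for(trg, f=1.0, dele=(30_000, 141_500)))
        starts = np.arange(0, 160_000, 25)
        inside = (starts >= 30_000) & (starts + 25 <= 141_500)
        outside = (starts + 25 <= 30_000) | (starts >= 141_500)
        assert np.allclose(prof[inside], 0.0)
        assert np.allclose(prof[outside], 2.0)

    def test_pure_polyclonal_profile_non_increasing_toward_j(self, trg):
        """Uniform V/J usage: c(x) declines stepwise across the V array
        toward the J cluster (brute-force pair sum as oracle)."""
        prof = tc.expected_copy_profile(spec_for(trg, fr=1.0))
        mids = np.arange(0, 160_000, 25) + 12.5
        v_span = (mids > trg.v_segments[0].end) & (mids < trg.j_segments[0].start)
        within = prof[v_span]
        assert np.all(np.diff(within) <= 1e-12)
        assert within[0] > within[-1]

        # brute-force oracle: sum over all (V, J) pairs at probe points
        probes = np.array([10_000.0, 60_000.0, 110_000.0, 141_000.0])
        nv, nj = len(trg.v_segments), len(trg.j_segments)
        expected = []
        for x in probes:
            p = sum(
                (1.0 / nv) * (1.0 / nj)
                for v in trg.v_segments
                for j in trg.j_segments
                if v.end < x < j.start
            )
            expected.append(2.0 * (1.0 - p))
        assert np.allclose(copy_number_at(spec_for(trg, fr=1.0), probes), expected)

    def test_monte_carlo_cell_simulator_agrees(self, trg):
        """Independent cell-by-cell simulator: draw cells, apply clonal and
        background deletions explicitly, average copy number at probes."""
        spec = spec_for(trg, f=0.3, dele=(30_000, 141_500), fr=0.6, biallelic=False)
        probes = np.array([15_000.0, 50_000.0, 100_000.0, 141_000.0, 150_000.0])
        n_cells = 100_000
        rng = np.random.default_rng(123)
        v_ends = np.array([v.end for v in trg.v_segments])
        j_starts = np.array([j.start for j in trg.j_segments])

        is_tumor = rng.random(n_cells) < spec.tumor_fraction
        n_tum, n_bg = int(is_tumor.sum()), int((~is_tumor).sum())
        counts = np.zeros(len(probes))
        # tumor cells: allele 1 carries the deletion, allele 2 is intact
        inside = (probes >= 30_000) & (probes < 141_500)
        counts += n_tum * (1.0 + (~inside).astype(float))
        # background cells: each allele independently rearranged with prob fr
        for _allele in range(2):
            rearranged = rng.random(n_bg) < 0.6
            v = v_ends[rng.integers(len(v_ends), size=n_bg)]
            j = j_starts[rng.integers(len(j_starts), size=n_bg)]
            for k, x in enumerate(probes):
                deleted = rearranged & (v < x) & (x < j)
                counts[k] += n_bg - int(deleted.sum())
        mc = counts / n_cells
        analytic = copy_number_at(spec, probes)
        se = np.sqrt(analytic * (2 - analytic) / (2 * n_cells)) + 1e-9
        assert np.all(np.abs(mc - analytic) <= 3 * se + 0.01)

    def test_deletion_must_be_vj_bounded(self, trg):
        with pytest.raises(ValueError, match="start after"):
            spec_for(trg, f=0.5, dele=(1_000, 100_000))
        with pytest.raises(ValueError, match="end before"):
            spec_for(trg, f=0.5, dele=(30_000, 155_000))


class TestSimulateSample:
    def test_depth_conservation_in_neutral_region(self, trg):
        """Mean tumor depth over copy-neutral ground ~ mean_depth (3 SE)."""
        spec = spec_for(trg, f=0.5, dele=(30_000, 141_500), seed=9)
        tumor, normal, _ = tc.simulate_sample(spec)
        neutral = tumor.values[: 30_000 // 25 - 1]
        n_bases = len(neutral) * 25
        se = np.sqrt(30.0 / n_bases)
        assert np.mean(neutral) == pytest.approx(30.0, abs=3 * se)
        assert normal.mean_depth() == pytest.approx(30.0, rel=0.02)

    def test_truth_labels(self, trg):
        t1 = spec_for(trg, f=0.5, dele=(30_000, 141_500)).truth_call()
        assert (t1.category, t1.allelic) == ("monoclonal", "biallelic")
        t2 = spec_for(trg, f=0.5, dele=(30_000, 141_500), biallelic=False).truth_call()
        assert (t2.category, t2.allelic) == ("monoclonal", "monoallelic")
        t3 = spec_for(trg, fr=0.7).truth_call()
        assert t3.category == "polyclonal"
        t4 = spec_for(trg).truth_call()
        assert t4.category == "no_loss"

    def test_seed_reproducibility(self, trg):
        s = spec_for(trg, f=0.4, dele=(30_000, 141_500), seed=77)
        t1, n1, _ = tc.simulate_sample(s)
        t2, n2, _ = tc.simulate_sample(s)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(n1.values, n2.values)

    def test_pipeline_recovers_breakpoints(self, trg_biallelic_pair, params):
        """f=0.93 biallelic 111.5 kb deletion at 30x: recovered monoclonal
        biallelic with breakpoints within 2 whole-locus bins."""
        spec, tumor, normal, truth = trg_biallelic_pair
        call, segs, _ = tc.call_locus(tumor, normal, spec.locus, params)
        assert call.category == "monoclonal" and call.allelic == "biallelic"
        trough = min(call.evidence, key=lambda rs: rs.log2_ratio)
        assert abs(trough.segment.start_bp - 30_000) <= 200
        assert abs(trough.segment.end_bp - 141_500) <= 200

    def test_sensitivity_non_decreasing_in_tumor_fraction(self, trg):
        """Detection of a biallelic deletion should not get worse as the
        tumor fraction grows (coarse grid, purity-aware calling)."""
        rates = []
        for f in (0.1, 0.3, 0.6, 0.9):
            hits = 0
            for seed in range(6):
                spec = spec_for(trg, f=f, dele=(30_000, 141_500), seed=500 + seed)
                tumor, normal, _ = tc.simulate_sample(spec)
                p = tc.ClonalityParams(
                    purity=f, tumor_lib_depth=30.0, normal_lib_depth=30.0
                )
                call, _, _ = tc.call_locus(tumor, normal, trg, p)
                hits += call.category == "monoclonal"
            rates.append(hits)
        assert all(a <= b + 1 for a, b in zip(rates, rates[1:]))  # allow 1-seed jitter
        assert rates[-1] == 6


class TestSimulateVafs:
    def test_estimate_recovers_tumor_fraction(self, trg):
        spec = spec_for(trg, f=0.5, dele=(30_000, 141_500), mean_depth=100.0)
        vafs = tc.simulate_vafs(spec, 999, seed=5)
        assert tc.estimate_tumor_content(vafs) == pytest.approx(0.5, abs=0.05)

    def test_fully_clonal_sample_near_one(self, trg):
        spec = spec_for(trg, f=1.0, dele=(30_000, 141_500), mean_depth=100.0)
        vafs = tc.simulate_vafs(spec, 999, seed=6)
        assert tc.estimate_tumor_content(vafs) == pytest.approx(1.0, abs=0.06)

    def test_single_variant_allowed_but_noisy(self, trg):
        spec = spec_for(trg, f=0.5, dele=(30_000, 141_500))
        vafs = tc.simulate_vafs(spec, 1, seed=7)
        assert len(vafs) == 1 and 0 <= vafs[0] <= 1

    def test_zero_variants_rejected(self, trg):
        with pytest.raises(ValueError):
            tc.simulate_vafs(spec_for(trg), 0, seed=1)


class TestPolyclonalSpec:
    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            tc.PolyclonalSpec(fraction_rearranged=0.5, v_usage=[-1, 2])
        with pytest.raises(ValueError):
            tc.PolyclonalSpec(fraction_rearranged=1.5)

    def test_skewed_usage_shifts_profile(self, trg):
        """Concentrating V usage on the first V deepens the loss early."""
        skew = [10.0] + [0.1] * (len(trg.v_segments) - 1)
        uniform = tc.PolyclonalSpec(fraction_rearranged=1.0)
        skewed = tc.PolyclonalSpec(fraction_rearranged=1.0, v_usage=skew)
        x = np.array([20_000.0])
        p_uni = background_deletion_probability(trg, uniform, x)[0]
        p_skw = background_deletion_probability(trg, skewed, x)[0]
        assert p_skw > p_uni
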