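"""Monoclonal/polyclonal/no-loss classification, D-J zoom, TRD attribution."""

import math

import numpy as np
import pytest

import tcrclone as tc
from tcrclone.clonality import (
    MONOCLONAL,
    NO_LOSS,
    POLYCLONAL,
    classify_locus,
)
from tcrclone.cn import RatioSegment, call_cn
from tcrclone.segmentation import Segment


def seg_from_log2(start_bp, end_bp, log2, bin_size=100, start_bin=None):
    """Hand-built RatioSegment (copy-space mean derived from the log2)."""
    n = (end_bp - start_bp) // bin_size
    sb = start_bin if start_bin is not None else start_bp // bin_size
    mean_c = 2.0 * 2.0**log2
    segment = Segment(
        start_bin=sb,
        end_bin=sb + n,
        start_bp=start_bp,
        end_bp=end_bp,
        mean_value=mean_c,
        n_bins=n,
    )
    return RatioSegment(
        segment=segment, log2_ratio=log2, cn=call_cn(log2), slope_per_10kb=0.0
    )


def tile(log2_widths, bin_size=100):
    """Tiling of RatioSegments from (log2, width_bp) pairs."""
    out, pos, bin0 = [], 0, 0
    for log2, width in log2_widths:
        rs = seg_from_log2(pos, pos + width, log2, bin_size, start_bin=bin0)
        out.append(rs)
        pos += width
        bin0 += width // bin_size
    return out


@pytest.fixture()
def abstract_locus():
    chrom = "chrT"
    v = [tc.GenomicInterval(chrom, 1_000 + i * 5_000, 1_500 + i * 5_000) for i in range(5)]
    j = [tc.GenomicInterval(chrom, 90_000 + i * 500, 90_060 + i * 500) for i in range(4)]
    return tc.LocusDefinition(
        name="TRG", extent=tc.GenomicInterval(chrom, 0, 100_000), v_segments=v, j_segments=j
    )


class TestClassifyLocus:
    def test_flat_deep_loss_is_monoclonal_biallelic(self, abstract_locus):
        segs = tile([(0.0, 40_000), (-2.3, 20_000), (0.0, 40_000)])
        call = classify_locus(segs, abstract_locus)
        assert call.category == MONOCLONAL
        assert call.allelic == "biallelic"
        assert call.evidence[0].segment.start_bp == 40_000

    def test_monoallelic_band_reported(self, abstract_locus):
        segs = tile([(0.0, 40_000), (-0.7, 20_000), (0.0, 40_000)])
        call = classify_locus(segs, abstract_locus)
        assert (call.category, call.allelic) == (MONOCLONAL, "monoallelic")

    def test_near_boundary_loss_is_indeterminate(self, abstract_locus):
        segs = tile([(0.0, 40_000), (-1.08, 20_000), (0.0, 40_000)])
        call = classify_locus(segs, abstract_locus)
        assert (call.category, call.allelic) == (MONOCLONAL, "indeterminate")

    def test_descending_staircase_is_polyclonal(self, abstract_locus):
        steps = [0.0, -0.18, -0.36, -0.54, -0.72, -0.9]
        segs = tile([(s, 16_000) for s in steps] + [(0.0, 4_000)])
        call = classify_locus(segs, abstract_locus)
        assert call.category == POLYCLONAL
        assert len(call.evidence) >= 3

    def test_single_neutral_segment_is_no_loss(self, abstract_locus):
        segs = tile([(0.01, 100_000)])
        call = classify_locus(segs, abstract_locus)
        assert call.category == NO_LOSS
        assert call.allelic == "indeterminate" and call.evidence == []

    def test_flat_loss_inside_slopy_background_still_triggers(self, abstract_locus):
        """A clonal trough takes precedence over its polyclonal context."""
        segs = tile(
            [(0.0, 20_000), (-0.2, 16_000), (-0.4, 10_000),
             (-2.0, 20_000),  # the clonal biallelic trough
             (-0.5, 14_000), (0.0, 20_000)]
        )
        call = classify_locus(segs, abstract_locus)
        assert call.category == MONOCLONAL
        assert call.allelic == "biallelic"
        assert [rs.segment.start_bp for rs in call.evidence] == [46_000]

    def test_staircase_step_does_not_masquerade_as_loss(self, abstract_locus):
        """A wide low segment that never recovers on the J side is the tail
        of a polyclonal staircase, not a clonal deletion."""
        segs = tile(
            [(0.0, 30_000), (-0.4, 20_000), (-1.3, 30_000), (-1.35, 20_000)]
        )
        call = classify_locus(segs, abstract_locus)
        assert call.category == POLYCLONAL

    def test_narrow_loss_below_min_width_ignored(self, abstract_locus):
        segs = tile([(0.0, 49_000), (-2.0, 1_000), (0.0, 50_000)])
        call = classify_locus(segs, abstract_locus)
        assert call.category == NO_LOSS

    def test_non_tiling_segments_rejected(self, abstract_locus):
        segs = tile([(0.0, 50_000), (0.0, 50_000)])
        segs[1].segment.start_bin += 3
        with pytest.raises(ValueError, match="tile"):
            classify_locus(segs, abstract_locus)

    def test_deterministic(self, abstract_locus):
        segs = tile([(0.0, 40_000), (-2.3, 20_000), (0.0, 40_000)])
        c1 = classify_locus(segs, abstract_locus)
        c2 = classify_locus(segs, abstract_locus)
        assert c1 == c2


class TestDjMicrodeletion:
    def make_pair(self, trb, deletion, seed, f=0.4):
        iv = tc.GenomicInterval(trb.extent.chrom, *deletion) if deletion else None
        spec = tc.CloneSimSpec(
            locus=trb,
            tumor_fraction=f,
            allele1_deletion=iv,
            background=tc.PolyclonalSpec(fraction_rearranged=0.0),
            mean_depth=30.0,
            bin_size=25,
            seed=seed,
        )
        tumor, normal, _ = tc.simulate_sample(spec)
        return tumor, normal

    def test_dj_deletion_found_only_by_zoom(self, trb, params):
        tumor, normal = self.make_pair(trb, (471_720, 473_280), seed=11)
        whole, _, _ = tc.call_locus(tumor, normal, trb, params)
        assert whole.category != MONOCLONAL
        hit = tc.detect_dj_microdeletion(tumor, normal, trb, params)
        assert hit is not None
        assert hit.cn <= 1
        assert hit.segment.start_bp < 473_280 and hit.segment.end_bp > 471_720

    def test_no_deletion_gives_no_hit(self, trb, params):
        tumor, normal = self.make_pair(trb, None, seed=12)
        assert tc.detect_dj_microdeletion(tumor, normal, trb, params) is None

    def test_sub_threshold_width_not_called(self, trb, params, caplog):
        tumor, normal = self.make_pair(trb, (472_650, 472_750), seed=13, f=0.9)
        with caplog.at_level("DEBUG", logger="tcrclone.clonality"):
            hit = tc.detect_dj_microdeletion(tumor, normal, trb, params)
        assert hit is None

    def test_locus_without_d_segments_rejected(self, trg, params):
        tumor, normal = self.make_pair(trg, None, seed=14)
        with pytest.raises(ValueError, match="no D segments"):
            tc.detect_dj_microdeletion(tumor, normal, trg, params)

    def test_zoom_hit_upgrades_sample_call(self, trb, params):
        tumor, normal = self.make_pair(trb, (471_720, 473_280), seed=15)
        result = tc.call_sample({"TRB": tumor}, {"TRB": normal}, [trb], params)
        call = result.call_for("TRB")
        assert call.category == MONOCLONAL
        assert call.zoom_hit is not None
        assert result.clonal_t_cell_process


class TestNestedTrdAttribution:
    def simulate(self, tra, deletion, f, fr, seed):
        iv = tc.GenomicInterval(tra.extent.chrom, *deletion)
        spec = tc.CloneSimSpec(
            locus=tra,
            tumor_fraction=f,
            allele1_deletion=iv,
            allele2_deletion=iv,
            background=tc.PolyclonalSpec(fraction_rearranged=fr),
            mean_depth=30.0,
            bin_size=25,
            seed=seed,
        )
        tumor, normal, _ = tc.simulate_sample(spec)
        return tumor, normal

    def test_focal_trd_loss_reattributed(self, tra_trd, params):
        tra, trd = tra_trd
        tumor, normal = self.simulate(tra, (360_000, 373_900), f=0.5, fr=0.0, seed=21)
        call, segs, _ = tc.call_locus(tumor, normal, tra, params)
        assert call.category == MONOCLONAL
        new_tra, trd_call = tc.attribute_nested_trd(call, tra, trd, params, segs)
        assert trd_call is not None
        assert (trd_call.locus, trd_call.category) == ("TRD", MONOCLONAL)
        assert trd_call.attributed_from == "TRA"
        assert new_tra.category == NO_LOSS

    def test_focal_trd_in_polyclonal_tra_keeps_slopy_call(self, tra_trd, params):
        tra, trd = tra_trd
        tumor, normal = self.simulate(tra, (360_000, 373_900), f=0.5, fr=0.7, seed=22)
        call, segs, _ = tc.call_locus(tumor, normal, tra, params)
        assert call.category == MONOCLONAL
        new_tra, trd_call = tc.attribute_nested_trd(call, tra, trd, params, segs)
        assert trd_call is not None and trd_call.category == MONOCLONAL
        assert new_tra.category == POLYCLONAL

    def test_broad_tra_deletion_not_reattributed(self, tra_trd, params):
        tra, trd = tra_trd
        tumor, normal = self.simulate(tra, (100_000, 399_000), f=0.9, fr=0.0, seed=23)
        call, segs, _ = tc.call_locus(tumor, normal, tra, params)
        assert call.category == MONOCLONAL
        new_tra, trd_call = tc.attribute_nested_trd(call, tra, trd, params, segs)
        assert trd_call is None
        assert new_tra is call

    def test_missing_trd_definition_rejected(self, tra_trd, params):
        tra, _ = tra_trd
        call = tc.ClonalityCall(locus="TRA", category=MONOCLONAL, allelic="biallelic")
        with pytest.raises(ValueError, match="nested"):
            tc.attribute_nested_trd(call, tra, None, params)


class TestCallSample:
    def simulate_locus(self, locus, f, deletion, fr, seed, biallelic=True):
        iv = tc.GenomicInterval(locus.extent.chrom, *deletion) if deletion else None
        spec = tc.CloneSimSpec(
            locus=locus,
            tumor_fraction=f,
            allele1_deletion=iv,
            allele2_deletion=iv if biallelic else None,
            background=tc.PolyclonalSpec(fraction_rearranged=fr),
            mean_depth=30.0,
            bin_size=25,
            seed=seed,
        )
        tumor, normal, _ = tc.simulate_sample(spec)
        return tumor, normal

    def test_aitl_like_sample_flags_clonal_process(self, trg, trb, params):
        """TRG biallelic + TRB monoallelic losses at 23% content: both
        monoclonal with the right allelic states, sample flagged clonal."""
        params.purity = 0.23
        tg = self.simulate_locus(trg, 0.23, (30_000, 141_500), 0.3, seed=31)
        tb = self.simulate_locus(trb, 0.23, (200_000, 471_500), 0.3, seed=32, biallelic=False)
        result = tc.call_sample(
            {"TRG": tg[0], "TRB": tb[0]},
            {"TRG": tg[1], "TRB": tb[1]},
            [trg, trb],
            params,
            sample_id="case12",
        )
        g, b = result.call_for("TRG"), result.call_for("TRB")
        assert g.category == MONOCLONAL and g.allelic == "biallelic"
        assert b.category == MONOCLONAL and b.allelic == "monoallelic"
        assert result.clonal_t_cell_process

    def test_nk_lineage_sample_all_no_loss(self, trg, trb, params):
        tg = self.simulate_locus(trg, 0.0, None, 0.0, seed=33)
        tb = self.simulate_locus(trb, 0.0, None, 0.0, seed=34)
        result = tc.call_sample(
            {"TRG": tg[0], "TRB": tb[0]}, {"TRG": tg[1], "TRB": tb[1]}, [trg, trb], params
        )
        assert all(c.category == NO_LOSS for c in result.calls)
        assert not result.clonal_t_cell_process

    def test_pure_normal_t_sample_polyclonal_not_monoclonal(self, trg, trb, params):
        tg = self.simulate_locus(trg, 0.0, None, 0.7, seed=35)
        tb = self.simulate_locus(trb, 0.0, None, 0.7, seed=36)
        result = tc.call_sample(
            {"TRG": tg[0], "TRB": tb[0]}, {"TRG": tg[1], "TRB": tb[1]}, [trg, trb], params
        )
        assert {c.category for c in result.calls} == {POLYCLONAL}
        assert not result.clonal_t_cell_process

    def test_missing_normal_rejected(self, trg, params):
        tg = self.simulate_locus(trg, 0.0, None, 0.0, seed=37)
        with pytest.raises(ValueError, match="matched normal"):
            tc.call_sample({"TRG": tg[0]}, {}, [trg], params)

    def test_identical_inputs_identical_calls(self, trg, params):
        tg = self.simulate_locus(trg, 0.5, (30_000, 141_500), 0.2, seed=38)
        r1 = tc.call_sample({"TRG": tg[0]}, {"TRG": tg[1]}, [trg], params)
        r2 = tc.call_sample({"TRG": tg[0]}, {"TRG": tg[1]}, [trg], params)
        assert r1.calls == r2.calls


class TestRecovery:
    def test_sensitivity_and_specificity_over_seeds(self, trg, params):
        """>=95% monoclonal detection for 10kb+ deletions at f in
        {0.25, 0.5, 0.9}; <=5% false monoclonal on tumor-free samples."""
        hits, total = 0, 0
        for f in (0.25, 0.5, 0.9):
            for seed in range(17):
                iv = tc.GenomicInterval(trg.extent.chrom, 30_000, 141_500)
                spec = tc.CloneSimSpec(
                    locus=trg, tumor_fraction=f,
                    allele1_deletion=iv, allele2_deletion=iv,
                    background=tc.PolyclonalSpec(fraction_rearranged=0.3),
                    mean_depth=30.0, bin_size=25, seed=1000 + seed,
                )
                tumor, normal, _ = tc.simulate_sample(spec)
                p = tc.ClonalityParams(
                    purity=f, tumor_lib_depth=30.0, normal_lib_depth=30.0
                )
                call, _, _ = tc.call_locus(tumor, normal, trg, p)
                hits += call.category == MONOCLONAL
                total += 1
        assert hits / total >= 0.95

        false_pos = 0
        for fr in (0.0, 0.7):
            for seed in range(25):
                spec = tc.CloneSimSpec(
                    locus=trg, tumor_fraction=0.0,
                    background=tc.PolyclonalSpec(fraction_rearranged=fr),
                    mean_depth=30.0, bin_size=25, seed=2000 + seed,
                )
                tumor, normal, _ = tc.simulate_sample(spec)
                call, _, _ = tc.call_locus(tumor, normal, trg, params)
                false_pos += call.category == MONOCLONAL
        assert false_pos / 50 <= 0.05

    def test_allelic_concordance_at_moderate_purity(self, trg, params):
        """At f >= 0.6 the biallelic/monoallelic verdict matches truth in
        >=90% of replicates."""
        ok, total = 0, 0
        for biallelic in (True, False):
            for seed in range(15):
                iv = tc.GenomicInterval(trg.extent.chrom, 30_000, 141_500)
                spec = tc.CloneSimSpec(
                    locus=trg, tumor_fraction=0.6,
                    allele1_deletion=iv,
                    allele2_deletion=iv if biallelic else None,
                    background=tc.PolyclonalSpec(fraction_rearranged=0.0),
                    mean_depth=30.0, bin_size=25, seed=3000 + seed,
                )
                tumor, normal, truth = tc.simulate_sample(spec)
                call, _, _ = tc.call_locus(tumor, normal, trg, params)
                total += 1
                ok += (call.category, call.allelic) == (MONOCLONAL, truth.allelic)
        assert ok / total >= 0.9
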