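"""TSS-anchored bins, bin-level DE, operon assignment and polarity summaries."""

import numpy as np
import pandas as pd
import pytest

from polarity import binning, de
from polarity.io import CoverageTrack, GeneRecord
from polarity.simulate import OperonSpec, simulate_operon_coverage
from polarity.tss import DEGLink


def make_tss(pos, strand="+", tss_class="gTSS", height=50.0):
    from polarity.tss import TSSRecord

    return TSSRecord("chr1", strand, pos, height, 10.0, 50.0, tss_class)


class TestMakeBins:
    def test_plus_strand_arithmetic(self):
        bs = binning.make_bins(make_tss(1001))
        assert bs.intervals[0] == (1001, 1100)
        assert bs.intervals[24] == (3401, 3500)
        assert bs.span_nt == 2500

    def test_minus_strand_mirror(self):
        bs = binning.make_bins(make_tss(5000, "-"))
        assert bs.intervals[0] == (4901, 5000)
        assert bs.intervals[1] == (4801, 4900)

    def test_bins_contiguous_non_overlapping(self):
        bs = binning.make_bins(make_tss(1001))
        for (a1, b1), (a2, b2) in zip(bs.intervals, bs.intervals[1:]):
            assert a2 == b1 + 1

    def test_off_chromosome_truncated_with_warning(self):
        with pytest.warns(UserWarning):
            bs = binning.make_bins(make_tss(150, "-"))
        assert bs.span_nt < 2500
        assert all(a >= 1 for a, _ in bs.intervals)


class TestBinCounts:
    def test_uniform_depth_sum(self):
        track = CoverageTrack("chr1", "+", np.full(3000, 10.0), 1)
        bs = binning.make_bins(make_tss(1))
        counts = binning.bin_counts(bs, {"s1": track})
        assert (counts["s1"] == 1000).all()

    def test_zero_coverage(self):
        track = CoverageTrack("chr1", "+", np.zeros(3000), 1)
        counts = binning.bin_counts(binning.make_bins(make_tss(1)), {"s1": track})
        assert (counts["s1"] == 0).all()

    def test_read_length_rescales(self):
        track = CoverageTrack("chr1", "+", np.full(3000, 10.0), 1)
        counts = binning.bin_counts(
            binning.make_bins(make_tss(1)), {"s1": track}, read_length=50
        )
        assert (counts["s1"] == 20).all()

    def test_normalized_coverage_rejected(self):
        track = CoverageTrack("chr1", "+", np.ones(3000), 1)
        track.normalized = True
        with pytest.raises(ValueError, match="raw"):
            binning.bin_counts(binning.make_bins(make_tss(1)), {"s1": track})

    def test_missing_sample_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            binning.bin_counts(binning.make_bins(make_tss(1)), {"s1": None})

    def test_ptt_counts_decay_geometrically(self):
        # beyond the protected prefix, expected bin means fall by a constant
        # factor per bin: exp(-hazard * bin_width)
        spec = OperonSpec("op", (2300,), (), 0, 0.05, 0.01, 200, 0.002, 1.0)
        track, _ = simulate_operon_coverage(spec, "+Tc", depth=200, seed=0)
        counts = binning.bin_counts(
            binning.make_bins(make_tss(1), n_bins=23), {"s": track}
        )["s"].values
        ratios = counts[3:22] / counts[2:21]
        assert np.exp(-0.002 * 100) == pytest.approx(np.mean(ratios), rel=0.05)


class TestBinDe:
    @staticmethod
    def sim_bins(hazard, stabilization, n=3, seed=0, depth=50.0, n_null=4):
        """Bin counts of one perturbed operon plus null operons.

        The null operons anchor the size factors, as the mostly-unchanged
        transcriptome does in a genome-wide bin analysis; the returned
        frame holds only the perturbed operon's 25 bins.
        """
        specs = [
            OperonSpec("op", (2400,), (), 50, 0.01, 0.01, 300, hazard, stabilization)
        ] + [
            OperonSpec(f"null{i}", (2400,), (), 50, 0.01, 0.01, 300, 0.0, 1.0)
            for i in range(n_null)
        ]
        rng_seed = seed
        frames = {}
        for cond, label in (("-Tc", "control"), ("+Tc", "treated")):
            for j in range(n):
                per_spec = []
                for i, spec in enumerate(specs):
                    track, _ = simulate_operon_coverage(spec, cond, depth, rng_seed)
                    rng_seed += 1
                    c = binning.bin_counts(binning.make_bins(make_tss(1)), {"x": track})
                    c.index = [f"{spec.operon_id}:{b}" for b in c.index]
                    per_spec.append(c["x"])
                frames[f"{label}_{j}"] = pd.concat(per_spec)
        counts = pd.DataFrame(frames)
        conds = pd.Series(
            {c: ("control" if c.startswith("control") else "treated") for c in counts},
        )
        res = binning.bin_de(counts, conds)
        return res.loc[[i for i in res.index if i.startswith("op:")]]

    def test_null_type_i_controlled(self):
        res = self.sim_bins(0.0, 1.0, seed=10)
        assert res["is_deg"].mean() <= 0.05 + 1e-9

    def test_stabilization_only_up_everywhere(self):
        res = self.sim_bins(0.0, 3.0, seed=20)
        up = res[res["is_deg"] & (res["log2fc"] > 1)]
        assert len(up) >= 20  # nearly all 25 bins rise ~3x

    def test_ptt_polar_pattern(self):
        res = self.sim_bins(0.002, 3.0, seed=30).reset_index(drop=True)
        up_idx = res.index[res["is_deg"] & (res["log2fc"] > 1)]
        down_idx = res.index[res["is_deg"] & (res["log2fc"] < -1)]
        assert len(up_idx) > 0 and len(down_idx) > 0
        assert max(up_idx) < min(down_idx)

    def test_expected_bin_log2fc_monotone_beyond_prefix(self):
        spec = OperonSpec("op", (2400,), (), 50, 0.01, 0.01, 300, 0.002, 3.0)
        from polarity.simulate import expected_profile

        minus = expected_profile(spec, "-Tc")
        plus = expected_profile(spec, "+Tc")
        lfc = [
            np.log2(plus[k * 100 : (k + 1) * 100].mean() / minus[k * 100 : (k + 1) * 100].mean())
            for k in range(24)
        ]
        assert np.all(np.diff(lfc[3:]) < 1e-12)


class TestAssignOperons:
    def test_two_close_genes_one_operon(self):
        genes = [
            GeneRecord("a", "chr1", "+", 100, 400),
            GeneRecord("b", "chr1", "+", 450, 800),
        ]
        gtss = [make_tss(60)]
        (op,) = binning.assign_operons(genes, gtss)
        assert op.gene_ids == ["a", "b"]
        assert op.anchor_gtss.pos == 60

    def test_large_gap_splits(self):
        genes = [
            GeneRecord("a", "chr1", "+", 100, 400),
            GeneRecord("b", "chr1", "+", 901, 1200),
        ]
        ops = binning.assign_operons(genes, [])
        assert [o.gene_ids for o in ops] == [["a"], ["b"]]

    def test_intervening_gtss_splits(self):
        genes = [
            GeneRecord("a", "chr1", "+", 100, 400),
            GeneRecord("b", "chr1", "+", 450, 800),
        ]
        ops = binning.assign_operons(genes, [make_tss(420)])
        assert [o.gene_ids for o in ops] == [["a"], ["b"]]

    def test_minus_strand_order_promoter_first(self):
        genes = [
            GeneRecord("a", "chr1", "-", 100, 400),
            GeneRecord("b", "chr1", "-", 450, 800),
        ]
        (op,) = binning.assign_operons(genes, [])
        assert op.gene_ids == ["b", "a"]


class TestPolaritySummary:
    def toy(self):
        up = [
            DEGLink("u1", make_tss(10, tss_class="gTSS"), 5, "up"),
            DEGLink("u2", make_tss(20, tss_class="gTSS"), 5, "up"),
            DEGLink("u3", None, None, "up"),
        ]
        down = [
            DEGLink("d1", make_tss(30, tss_class="iTSS"), 5, "down"),
            DEGLink("d2", None, None, "down"),
            DEGLink("d3", None, None, "down"),
        ]
        return up + down

    def test_toy_counts(self):
        s = binning.polarity_summary(self.toy(), [], pd.DataFrame())
        assert (s.n_up_with_gtss, s.n_up_unassigned) == (2, 1)
        assert (s.n_down_with_itss, s.n_down_unassigned) == (1, 2)
        assert s.n_up == 3 and s.n_down == 3

    def test_empty_deg_list_all_zero(self):
        s = binning.polarity_summary([], [], pd.DataFrame())
        assert s.n_up == s.n_down == s.peak_ratio_gt5_count == 0
        assert s.position_table.empty

    def test_counts_invariant_under_relabel_and_translation(self):
        links = self.toy()
        shifted = [
            DEGLink(
                f"x_{l.gene_id}",
                None
                if l.tss is None
                else make_tss(l.tss.pos + 10_000, tss_class=l.tss.tss_class),
                l.distance_nt,
                l.direction_of_change,
            )
            for l in links
        ]
        a = binning.polarity_summary(links, [], pd.DataFrame())
        b = binning.polarity_summary(shifted, [], pd.DataFrame())
        assert (a.n_up_with_gtss, a.n_down_with_itss, a.n_up, a.n_down) == (
            b.n_up_with_gtss,
            b.n_down_with_itss,
            b.n_up,
            b.n_down,
        )

    def test_position_table_indexes_from_promoter(self):
        genes_res = pd.DataFrame(
            {"log2fc": [1.5, -2.0], "is_deg": [True, True]}, index=["a", "b"]
        )
        ops = [binning.OperonAssignment("op1", ["a", "b"])]
        links = [
            DEGLink("a", make_tss(1, tss_class="gTSS"), 0, "up"),
            DEGLink("b", None, None, "down"),
        ]
        s = binning.polarity_summary(links, ops, genes_res)
        tbl = s.position_table.set_index("gene_id")
        assert tbl.loc["a", "gene_index"] == 1
        assert tbl.loc["b", "gene_index"] == 2
        assert tbl.loc["b", "deg_status"] == "down"
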