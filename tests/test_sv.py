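import numpy as np
import pytest

from ylandscape import simulate as sim
from ylandscape.concordance import binarize
from ylandscape.intervals import Interval
from ylandscape.sv import (
    HET_ALT,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SVPanel,
    SVRecord,
    classify_size,
    filter_genotypes,
    filter_imprecise,
    merge_indels,
    repeat_fraction,
    sharing_profile,
)


def rec(start, svtype="DEL", length=60, gt=HOM_ALT, sample="s1", qual=60.0,
        precise=True, chrom="chrY"):
    return SVRecord(
        chrom=chrom, start=start, svtype=svtype, length=length,
        genotypes={sample: gt}, qualities={sample: qual}, precise=precise,
    )


class TestFilterImprecise:
    def test_removes_only_imprecise(self):
        panel = SVPanel(
            [rec(100), rec(200, precise=False), rec(300)], ["s1"]
        )
        out = filter_imprecise(panel)
        assert [r.start for r in out.records] == [100, 300]

    def test_empty_and_all_precise_unchanged(self):
        assert filter_imprecise(SVPanel([], ["s1"])).records == []
        panel = SVPanel([rec(1), rec(2)], ["s1"])
        assert len(filter_imprecise(panel).records) == 2


class TestMergeIndels:
    def test_events_within_100bp_merge(self):
        p1 = SVPanel([rec(100, length=60, sample="s1")], ["s1"])
        p2 = SVPanel([rec(180, length=55, sample="s2")], ["s2"])
        merged = merge_indels([p1, p2], max_distance=100)
        assert len(merged.records) == 1
        m = merged.records[0]
        assert (m.start, m.length) == (100, 60)  # representative = first member
        assert m.genotypes == {"s1": HOM_ALT, "s2": HOM_ALT}

    def test_types_merge_separately(self):
        p = SVPanel([rec(100, "INS", 30), rec(100, "DEL", 30)], ["s1"])
        assert len(merge_indels(p).records) == 2

    def test_distance_over_100_keeps_events_apart(self):
        p = SVPanel([rec(100, "INS", 30), rec(250, "INS", 30)], ["s1"])
        assert len(merge_indels(p).records) == 2

    def test_sample_without_member_is_missing(self):
        p1 = SVPanel([rec(100, sample="s1")], ["s1"])
        p2 = SVPanel([rec(500, sample="s2")], ["s2"])
        merged = merge_indels([p1, p2])
        for m in merged.records:
            gts = set(m.genotypes.values())
            assert MISSING in gts and HOM_ALT in gts

    def test_dup_and_tra_pass_through_unmerged(self):
        p = SVPanel(
            [rec(100, "DUP", 500), rec(120, "DUP", 500), rec(200, "INS", 30)], ["s1"]
        )
        merged = merge_indels(p)
        assert sum(r.svtype == "DUP" for r in merged.records) == 2

    def test_idempotent_and_monotone_on_random_panels(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            panels = []
            for s in ("s1", "s2"):
                records = [
                    rec(int(rng.integers(0, 3000)),
                        "INS" if rng.random() < 0.5 else "DEL",
                        int(rng.integers(10, 400)), sample=s)
                    for _ in range(n)
                ]
                panels.append(SVPanel(records, [s]))
            merged = merge_indels(panels, max_distance=100)
            again = merge_indels(merged, max_distance=100)
            assert [(r.chrom, r.start, r.svtype, r.length) for r in again.records] == [
                (r.chrom, r.start, r.svtype, r.length) for r in merged.records
            ]
            wider = merge_indels(panels, max_distance=200)
            assert len(wider.records) <= len(merged.records)


class TestFilterGenotypes:
    def test_quality_boundary_is_strict_under_25(self):
        panel = SVPanel(
            [
                SVRecord("chrY", 100, "DEL", 60,
                         {"s1": HOM_ALT, "s2": HOM_ALT},
                         {"s1": 24.9, "s2": 25.0}),
            ],
            ["s1", "s2"],
        )
        out = filter_genotypes(panel)
        assert out.records[0].genotypes == {"s1": MISSING, "s2": HOM_ALT}

    def test_all_hom_ref_events_dropped(self):
        panel = SVPanel(
            [
                SVRecord("chrY", 100, "DEL", 60, {"s1": HOM_REF, "s2": HOM_REF},
                         {"s1": 60, "s2": 60}),
                SVRecord("chrY", 500, "DEL", 60, {"s1": HOM_ALT, "s2": HOM_REF},
                         {"s1": 60, "s2": 60}),
            ],
            ["s1", "s2"],
        )
        out = filter_genotypes(panel)
        assert len(out.records) == 1 and out.records[0].start == 500

    def test_never_increases_events_or_calls(self):
        rng = np.random.default_rng(3)
        gts = [HOM_REF, HET_ALT, HOM_ALT, MISSING]
        records = [
            SVRecord("chrY", int(rng.integers(0, 10_000)), "INS", 30,
                     {s: gts[int(rng.integers(4))] for s in ("a", "b", "c")},
                     {s: float(rng.uniform(0, 60)) for s in ("a", "b", "c")})
            for _ in range(50)
        ]
        panel = SVPanel(records, ["a", "b", "c"])
        out = filter_genotypes(panel)
        assert len(out.records) <= len(panel.records)
        n_calls = lambda p: sum(
            gt != MISSING for r in p.records for gt in r.genotypes.values()
        )
        assert n_calls(out) <= n_calls(panel)


class TestClassifySize:
    @pytest.mark.parametrize(
        "length,expected",
        [(10, "small"), (49, "small"), (50, "sv"), (499, "sv"), (500, "large"), (6314, "large")],
    )
    def test_bin_boundaries(self, length, expected):
        assert classify_size(length) == expected

    def test_below_panel_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            classify_size(9)


class TestRepeatFraction:
    def test_full_partial_and_no_overlap(self):
        r = rec(1000, "DEL", 100)
        full = [Interval("chrY", 900, 1200, name="L1HS")]
        assert repeat_fraction(r, full) == (1.0, "L1HS")
        partial = [Interval("chrY", 1000, 1038, name="AluSc")]
        frac, cls = repeat_fraction(r, partial)
        assert frac == pytest.approx(0.38) and cls == "AluSc"
        assert repeat_fraction(r, [Interval("chrY", 5000, 6000, name="x")]) == (0.0, None)

    def test_dominant_class_tie_broken_lexicographically(self):
        r = rec(0, "DEL", 100)
        reps = [Interval("chrY", 0, 50, name="B"), Interval("chrY", 50, 100, name="A")]
        assert repeat_fraction(r, reps) == (1.0, "A")


class TestSharingProfile:
    def test_shared_singleton_and_fraction(self, haplogroup_tree):
        import pandas as pd

        samples = haplogroup_tree.leaf_names
        rows = [
            [1] * len(samples),                       # shared by all
            [1] + [0] * (len(samples) - 1),           # singleton of first sample
            [1, 1] + [0] * (len(samples) - 2),        # intermediate pattern
            [1] + [np.nan] + [0] * (len(samples) - 2),  # incomplete: excluded
        ]
        m = pd.DataFrame(rows, columns=samples, dtype=float)
        prof = sharing_profile(m, haplogroup_tree)
        assert prof.n_complete == 3
        assert prof.shared_by_all == 1
        assert prof.singletons[samples[0]] == 1
        assert prof.fraction_shared == pytest.approx(1 / 3)

    def test_sample_mismatch_with_tree_rejected(self, haplogroup_tree):
        import pandas as pd

        m = pd.DataFrame([[1, 0]], columns=["x", "y"], dtype=float)
        with pytest.raises(ValueError, match="do not match"):
            sharing_profile(m, haplogroup_tree)

    def test_recovers_truth_branch_assignments(self, haplogroup_tree):
        """With no platform noise and no missing calls, the carrier set of
        every variant is exactly the leaf set of its simulated branch."""
        ont, _, truth = sim.simulate_sv_panel(
            haplogroup_tree, n_variants=150, platform_error=0.0,
            missing_rate=0.0, seed=9,
        )
        matrix = binarize(ont).data
        prof = sharing_profile(matrix, haplogroup_tree)
        assert prof.n_complete == 150
        from collections import Counter

        expected = Counter(truth.branch_leaves)
        assert prof.pattern_counts == expected
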