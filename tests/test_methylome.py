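import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ylandscape import simulate as sim
from ylandscape.core_io import GeneModel, GenomeDef
from ylandscape.intervals import Interval
from ylandscape.methylome import (
    annotate_cpg_category,
    annotate_gene_feature,
    annotate_methylome,
    build_matrix,
    cgi_means,
    class_category_summary,
    dispersion_scan,
    filter_sites,
    load_frequency_table,
    methylome_tree,
    quantile_normalize,
    window_track,
    write_frequency_table,
)

NANOPOLISH_HEADER = (
    "chromosome\tstart\tend\tnum_motifs_in_group\tcalled_sites\t"
    "called_sites_methylated\tmethylated_frequency\tgroup_sequence\n"
)


class TestLoadAndFilter:
    def test_frequency_is_the_count_ratio(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(NANOPOLISH_HEADER + "chrY\t100\t100\t1\t10\t7\t0.700\tACGTA\n")
        df = load_frequency_table(p)
        assert df.loc[0, "frequency"] == pytest.approx(0.7)

    def test_malformed_row_rejected(self, tmp_path, caplog):
        p = tmp_path / "m.tsv"
        p.write_text(
            NANOPOLISH_HEADER
            + "chrY\t100\t100\t1\t5\t7\t1.0\tACGTA\n"
            + "chrY\t200\t200\t1\t5\t2\t0.4\tACGTA\n"
        )
        df = load_frequency_table(p)
        assert len(df) == 1 and df.loc[0, "start"] == 200

    def test_round_trip(self, tmp_path, synthetic_genome):
        tables, _ = sim.simulate_methylome(synthetic_genome, n_samples=1,
                                           n_sites=200, seed=3)
        df = next(iter(tables.values()))
        p = tmp_path / "rt.tsv"
        write_frequency_table(df, p)
        back = load_frequency_table(p)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), df.reset_index(drop=True), check_dtype=False
        )

    def test_coverage_boundary_and_mask(self):
        df = pd.DataFrame(
            {
                "chrom": ["chrY"] * 3,
                "start": [10, 20, 30],
                "end": [11, 21, 31],
                "n_motifs": 1,
                "called": [3, 4, 10],
                "methylated": [1, 2, 5],
                "frequency": [1 / 3, 0.5, 0.5],
            }
        )
        out = filter_sites(df, min_coverage=4)
        assert out["start"].tolist() == [20, 30]  # 3x dropped, 4x kept
        masked = filter_sites(df, min_coverage=0,
                              alt_allele_mask=[Interval("chrY", 25, 40)])
        assert masked["start"].tolist() == [10, 20]


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = pd.DataFrame({"S1": [0.0, 0.5, 1.0], "S2": [0.2, 0.4, 0.6]})
        out = quantile_normalize(m)
        expected = [0.1, 0.45, 0.8]
        assert out["S1"].tolist() == pytest.approx(expected)
        assert out["S2"].tolist() == pytest.approx(expected)

    def test_identical_samples_are_a_fixed_point(self):
        col = [0.1, 0.9, 0.4, 0.4]
        m = pd.DataFrame({"a": col, "b": col})
        pd.testing.assert_frame_equal(quantile_normalize(m), m.astype(float))

    def test_tied_values_receive_mean_of_tied_ranks(self):
        m = pd.DataFrame({"a": [0.2, 0.2, 0.8], "b": [0.1, 0.5, 0.9]})
        out = quantile_normalize(m)
        # order-statistic means are [0.15, 0.35, 0.85]; the tie in column a
        # gets the mean of the two tied ranks' values
        assert out["a"].tolist() == pytest.approx([0.25, 0.25, 0.85])
        assert out["b"].tolist() == pytest.approx([0.15, 0.35, 0.85])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        arrays(float, (12, 4), elements=st.floats(0, 1, allow_nan=False, width=32))
    )
    def test_defining_properties_on_random_matrices(self, vals):
        # de-tie: with ties the sorted-multiset identity intentionally gives
        # way to tie-averaging (see the tie test above)
        vals = np.clip(vals + np.arange(vals.size).reshape(vals.shape) * 1e-9, 0, 1)
        for j in range(vals.shape[1]):
            if len(np.unique(vals[:, j])) < vals.shape[0]:
                vals[:, j] = np.sort(np.random.default_rng(j).random(vals.shape[0]))
        m = pd.DataFrame(vals, columns=list("abcd"))
        out = quantile_normalize(m)
        # sorted columns identical
        ref = np.sort(out["a"].to_numpy())
        for c in "bcd":
            assert np.allclose(np.sort(out[c].to_numpy()), ref, atol=1e-12)
        # idempotent
        again = quantile_normalize(out)
        assert np.allclose(again.to_numpy(), out.to_numpy(), atol=1e-12)
        # rank order preserved within each column (up to ties)
        for c in "abcd":
            x, y = m[c].to_numpy(), out[c].to_numpy()
            ix = np.argsort(x, kind="stable")
            assert (np.diff(y[ix]) >= -1e-12).all()
        # values stay in [0, 1]
        assert ((out.to_numpy() >= 0) & (out.to_numpy() <= 1)).all()

    def test_single_sample_returned_unchanged(self):
        m = pd.DataFrame({"a": [0.2, 0.8]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)


class TestCpGCategories:
    def test_two_kb_worked_examples(self):
        cgi = [Interval("chrY", 10_000, 11_000)]
        pos = pd.DataFrame({"chrom": ["chrY"] * 4, "start": [10_500, 9_500, 7_000, 5_000]})
        cats = annotate_cpg_category(pos, cgi).tolist()
        assert cats == ["island", "shore", "shelf", "open_sea"]

    def test_close_islands_keep_island_priority(self):
        # two CGIs 1 kb apart: the gap is entirely shore, islands intact
        cgi = [Interval("chrY", 10_000, 11_000), Interval("chrY", 12_000, 13_000)]
        pos = pd.DataFrame({"chrom": ["chrY"] * 3, "start": [11_500, 10_500, 12_500]})
        assert annotate_cpg_category(pos, cgi).tolist() == ["shore", "island", "island"]

    def test_no_islands_everything_open_sea(self):
        pos = pd.DataFrame({"chrom": ["chrY"], "start": [42]})
        assert annotate_cpg_category(pos, []).tolist() == ["open_sea"]

    def test_partition_mutually_exclusive_and_exhaustive(self):
        """Every sampled position gets exactly one category, and the four
        categories tile the chromosome."""
        rng = np.random.default_rng(13)
        cgi = []
        occupied = []
        while len(cgi) < 20:
            s = int(rng.integers(0, 990_000))
            e = s + int(rng.integers(200, 2_000))
            if any(s < oe and e > os_ for os_, oe in occupied):
                continue
            occupied.append((s, e))
            cgi.append(Interval("chrY", s, e))
        pts = rng.integers(0, 1_000_000, size=20_000)
        pos = pd.DataFrame({"chrom": "chrY", "start": pts})
        cats = annotate_cpg_category(pos, cgi)
        assert set(cats.unique()) <= {"island", "shore", "shelf", "open_sea"}
        assert cats.notna().all()
        # spot-check exclusivity against a brute-force distance rule
        starts = np.array([c.start for c in cgi])
        ends = np.array([c.end for c in cgi])
        for p, cat in zip(pts[:2_000], cats[:2_000]):
            inside = ((starts <= p) & (p < ends)).any()
            dist = 0 if inside else np.minimum(
                np.abs(starts - p), np.abs(p - ends + 1)
            ).min()
            if inside:
                assert cat == "island"
            elif dist <= 2_000:
                assert cat == "shore"
            elif dist <= 4_000:
                assert cat == "shelf"
            else:
                assert cat == "open_sea"


class TestGeneFeatures:
    @pytest.fixture
    def gene(self):
        return GeneModel(
            chrom="chrY", start=10_000, end=20_000, name="G", strand="+",
            exons=[(10_000, 11_000), (14_000, 15_000), (19_000, 20_000)],
            thick_start=10_500, thick_end=19_500,
        )

    def test_priority_and_collapse(self, gene):
        pos = pd.DataFrame(
            {
                "chrom": ["chrY"] * 6,
                "start": [10_200, 9_900, 14_500, 12_000, 19_700, 50_000],
            }
        )
        feats = annotate_gene_feature(pos, [gene]).tolist()
        # 5'UTR beats first exon; TSS region is the 200 bp upstream; the
        # exonic tail beyond the CDS is 3'UTR; non-first exons and introns
        # collapse to intragenic
        assert feats == ["utr5", "tss", "intragenic", "intragenic", "utr3", "intergenic"]

    def test_no_site_gets_two_features(self, gene):
        pts = np.arange(7_000, 21_000, 13)
        pos = pd.DataFrame({"chrom": "chrY", "start": pts})
        feats = annotate_gene_feature(pos, [gene])
        assert feats.notna().all()
        inside = (pts >= gene.start - 200) & (pts < gene.end)
        before = (pts >= gene.start - 2_200) & (pts < gene.start - 200)
        assert (feats[before] == "upstream").all()
        assert not (feats[inside] == "intergenic").any()


@pytest.fixture(scope="module")
def dataset():
    syn = sim.make_genome(seed=11)
    tables, truth = sim.simulate_methylome(syn, n_samples=4, n_sites=12_000, seed=11)
    matrix = quantile_normalize(build_matrix(tables))
    return syn, annotate_methylome(matrix, syn.cgi, syn.classes, syn.genes), truth


class TestSummariesAndTracks:

    def test_category_medians_recover_simulated_ordering(self, dataset):
        _, ds, _ = dataset
        summary = class_category_summary(ds)
        med = summary.groupby("cpg_category")["median"].median()
        assert med["island"] < med["shore"] <= med["shelf"] < med["open_sea"]

    def test_x_degenerate_open_sea_median_near_landmark(self, dataset):
        _, ds, _ = dataset
        summary = class_category_summary(ds)
        cell = summary[
            (summary.sequence_class == "X-degenerate") & (summary.cpg_category == "open_sea")
        ]
        assert cell["median"].median() == pytest.approx(0.75, abs=0.05)

    def test_window_medians_match_brute_force(self, dataset):
        syn, ds, _ = dataset
        track = window_track(ds, syn.genome, width=20_000)
        sample = ds.samples[0]
        starts = ds.matrix.index.get_level_values(1).to_numpy()
        vals = ds.matrix[sample].to_numpy()
        for rec in track.windows.itertuples():
            if rec.chrom != "chrY" or rec.n_sites == 0:
                continue
            inside = (starts >= rec.start) & (starts < rec.end)
            assert getattr(rec, sample) == pytest.approx(np.median(vals[inside]))

    def test_identical_samples_have_zero_sd(self):
        g = GenomeDef([("chrY", 100_000)], ploidy={"chrY": 1})
        idx = pd.MultiIndex.from_arrays([["chrY"] * 50, np.arange(0, 50_000, 1000)])
        col = np.linspace(0, 1, 50)
        m = pd.DataFrame({"a": col, "b": col, "c": col}, index=idx)
        track = window_track(m, g, width=25_000)
        filled = track.windows.dropna(subset=["sd"])
        assert filled["sd"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        # empty windows have missing median and SD
        empty = track.windows[track.windows.n_sites == 0]
        assert empty["sd"].isna().all()

    def test_cgi_means_worked_examples(self):
        idx = pd.MultiIndex.from_arrays([["chrY", "chrY"], [100, 150]])
        m = pd.DataFrame({"a": [0.1, 0.2], "b": [0.0, 0.0]}, index=idx)
        out = cgi_means(m, [Interval("chrY", 50, 200, name="CGI_1"),
                            Interval("chrY", 5_000, 6_000, name="CGI_2")])
        assert len(out) == 1  # CGI without sites omitted
        assert out.loc[0, "a"] == pytest.approx(0.15)
        assert out.loc[0, "b"] == 0.0
        assert out.loc[0, "grand_mean"] == pytest.approx(0.075)

    def test_fully_methylated_cgi_has_grand_mean_one(self):
        idx = pd.MultiIndex.from_arrays([["chrY"] * 3, [10, 20, 30]])
        m = pd.DataFrame({s: [1.0, 1.0, 1.0] for s in "abc"}, index=idx)
        out = cgi_means(m, [Interval("chrY", 0, 100, name="CGI_3")])
        assert out.loc[0, "grand_mean"] == 1.0


class TestDispersionAndTree:
    def test_planted_region_is_top_ranked_and_sample_identified(self):
        spec = sim.GenomeSpec(
            chromosomes=[("chr1", 2_000_000), ("chrY", 5_000_000)],
            gap_fraction={"chrY": 0.1}, n_cgi=50,
        )
        syn = sim.make_genome(spec, seed=2)
        planted = sim.PlantedRegion(Interval("chrY", 2_000_000, 2_250_000), "S2", -0.3)
        tables, _ = sim.simulate_methylome(
            syn, n_samples=5, n_sites=15_000, planted_region=planted,
            coverage_mean=10, seed=2,
        )
        matrix = quantile_normalize(build_matrix(tables))
        track = window_track(matrix, syn.genome, width=250_000)
        regions = dispersion_scan(track, syn.genes)
        assert regions, "no high-dispersion region found"
        top = regions[0]
        assert top.chrom == "chrY" and top.start < 2_250_000 and top.end > 2_000_000
        assert top.deviating_sample == "S2"

    def test_methylome_tree_recovers_generating_topology(self, haplogroup_tree):
        syn = sim.make_genome(seed=6)
        tables, _ = sim.simulate_methylome(
            syn, n_sites=6_000, seed=6, tree=haplogroup_tree, branch_scale=0.35
        )
        matrix = quantile_normalize(build_matrix(tables))
        res = methylome_tree(matrix, haplogroup_tree)
        assert res.rf_distance == 0

    def test_duplicate_columns_join_first(self):
        rng = np.random.default_rng(8)
        base = rng.random(500)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": rng.random(500), "d": rng.random(500)}
        )
        res = methylome_tree(m)
        assert res.distance_matrix.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        for node in res.tree.tree.preorder_internal_node_iter():
            labels = {lf.taxon.label for lf in node.leaf_iter()}
            if labels == {"a", "b"}:
                return
        pytest.fail("duplicate samples were not joined first")

    def test_fewer_than_three_samples_rejected(self):
        m = pd.DataFrame({"a": [0.1, 0.2], "b": [0.3, 0.4]})
        with pytest.raises(ValueError, match="3 samples"):
            methylome_tree(m)
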