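"""Preprocessing: OTU table I/O, filtering, rarefaction, alpha diversity."""

import numpy as np
import pandas as pd
import pytest

from reservoirnet import (
    ConfigurationError,
    FormatError,
    OtuTable,
    alpha_diversity,
    filter_low_abundance,
    rarefy,
    read_otu_table,
    relative_abundance,
    write_otu_table,
)


class TestIO:
    def test_round_trip_identity(self, toy_table, tmp_path):
        write_otu_table(toy_table, tmp_path / "t.tsv", tmp_path / "m.tsv")
        back = read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert back == toy_table

    def test_parsed_dimensions(self, tmp_path):
        (tmp_path / "t.tsv").write_text(
            "#OTU ID\ts1\ts2\nA\t1\t2\nB\t0\t3\nC\t5\t5\n"
        )
        (tmp_path / "m.tsv").write_text(
            "sample\tday\tport\tstage\ns1\t1\tSP1\thigh\ns2\t2\tSP1\thigh\n"
        )
        table = read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert table.counts.shape == (3, 2)

    def test_sample_missing_from_metadata_errors(self, toy_table, tmp_path):
        write_otu_table(toy_table, tmp_path / "t.tsv", tmp_path / "m.tsv")
        meta = pd.read_csv(tmp_path / "m.tsv", sep="\t").iloc[:-1]
        meta.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="s4"):
            read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    @pytest.mark.parametrize("bad", ["negative", "duplicate"])
    def test_invalid_counts_rejected(self, toy_table, bad):
        counts = toy_table.counts.copy()
        if bad == "negative":
            counts.iloc[0, 0] = -1
        else:
            counts.index = ["A", "A", "C"]
        with pytest.raises(FormatError):
            OtuTable(counts, toy_table.metadata)


class TestRelativeAbundance:
    def test_known_proportions(self, toy_table):
        rel = relative_abundance(toy_table)
        assert rel["s1"].tolist() == [0.5, 0.5, 0.0]
        assert rel["s2"].tolist() == pytest.approx([1e-4, 0.9999, 0.0])
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-9)

    def test_all_zero_sample_named_in_error(self, toy_table):
        counts = toy_table.counts.copy()
        counts["s3"] = 0
        with pytest.raises(FormatError, match="s3"):
            relative_abundance(OtuTable(counts, toy_table.metadata))


class TestFilter:
    def test_mean_abundance_criterion_hand_computed(self):
        # 2 samples; mean relative abundances: A 0.5, B 0.49985, C 5e-05, D 1e-4
        counts = pd.DataFrame(
            {"s1": [5000, 4998, 1, 1], "s2": [5000, 4999, 0, 1]},
            index=["A", "B", "C", "D"],
        )
        meta = pd.DataFrame(
            {"day": [1, 2], "port": ["SP1", "SP1"], "stage": ["high", "high"]},
            index=pd.Index(["s1", "s2"], name="sample"),
        )
        out = filter_low_abundance(OtuTable(counts, meta), threshold=1e-4)
        assert out.otu_ids == ["A", "B", "D"]  # boundary OTU D retained

    def test_zero_threshold_keeps_all(self, toy_table):
        assert filter_low_abundance(toy_table, threshold=0).otu_ids == toy_table.otu_ids

    def test_absent_otu_removed_and_renormalizes(self, toy_table):
        counts = toy_table.counts.copy()
        counts.loc["Z"] = 0
        out = filter_low_abundance(OtuTable(counts, toy_table.metadata), threshold=1e-6)
        assert "Z" not in out.otu_ids
        assert np.allclose(relative_abundance(out).sum(axis=0), 1.0)

    def test_bad_threshold(self, toy_table):
        with pytest.raises(ConfigurationError):
            filter_low_abundance(toy_table, threshold=1.5)


class TestRarefy:
    def test_depth_equal_total_leaves_counts(self, toy_table):
        out = rarefy(toy_table, depth=30, seed=0)  # s3 total is exactly 30
        assert out.counts["s3"].tolist() == [10, 10, 10]

    def test_totals_and_bounds(self, toy_table):
        out = rarefy(toy_table, depth=50, seed=3)
        assert (out.counts.sum(axis=0) == 50).all()
        assert (out.counts.to_numpy() <= toy_table.counts[out.sample_ids].to_numpy()).all()

    def test_shallow_samples_dropped_with_warning(self, toy_table, caplog):
        with caplog.at_level("WARNING"):
            out = rarefy(toy_table, depth=50, seed=0)
        assert set(out.sample_ids) == {"s1", "s2"} and "s4" in caplog.text

    def test_deterministic_given_seed(self, toy_table):
        a = rarefy(toy_table, depth=50, seed=7)
        b = rarefy(toy_table, depth=50, seed=7)
        assert a == b

    def test_observed_otus_monotone_in_depth_in_expectation(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"s": rng.integers(0, 200, size=30)}, index=[f"O{i}" for i in range(30)])
        meta = pd.DataFrame({"day": [1], "port": ["SP1"], "stage": ["high"]},
                            index=pd.Index(["s"], name="sample"))
        table = OtuTable(counts, meta)
        means = []
        for depth in (50, 500):
            obs = [
                alpha_diversity(rarefy(table, depth=depth, seed=s), "observed_otus").values["s"]
                for s in range(50)
            ]
            means.append(np.mean(obs))
        assert means[0] <= means[1]

    def test_bad_depth(self, toy_table):
        with pytest.raises(ConfigurationError):
            rarefy(toy_table, depth=0)


class TestAlphaDiversity:
    def test_shannon_uniform_and_degenerate(self, toy_table):
        div = alpha_diversity(toy_table, "shannon")
        assert div.values["s3"] == pytest.approx(np.log2(3))
        assert div.values["s4"] == 0.0
        assert alpha_diversity(toy_table, "observed_otus").values["s4"] == 1

    def test_shannon_hand_example(self):
        counts = pd.DataFrame({"s": [2, 1, 1]}, index=["A", "B", "C"])
        meta = pd.DataFrame({"day": [1], "port": ["SP1"], "stage": ["high"]},
                            index=pd.Index(["s"], name="sample"))
        div = alpha_diversity(OtuTable(counts, meta), "shannon")
        assert div.values["s"] == pytest.approx(1.5)  # -sum p log2 p at (.5,.25,.25)

    def test_permutation_invariance(self, toy_table):
        shuffled = OtuTable(toy_table.counts.iloc[::-1], toy_table.metadata)
        a = alpha_diversity(toy_table, "shannon").values
        b = alpha_diversity(shuffled, "shannon").values
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_unknown_metric(self, toy_table):
        with pytest.raises(ConfigurationError):
            alpha_diversity(toy_table, "chao9")
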