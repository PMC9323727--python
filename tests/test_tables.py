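import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oronasal.tables import (
    AbundanceTable,
    aggregate_to_genus,
    group_mean_relative,
    load_metadata,
    load_table,
    to_relative,
    top_n_genera,
    write_metadata,
    write_table,
)
from conftest import make_metadata, make_table


class TestLoadTable:
    def test_reads_shape_and_values(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("taxon\ts1\ts2\nA\t1\t2\nB\t3\t4\nC\t5\t6\n")
        table = load_table(path)
        assert table.shape == (3, 2)
        assert table.data.to_numpy().sum() == 21
        assert table.taxa == ["A", "B", "C"] and table.samples == ["s1", "s2"]
        assert table.mode == "counts"

    def test_roundtrip_preserves_random_integer_table(self, tmp_path):
        rng = np.random.default_rng(5)
        table = make_table(rng.integers(0, 1000, size=(50, 20)))
        path = tmp_path / "round.tsv"
        write_table(table, path)
        back = load_table(path)
        assert back.taxa == table.taxa and back.samples == table.samples
        assert (back.data.to_numpy() == table.data.to_numpy()).all()

    @pytest.mark.parametrize(
        "content,match",
        [
            ("", "no data rows"),
            ("taxon\ts1\ts2\n", "no data rows"),
            ("taxon\ts1\nA\t-3\n", "negative cell at taxon 'A', sample 's1'"),
            ("taxon\ts1\nA\tfoo\n", "non-numeric cell at taxon 'A', sample 's1'"),
            ("taxon\ts1\nA\t1\nA\t2\n", "duplicate taxon"),
            ("taxon\ts1\ts1\nA\t1\t2\n", "duplicate sample"),
        ],
    )
    def test_rejects_malformed_input(self, tmp_path, content, match):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(ValueError, match=match):
            load_table(path)

    @pytest.mark.parametrize("matrix_type", ["dense", "sparse"])
    def test_biom_json_matches_tsv(self, tmp_path, matrix_type):
        values = np.array([[5, 0, 2], [0, 7, 1]])
        doc = {
            "rows": [{"id": "A"}, {"id": "B"}],
            "columns": [{"id": "s1"}, {"id": "s2"}, {"id": "s3"}],
            "shape": [2, 3],
            "matrix_type": matrix_type,
            "data": (
                values.tolist()
                if matrix_type == "dense"
                else [[i, j, int(values[i, j])] for i in range(2) for j in range(3) if values[i, j]]
            ),
        }
        path = tmp_path / "t.biom"
        path.write_text(json.dumps(doc))
        table = load_table(path, format="biom-json")
        assert (table.data.to_numpy() == values).all()
        assert table.samples == ["s1", "s2", "s3"]


class TestInvariants:
    def test_negative_value_rejected_with_coordinates(self):
        with pytest.raises(ValueError, match="negative value at taxon 'G1', sample 's0'"):
            make_table([[1, 2], [-1, 3]])

    def test_relative_mode_requires_unit_columns(self):
        with pytest.raises(ValueError, match="sums to"):
            make_table([[0.5, 0.5], [0.4, 0.5]], mode="relative")


class TestAggregate:
    def test_additivity(self):
        table = make_table([[3, 4], [1, 0], [2, 2]], taxa=["otu1", "otu2", "otu3"])
        out = aggregate_to_genus(
            table, {"otu1": "Streptococcus", "otu2": "Streptococcus", "otu3": "Rothia"}
        )
        assert out.data.loc["Streptococcus"].tolist() == [4, 4]
        assert out.data.loc["Rothia"].tolist() == [2, 2]

    def test_identity_map_preserves_table(self):
        table = make_table(np.arange(12).reshape(4, 3))
        out = aggregate_to_genus(table, {t: t for t in table.taxa})
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_column_sums_conserved_on_random_maps(self):
        rng = np.random.default_rng(7)
        table = make_table(rng.integers(0, 50, size=(100, 10)),
                           taxa=[f"otu{i}" for i in range(100)])
        genera = [f"Genus{k}" for k in range(10)] + ["unclassified"]
        mapping = {t: genera[rng.integers(0, len(genera))] for t in table.taxa}
        out = aggregate_to_genus(table, mapping)
        assert (out.data.sum(axis=0).to_numpy() == table.data.sum(axis=0).to_numpy()).all()

    def test_unmapped_taxon_is_an_error_listing_offenders(self):
        table = make_table([[1, 1]], taxa=["otuX"])
        with pytest.raises(ValueError, match="otuX"):
            aggregate_to_genus(table, {})

    def test_drop_unclassified_renormalizes_relative_tables(self):
        table = make_table([[0.5, 0.25], [0.25, 0.25], [0.25, 0.5]],
                           taxa=["A", "unclassified", "B"], mode="relative")
        out = aggregate_to_genus(table, {t: t for t in table.taxa}, drop_unclassified=True)
        assert "unclassified" not in out.taxa
        np.testing.assert_allclose(out.data.sum(axis=0), 1.0)


class TestToRelative:
    def test_normalizes_columns(self):
        out = to_relative(make_table([[2], [3], [5]]))
        assert out.data.iloc[:, 0].tolist() == [0.2, 0.3, 0.5]
        assert out.mode == "relative"

    def test_single_taxon_gives_ones(self):
        out = to_relative(make_table([[7, 3, 11]]))
        assert (out.data.to_numpy() == 1.0).all()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 12), st.integers(2, 8), st.integers(0, 10**6))
    def test_columns_sum_to_one(self, n_taxa, n_samples, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 100, size=(n_taxa, n_samples)) + np.eye(n_taxa, n_samples, dtype=int)
        out = to_relative(make_table(counts))
        np.testing.assert_allclose(out.data.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_is_an_error_naming_the_sample(self):
        with pytest.raises(ValueError, match="'s1'"):
            to_relative(make_table([[1, 0], [2, 0]]))

    def test_relative_input_is_a_warned_noop(self):
        table = make_table([[0.4, 0.3], [0.6, 0.7]], mode="relative")
        with pytest.warns(UserWarning, match="relative-mode"):
            out = to_relative(table)
        assert out is table


class TestGroupMeans:
    def _paired(self):
        table = make_table([[2, 4, 50], [98, 96, 50]], taxa=["A", "B"],
                           samples=["h1_nasal", "h2_nasal", "c1_nasal"])
        meta = make_metadata(
            ["h1_nasal", "h2_nasal", "c1_nasal"],
            ["healthy", "healthy", "CP"], ["nasal"] * 3, ["child"] * 3,
        )
        return table, meta

    def test_mean_of_per_sample_fractions(self):
        table, meta = self._paired()
        means = group_mean_relative(table, meta, "healthy", "nasal")
        assert means["A"] == pytest.approx(0.03)

    def test_absent_genus_is_zero(self):
        table = make_table([[0, 0], [5, 5]], taxa=["A", "B"], samples=["x_nasal", "y_nasal"])
        meta = make_metadata(["x_nasal", "y_nasal"], ["CP"] * 2, ["nasal"] * 2, ["child"] * 2)
        assert group_mean_relative(table, meta, "CP", "nasal")["A"] == 0.0

    def test_matches_bruteforce_mean_on_random_samples(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 200, size=(8, 10))
        ids = [f"s{i}_nasal" for i in range(10)]
        table = make_table(counts, samples=ids)
        meta = make_metadata(ids, ["CP"] * 10, ["nasal"] * 10, ["child"] * 10)
        means = group_mean_relative(table, meta, "CP", "nasal")
        brute = np.mean(counts / counts.sum(axis=0, keepdims=True), axis=1)
        np.testing.assert_allclose(means.to_numpy(), brute, atol=1e-12)

    def test_no_matching_samples_is_an_error(self):
        table, meta = self._paired()
        with pytest.raises(ValueError, match="no samples match"):
            group_mean_relative(table, meta, "postoperative", "nasal")


class TestTopGenera:
    def test_single_top_genus(self):
        table = make_table([[90, 80], [10, 20]], taxa=["Pseudomonas", "Moraxella"],
                           samples=["a_nasal", "b_nasal"])
        meta = make_metadata(["a_nasal", "b_nasal"], ["healthy"] * 2, ["nasal"] * 2, ["child"] * 2)
        top = top_n_genera(table, meta, "healthy", "nasal", 1)
        assert top[0][0] == "Pseudomonas" and top[0][1] == pytest.approx(0.85)

    def test_n_beyond_taxon_count_returns_full_ranking(self):
        table = make_table([[5], [3], [2]], samples=["a_nasal"])
        meta = make_metadata(["a_nasal"], ["healthy"], ["nasal"], ["child"])
        assert len(top_n_genera(table, meta, "healthy", "nasal", 99)) == 3

    def test_planted_dominants_rank_in_construction_order(self, cohort):
        table, meta, truth = cohort
        top = top_n_genera(table, meta, "healthy", "nasal", 3, age_class="child")
        assert [g for g, _ in top] == ["Pseudomonas", "Dolosigranulum", "Moraxella"]


class TestMetadataIO:
    def test_roundtrip(self, tmp_path, cohort):
        _, meta, _ = cohort
        path = tmp_path / "meta.tsv"
        write_metadata(meta, path)
        back = load_metadata(path)
        pd.testing.assert_frame_equal(back, meta[back.columns])

    def test_invalid_group_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tsubject_id\tgroup\tniche\tage_class\ns1\tp1\tsick\toral\tchild\n")
        with pytest.raises(ValueError, match="invalid value"):
            load_metadata(path)
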