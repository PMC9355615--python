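import numpy as np
import pandas as pd
import pytest
import yaml
from guildassembly.errors import ConfigError, ParseError, ValidationError
from guildassembly.tabular_io import (DistanceMatrix, GuildAnnotation,
                                      GuildRecord, OtuTable, load_config,
                                      read_annotation, read_distance_matrix,
                                      read_metadata, read_otu_table,
                                      read_plant_community, write_annotation,
                                      write_distance_matrix, write_metadata,
                                      write_otu_table)

from conftest import random_table


class TestOtuTable:
    def test_roundtrip_exact(self, tmp_path):
        table = OtuTable(("A", "B"), ("o1", "o2"),
                         np.array([[1, 3], [0, 2]]))
        path = tmp_path / "t.tsv"
        write_otu_table(table, path)
        assert read_otu_table(path) == table

    def test_roundtrip_byte_identical(self, tmp_path):
        table = OtuTable(("A", "B"), ("o1", "o2"),
                         np.array([[1, 3], [0, 2]]))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_otu_table(table, p1)
        write_otu_table(read_otu_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_roundtrip_samples_as_rows(self, tmp_path):
        table = random_table(np.random.default_rng(0))
        path = tmp_path / "t.tsv"
        write_otu_table(table, path, orientation="samples_as_rows")
        assert read_otu_table(path, orientation="samples_as_rows") == table

    @pytest.mark.parametrize("seed", range(20))
    def test_roundtrip_randomized(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        table = random_table(rng, int(rng.integers(2, 7)),
                             int(rng.integers(1, 10)))
        path = tmp_path / "t.tsv"
        write_otu_table(table, path)
        assert read_otu_table(path) == table

    def test_negative_count_cites_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("otu_id\tA\tB\no1\t1\t-1\n")
        with pytest.raises(ParseError, match=r"line=2.*column=3"):
            read_otu_table(path)

    def test_non_integer_count(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("otu_id\tA\no1\t1.5\n")
        with pytest.raises(ParseError, match="non-integer"):
            read_otu_table(path)

    def test_duplicate_sample_id(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("otu_id\tA\tA\no1\t1\t2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_otu_table(path)

    def test_negative_count_in_constructor(self):
        with pytest.raises(ValidationError, match="negative"):
            OtuTable(("a",), ("o",), np.array([[-1]]))

    def test_select_otus_and_samples(self, small_table):
        sub = small_table.select_otus(["o3", "o1"])
        assert sub.otu_ids == ("o3", "o1")
        assert np.array_equal(sub.counts[:, 1], small_table.counts[:, 0])
        subs = small_table.select_samples(["s3"])
        assert subs.sample_ids == ("s3",)


class TestDistanceMatrix:
    def test_zero_matrix_valid(self):
        m = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        assert m.condensed().tolist() == [0, 0, 0]

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(size=(4, 4)))
        vals = (vals + vals.T)
        np.fill_diagonal(vals, 0)
        m = DistanceMatrix(("a", "b", "c", "d"), vals)
        path = tmp_path / "d.tsv"
        write_distance_matrix(m, path)
        m2 = read_distance_matrix(path)
        assert m2.labels == m.labels
        np.testing.assert_allclose(m2.values, m.values, atol=1e-9)

    def test_asymmetry_error(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("label\ta\tb\na\t0\t1\nb\t2\t0\n")
        with pytest.raises(ParseError, match="asymmetry"):
            read_distance_matrix(path)

    def test_non_square_error(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("label\ta\tb\na\t0\t1\n")
        with pytest.raises(ParseError, match="not square"):
            read_distance_matrix(path)

    def test_label_mismatch_error(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("label\ta\tb\na\t0\t1\nc\t1\t0\n")
        with pytest.raises(ParseError, match="labels"):
            read_distance_matrix(path)

    def test_signed_matrix_roundtrip(self, tmp_path):
        m = DistanceMatrix(("a", "b"), np.array([[0.0, -2.5], [-2.5, 0.0]]),
                           signed=True)
        path = tmp_path / "d.tsv"
        write_distance_matrix(m, path)
        m2 = read_distance_matrix(path)
        assert m2.signed
        assert m2.values[0, 1] == -2.5

    def test_negative_unsigned_rejected(self):
        with pytest.raises(ValidationError, match="signed"):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_reorder_roundtrip(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(size=4)
        m = DistanceMatrix(tuple("abcd"), np.abs(pts[:, None] - pts[None, :]))
        m2 = m.reorder(("d", "b", "a", "c")).reorder(("a", "b", "c", "d"))
        np.testing.assert_allclose(m2.values, m.values)


class TestAnnotationIO:
    def test_roundtrip(self, tmp_path):
        ann = GuildAnnotation((
            GuildRecord("o1", "Saprotroph", "Wood Saprotroph", "Probable"),
            GuildRecord("o2", "Symbiotroph", "Ectomycorrhizal",
                        "Highly Probable"),
        ))
        path = tmp_path / "a.tsv"
        write_annotation(ann, path)
        assert read_annotation(path) == ann

    def test_bad_confidence(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("otu_id\ttrophic_mode\tguild\tconfidence\n"
                        "o1\tSaprotroph\tx\tMaybe\n")
        with pytest.raises(ParseError, match="confidence"):
            read_annotation(path)


class TestMetadataIO:
    def _frame(self, **overrides):
        base = {"sample_id": ["s1", "s2"], "site_id": ["S1", "S1"],
                "quadrat_id": ["Q1", "Q1"],
                "depth_layer": ["surface", "subsurface"],
                "latitude": [41.0, 41.1], "longitude": [101.0, 101.1],
                "vegetation_type": ["desert", "desert"], "SM": [1.0, 2.0]}
        base.update(overrides)
        return pd.DataFrame(base)

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_metadata(self._frame(), path)
        md = read_metadata(path)
        assert list(md["sample_id"]) == ["s1", "s2"]

    def test_latitude_range(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_metadata(self._frame(latitude=[95.0, 41.0]), path)
        with pytest.raises(ParseError, match="latitude"):
            read_metadata(path)

    def test_depth_vocabulary(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_metadata(self._frame(depth_layer=["top", "surface"]), path)
        with pytest.raises(ParseError, match="depth_layer"):
            read_metadata(path)


class TestPlantCommunityIO:
    def test_rows_must_sum_to_one(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("quadrat_id\tsp1\tsp2\nQ1\t0.5\t0.4\n")
        with pytest.raises(ParseError, match="sum to 1"):
            read_plant_community(path)

    def test_valid(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("quadrat_id\tsp1\tsp2\nQ1\t0.5\t0.5\nQ2\t1\t0\n")
        df = read_plant_community(path)
        assert df.loc["Q2", "sp1"] == 1.0


class TestConfig:
    def _write(self, tmp_path, payload):
        path = tmp_path / "c.yml"
        path.write_text(yaml.safe_dump(payload))
        return path

    def test_defaults_applied(self, tmp_path):
        cfg = load_config(self._write(tmp_path, {
            "simulate": {"regime": "neutral"}}))
        assert cfg["n_null"] == 999
        assert cfg["n_perm"] == 999
        assert cfg["alpha"] == 0.05

    def test_unknown_key_suggestion(self, tmp_path):
        path = self._write(tmp_path, {"simulate": {"regime": "neutral"},
                                      "n_nulls": 99})
        with pytest.raises(ConfigError, match="n_null"):
            load_config(path)

    def test_missing_input_path_listed(self, tmp_path):
        path = self._write(tmp_path, {"inputs": {"otu_table": "x.tsv"}})
        with pytest.raises(ConfigError, match="annotation"):
            load_config(path)

    def test_requires_exactly_one_source(self, tmp_path):
        with pytest.raises(ConfigError, match="exactly one"):
            load_config(self._write(tmp_path, {}))
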