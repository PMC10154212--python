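"""Abundance-table I/O, compositional transforms and prevalence filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microaging.profiles import (
    AbundanceTable,
    ParseError,
    ValidationError,
    auto_pseudocount,
    clr_transform,
    filter_prevalent_taxa,
    range_scale,
    read_abundance_table,
    to_relative,
    write_abundance_table,
)
from tests.conftest import make_collection


def _table(arr, scale="counts", taxa=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return AbundanceTable(pd.DataFrame(arr, index=taxa, columns=samples), scale=scale)


class TestIO:
    def test_roundtrip_small_counts(self, tmp_path):
        t = _table([[1, 2], [3, 4], [5, 6]])
        path = tmp_path / "t.tsv"
        write_abundance_table(t, path)
        back = read_abundance_table(path)
        assert back.shape == (3, 2)
        assert back.scale == "counts"
        pd.testing.assert_frame_equal(back.values, t.values, check_names=False)

    def test_roundtrip_random_bitwise(self, tmp_path, rng):
        vals = rng.random(size=(50, 20)) * 1e4
        t = _table(vals)
        path = tmp_path / "r.tsv"
        write_abundance_table(t, path)
        back = read_abundance_table(path)
        # full decimal repr on write => bitwise-identical values after reread
        assert np.array_equal(back.values.to_numpy(), t.values.to_numpy())

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_id\ts1\ts2\nta\t1\tx\ntb\t2\t3\n")
        with pytest.raises(ParseError, match="ta.*s2"):
            read_abundance_table(path)

    def test_duplicate_taxon_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("taxon_id\ts1\nta\t1\nta\t2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_abundance_table(path)

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("taxon_id\ts1\n")
        with pytest.raises(ParseError, match="empty"):
            read_abundance_table(path)

    def test_relative_sum_violation_rejected(self, tmp_path):
        path = tmp_path / "rel.tsv"
        path.write_text("taxon_id\ts1\nta\t0.4\ntb\t0.5\n")
        with pytest.raises(ValidationError, match="sum to 1"):
            read_abundance_table(path, scale="relative")

    def test_comma_dialect_accepted(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("taxon_id,s1,s2\nta,1,2\ntb,3,4\n")
        t = read_abundance_table(path)
        assert t.shape == (2, 2)


class TestToRelative:
    def test_hand_example(self):
        rel = to_relative(_table([[2], [8]]))
        assert np.allclose(rel.values.to_numpy().ravel(), [0.2, 0.8])
        assert rel.scale == "relative"

    def test_idempotent(self, rng):
        t = _table(rng.integers(0, 50, size=(8, 5)) + 1)
        once = to_relative(t)
        twice = to_relative(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-15
        )

    def test_columns_sum_to_one(self, rng):
        t = _table(rng.integers(0, 100, size=(12, 9)) + 1)
        sums = to_relative(t).values.sum(axis=0)
        assert np.abs(sums - 1).max() < 1e-12

    def test_all_zero_sample_named(self):
        with pytest.raises(ValidationError, match="s1"):
            to_relative(_table([[1, 0], [1, 0]]))


class TestClr:
    def test_uniform_composition_is_zero(self):
        out = clr_transform(_table([[1], [1], [1], [1]]), pseudocount=0)
        assert np.allclose(out.values.to_numpy(), 0)

    def test_hand_example_two_taxa(self):
        out = clr_transform(_table([[2], [8]]), pseudocount=0)
        np.testing.assert_allclose(
            out.values.to_numpy().ravel(), [-0.6931, 0.6931], atol=5e-5
        )

    def test_columns_centered(self, rng):
        t = _table(rng.integers(1, 100, size=(15, 6)))
        out = clr_transform(t, pseudocount=0)
        assert np.abs(out.values.sum(axis=0)).max() < 1e-12

    def test_scale_invariance(self, rng):
        arr = rng.integers(1, 100, size=(10, 4)).astype(float)
        a = clr_transform(_table(arr), pseudocount=0)
        b = clr_transform(_table(arr * 7.3), pseudocount=0)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-12)

    def test_zero_needs_positive_pseudocount(self):
        with pytest.raises(ValidationError, match="pseudocount"):
            clr_transform(_table([[0, 1], [1, 1]]), pseudocount=0)

    def test_auto_pseudocount_half_min_nonzero(self):
        t = _table([[0, 4], [2, 4]])
        # relative columns: [0, 1] and [0.5, 0.5] -> min nonzero 0.5
        assert auto_pseudocount(t) == pytest.approx(0.25)


class TestPrevalenceFilter:
    @staticmethod
    def _random_collection(rng, n_studies=5, n_taxa=12, n_samples=40):
        tables = {}
        for s in range(n_studies):
            arr = rng.integers(0, 4, size=(n_taxa, n_samples)).astype(float)
            arr[rng.random(arr.shape) < 0.6] = 0
            arr[0, :] += 1  # avoid all-zero samples
            tables[f"st{s}"] = pd.DataFrame(
                arr,
                index=[f"t{i}" for i in range(n_taxa)],
                columns=[f"st{s}_x{j}" for j in range(n_samples)],
            )
        data_types = {f"st{s}": ("shotgun" if s % 2 else "amplicon") for s in range(n_studies)}
        return make_collection(tables, data_types=data_types)

    def test_matches_bruteforce_enumeration(self, rng):
        coll = self._random_collection(rng)
        min_sf, min_stf = 0.3, 0.6
        got = filter_prevalent_taxa(coll, min_sf, min_stf, per_data_type=True)
        meta = coll.metadata.frame
        strata = {}
        for study in coll.study_ids:
            dt = meta.loc[meta.study_id == study, "data_type"].iloc[0]
            strata.setdefault(dt, []).append(study)
        expected = []
        for taxon in sorted({t for tab in coll.tables.values() for t in tab.taxon_ids}):
            ok = True
            for studies in strata.values():
                hits = 0
                for study in studies:
                    vals = coll.tables[study].values.loc[taxon]
                    if (vals > 0).sum() / len(vals) >= min_sf:
                        hits += 1
                if hits < min_stf * len(studies):
                    ok = False
            if ok:
                expected.append(taxon)
        assert got == expected

    def test_absent_taxon_excluded(self, rng):
        coll = self._random_collection(rng)
        for table in coll.tables.values():
            table.values.loc["t5"] = 0.0
        assert "t5" not in filter_prevalent_taxa(coll, 0.05, 0.6)

    def test_monotone_in_thresholds(self, rng):
        coll = self._random_collection(rng)
        loose = set(filter_prevalent_taxa(coll, 0.1, 0.4, per_data_type=False))
        tight = set(filter_prevalent_taxa(coll, 0.3, 0.8, per_data_type=False))
        assert tight <= loose

    def test_threshold_domain(self, rng):
        coll = self._random_collection(rng)
        with pytest.raises(ValidationError):
            filter_prevalent_taxa(coll, -0.1, 0.6)
        with pytest.raises(ValidationError):
            filter_prevalent_taxa(coll, 0.05, 1.2)


class TestRangeScale:
    def test_formula(self):
        out = range_scale([0.0, 5.0, 10.0])
        assert out[1] == pytest.approx(0.5)
        assert out[0] == 0.0 and out[2] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30),
        st.floats(0.01, 100),
        st.floats(-50, 50),
    )
    def test_affine_invariance_and_bounds(self, vals, a, b):
        v = np.asarray(vals)
        if np.ptp(v) == 0:
            return
        base = range_scale(v)
        assert base.min() == 0.0 and base.max() == 1.0
        np.testing.assert_allclose(range_scale(a * v + b), base, atol=1e-9)

    def test_constant_maps_to_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            out = range_scale([3.0, 3.0, 3.0])
        assert np.array_equal(out, np.zeros(3))
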