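"""Probe harmonization, filtering, M-transform, covariate residuals, z-scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epicoord as ec
from conftest import make_annotation, make_dataset


def _ds_with_probes(probe_ids, n_samples=4, seed=0):
    rng = np.random.default_rng(seed)
    ann = make_annotation(len(probe_ids))
    ann.index = pd.Index(probe_ids, name="probe_id")
    return make_dataset(rng.normal(size=(len(probe_ids), n_samples)),
                        ["case"] * 2 + ["control"] * (n_samples - 2),
                        annotation=ann)


class TestHarmonize:
    def test_restricts_to_intersection(self):
        a = _ds_with_probes(["A", "B", "C"])
        b = _ds_with_probes(["B", "C", "D"], seed=1)
        out = ec.harmonize_probes([a, b])
        for ds in out:
            assert list(ds.probe_ids) == ["B", "C"]

    def test_identical_probe_sets_are_identity_up_to_order(self):
        a = _ds_with_probes(["C", "A", "B"])
        b = _ds_with_probes(["A", "B", "C"], seed=1)
        out = ec.harmonize_probes([a, b])
        pd.testing.assert_frame_equal(out[0].values, a.values.sort_index())

    def test_disjoint_sets_error(self):
        a = _ds_with_probes(["A", "B"])
        b = _ds_with_probes(["C", "D"], seed=1)
        with pytest.raises(ValueError, match="zero probes"):
            ec.harmonize_probes([a, b])

    def test_harmonize_filter_harmonize_idempotent(self):
        flags = [frozenset({"cross_reactive"})] + [frozenset()] * 5
        ann = make_annotation(6, flags=flags)
        rng = np.random.default_rng(2)
        a = make_dataset(rng.normal(size=(6, 4)), ["case"] * 2 + ["control"] * 2,
                         annotation=ann)
        b = make_dataset(rng.normal(size=(6, 4)), ["case"] * 2 + ["control"] * 2,
                         annotation=ann)
        once = [ec.filter_probes(d)[0] for d in ec.harmonize_probes([a, b])]
        twice = ec.harmonize_probes(once)
        for d1, d2 in zip(once, twice):
            pd.testing.assert_frame_equal(d1.values, d2.values)


class TestFilterProbes:
    def test_flagged_probes_removed_and_reported(self):
        flags = [frozenset({"cross_reactive"})] * 2 + [frozenset()] * 8
        ann = make_annotation(10, flags=flags)
        ds = make_dataset(np.zeros((10, 4)) + 0.5,
                          ["case"] * 2 + ["control"] * 2, annotation=ann)
        out, report = ec.filter_probes(ds, exclude_flags={"cross_reactive"},
                                       exclude_sex=False)
        assert len(out.probe_ids) == 8
        assert report["cross_reactive"] == 2

    def test_empty_exclusions_are_identity(self):
        ds = _ds_with_probes(list("ABCD"))
        out, report = ec.filter_probes(ds, exclude_flags=set(), exclude_sex=False)
        pd.testing.assert_frame_equal(out.values, ds.values)
        assert report["total_removed"] == 0

    def test_doubly_flagged_probe_removed_once(self):
        flags = [frozenset({"cross_reactive", "age_associated"})] + [frozenset()] * 4
        ann = make_annotation(5, flags=flags)
        ds = make_dataset(np.full((5, 4), 0.5), ["case"] * 2 + ["control"] * 2,
                          annotation=ann)
        out, report = ec.filter_probes(
            ds, exclude_flags={"cross_reactive", "age_associated"}, exclude_sex=False
        )
        assert report["total_removed"] == 1
        assert len(out.probe_ids) == 4

    def test_sex_chromosome_probes_removed(self):
        ann = make_annotation(4)
        ann.loc[ann.index[0], "chromosome"] = "chrX"
        ds = make_dataset(np.full((4, 4), 0.5), ["case"] * 2 + ["control"] * 2,
                          annotation=ann)
        out, report = ec.filter_probes(ds, exclude_flags=set(), exclude_sex=True)
        assert report["sex_chromosome"] == 1
        assert "chrX" not in set(ds.annotation.loc[out.probe_ids, "chromosome"])

    def test_all_removed_errors(self):
        flags = [frozenset({"cross_reactive"})] * 3
        ann = make_annotation(3, flags=flags)
        ds = make_dataset(np.full((3, 4), 0.5), ["case"] * 2 + ["control"] * 2,
                          annotation=ann)
        with pytest.raises(ValueError, match="all probes"):
            ec.filter_probes(ds, exclude_flags={"cross_reactive"}, exclude_sex=False)


class TestBetaToM:
    def test_closed_form_values(self):
        ds = make_dataset([[0.5, 0.8, 0.0, 1.0]],
                          ["case", "case", "control", "control"], scale="beta")
        m = ec.beta_to_m(ds, epsilon=1e-6).values.to_numpy()[0]
        assert m[0] == pytest.approx(0.0)
        assert m[1] == pytest.approx(2.0)
        assert m[2] == pytest.approx(np.log2(1e-6 / (1 - 1e-6)))
        assert np.isfinite(m).all()

    def test_wrong_scale_rejected(self):
        ds = make_dataset(np.zeros((2, 4)), ["case"] * 2 + ["control"] * 2, scale="M")
        with pytest.raises(ValueError, match="beta"):
            ec.beta_to_m(ds)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_invertible(self, b):
        m = np.log2(b / (1 - b))
        assert ec.m_to_beta(m) == pytest.approx(b, abs=1e-9)
        b2 = min(b + 1e-4, 1 - 1e-6)
        m2 = np.log2(b2 / (1 - b2))
        assert m2 >= m


class TestAdjustCovariates:
    def test_intercept_only_is_identity(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(5, 6)), ["case"] * 3 + ["control"] * 3)
        cov = pd.DataFrame({"c": np.ones(6)}, index=ds.sample_ids)
        with pytest.raises(ValueError, match="rank"):
            # column of ones duplicates the internal intercept
            ec.adjust_covariates(ds, cov)

    def test_linear_in_covariate_residuals_constant(self):
        x = np.arange(6, dtype=float)
        vals = np.vstack([2 * x + 1, -x + 3])
        ds = make_dataset(vals, ["case"] * 3 + ["control"] * 3)
        cov = pd.DataFrame({"c": x}, index=ds.sample_ids)
        out = ec.adjust_covariates(ds, cov).values.to_numpy()
        assert np.allclose(out[0], vals[0].mean())
        assert np.allclose(out[1], vals[1].mean())

    def test_residuals_orthogonal_to_centered_covariates(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.normal(size=(20, 12)), ["case"] * 6 + ["control"] * 6)
        cov = pd.DataFrame(rng.normal(size=(12, 3)), index=ds.sample_ids,
                           columns=list("abc"))
        out = ec.adjust_covariates(ds, cov).values.to_numpy()
        centered = cov.to_numpy() - cov.to_numpy().mean(axis=0)
        resid = out - out.mean(axis=1, keepdims=True)
        assert np.abs(resid @ centered).max() < 1e-8


class TestZScore:
    def test_rows_standardized(self):
        ds = make_dataset([[1.0, 2.0, 3.0, 4.0]], ["case"] * 2 + ["control"] * 2)
        out, _ = ec.zscore_normalize(ds)
        row = out.values.to_numpy()[0]
        assert row.mean() == pytest.approx(0.0, abs=1e-12)
        assert row.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_three_point_row(self):
        ann = make_annotation(1)
        ds = make_dataset([[1.0, 2.0, 3.0]], ["case", "case", "control"],
                          annotation=ann)
        out, _ = ec.zscore_normalize(ds)
        assert np.allclose(out.values.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_constant_rows_dropped_with_report(self):
        ds = make_dataset([[1, 1, 1, 1], [1, 2, 3, 4]],
                          ["case"] * 2 + ["control"] * 2)
        out, report = ec.zscore_normalize(ds)
        assert report == {"constant_dropped": 1, "retained": 1}
        assert len(out.probe_ids) == 1

    def test_all_rows_recentred_exactly(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(size=(50, 9)), ["case"] * 4 + ["control"] * 5)
        out, _ = ec.zscore_normalize(ds)
        arr = out.values.to_numpy()
        assert np.abs(arr.mean(axis=1)).max() < 1e-8
        assert np.abs(arr.std(axis=1, ddof=1) - 1).max() < 1e-8

    def test_all_constant_errors(self):
        ds = make_dataset(np.ones((3, 4)), ["case"] * 2 + ["control"] * 2)
        with pytest.raises(ValueError, match="constant"):
            ec.zscore_normalize(ds)
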