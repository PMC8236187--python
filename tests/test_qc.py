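"""Detection-p filtering, blacklist exclusion, normalization and splitting."""

import numpy as np
import pandas as pd
import pytest

import devclock as dc
from devclock.datamodel import ValidationError, matrix_container
from devclock.qc import quantile_normalize_columns


def detp(values):
    p, n = np.asarray(values).shape
    return matrix_container(
        [f"cg{i}" for i in range(p)], [f"s{j}" for j in range(n)], values
    )


class TestPfilter:
    def test_sample_with_two_percent_failures_excluded(self):
        P = np.full((100, 3), 0.001)
        P[:2, 0] = 0.2  # 2% of probes fail in sample 0
        samples, probes, report = dc.pfilter(detp(P))
        assert samples == ["s1", "s2"]
        assert len(probes) == 100
        assert report.samples_excluded[0][0] == "s0"

    def test_exactly_one_percent_retained_strict_inequality(self):
        P = np.full((100, 3), 0.001)
        P[0, 0] = 0.2  # exactly 1%, not > 1%
        samples, probes, _ = dc.pfilter(detp(P))
        assert samples == ["s0", "s1", "s2"]

    def test_clean_matrix_removes_nothing(self):
        P = np.full((50, 200), 0.001)
        samples, probes, report = dc.pfilter(detp(P))
        assert len(samples) == 200 and len(probes) == 50
        assert not report.samples_excluded and not report.probes_excluded
        assert report.n_samples_after == 200

    def test_probe_pass_uses_retained_samples(self):
        # probe 0 fails only in the to-be-removed sample: it must survive
        P = np.full((100, 40), 0.001)
        P[:3, 0] = 0.2  # sample 0 removed (3% failures)
        samples, probes, _ = dc.pfilter(detp(P))
        assert "s0" not in samples
        assert "cg0" in probes

    def test_probe_exceeding_threshold_removed(self):
        # each failing sample has exactly 1% failing probes (retained, strict >),
        # while probe 0 fails in 2% of samples (removed)
        P = np.full((100, 100), 0.001)
        P[0, :2] = 0.9
        samples, probes, report = dc.pfilter(detp(P))
        assert "cg0" not in probes
        assert len(samples) == 100

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(0, 0.01, size=(200, 50))
        P[rng.uniform(size=P.shape) < 0.005] = 0.5
        m = detp(P)
        samples, probes, _ = dc.pfilter(m)
        sub = m.subset_probes(probes).subset_samples(samples)
        samples2, probes2, report2 = dc.pfilter(sub)
        assert samples2 == samples and probes2 == probes
        assert not report2.samples_excluded and not report2.probes_excluded

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            dc.pfilter(detp(np.empty((0, 0))))

    def test_all_samples_removed_is_error_with_report(self):
        P = np.full((10, 3), 0.9)
        with pytest.raises(ValidationError, match="all samples"):
            dc.pfilter(detp(P))


class TestBlacklist:
    @pytest.fixture()
    def annot(self):
        return dc.ProbeAnnotation(
            pd.DataFrame(
                {
                    "design_type": ["II"] * 5,
                    "snp_affected": [True, False, False, False, False],
                    "cross_hybridizing": [False, True, False, False, False],
                },
                index=pd.Index([f"cg{i}" for i in range(5)], name="probe_id"),
            )
        )

    def test_flagged_probes_removed_with_reasons(self, annot):
        retained, report = dc.exclude_blacklisted([f"cg{i}" for i in range(5)], annot)
        assert retained == ["cg2", "cg3", "cg4"]
        reasons = dict(report.probes_excluded)
        assert reasons == {"cg0": "snp_affected", "cg1": "cross_hybridizing"}

    def test_no_flags_is_identity(self, annot):
        retained, report = dc.exclude_blacklisted(["cg2", "cg3"], annot)
        assert retained == ["cg2", "cg3"]
        assert not report.probes_excluded

    def test_unannotated_probe_retained_with_warning(self, annot):
        with pytest.warns(UserWarning, match="absent from annotation"):
            retained, report = dc.exclude_blacklisted(["cg2", "cgNOVEL"], annot)
        assert retained == ["cg2", "cgNOVEL"]
        assert report.warnings


class TestQuantileNormalization:
    def test_two_sample_example(self):
        X = np.array([[0.1, 0.2], [0.5, 0.6], [0.9, 0.8]])
        out = quantile_normalize_columns(X)
        np.testing.assert_allclose(out[:, 0], [0.15, 0.55, 0.85])
        np.testing.assert_allclose(out[:, 1], [0.15, 0.55, 0.85])

    def test_identical_columns_unchanged(self):
        col = np.array([0.2, 0.5, 0.7, 0.1])
        X = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize_columns(X), X, atol=1e-15)

    def test_multiset_identical_across_samples(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(100, 7))
        out = quantile_normalize_columns(X)
        ref = np.sort(out[:, 0])
        for j in range(1, 7):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_rank_order_preserved_within_column(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 4))
        out = quantile_normalize_columns(X)
        for j in range(4):
            assert (np.argsort(X[:, j]) == np.argsort(out[:, j])).all()


class TestDasen:
    def _annot(self, design):
        return dc.ProbeAnnotation(
            pd.DataFrame(
                {"design_type": design},
                index=pd.Index([f"cg{i}" for i in range(len(design))], name="probe_id"),
            )
        )

    def test_identical_samples_stay_identical(self):
        rng = np.random.default_rng(1)
        p = 60
        M = rng.uniform(500, 5000, size=(p, 1)).repeat(3, axis=1)
        U = rng.uniform(500, 5000, size=(p, 1)).repeat(3, axis=1)
        intens = dc.IntensitySet(
            [f"cg{i}" for i in range(p)], ["a", "b", "c"], M, U, np.zeros((p, 3))
        )
        out = dc.dasen_normalize(intens, self._annot(["I"] * 30 + ["II"] * 30))
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], atol=1e-12)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 2], atol=1e-12)

    def test_single_probe_type_reduces_to_plain_qn(self):
        rng = np.random.default_rng(2)
        p = 40
        M = rng.uniform(100, 9000, size=(p, 4))
        U = rng.uniform(100, 9000, size=(p, 4))
        intens = dc.IntensitySet(
            [f"cg{i}" for i in range(p)], list("abcd"), M, U, np.zeros((p, 4))
        )
        out = dc.dasen_normalize(intens, self._annot(["II"] * p), beta_offset=100)
        Mq, Uq = quantile_normalize_columns(M), quantile_normalize_columns(U)
        np.testing.assert_allclose(out.values, Mq / (Mq + Uq + 100), atol=1e-12)

    def test_beta_arithmetic(self):
        # M=900, U=0, offset 100 -> 0.9
        assert 900 / (900 + 0 + 100) == 0.9

    def test_betas_in_unit_interval(self, sim_dataset):
        _, intens, _, _, annot = sim_dataset
        out = dc.dasen_normalize(intens, annot)
        assert np.nanmin(out.values) >= 0 and np.nanmax(out.values) <= 1

    def test_unknown_design_type_is_error(self):
        intens = dc.IntensitySet(
            ["cgA", "cgB"], ["a", "b"], np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2))
        )
        annot = self._annot(["II"])  # covers only cg0, not cgA/cgB
        with pytest.raises(ValidationError, match="design type"):
            dc.dasen_normalize(intens, annot)


class TestIntersectProbes:
    def _mat(self, probes, n=2, fill=0.5):
        return dc.BetaMatrix(
            probes, [f"s{i}" for i in range(n)], np.full((len(probes), n), fill)
        )

    def test_basic_intersection_in_first_matrix_order(self):
        a = self._mat(["A", "B", "C"])
        b = dc.BetaMatrix(["B", "C", "D"], ["t0", "t1"], np.full((3, 2), 0.5))
        common, (sa, sb) = dc.intersect_probes([a, b])
        assert common == ["B", "C"]
        assert sa.probe_ids == sb.probe_ids == ["B", "C"]

    def test_single_matrix_keeps_fully_observed(self):
        vals = np.array([[0.1, 0.2], [np.nan, 0.4], [0.5, 0.6]])
        m = dc.BetaMatrix(["A", "B", "C"], ["s0", "s1"], vals)
        common, _ = dc.intersect_probes([m])
        assert common == ["A", "C"]

    def test_disjoint_sets_error(self):
        with pytest.raises(ValidationError, match="empty"):
            dc.intersect_probes([self._mat(["A"]), self._mat(["B"])])

    def test_order_invariance_up_to_row_ordering(self):
        a = self._mat(["A", "B", "C"])
        b = self._mat(["C", "B"])
        c1, _ = dc.intersect_probes([a, b])
        c2, _ = dc.intersect_probes([b, a])
        assert set(c1) == set(c2)


class TestStratifiedSplit:
    def _sheet(self, sizes):
        rows = []
        for ds, n in sizes.items():
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{ds}_{i}",
                        "age_value": 100.0,
                        "age_unit": "dpc",
                        "sex": "female",
                        "dataset_id": ds,
                        "group": "g",
                    }
                )
        return dc.SampleSheet(pd.DataFrame(rows))

    def test_four_samples_three_train(self):
        split = dc.stratified_split(self._sheet({"d": 4}), 0.75, seed=1)
        assert len(split.train_ids) == 3 and len(split.test_ids) == 1

    def test_sixty_forty_strata(self):
        split = dc.stratified_split(self._sheet({"a": 60, "b": 40}), 0.75, seed=1)
        frame = split.to_frame()
        counts = frame.groupby("dataset_id")["split"].value_counts()
        assert counts[("a", "train")] == 45 and counts[("a", "test")] == 15
        assert counts[("b", "train")] == 30 and counts[("b", "test")] == 10

    def test_determinism_and_seed_sensitivity(self):
        sheet = self._sheet({"a": 20, "b": 12})
        s1 = dc.stratified_split(sheet, seed=42)
        s2 = dc.stratified_split(sheet, seed=42)
        s3 = dc.stratified_split(sheet, seed=43)
        assert s1.assignment == s2.assignment
        assert s1.assignment != s3.assignment

    def test_singleton_stratum_goes_to_train_with_warning(self):
        with pytest.warns(UserWarning, match="single sample"):
            split = dc.stratified_split(self._sheet({"a": 4, "solo": 1}), seed=0)
        assert split.assignment["solo_0"] == "train"

    def test_round_half_up(self):
        # n=2, fraction 0.75 -> 1.5 -> 2 train
        split = dc.stratified_split(self._sheet({"a": 2}), 0.75, seed=0)
        assert len(split.train_ids) == 2
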