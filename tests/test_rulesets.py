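"""Rule-set model fitting, best-subsets selection, prediction and overlap."""

import numpy as np
import pytest

from seasonniche import (
    EnvMatrix,
    GridSpec,
    NicheEnsemble,
    OccurrenceRecord,
    OccurrenceSet,
    Rule,
    RuleSetModel,
    SuitabilityMap,
    fit_rule_model,
    geographic_overlap,
    predict,
    select_best_subset,
    split_calibration,
)
import pandas as pd

COLS = ("tmax", "tmin", "prec")


def _env(values):
    values = np.atleast_2d(values)
    return EnvMatrix(values, COLS[: values.shape[1]], list(range(values.shape[0])))


class TestSplitCalibration:
    def _occ(self, n):
        return OccurrenceSet(
            [OccurrenceRecord(str(i), float(i % 50), float(i // 50), 5) for i in range(n)]
        )

    def test_eighty_twenty(self):
        train, test = split_calibration(self._occ(100), 0.8, seed=0)
        assert (len(train), len(test)) == (80, 20)

    def test_minimum_size_rounding(self):
        train, test = split_calibration(self._occ(5), 0.8, seed=0)
        assert (len(train), len(test)) == (4, 1)

    def test_partition_disjoint_and_complete(self):
        occ = self._occ(37)
        train, test = split_calibration(occ, 0.8, seed=3)
        ids = {r.id for r in train.records} | {r.id for r in test.records}
        assert len(ids) == 37
        assert not ({r.id for r in train.records} & {r.id for r in test.records})

    def test_deterministic(self):
        occ = self._occ(50)
        a = split_calibration(occ, 0.8, seed=9)
        b = split_calibration(occ, 0.8, seed=9)
        assert [r.id for r in a[0].records] == [r.id for r in b[0].records]

    def test_too_few_records_errors(self):
        with pytest.raises(ValueError):
            split_calibration(self._occ(4), 0.8, seed=0)


class TestRule:
    def test_range_rule_matches_box(self):
        rule = Rule("range", 1, low=[0, 0, 0], high=[1, 1, 1])
        X = np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5]])
        np.testing.assert_array_equal(rule.matches(X), [True, False])

    def test_negated_range_is_complement(self):
        box = Rule("range", 1, low=[0, 0, 0], high=[1, 1, 1])
        neg = Rule("negated_range", 0, low=[0, 0, 0], high=[1, 1, 1])
        X = np.random.default_rng(0).uniform(-1, 2, size=(50, 3))
        np.testing.assert_array_equal(neg.matches(X), ~box.matches(X))

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Rule("range", 1, low=[1.0], high=[0.0])

    def test_serialization_roundtrip(self):
        rules = [
            Rule("range", 1, low=[0, -np.inf, 2], high=[1, np.inf, 3], fitness=2.5),
            Rule("logit", 1, coef=[0.1, -0.2, 0.3], intercept=-1.0, fitness=1.0),
        ]
        model = RuleSetModel(rules, omission=0.05, commission=0.2, seed=7, columns=COLS)
        again = RuleSetModel.from_dict(model.to_dict())
        X = np.random.default_rng(1).normal(size=(100, 3))
        np.testing.assert_array_equal(model.predict(X), again.predict(X))


class TestFitRuleModel:
    def _box_data(self, rng, n_pres=100, n_bg=2000):
        """Presence uniform in a climatic box, background uniform and much
        wider."""
        lo = np.array([10.0, 0.0, 50.0])
        hi = np.array([20.0, 8.0, 90.0])
        pres = rng.uniform(lo, hi, size=(n_pres, 3))
        bg = rng.uniform(lo - 30, hi + 30, size=(n_bg, 3))
        return _env(pres), _env(bg), lo, hi

    def test_box_niche_low_omission(self, rng):
        pres, bg, lo, hi = self._box_data(rng)
        model = fit_rule_model(pres, bg, seed=4)
        assert model.omission <= 0.10
        # and it should not predict presence everywhere
        assert model.commission < 0.5

    def test_deterministic_under_seed(self, rng):
        pres, bg, _, _ = self._box_data(rng)
        a = fit_rule_model(pres, bg, seed=11)
        b = fit_rule_model(pres, bg, seed=11)
        assert a.to_dict() == b.to_dict()

    def test_constant_variable_dropped_with_warning(self, rng):
        pres, bg, _, _ = self._box_data(rng)
        pres.values[:, 1] = 5.0
        bg.values[:, 1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_rule_model(pres, bg, seed=0)
        assert model.columns == ("tmax", "prec")

    def test_too_few_presence_errors(self, rng):
        pres, bg, _, _ = self._box_data(rng, n_pres=4)
        with pytest.raises(ValueError, match="at least 5"):
            fit_rule_model(pres, bg, seed=0)


class TestSelectBestSubset:
    def _replicates(self, omissions, commission_fracs, region):
        """Models with exact, known omission and commission: a single range
        rule covering the first fraction of the unit interval."""
        reps = []
        for om, cf in zip(omissions, commission_fracs):
            rule = Rule("range", 1, low=[0.0, -np.inf, -np.inf],
                        high=[cf, np.inf, np.inf])
            model = RuleSetModel([rule], omission=om, commission=cf, seed=0,
                                 columns=COLS)
            reps.append(model)
        return reps

    def test_known_commissions_vs_exhaustive_oracle(self):
        """k members are exactly the ones with commission nearest the
        survivors' median, verified against a brute-force sort."""
        region = _env(np.column_stack([
            np.linspace(0, 1, 101, endpoint=False) + 0.005,
            np.zeros(101), np.zeros(101)]))
        omissions = [0.05] * 10
        commissions = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        reps = self._replicates(omissions, commissions, region)
        ens = select_best_subset(reps, region, omission_max=0.10, k=4)
        got = sorted(m.rules[0].high[0] for m in ens.members)
        med = float(np.median(commissions))
        oracle = sorted(sorted(commissions, key=lambda c: abs(c - med))[:4])
        assert got == pytest.approx(oracle)

    def test_omission_filter_enforced(self):
        region = _env(np.column_stack([
            np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)]))
        omissions = [0.05, 0.5, 0.02, 0.2, 0.08, 0.01, 0.3, 0.09, 0.04, 0.06]
        commissions = np.linspace(0.1, 1.0, 10).tolist()
        reps = self._replicates(omissions, commissions, region)
        ens = select_best_subset(reps, region, omission_max=0.10, k=5)
        assert all(m.omission <= 0.10 for m in ens.members)
        assert ens.k == 5

    def test_too_few_survivors_errors(self):
        region = _env(np.column_stack([
            np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)]))
        reps = self._replicates([0.5] * 10, np.linspace(0.1, 1.0, 10), region)
        with pytest.raises(ValueError, match="passed the omission filter"):
            select_best_subset(reps, region, omission_max=0.10, k=5)

    def test_identical_replicates_all_at_median(self):
        region = _env(np.column_stack([
            np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)]))
        reps = self._replicates([0.0] * 12, [0.5] * 12, region)
        ens = select_best_subset(reps, region, omission_max=0.10, k=10)
        assert ens.k == 10
        med = ens.selection_log["commission"].median()
        assert all(np.isclose(c, med) for c in
                   ens.selection_log.loc[ens.selection_log.selected, "commission"])


def _degenerate_ensemble(k=10, predicted=1):
    """Ensemble whose every member predicts one class everywhere."""
    rule = Rule("range", predicted,
                low=[-np.inf] * 3, high=[np.inf] * 3, fitness=1.0)
    members = [RuleSetModel([rule], 0.0, 1.0, i, COLS) for i in range(k)]
    return NicheEnsemble(members, pd.DataFrame(), COLS)


class TestPredict:
    def test_all_presence_ensemble_full_agreement(self, small_stack):
        ens = _degenerate_ensemble()
        smap = predict(ens, small_stack, "winter")
        assert np.nanmax(smap.agreement) == 10
        assert np.nanmin(smap.agreement) == 10
        assert smap.binary.all()

    def test_repeated_calls_identical(self, small_stack):
        ens = _degenerate_ensemble()
        a = predict(ens, small_stack, [5, 6])
        b = predict(ens, small_stack, [5, 6])
        np.testing.assert_array_equal(a.agreement, b.agreement)

    def test_nodata_propagates(self):
        from seasonniche import ClimateStack, Layer

        grid = GridSpec(2, 2, 0.0, 2.0, 1.0)
        layers = []
        for var in ("tmax", "tmin", "prec"):
            vals = np.ones((2, 2))
            vals[0, 0] = grid.nodata
            layers.append(Layer(grid, var, 1, vals))
        stack = ClimateStack(layers)
        smap = predict(_degenerate_ensemble(), stack, 1)
        assert np.isnan(smap.agreement[0, 0])
        assert not smap.binary[0, 0]

    def test_ensemble_json_roundtrip(self, small_stack, tmp_path):
        ens = _degenerate_ensemble()
        path = tmp_path / "e.json"
        ens.save(path)
        again = NicheEnsemble.load(path)
        a = predict(ens, small_stack, 1)
        b = predict(again, small_stack, 1)
        np.testing.assert_array_equal(a.agreement, b.agreement)


class TestGeographicOverlap:
    def _map(self, binary, k=10):
        grid = GridSpec(*binary.shape, 0.0, float(binary.shape[0]), 1.0)
        agreement = np.where(binary, float(k), 0.0)
        return SuitabilityMap(grid, agreement, k, consensus=k)

    def test_identical_maps_100(self):
        b = np.zeros((5, 5), dtype=bool)
        b[1:3, 1:4] = True
        ov = geographic_overlap(self._map(b), self._map(b))
        assert ov["a_to_b"] == 100.0 and ov["b_to_a"] == 100.0

    def test_disjoint_maps_0(self):
        a = np.zeros((5, 5), dtype=bool); a[0, :] = True
        b = np.zeros((5, 5), dtype=bool); b[4, :] = True
        ov = geographic_overlap(self._map(a), self._map(b))
        assert ov["a_to_b"] == 0.0 and ov["b_to_a"] == 0.0

    def test_partial_overlap_arithmetic(self):
        a = np.zeros((5, 5), dtype=bool); a.ravel()[:10] = True
        b = np.zeros((5, 5), dtype=bool); b.ravel()[6:10] = True
        ov = geographic_overlap(self._map(a), self._map(b))
        assert ov["a_to_b"] == pytest.approx(40.0)
        assert ov["b_to_a"] == pytest.approx(100.0)

    def test_empty_source_reports_na(self):
        a = np.zeros((3, 3), dtype=bool)
        b = np.ones((3, 3), dtype=bool)
        ov = geographic_overlap(self._map(a), self._map(b))
        assert ov["a_to_b"] is None
        assert ov["b_to_a"] == 0.0

    def test_mismatched_grids_error(self):
        a = self._map(np.ones((3, 3), dtype=bool))
        b = self._map(np.ones((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="share one grid"):
            geographic_overlap(a, b)
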