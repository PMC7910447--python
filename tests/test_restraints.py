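import numpy as np
import pytest

from accref.estogram import BinSpec
from accref.metrics import pairwise_cb_distances
from accref.oracle import oracle_predict
from accref.restraints import (AGGRESSIVE_THRESHOLDS, DEFAULT_THRESHOLDS,
                               ConfidenceThresholds, PairClass,
                               RestraintParams, RestraintSet, bounded_potential,
                               build_restraints, classify_pairs,
                               contact_potential, ema_pair_weights,
                               estogram_spline_potential, read_cst,
                               recompute_background, sigmoid_potential,
                               write_cst)

P11 = RestraintParams(s=1.0, tol=1.0, w_fa=1.0)


class TestBoundedPotential:
    def test_flat_within_tolerance(self):
        assert bounded_potential(10.0, 10.0, P11) == 0.0
        assert bounded_potential(10.9, 10.0, P11) == 0.0

    def test_quadratic_edge_value(self):
        # d = d0 + tol + s sits at the end of the quadratic region: ((s)/s)^2
        assert bounded_potential(12.0, 10.0, P11) == pytest.approx(1.0)

    def test_linear_branch(self):
        # d = d0 + tol + 2s: (d - (d0+tol+s))/s + 1 = 2
        assert bounded_potential(13.0, 10.0, P11) == pytest.approx(2.0)
        assert bounded_potential(7.0, 10.0, P11) == pytest.approx(2.0)

    def test_monotone_beyond_tolerance(self):
        d = np.linspace(11.0, 30.0, 200)
        e = bounded_potential(d, 10.0, P11)
        assert np.all(np.diff(e) >= 0)


class TestSigmoidPotential:
    def test_limits_equal_w_fa(self):
        p = RestraintParams(s=1.0, tol=1.0, w_fa=0.7)
        assert sigmoid_potential(1e6, 10.0, p) == pytest.approx(0.7, abs=1e-9)
        assert sigmoid_potential(0.0, 1e6, p) == pytest.approx(0.7, abs=1e-3)

    def test_value_at_center(self):
        expected = 1 - 1 / (1 + np.exp(-5)) + 1 / (1 + np.exp(5))
        assert sigmoid_potential(10.0, 10.0, P11) == pytest.approx(expected)
        assert expected == pytest.approx(0.01338, abs=1e-5)

    def test_symmetric_about_d0(self):
        x = np.linspace(0.1, 9.9, 50)
        np.testing.assert_allclose(sigmoid_potential(10.0 + x, 10.0, P11),
                                   sigmoid_potential(10.0 - x, 10.0, P11))


class TestContactPotential:
    @pytest.mark.parametrize("d,expected", [
        (7.0, 0.0), (8.5, 0.25), (10.0, 2.0), (9.0, 1.0),
    ])
    def test_hand_values(self, d, expected):
        assert contact_potential(d) == pytest.approx(expected)


@pytest.mark.parametrize("potential,args", [
    (bounded_potential, (10.0, P11)),
    (sigmoid_potential, (10.0, P11)),
    (contact_potential, ()),
])
def test_potentials_continuous_at_region_boundaries(potential, args):
    """All analytic forms are continuous at every piecewise boundary."""
    boundaries = [8.0, 9.0, 10.0, 11.0, 12.0]
    for b in boundaries:
        lo = potential(b - 1e-4, *args)
        hi = potential(b + 1e-4, *args)
        assert abs(float(hi) - float(lo)) < 1e-3
        # tighter check right at the boundary
        assert abs(float(potential(b, *args)) -
                   float(potential(b - 1e-7, *args))) < 1e-6


class TestSplinePotential:
    def setup_method(self):
        self.bins = BinSpec()

    def _one_hot(self, category):
        p = np.zeros(15)
        p[category] = 1.0
        return p

    def test_one_hot_central_minimum_at_d0(self):
        pot = estogram_spline_potential(self._one_hot(7), 12.0,
                                        self.bins.centers)
        assert pot.argmin() == pytest.approx(12.0, abs=1.0)

    def test_uniform_with_uniform_background_is_flat_zero(self):
        pot = estogram_spline_potential(np.full(15, 1 / 15), 12.0,
                                        self.bins.centers)
        d = np.linspace(pot.x[0], pot.x[-1], 100)
        np.testing.assert_allclose(pot(d), 0.0, atol=1e-9)

    def test_shifted_mass_moves_minimum(self):
        # mass in the [2, 4) bin (center 3): minimum near d0 - 3
        pot = estogram_spline_potential(self._one_hot(10), 12.0,
                                        self.bins.centers)
        assert pot.argmin() == pytest.approx(9.0, abs=1.0)

    def test_not_applicable_beyond_40(self):
        with pytest.raises(ValueError):
            estogram_spline_potential(self._one_hot(7), 45.0, self.bins.centers)

    def test_minimum_tracks_native_distance_under_exact_oracle(
            self, native30, decoys30):
        """For nonpreserving pairs of a real decoy, the spline minimum lies
        within one bin width of the native distance (interior error bins)."""
        decoy = decoys30[3][0]
        pred = oracle_predict(decoy, native30)
        d_model = pairwise_cb_distances(decoy)
        d_native = pairwise_cb_distances(native30)
        bins = pred.estogram.bin_spec
        widths = np.diff(np.concatenate(([-np.inf], bins.boundaries, [np.inf])))
        checked = 0
        for i in range(30):
            for j in range(i + 1, 30):
                e = d_model[i, j] - d_native[i, j]
                cat = int(np.argmax(pred.estogram.probs[i, j]))
                if cat in (0, 14) or abs(e) <= 1.0 or d_model[i, j] >= 40:
                    continue
                pot = estogram_spline_potential(pred.estogram.probs[i, j],
                                                d_model[i, j], bins.centers)
                assert abs(pot.argmin() - d_native[i, j]) <= widths[cat] + 0.1
                checked += 1
        assert checked > 20


class TestClassification:
    def _pred(self, native30, decoys30):
        return oracle_predict(decoys30[2][0], native30)

    def test_thresholds(self):
        assert DEFAULT_THRESHOLDS.p_high == 0.8
        assert DEFAULT_THRESHOLDS.p_moderate == 0.7
        assert AGGRESSIVE_THRESHOLDS.w_fa == 0.2
        assert AGGRESSIVE_THRESHOLDS.p_high == 0.9
        with pytest.raises(ValueError):
            ConfidenceThresholds(p_high=0.5, p_moderate=0.8)

    def test_class_rules_on_synthetic_pcen(self, native30):
        pred = oracle_predict(native30, native30)
        n = pred.n
        d0 = np.full((n, n), 12.0)
        classes = classify_pairs(pred, d0)
        off = ~np.eye(n, dtype=bool)
        assert np.all(classes[off] == PairClass.HIGH)  # P_cen = 1
        far = np.full((n, n), 25.0)
        classes = classify_pairs(pred, far)
        assert np.all(classes[off] == PairClass.NONPRESERVING)
        excluded = np.full((n, n), 45.0)
        classes = classify_pairs(pred, excluded)
        assert np.all(classes[off] == PairClass.EXCLUDED)


class TestBuildRestraints:
    def test_default_vs_aggressive_wfa(self, native30, decoys30):
        decoy = decoys30[2][0]
        pred = oracle_predict(decoy, native30)
        rs_def = build_restraints(pred, decoy, stage="fullatom")
        rs_agg = build_restraints(pred, decoy, stage="fullatom",
                                  mode="aggressive")
        w_def = {r.params.w_fa for r in rs_def.entries if r.form == "sigmoid"}
        w_agg = {r.params.w_fa for r in rs_agg.entries if r.form == "sigmoid"}
        assert w_def == {1.0}
        assert w_agg == {0.2}

    def test_stage_selects_functional_form(self, native30, decoys30):
        decoy = decoys30[2][0]
        pred = oracle_predict(decoy, native30)
        forms_coarse = {r.form for r in
                        build_restraints(pred, decoy, stage="coarse").entries}
        forms_fa = {r.form for r in
                    build_restraints(pred, decoy, stage="fullatom").entries}
        assert "bounded" in forms_coarse and "sigmoid" not in forms_coarse
        assert "sigmoid" in forms_fa and "bounded" not in forms_fa

    def test_iterative_stage_uses_contact_form(self, native30, decoys30):
        decoy = decoys30[3][0]
        pred = oracle_predict(decoy, native30)
        rs = build_restraints(pred, decoy, iterative=True)
        forms = {r.form for r in rs.entries}
        assert "spline" not in forms
        assert "contact" in forms


class TestEmaWeights:
    def test_closed_form_value(self):
        w = ema_pair_weights(np.array([0.7, 0.7, 0.7]), lam=1.4)
        # P_i = e^-2; after percentile normalization entries cap at 1
        assert np.exp(-1.4 / 0.7) == pytest.approx(0.1353, abs=1e-4)
        assert np.all(w[~np.eye(3, dtype=bool)] == 1.0)

    def test_high_scores_saturate(self):
        scores = np.array([1e6, 1e6, 0.5])
        w = ema_pair_weights(scores, lam=1.4)
        assert w[0, 1] == 1.0
        assert w[0, 2] < w[0, 1]

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        w = ema_pair_weights(rng.uniform(0.3, 0.9, 8))
        np.testing.assert_allclose(w, w.T)
        assert np.all(np.diag(w) == 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ema_pair_weights(np.array([0.5, 0.0]))


def test_cst_round_trip(tmp_path, native30, decoys30):
    decoy = decoys30[2][0]
    pred = oracle_predict(decoy, native30)
    rs = build_restraints(pred, decoy, stage="coarse")
    path = str(tmp_path / "out.cst")
    write_cst(rs, path)
    back = read_cst(path)
    assert len(back) == len(rs)
    d_test = np.linspace(2.0, 30.0, 40)
    for a, b in zip(rs.entries, back.entries):
        assert (a.i, a.j, a.form) == (b.i, b.j, b.form)
        np.testing.assert_allclose(b.energy(d_test), a.energy(d_test),
                                   atol=5e-3)


def test_background_table_recompute(native30, decoys30):
    preds = [oracle_predict(d, native30) for d, _ in decoys30[:3]]
    models = [d for d, _ in decoys30[:3]]
    table = recompute_background(preds, models)
    assert table
    for vec in table.values():
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(vec >= 0)
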