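import numpy as np
import pytest

from accref.estogram import AccuracyPrediction, Estogram
from accref.metrics import smooth_profile
from accref.oracle import make_oracle_predictor, oracle_predict
from accref.refinement import (DEMO_POOL_CONFIG, PoolConfig, PoolMember,
                               RegionParams, complementarity,
                               dynamic_fraction, final_select, recombine,
                               run_demo_refinement, schedule_iteration,
                               select_unreliable, toy_sampler)
from accref.restraints import RestraintSet, build_restraints
from accref.structures import ca_rmsd
from accref.synthetic import make_decoys


def prediction_with_profile(profile: np.ndarray) -> AccuracyPrediction:
    """Synthetic prediction whose corrected l-DDT equals ``profile``.

    Long-range one-hot estograms: the central bin with probability equal to
    engineering the profile directly is complex, so instead build a mask of
    long-range contacts and put each residue's pairs at the central bin with
    the desired fraction.
    """
    n = len(profile)
    probs = np.zeros((n, n, 15))
    probs[:, :, 7] = 1.0
    mask = np.zeros((n, n))
    seqsep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    long_range = seqsep > 11
    # pair (i, j) preserved with probability = mean of the two targets:
    # use soft estograms so per-residue means land on the requested profile
    for i in range(n):
        for j in range(n):
            if i == j or not long_range[i, j]:
                continue
            mask[i, j] = 1.0
            p = (profile[i] + profile[j]) / 2.0
            probs[i, j, 7] = p
            probs[i, j, 14] = 1.0 - p
    return AccuracyPrediction.from_estogram_mask(Estogram(probs), mask)


class TestSelectUnreliable:
    def test_static_fraction_within_range(self):
        rng = np.random.default_rng(0)
        pred = prediction_with_profile(rng.uniform(0.3, 0.9, 100))
        sel = select_unreliable(pred, RegionParams("static"))
        assert sel.sum() == 15
        assert 0.10 <= sel.mean() <= 0.20

    def test_selects_lowest_scoring(self):
        profile = np.linspace(0.2, 0.9, 40)
        pred = prediction_with_profile(profile)
        sel = select_unreliable(pred, RegionParams("static"))
        # smoothing preserves the monotone ordering: lowest indices selected
        assert np.all(np.flatnonzero(sel) == np.arange(6))

    def test_dynamic_high_accuracy_caps_at_20(self):
        pred = prediction_with_profile(np.full(100, 0.9))
        sel = select_unreliable(pred, RegionParams("dynamic"))
        assert sel.sum() == 25  # f_dyn capped at 20, +5 midpoint

    def test_tie_break_lower_index(self):
        pred = prediction_with_profile(np.full(40, 0.5))
        sel = select_unreliable(pred, RegionParams("static"))
        assert np.all(np.flatnonzero(sel) == np.arange(6))

    def test_too_short_rejected(self):
        pred = prediction_with_profile(np.full(5, 0.5))
        with pytest.raises(ValueError):
            select_unreliable(pred)


class TestDynamicFraction:
    def test_cap_behavior(self):
        assert dynamic_fraction(0.9) == 20.0   # formula below cap
        assert dynamic_fraction(0.55) == pytest.approx(20.0)
        assert dynamic_fraction(0.0) == pytest.approx(20.0 + 20 * 0.55 / 30)
        # percent-scale Q drives the formula into the cap at 40
        assert dynamic_fraction(0.05, q_scale=100.0) == 20.0
        assert dynamic_fraction(-50.0, q_scale=1.0) == 40.0


class TestToySampler:
    def test_noop_without_restraints_or_noise(self, native30):
        out = toy_sampler(native30, RestraintSet(), sigma_rest=0.0, seed=1)
        np.testing.assert_allclose(out.ca_coords(), native30.ca_coords(),
                                   atol=1e-9)

    def test_energy_decreases(self, native30, decoys30):
        decoy = decoys30[3][0]
        pred = oracle_predict(decoy, native30)
        rs = build_restraints(pred, decoy)
        _, info = toy_sampler(decoy, rs, seed=2, steps=60, return_info=True)
        trace = info["energy_trace"]
        assert trace[-1] < trace[0]
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_seeded_reproducible(self, native30, decoys30):
        decoy = decoys30[2][0]
        pred = oracle_predict(decoy, native30)
        rs = build_restraints(pred, decoy)
        a = toy_sampler(decoy, rs, seed=3, steps=30)
        b = toy_sampler(decoy, rs, seed=3, steps=30)
        np.testing.assert_array_equal(a.ca_coords(), b.ca_coords())


def _fast_sampler(model, prediction, regions, seed):
    """Cheap stand-in sampler: small seeded perturbation of the regions."""
    rng = np.random.default_rng(seed)
    out = model.copy()
    for i in np.flatnonzero(regions):
        shift = rng.normal(scale=0.3, size=3)
        for k in out.residues[i].atoms:
            out.residues[i].atoms[k] = out.residues[i].atoms[k] + shift
    return out


class TestScheduleIteration:
    def test_counts_conserved(self, native30, helix_spec):
        config = PoolConfig()  # full-protocol counts: 50 / 10 / 12
        decoys = make_decoys(native30, config.pool_size, 20.0, seed=60,
                             spec=helix_spec)
        predictor = make_oracle_predictor(native30)
        pool = [PoolMember(m, predictor(m)) for m, _ in decoys]
        calls = []

        def counting_sampler(model, prediction, regions, seed):
            calls.append(seed)
            return _fast_sampler(model, prediction, regions, seed)

        new_pool = schedule_iteration(pool, config, counting_sampler,
                                      predictor, seed=1)
        assert len(calls) == 120
        assert len(new_pool) == 50

    def test_best_candidate_retained(self, native30, helix_spec):
        config = PoolConfig(pool_size=8, seeds_per_iter=2, children_per_seed=2)
        decoys = make_decoys(native30, 8, 25.0, seed=61, spec=helix_spec)
        predictor = make_oracle_predictor(native30)
        pool = [PoolMember(m, predictor(m)) for m, _ in decoys]
        new_pool = schedule_iteration(pool, config, _fast_sampler, predictor,
                                      seed=2)
        best_before = max(m.score for m in pool)
        assert max(m.score for m in new_pool) >= best_before


class TestRecombine:
    def test_hybrid_count_and_coverage(self, native30, helix_spec):
        config = PoolConfig()  # 50-member pool, 4 partners -> 200 hybrids
        decoys = make_decoys(native30, 50, 25.0, seed=62, spec=helix_spec)
        predictor = make_oracle_predictor(native30)
        pool = [PoolMember(m, predictor(m)) for m, _ in decoys]
        hybrids = recombine(pool, config)
        assert len(hybrids) == 200
        n = len(native30)
        for _, src_map, _ in hybrids:
            region = src_map.diagonal()
            assert 0.20 * n <= region.sum() <= 0.50 * n + 1

    def test_partner_ranking_by_complementarity(self):
        seed = np.full(30, 0.5)
        better = np.full(30, 0.6)
        worse = np.full(30, 0.4)
        assert complementarity(seed, better) > complementarity(seed, worse)
        assert complementarity(seed, worse) == 0.0

    def test_identical_pool_skips(self, native30):
        predictor = make_oracle_predictor(native30)
        pool = [PoolMember(native30.copy(), predictor(native30))
                for _ in range(6)]
        hybrids = recombine(pool, PoolConfig(pool_size=6, partners=2))
        assert hybrids == []


class TestFinalSelect:
    def test_unique_maximum_chosen(self, native30, helix_spec):
        decoys = make_decoys(native30, 6, 20.0, seed=63, spec=helix_spec)
        predictor = make_oracle_predictor(native30)
        members = [PoolMember(m, predictor(m)) for m, _ in decoys]
        best = max(members, key=lambda m: m.score)
        final, meta = final_select(members, members)
        # averaged model stays within the S > 0.8 neighborhood of the anchor
        assert meta["anchor_score"] == best.score

    def test_identical_members_average_to_member(self, native30):
        predictor = make_oracle_predictor(native30)
        members = [PoolMember(native30.copy(), predictor(native30))
                   for _ in range(4)]
        final, meta = final_select(members, members)
        assert meta["n_collected"] == 4
        np.testing.assert_allclose(final.ca_coords(), native30.ca_coords(),
                                   atol=1e-6)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            final_select([], [])


class TestDemoRefinement:
    def test_end_to_end_improves_or_preserves(self, helix_spec):
        from accref.synthetic import DecoySpec, make_native
        spec = DecoySpec(n_residues=40, seed=71)
        native = make_native(spec)
        decoy, info = make_decoys(native, 1, 25.0, seed=72, spec=spec)[0]
        report = run_demo_refinement(native, decoy, DEMO_POOL_CONFIG,
                                     seed=0, dual=False, sampler_steps=40)
        assert report["final_true_lddt"] >= report["start_true_lddt"] - 1e-9
        kinds = {row["iteration"]: row["kind"] for row in report["iterations"]}
        assert kinds[5] == "recombination"
        assert kinds[10] == "recombination"
        assert all(kinds[i] == "regular" for i in (1, 2, 3, 4, 6, 7, 8, 9))
        # under the exact oracle, predicted and true quality coincide
        pred = [r["predicted_global_lddt"] for r in report["iterations"]]
        true = [r["true_global_lddt"] for r in report["iterations"]]
        np.testing.assert_allclose(pred, true, atol=1e-9)
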