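"""The Bayesian engine: channel probabilities, iJ filtering, the full
pipeline and mix averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixjdp4 import (
    AssignmentConfig,
    ERROR_MODEL_PROFILES,
    TChannel,
    classification_report,
    combine_channels,
    dp4_channel,
    enumerate_diastereomers,
    ij_filter,
    karplus_dihedral_solutions,
    karplus_j,
    mix_jdp4,
    run_assignment,
    wi_correlation,
)
from mixjdp4.ensemble import BoltzmannWeights
from mixjdp4.fixtures import FixtureSpec, make_fixture
from mixjdp4.probability import AssignmentResult, ProbabilityError

from conftest import t_logpdf_oracle


CH = TChannel(mu=0.0, sigma=2.0, nu=10.0)


class TestEnumerateDiastereomers:
    def test_seven_centers_relative_configuration(self):
        cs = enumerate_diastereomers(7, fix_reference=True)
        assert len(cs) == 64

    def test_single_center(self):
        assert len(enumerate_diastereomers(1)) == 1

    def test_three_centers_absolute_all_distinct(self):
        cs = enumerate_diastereomers(3, fix_reference=False)
        assert len(cs) == 8
        assert len(set(cs.descriptors)) == 8

    def test_combinatorial_guard(self):
        with pytest.raises(ProbabilityError):
            enumerate_diastereomers(25)


class TestDP4Channel:
    def test_single_candidate_is_certain(self):
        p = dp4_channel([np.array([0.5, -0.2])], CH)
        assert p[0] == pytest.approx(1.0)

    def test_identical_errors_uniform(self):
        e = np.array([0.1, -0.3, 0.7])
        p = dp4_channel([e, e.copy()], CH)
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_three_sigma_case_matches_density_ratio_oracle(self):
        # errors (0,0,0) vs (3s,3s,3s): p1/p2 = [f(0)/f(3)]^3
        s = CH.sigma
        p = dp4_channel([np.zeros(3), np.full(3, 3 * s)], CH)
        lr = 3 * (t_logpdf_oracle(0.0, CH.nu) - t_logpdf_oracle(3.0, CH.nu))
        expected_p0 = 1.0 / (1.0 + math.exp(-lr))
        assert p[0] == pytest.approx(expected_p0, rel=1e-9)

    def test_no_underflow_for_200_signals_at_10_sigma(self):
        far = np.full(200, 10 * CH.sigma)
        p = dp4_channel([np.zeros(200), far], CH)
        assert np.all(np.isfinite(p))  # log-space: no NaN/inf blowup
        assert p[0] > 1.0 - 1e-12  # never collapses to an all-zero vector
        assert abs(p.sum() - 1.0) < 1e-9

    def test_error_order_irrelevant(self, rng):
        e1, e2 = rng.normal(0, 2, 50), rng.normal(1, 2, 50)
        p = dp4_channel([e1, e2], CH)
        p_shuf = dp4_channel([rng.permutation(e1), rng.permutation(e2)], CH)
        np.testing.assert_allclose(p, p_shuf, rtol=1e-9)

    def test_mismatched_signal_counts_rejected(self):
        with pytest.raises(ProbabilityError):
            dp4_channel([np.zeros(3), np.zeros(4)], CH)

    def test_nonfinite_errors_rejected(self):
        with pytest.raises(ProbabilityError):
            dp4_channel([np.array([np.nan]), np.array([0.0])], CH)


class TestCombineChannels:
    def test_uniform_channel_is_neutral(self):
        pa = np.array([0.7, 0.2, 0.1])
        u = np.full(3, 1 / 3)
        out = combine_channels({"H": pa, "C": u}, ["H", "C"])
        np.testing.assert_allclose(out, pa, atol=1e-12)

    def test_single_channel_identity(self):
        pa = np.array([0.9, 0.1])
        np.testing.assert_allclose(
            combine_channels({"H": pa}, ["H"]), pa, atol=1e-12
        )

    def test_hand_multiplied_three_candidates(self):
        ph = np.array([0.5, 0.3, 0.2])
        pc = np.array([0.1, 0.6, 0.3])
        raw = ph * pc
        expected = raw / raw.sum()
        out = combine_channels({"H": ph, "C": pc}, ["H", "C"])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_probability_entries_survive_in_log_space(self):
        ph = np.array([1.0, 0.0])
        pc = np.array([0.5, 0.5])
        out = combine_channels({"H": ph, "C": pc}, ["H", "C"])
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_empty_subset_rejected(self):
        with pytest.raises(ProbabilityError):
            combine_channels({"H": np.array([1.0])}, [])


class TestKarplus:
    def test_curve_extremes(self):
        # trans couplings large, perpendicular small
        assert karplus_j(180.0) > karplus_j(60.0)
        assert karplus_j(90.0) < karplus_j(0.0)

    def test_solutions_recover_known_angles(self):
        j = float(karplus_j(123.0))
        sols = karplus_dihedral_solutions(j)
        assert any(abs(s - 123.0) < 0.01 for s in sols)
        assert any(abs(s + 123.0) < 0.01 for s in sols)  # cosine symmetry

    def test_out_of_range_j_falls_back_to_nearest_approach(self):
        sols = karplus_dihedral_solutions(50.0)
        assert sols  # nearest approach, not empty
        assert all(abs(abs(s) - 180.0) < 1.0 for s in sols)


class TestIJFilter:
    @staticmethod
    def _mixed_ensemble():
        spec = FixtureSpec(seed=42, n_conformers=3, n_decoys=3, rotamer_jitter=2.0)
        fx = make_fixture(spec)
        return fx, fx.ensembles["cand1"]

    def test_trans_coupling_keeps_trans_conformers_only(self):
        fx, ens = self._mixed_ensemble()
        filtered, report = ij_filter(ens, fx.exp.couplings, "dihedral_window")
        assert report.n_after == 3  # the three trans rotamers
        assert not report.released
        dih = fx.truth["reporter_dihedrals"]
        for c in filtered:
            assert abs(abs(dih[c.id]) - 180.0) < 30.0

    def test_vacuous_tolerance_keeps_everything(self):
        fx, ens = self._mixed_ensemble()
        filtered, report = ij_filter(
            ens, fx.exp.couplings, "dihedral_window", tolerance_deg=180.0
        )
        assert len(filtered) == len(ens)

    def test_monotone_in_tolerance(self):
        fx, ens = self._mixed_ensemble()
        sizes = []
        for tol in (5.0, 15.0, 30.0, 90.0, 180.0):
            filtered, _ = ij_filter(
                ens, fx.exp.couplings, "dihedral_window", tolerance_deg=tol
            )
            sizes.append(len(filtered))
        assert sizes == sorted(sizes)

    def test_released_when_nothing_survives(self):
        fx, ens = self._mixed_ensemble()
        # an experimental J that matches no conformer at tight tolerance
        from mixjdp4 import CouplingObservation

        impossible = [
            CouplingObservation("Jx", 1, 4, (1, 2, 3, 4), j_exp=float(karplus_j(100.0)),
                                use_for_filter=True)
        ]
        with pytest.warns(UserWarning, match="released"):
            filtered, report = ij_filter(
                ens, impossible, "dihedral_window", tolerance_deg=3.0
            )
        assert report.released
        assert len(filtered) == len(ens)

    def test_j_match_mode(self):
        fx, ens = self._mixed_ensemble()
        filtered, report = ij_filter(
            ens,
            fx.exp.couplings,
            "J_match",
            tolerance_j=2.0,
            coupling_table=fx.couplings["cand1"],
        )
        assert 0 < len(filtered) <= len(ens)

    def test_filtered_ensemble_energies_rereferenced(self):
        fx, ens = self._mixed_ensemble()
        filtered, _ = ij_filter(ens, fx.exp.couplings, "dihedral_window")
        assert min(c.rel_energy for c in filtered) == pytest.approx(0.0)


class TestRunAssignment:
    def test_indistinguishable_candidates_uniform(self):
        # zero inflation and zero geometry-linked offsets: the candidates'
        # predictions are identical, so every channel must return 1/2
        spec = FixtureSpec(
            seed=1, inflation_shift=0.0, sigma_spread=0.0, decoy_offset_scale=0.0
        )
        fx = make_fixture(spec)
        res = run_assignment(
            fx.ensembles, fx.shieldings, fx.exp,
            AssignmentConfig(reference=fx.reference), couplings=fx.couplings,
        )
        for name, p in res.probabilities.items():
            np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-9, err_msg=name)

    def test_correct_candidate_wins_decisively_at_3_sigma(self):
        spec = FixtureSpec(seed=7, inflation_shift=3.0)
        fx = make_fixture(spec)
        res = run_assignment(
            fx.ensembles, fx.shieldings, fx.exp,
            AssignmentConfig(reference=fx.reference), couplings=fx.couplings,
        )
        k = fx.ensembles and list(fx.ensembles).index(fx.truth["true_candidate"])
        assert res.combined[k] > 0.99

    def test_hc_subset_reproduces_plain_dp4(self):
        spec = FixtureSpec(seed=3)
        fx = make_fixture(spec)
        cfg_all = AssignmentConfig(reference=fx.reference, use_ij=False)
        res = run_assignment(
            fx.ensembles, fx.shieldings, fx.exp, cfg_all, couplings=fx.couplings
        )
        dp4 = combine_channels(
            {"H": res.probabilities["H"], "C": res.probabilities["C"]}, ["H", "C"]
        )
        cfg_hc = AssignmentConfig(
            reference=fx.reference, use_ij=False, channels=("H", "C")
        )
        res_hc = run_assignment(
            fx.ensembles, fx.shieldings, fx.exp, cfg_hc, couplings=fx.couplings
        )
        np.testing.assert_allclose(res_hc.combined, dp4, atol=1e-9)

    def test_deterministic_rerun(self):
        spec = FixtureSpec(seed=9)
        outs = []
        for _ in range(2):
            fx = make_fixture(spec)
            res = run_assignment(
                fx.ensembles, fx.shieldings, fx.exp,
                AssignmentConfig(reference=fx.reference), couplings=fx.couplings,
            )
            outs.append(np.asarray(res.combined))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_every_vector_is_a_probability_vector(self):
        fx = make_fixture(FixtureSpec(seed=13, n_candidates=4))
        res = run_assignment(
            fx.ensembles, fx.shieldings, fx.exp,
            AssignmentConfig(reference=fx.reference), couplings=fx.couplings,
        )
        for name, p in res.probabilities.items():
            assert abs(np.sum(p) - 1.0) < 1e-9, name
            assert np.all((p >= 0) & (p <= 1)), name


def _result_from(probs, ff="FFX", ids=("a", "b")):
    p = np.asarray(probs, dtype=float)
    return AssignmentResult(
        ff_tag=ff,
        candidate_ids=list(ids),
        probabilities={"combined": p},
        errors={}, diagnostics={}, scaling={}, weights={},
        filter_reports={}, metadata={},
    )


class TestMix:
    def test_saturated_worked_example(self):
        # one force field fails (<0.1% -> 0), two succeed (>99.9% -> 1):
        # consensus for the right isomer is 66.6%
        results = [
            _result_from([0.0, 1.0], "AMBER"),
            _result_from([1.0, 0.0], "MM3"),
            _result_from([1.0, 0.0], "MMFF"),
        ]
        mixed = mix_jdp4(results)
        assert 100 * mixed.averaged[0] == pytest.approx(66.6, abs=0.1)

    def test_idempotent_on_agreement(self):
        results = [_result_from([0.9, 0.1], ff) for ff in ("A", "B", "C")]
        mixed = mix_jdp4(results)
        np.testing.assert_allclose(mixed.averaged, [0.9, 0.1], atol=1e-12)

    def test_mean_of_probability_vectors_sums_to_one(self, rng):
        vecs = []
        for ff in ("A", "B", "C"):
            raw = rng.uniform(0, 1, 5)
            vecs.append(_result_from(raw / raw.sum(), ff, ids="abcde"))
        mixed = mix_jdp4(vecs)
        assert abs(mixed.averaged.sum() - 1.0) < 1e-9

    def test_candidate_mismatch_rejected(self):
        with pytest.raises(ProbabilityError):
            mix_jdp4([_result_from([1, 0], ids=("a", "b")),
                      _result_from([1, 0], ids=("a", "c"))])

    def test_two_ff_mix_warns(self):
        with pytest.warns(UserWarning, match="3"):
            mix_jdp4([_result_from([1, 0], "A"), _result_from([1, 0], "B")])


class TestWiCorrelation:
    def test_identical_sets_give_unity(self):
        w = BoltzmannWeights({"a": 0.7, "b": 0.3}, 298.0)
        df = wi_correlation({"A": w, "B": BoltzmannWeights({"a": 0.7, "b": 0.3}, 298.0)})
        assert df.loc["A", "B"] == pytest.approx(1.0)

    def test_affine_relation_gives_unity(self):
        w1 = BoltzmannWeights({"a": 0.6, "b": 0.3, "c": 0.1}, 298.0)
        # affine map of w1, renormalized to stay a weight vector
        raw = 0.5 * np.array([0.6, 0.3, 0.1]) + 0.1
        raw /= raw.sum()
        w2 = BoltzmannWeights(dict(zip("abc", raw.tolist())), 298.0)
        df = wi_correlation({"A": w1, "B": w2})
        assert df.loc["A", "B"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_vectors_match_corr_squared_oracle(self, rng):
        ids = [f"c{i}" for i in range(200)]
        raws = {}
        for tag in ("A", "B"):
            v = rng.uniform(0, 1, 200)
            v /= v.sum()
            raws[tag] = v
        sets = {
            tag: BoltzmannWeights(dict(zip(ids, v.tolist())), 298.0)
            for tag, v in raws.items()
        }
        df = wi_correlation(sets)
        a, b = raws["A"], raws["B"]
        r = np.corrcoef(a, b)[0, 1]
        assert df.loc["A", "B"] == pytest.approx(r * r, abs=1e-12)
        assert df.loc["A", "B"] < 0.05  # near zero for independent draws

    def test_zero_variance_reported_missing(self):
        w1 = BoltzmannWeights({"a": 0.5, "b": 0.5}, 298.0)
        w2 = BoltzmannWeights({"a": 0.9, "b": 0.1}, 298.0)
        df = wi_correlation({"A": w1, "B": w2})
        assert np.isnan(df.loc["A", "B"])


class TestClassificationReport:
    def test_all_solved(self):
        recs = [
            {"probs": {"dp4": np.array([0.9, 0.1])}, "correct": 0} for _ in range(5)
        ]
        df = classification_report(recs)
        row = df[df.method == "dp4"].iloc[0]
        assert row.success_rate == 1.0
        assert row.mean_p_correct == pytest.approx(0.9)

    def test_coin_flip_fixtures(self):
        recs = [
            {"probs": {"dp4": np.array([0.5, 0.5])}, "correct": 0} for _ in range(4)
        ]
        df = classification_report(recs)
        row = df.iloc[0]
        assert row.success_rate == 0.0  # a tie is not a decisive assignment
        assert row.mean_p_correct == pytest.approx(0.5)

    def test_success_increases_with_signal_count(self, rng):
        # calibration: data generated from the error model itself
        ch = ERROR_MODEL_PROFILES["dp4-2010"].channel("C")
        rates = []
        for n_sig in (1, 30):
            hits = 0
            for _ in range(300):
                true_err = ch.sigma * rng.standard_t(ch.nu, n_sig)
                wrong_err = true_err + 1.5 * ch.sigma * rng.choice((-1, 1), n_sig)
                p = dp4_channel([true_err, wrong_err], ch)
                hits += int(np.argmax(p) == 0)
            rates.append(hits / 300)
        assert rates[1] > rates[0]


@given(perm=st.permutations(list(range(4))))
@settings(max_examples=20, deadline=None)
def test_candidate_permutation_equivariance(perm):
    rng = np.random.default_rng(5)
    errors = [rng.normal(0, 2, 10) for _ in range(4)]
    p = dp4_channel(errors, CH)
    p_perm = dp4_channel([errors[i] for i in perm], CH)
    np.testing.assert_allclose(p_perm, p[list(perm)], rtol=1e-9)
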