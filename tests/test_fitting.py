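import numpy as np
import pytest

from bmpscreen.fitting import (
    CompetitiveBindingFitter,
    FitResult,
    assemble_observations,
    evaluate_recovery,
    filter_solutions,
    predicted_categories,
)
from bmpscreen.preprocess import preprocess
from bmpscreen.simulate import NoiseModel, fit_truth, generate_dataset


@pytest.fixture(scope="module")
def fit_setup():
    truth, contexts, panel = fit_truth()
    wells, _ = generate_dataset(panel, contexts, truth, NoiseModel.noiseless(),
                                n_replicates=2, seed=0)
    proc = preprocess(wells)
    obs = assemble_observations(
        proc, panel.ligands, {c.name: c for c in contexts},
        truth.type1, truth.type2, ratio_indices=[1, 5, 9],
    )
    return truth, contexts, panel, obs


def truth_vector(truth, obs):
    lo, hi = np.log(1e-4), np.log(1e2)
    xK = np.clip(np.log(np.maximum(truth.K, 1e-4)), lo, hi).ravel()
    xE = np.clip(np.log(np.maximum(truth.eps, 1e-4)), lo, hi).ravel()
    return np.concatenate([xK, xE, np.ones(len(obs.type1) + len(obs.type2))])


class TestAssembleObservations:
    def test_condition_counts(self, fit_setup):
        _, _, _, obs = fit_setup
        led = obs.ledger
        # per context: 5 gradients + 5 self-pairs + 10 pairs, each at the
        # 3 requested ratios plus its own zero-dose control
        per_ctx = led.groupby("context_id").size()
        assert (per_ctx == 20 * 3 + 20).all()

    def test_normalized_to_unit_maximum(self, fit_setup):
        _, _, _, obs = fit_setup
        assert obs.y.max() == pytest.approx(1.0)
        assert obs.y.min() >= 0.0
        assert obs.A0.max() == pytest.approx(1.0) or obs.B0.max() == pytest.approx(1.0)

    def test_ledger_round_trip(self, fit_setup):
        """Every observation maps back to exactly its generating condition."""
        _, _, panel, obs = fit_setup
        li = {l: i for i, l in enumerate(obs.ligands)}
        for r, rec in enumerate(obs.ledger.itertuples(index=False)):
            expected = np.zeros(len(obs.ligands))
            expected[li[rec.ligand_a]] += rec.conc_a
            if rec.ligand_b:
                expected[li[rec.ligand_b]] += rec.conc_b
            assert np.array_equal(obs.L[r], expected)

    def test_missing_context_rejected(self, fit_setup):
        truth, contexts, panel, _ = fit_setup
        wells, _ = generate_dataset(panel, contexts[:1], truth,
                                    NoiseModel.noiseless(), n_replicates=2, seed=0)
        proc = preprocess(wells)
        with pytest.raises(ValueError, match="no observations"):
            assemble_observations(proc, ["nope"], {c.name: c for c in contexts},
                                  truth.type1, truth.type2)


class TestFitter:
    def test_truth_start_is_near_fixed_point(self, fit_setup):
        truth, _, _, obs = fit_setup
        x0 = truth_vector(truth, obs)
        est = CompetitiveBindingFitter(n_starts=1, seed=0, max_nfev=60)
        est.fit(obs, x0_list=[x0])
        # the truth start refines to an essentially perfect fit (the output
        # normalization is absorbed by the scale-free parameters)
        assert est.best_.residual < 1e-4

    def test_same_seed_reproducible(self, fit_setup):
        _, _, _, obs = fit_setup
        r1 = CompetitiveBindingFitter(n_starts=2, seed=5, max_nfev=25).fit(obs).results_
        r2 = CompetitiveBindingFitter(n_starts=2, seed=5, max_nfev=25).fit(obs).results_
        assert [a.residual for a in r1] == [b.residual for b in r2]
        assert np.array_equal(r1[0].params.K, r2[0].params.K)

    def test_parameters_within_bounds(self, fit_setup):
        _, _, _, obs = fit_setup
        res = CompetitiveBindingFitter(n_starts=2, seed=1, max_nfev=25).fit(obs).results_
        for r in res:
            assert np.all(r.params.K >= 1e-4 - 1e-12) and np.all(r.params.K <= 1e2 + 1e-9)
            assert np.all(r.rho1 >= 1 / 3 - 1e-9) and np.all(r.rho1 <= 3 + 1e-9)

    def test_analytic_jacobian_matches_finite_differences(self, fit_setup):
        _, _, _, obs = fit_setup
        est = CompetitiveBindingFitter(seed=0)
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.uniform(np.log(1e-3), np.log(10), 60),
                            rng.uniform(0.5, 2.0, 5)])
        r0, J = est._eval(x, obs)
        for idx in rng.choice(x.size, 8, replace=False):
            xp = x.copy()
            xp[idx] += 1e-6
            est._cache_key = None
            num = (est._residuals(xp, obs) - r0) / 1e-6
            scale = max(np.abs(num).max(), 1e-6)
            assert np.abs(num - J[:, idx]).max() / scale < 1e-2


class TestFilterSolutions:
    def test_truth_passes_its_own_categories(self, fit_setup):
        truth, _, _, obs = fit_setup
        tr = FitResult(params=truth, rho1=np.ones(2), rho2=np.ones(3),
                       residual=0.0, start_seed=-1)
        cats = predicted_categories(tr, obs)
        reqs = {k: v.value for k, v in cats.items()}
        accepted = filter_solutions([tr], obs, category_requirements=reqs)
        assert accepted == [tr]

    def test_wrong_category_rejected(self, fit_setup):
        truth, _, _, obs = fit_setup
        tr = FitResult(params=truth, rho1=np.ones(2), rho2=np.ones(3),
                       residual=0.0, start_seed=-1)
        cats = predicted_categories(tr, obs)
        key = next(k for k, v in cats.items() if v.value == "antagonistic")
        reqs = {key: "synergistic"}  # demand the opposite behavior
        accepted = filter_solutions([tr], obs, category_requirements=reqs)
        assert accepted == []
        assert not tr.accepted

    def test_residual_cap_filters(self, fit_setup):
        truth, _, _, obs = fit_setup
        good = FitResult(params=truth, rho1=np.ones(2), rho2=np.ones(3),
                         residual=1.0, start_seed=0)
        bad = FitResult(params=truth, rho1=np.ones(2), rho2=np.ones(3),
                        residual=10.0, start_seed=1)
        cats = predicted_categories(good, obs)
        reqs = {k: v.value for k, v in cats.items()}
        accepted = filter_solutions([good, bad], obs, category_requirements=reqs,
                                    residual_factor=2.0)
        assert bad not in accepted

    def test_no_criteria_accepts_all_with_warning(self, fit_setup):
        truth, _, _, obs = fit_setup
        r = FitResult(params=truth, rho1=np.ones(2), rho2=np.ones(3),
                      residual=1.0, start_seed=0)
        accepted = filter_solutions([r], obs, category_requirements=None)
        assert accepted == [r]
        assert "warning" in r.criteria_errors


class TestEvaluateRecovery:
    def test_truth_scores_perfectly(self, fit_setup):
        truth, _, _, obs = fit_setup
        tr = FitResult(params=truth, rho1=np.ones(2), rho2=np.ones(3),
                       residual=0.0, start_seed=-1)
        cats = {k: v.value for k, v in predicted_categories(tr, obs).items()}
        # scale-normalized observations differ from raw S by a constant gain;
        # R^2 is computed on predictions from the *fitted* scale, so feed the
        # truth rescaled to the observation units
        gain = obs.y.max() / CompetitiveBindingFitter().predict(obs, tr).max()
        from bmpscreen.equilibrium import ModelParams
        scaled = ModelParams(truth.ligands, truth.type1, truth.type2,
                             truth.K, truth.eps * gain)
        tr2 = FitResult(params=scaled, rho1=np.ones(2), rho2=np.ones(3),
                        residual=0.0, start_seed=-1)
        rep = evaluate_recovery(scaled, [tr2], obs, truth_categories=cats)
        assert rep["r2"].iloc[0] > 0.999
        assert rep["category_agreement"].iloc[0] == 1.0

    def test_anticorrelated_truth_detected(self, fit_setup):
        truth, _, _, obs = fit_setup
        from bmpscreen.equilibrium import ModelParams
        rng = np.random.default_rng(0)
        logk = rng.uniform(-2, 2, truth.K.shape)
        anti = ModelParams(truth.ligands, truth.type1, truth.type2,
                           10.0**logk, 10.0**(-logk))
        r = FitResult(params=anti, rho1=np.ones(2), rho2=np.ones(3),
                      residual=0.0, start_seed=0)
        rep = evaluate_recovery(anti, [r], obs)
        assert rep["k_eps_correlation"].iloc[0] < -0.9
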