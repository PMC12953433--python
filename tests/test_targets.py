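import numpy as np
import pytest

from bmca.infer import PosteriorSamples
from bmca.linlog import simulate_strain
from bmca.synth import make_toy_network
from bmca.targets import FCCPosterior, call_targets, fcc_posterior, hpd_interval


def _point_mass_posterior(truth, draws=200, jitter=0.0, seed=0):
    """Posterior concentrated at (or jittered around) the true elasticities."""
    rng = np.random.default_rng(seed)
    ex = np.repeat(truth.eps_true.eps_x[None], draws, axis=0)
    ey = np.repeat(truth.eps_true.eps_y[None], draws, axis=0)
    if jitter:
        ex = ex + rng.normal(0, jitter, ex.shape) * (ex != 0)
        ey = ey + rng.normal(0, jitter, ey.shape) * (ey != 0)
    return PosteriorSamples(draws=draws, eps_x_samples=ex, eps_y_samples=ey,
                            elbo_trace=np.zeros(1), seed=seed, converged=True,
                            theta_samples=np.zeros((draws, 1)))


def _brute_force_hpd(x, level):
    x = np.sort(x)
    n = len(x)
    k = int(np.ceil(level * n))
    best = None
    for i in range(n - k + 1):
        w = x[i + k - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + k - 1])
    return best[1], best[2]


class TestHpdInterval:
    @pytest.mark.parametrize("level", [0.5, 0.8, 0.95])
    def test_matches_brute_force_enumeration(self, level):
        rng = np.random.default_rng(42)
        for x in (np.arange(1.0, 101.0), rng.gamma(2.0, 1.0, 500),
                  rng.normal(0, 1, 321)):
            assert hpd_interval(x, level) == _brute_force_hpd(x, level)

    def test_sorted_integers_narrowest_window(self):
        lo, hi = hpd_interval(np.arange(1.0, 101.0), 0.95)
        assert hi - lo == 94.0  # width of a 95-sample window on 1..100

    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(7).standard_normal(10000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)
        assert lo < 0 < hi

    def test_degenerate_samples(self):
        lo, hi = hpd_interval(np.full(200, 3.25), 0.95)
        assert (lo, hi) == (3.25, 3.25)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="100 samples"):
            hpd_interval(np.arange(50.0), 0.95)
        with pytest.raises(ValueError, match="level"):
            hpd_interval(np.arange(200.0), 0.0)


class TestFccPosterior:
    def test_point_mass_posterior_equals_analytic_row(self, branched_truth):
        t = branched_truth
        post = _point_mass_posterior(t)
        fcc = fcc_posterior(post, t.model, t.ref)
        assert fcc.valid_mask.all()
        row = t.target_fcc_row()
        np.testing.assert_allclose(fcc.valid,
                                   np.broadcast_to(row, fcc.valid.shape),
                                   rtol=1e-10)

    def test_two_step_closed_form_per_draw(self, two_step):
        # eps1 fixed at -1; eps2 varies per draw: C2 row = (e2/(e2+1), 1/(e2+1))
        t = two_step
        draws = 150
        rng = np.random.default_rng(3)
        e2 = rng.uniform(0.2, 1.5, draws)
        ex = np.zeros((draws, 2, 1))
        ex[:, 0, 0] = -1.0
        ex[:, 1, 0] = e2
        post = PosteriorSamples(draws=draws, eps_x_samples=ex,
                                eps_y_samples=np.zeros((draws, 2, 2)),
                                elbo_trace=np.zeros(1), seed=0, converged=True,
                                theta_samples=np.zeros((draws, 1)))
        fcc = fcc_posterior(post, t.model, t.ref, "r2")
        np.testing.assert_allclose(fcc.valid[:, 0], e2 / (e2 + 1), rtol=1e-10)
        np.testing.assert_allclose(fcc.valid[:, 1], 1 / (e2 + 1), rtol=1e-10)

    def test_rows_sum_to_one_per_draw(self, branched_truth):
        post = _point_mass_posterior(branched_truth, jitter=0.05, seed=1)
        fcc = fcc_posterior(post, branched_truth.model, branched_truth.ref)
        np.testing.assert_allclose(fcc.valid.sum(axis=1), 1.0, atol=1e-6)


class TestCallTargets:
    def _fcc_from_draws(self, draws_by_rid, target="t"):
        rids = sorted(draws_by_rid) + [target]
        n = len(next(iter(draws_by_rid.values())))
        samples = np.column_stack([draws_by_rid[r] for r in sorted(draws_by_rid)]
                                  + [np.ones(n)])
        return FCCPosterior(target_reaction=target, samples=samples,
                            valid_mask=np.ones(n, bool), reaction_ids=rids)

    class _StubModel:
        def reaction(self, rid):
            from bmca.network import Reaction
            return Reaction(rid, {"x": 1.0}, protein_ids=(f"p_{rid}",))

    def test_clear_positive_called_overexpress(self):
        rng = np.random.default_rng(0)
        fcc = self._fcc_from_draws({"a": rng.normal(0.5, 0.05, 1000)})
        calls = call_targets(fcc, self._StubModel())
        assert calls[0].significant and calls[0].direction == "overexpress"

    def test_diffuse_posterior_not_called(self):
        rng = np.random.default_rng(0)
        fcc = self._fcc_from_draws({"a": rng.normal(0.0, 1.0, 1000)})
        calls = call_targets(fcc, self._StubModel())
        assert not calls[0].significant and calls[0].direction == "none"

    def test_below_magnitude_floor_not_called(self):
        rng = np.random.default_rng(0)
        fcc = self._fcc_from_draws({"a": rng.normal(0.03, 0.002, 1000)})
        calls = call_targets(fcc, self._StubModel(), magnitude_floor=0.05)
        assert not calls[0].significant

    def test_drain_called_delete_on_synthetic_truth(self, branched_truth):
        t = branched_truth
        post = _point_mass_posterior(t, jitter=0.02, seed=2)
        fcc = fcc_posterior(post, t.model, t.ref)
        calls = {c.reaction_id: c for c in call_targets(fcc, t.model)}
        assert calls["r_ald6"].direction == "delete"
        assert calls["r_pyc"].direction == "overexpress"
        assert "r_3hp_export" not in calls  # target excluded

    def test_ranked_by_median_magnitude(self, branched_truth):
        post = _point_mass_posterior(branched_truth, jitter=0.02, seed=2)
        fcc = fcc_posterior(post, branched_truth.model, branched_truth.ref)
        calls = call_targets(fcc, branched_truth.model)
        mags = [abs(c.fcc_median) for c in calls]
        assert mags == sorted(mags, reverse=True)

    def test_raising_level_monotone_selectivity(self, branched_truth):
        post = _point_mass_posterior(branched_truth, jitter=0.15, seed=3)
        fcc = fcc_posterior(post, branched_truth.model, branched_truth.ref)
        counts = [sum(c.significant for c in
                      call_targets(fcc, branched_truth.model, level=lv))
                  for lv in (0.5, 0.8, 0.95, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_invariant_to_reaction_permutation(self, branched_truth):
        t = branched_truth
        post = _point_mass_posterior(t, jitter=0.05, seed=4)
        fcc = fcc_posterior(post, t.model, t.ref)
        perm = np.random.default_rng(0).permutation(len(fcc.reaction_ids))
        fcc_p = FCCPosterior(
            target_reaction=fcc.target_reaction,
            samples=fcc.samples[:, perm],
            valid_mask=fcc.valid_mask,
            reaction_ids=[fcc.reaction_ids[i] for i in perm],
        )
        a = [(c.reaction_id, c.direction) for c in call_targets(fcc, t.model)]
        b = [(c.reaction_id, c.direction) for c in call_targets(fcc_p, t.model)]
        assert a == b

    def test_called_interventions_increase_target_flux(self, branched_truth):
        """Directionality: applying each true-positive call (x5 or
        delete-floor) raises the steady-state target flux for >=90%."""
        t = branched_truth
        post = _point_mass_posterior(t, jitter=0.02, seed=5)
        fcc = fcc_posterior(post, t.model, t.ref)
        calls = [c for c in call_targets(fcc, t.model) if c.significant]
        assert calls
        jt = t.model.reaction_index(t.model.target_reaction_id)
        base = simulate_strain(t.model, t.ref, t.eps_true, {}).v[jt]
        improved = 0
        for c in calls:
            fold = 5.0 if c.direction == "overexpress" else 0.0
            sol = simulate_strain(t.model, t.ref, t.eps_true,
                                  {c.reaction_id: fold})
            improved += sol.v[jt] > base
        assert improved / len(calls) >= 0.9
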