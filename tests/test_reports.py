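import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from socialrisk.exceptions import AlignmentError, DataValidationError
from socialrisk.prospect_model import EFFECT_NAMES, ParameterSet, SocialEffects
from socialrisk.reports import (
    condition_means_markdown,
    group_difference_ttests,
    implied_condition_means,
    implied_condition_means_from_draws,
    implied_other_means,
    recovery_report,
    trait_correlations,
)
from socialrisk.synthetic_cohort import default_population

BASE = ParameterSet.from_natural(1.07, 1.78, 18.0)
PUBLISHED = SocialEffects(
    d_rho_other=-0.11, d_rho_sharing=0.016, d_rho_identity=-0.05,
    d_lam_other=0.06, d_lam_sharing=0.0, d_lam_identity=0.02,
    d_mu_other=0.45, d_mu_sharing=0.0, d_mu_identity=-0.18,
)


class TestImpliedMeans:
    def test_zero_deltas_every_cell_is_baseline(self):
        tab = implied_condition_means(BASE, SocialEffects())
        for _, row in tab.iterrows():
            assert row["rho"] == pytest.approx(BASE.rho)
            assert row["lam"] == pytest.approx(BASE.lam)
            assert row["mu"] == pytest.approx(BASE.mu)

    def test_other_only_composition(self):
        rho, lam, mu = implied_other_means(BASE, PUBLISHED)
        assert rho == pytest.approx(0.96, abs=0.02)
        assert lam == pytest.approx(1.90, abs=0.02)
        assert mu == pytest.approx(28.3, abs=0.2)

    def test_other_only_friend_vs_stranger_rho(self):
        tab = implied_condition_means(BASE, PUBLISHED).set_index(["condition", "group"])
        assert 1.02 <= tab.loc[("other", "friend"), "rho"] <= 1.03
        assert 0.92 <= tab.loc[("other", "stranger"), "rho"] <= 0.93

    def test_self_row_is_baseline(self):
        tab = implied_condition_means(BASE, PUBLISHED)
        row = tab[tab["condition"] == "self"].iloc[0]
        assert row["rho"] == pytest.approx(1.07)

    def test_draw_wise_composition_with_hdis(self):
        rng = np.random.default_rng(0)
        logs = BASE.as_log_array() + 0.02 * rng.standard_normal((4000, 3))
        deltas = PUBLISHED.as_array() + 0.01 * rng.standard_normal((4000, 9))
        tab = implied_condition_means_from_draws(logs, deltas)
        row = tab.set_index(["condition", "group"]).loc[("other", "stranger")]
        assert row["rho_lower"] < row["rho"] < row["rho_upper"]
        assert row["rho"] == pytest.approx(0.9265, abs=0.01)

    def test_jensen_gap_property(self):
        # draw-wise mean of exp >= exp of mean (strict when spread is large),
        # and they coincide as the spread shrinks
        rng = np.random.default_rng(1)
        point = implied_condition_means(BASE, PUBLISHED).set_index(["condition", "group"])
        for spread, tol in ((0.5, None), (1e-4, 1e-3)):
            logs = BASE.as_log_array() + spread * rng.standard_normal((8000, 3))
            deltas = np.tile(PUBLISHED.as_array(), (8000, 1))
            tab = implied_condition_means_from_draws(logs, deltas)
            for _, row in tab[tab["condition"] != "self"].iterrows():
                ref = point.loc[(row["condition"], row["group"]), "mu"]
                if tol is None:
                    assert row["mu"] > ref  # Jensen gap
                else:
                    assert row["mu"] == pytest.approx(ref, rel=tol)

    def test_markdown_render(self):
        md = condition_means_markdown(implied_condition_means(BASE, PUBLISHED))
        assert md.startswith("| condition |")
        assert "self" in md and "stranger" in md


class _FakePosterior:
    """Minimal stand-in exposing the registry interface of a real fit."""

    def __init__(self, blocks, participants=()):
        self.registry = {}
        arrays = []
        off = 0
        for name, arr in blocks.items():
            arr = np.asarray(arr, dtype=float)
            shape = arr.shape[2:]
            self.registry[name] = (off, shape)
            arrays.append(arr.reshape(arr.shape[0], arr.shape[1], -1))
            off += arrays[-1].shape[2]
        self.draws = np.concatenate(arrays, axis=2)
        self.participants = list(participants)

    def get(self, name):
        off, shape = self.registry[name]
        size = int(np.prod(shape)) if shape else 1
        return self.draws[:, :, off:off + size].reshape(
            self.draws.shape[0], self.draws.shape[1], *shape)

    def flat(self, name):
        g = self.get(name)
        return g.reshape(-1, *g.shape[2:])


def _collapsed_posterior(pop, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = (2, 100)
    gm = np.tile(np.asarray(pop.group_log_means), (*n, 1))
    gsd = np.tile(np.log(np.asarray(pop.group_log_sds)), (*n, 1))
    deltas = np.tile(pop.true_social_effects.as_array(), (*n, 1))
    if jitter:
        gm = gm + jitter * rng.standard_normal(gm.shape)
        gsd = gsd + jitter * rng.standard_normal(gsd.shape)
        deltas = deltas + jitter * rng.standard_normal(deltas.shape)
    return _FakePosterior({"group_mean": gm, "group_log_sd": gsd, "delta": deltas})


class TestRecoveryReport:
    def test_collapsed_posterior_zero_bias_full_coverage(self):
        pop = default_population(seed=1, traits=())
        post = _collapsed_posterior(pop, jitter=1e-6)
        rep = recovery_report(pop, post)
        assert rep.coverage_rate == 1.0
        assert (rep.table["abs_error"] < 1e-4).all()

    def test_mis_scaled_truth_zero_coverage(self):
        pop = default_population(seed=1, traits=())
        post = _collapsed_posterior(pop, jitter=1e-6)
        shifted = default_population(
            seed=1, traits=(),
            group_log_means=tuple(m + 50 for m in pop.group_log_means),
            group_log_sds=tuple(s + 50 for s in pop.group_log_sds),
            true_social_effects=SocialEffects.from_array(
                pop.true_social_effects.as_array() + 50),
        )
        rep = recovery_report(shifted, post)
        assert rep.coverage_rate == 0.0

    def test_coverage_flag_consistency(self):
        pop = default_population(seed=2, traits=())
        rep = recovery_report(pop, _collapsed_posterior(pop, jitter=0.05, seed=3))
        for _, row in rep.table.iterrows():
            inside = row["hdi_lower"] <= row["truth"] <= row["hdi_upper"]
            assert row["covered"] == inside


class TestTraitCorrelations:
    def _frames(self, x, y):
        pid = [f"p{i:03d}" for i in range(len(x))]
        eff = pd.DataFrame({"participant_id": pid, "d_lam_other": y})
        tr = pd.DataFrame({"participant_id": pid, "trait": x})
        return eff, tr

    def test_identical_vectors_r_one(self):
        x = np.arange(10.0)
        eff, tr = self._frames(x, x)
        out = trait_correlations(eff, tr)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_orthogonal_pair_r_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0]) - 1 / 3
        y = y - y.mean()
        x = x - x.mean()
        y = y - (x @ y) / (x @ x) * x  # exact orthogonalization
        eff, tr = self._frames(x, y)
        out = trait_correlations(eff, tr)
        assert out.loc[0, "r"] == pytest.approx(0.0, abs=1e-12)

    def test_degrees_of_freedom_and_p(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        eff, tr = self._frames(x, y)
        out = trait_correlations(eff, tr)
        r, p = sps.pearsonr(x, y)
        assert out.loc[0, "r"] == pytest.approx(r)
        assert out.loc[0, "p"] == pytest.approx(p)
        assert out.loc[0, "n"] == 20

    def test_pairwise_missing_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        eff, tr = self._frames(x, y)
        tr.loc[0, "trait"] = np.nan
        out = trait_correlations(eff, tr)
        assert out.loc[0, "n"] == 14

    def test_zero_variance_rejected(self):
        eff, tr = self._frames(np.ones(5), np.arange(5.0))
        with pytest.raises(DataValidationError):
            trait_correlations(eff, tr)

    def test_too_few_pairs_rejected(self):
        eff, tr = self._frames(np.arange(2.0), np.arange(2.0))
        with pytest.raises(DataValidationError):
            trait_correlations(eff, tr)

    def test_bh_column_present_and_bounded(self):
        rng = np.random.default_rng(2)
        pid = [f"p{i:03d}" for i in range(30)]
        eff = pd.DataFrame({
            "participant_id": pid,
            "d_rho_other": rng.standard_normal(30),
            "d_lam_other": rng.standard_normal(30),
        })
        tr = pd.DataFrame({
            "participant_id": pid,
            "t1": rng.standard_normal(30),
            "t2": rng.standard_normal(30),
        })
        out = trait_correlations(eff, tr)
        assert len(out) == 4
        assert ((out["p_bh"] >= out["p"] - 1e-12) & (out["p_bh"] <= 1)).all()

    def test_null_permutation_calibration(self):
        # permuted trait labels exceed the alpha=0.01 critical |r| in ~1% of
        # permutations (>= 99% below, fixed seed)
        rng = np.random.default_rng(3)
        n = 57
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        crit = sps.t.ppf(0.995, n - 2)
        r_crit = math.sqrt(crit**2 / (crit**2 + n - 2))
        below = 0
        for _ in range(1000):
            xp = rng.permutation(x)
            r = np.corrcoef(xp, y)[0, 1]
            below += abs(r) < r_crit
        assert below >= 990


class TestGroupTTests:
    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        pid = [f"p{i:03d}" for i in range(20)]
        eff = pd.DataFrame({"participant_id": pid,
                            "d_rho_other": rng.standard_normal(20)})
        groups = pd.DataFrame({"participant_id": pid,
                               "group": ["stranger"] * 11 + ["friend"] * 9})
        out = group_difference_ttests(eff, groups)
        a = eff["d_rho_other"][:11]
        b = eff["d_rho_other"][11:]
        t, p = sps.ttest_ind(a, b)
        assert out.loc[0, "t"] == pytest.approx(t)
        assert out.loc[0, "p"] == pytest.approx(p)
        assert out.loc[0, "n_stranger"] == 11


class TestMixedModelEndToEnd:
    """M2 fit on a small model2-generated cohort: subject-level effect
    extraction, recovery report alignment, trait correlations, t-tests."""

    @pytest.fixture(scope="class")
    def m2_setup(self):
        from socialrisk.inference import MCMCConfig, fit_model
        from socialrisk.synthetic_cohort import agents_to_table, simulate_cohort

        pop = default_population(seed=71, n_friend=3, n_stranger=3,
                                 subject_effect_sd=0.3)
        agents, trials = simulate_cohort(pop, effects_mode="model2_mixed")
        post = fit_model(trials, "M2",
                         MCMCConfig(chains=2, warmup=200, draws=150, seed=1,
                                    scaled_down=True))
        return pop, agents, trials, post

    def test_subject_effect_draws_shape(self, m2_setup):
        from socialrisk.reports import subject_other_effect_draws
        _, agents, _, post = m2_setup
        draws = subject_other_effect_draws(post)
        assert draws.shape == (2 * 150, len(agents), 3)

    def test_recovery_report_includes_subject_effects(self, m2_setup):
        pop, agents, _, post = m2_setup
        rep = recovery_report(pop, post, agents=agents)
        subject_rows = rep.table[
            rep.table["parameter"].str.contains(r"\[p0", regex=True)]
        assert len(subject_rows) == 3 * len(agents)
        # well-specified small fit: most subject effects should be covered
        assert subject_rows["covered"].mean() > 0.5

    def test_point_estimates_and_downstream_stats(self, m2_setup):
        from socialrisk.reports import subject_other_effect_means
        from socialrisk.synthetic_cohort import agents_to_table
        _, agents, _, post = m2_setup
        effects = subject_other_effect_means(post)
        assert set(effects.columns) == {
            "participant_id", "d_rho_other", "d_lam_other", "d_mu_other"}
        tab = agents_to_table(agents)
        corr = trait_correlations(
            effects, tab[["participant_id", "social_risk", "empathy"]])
        assert len(corr) == 6
        tt = group_difference_ttests(effects, tab)
        assert len(tt) == 3 and tt["p"].between(0, 1).all()

    def test_misaligned_agents_rejected(self, m2_setup):
        pop, agents, _, post = m2_setup
        with pytest.raises(AlignmentError):
            recovery_report(pop, post, agents=agents[:-1])
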