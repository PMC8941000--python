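import numpy as np
import pandas as pd
import pytest

from ommnet import synthetic as syn
from ommnet.growth import compute_auc, estimate_growth_rate
from ommnet.network import CocultureModel, quantify_from_cq

from conftest import small_decoupled_design


class TestDesignValidation:
    def test_rejects_nonnegative_self_interaction(self):
        with pytest.raises(ValueError, match="a_ii"):
            d = small_decoupled_design([1.0, 1.0])
            bad = d.interactions.copy()
            bad[0, 0] = 0.0
            syn.SyntheticDesign(
                strains=d.strains, feature_usage=d.feature_usage,
                depletion_depth=d.depletion_depth,
                production_profile=d.production_profile,
                interactions=bad, bacteriocin=d.bacteriocin,
            )

    def test_rejects_bad_dilution_factor(self):
        with pytest.raises(ValueError, match="dilution"):
            small_decoupled_design([1.0], dilution_factor=1.5)

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            syn.NoiseSpec(od_sd=-0.1)

    def test_default_design_counts(self, default_design):
        assert len(default_design.strains) == 12
        assert default_design.n_features == 3092
        counts = default_design.edge_truth["type"].value_counts()
        assert counts.to_dict() == {
            "amensalism": 46, "neutralism": 11, "competition": 7,
            "predation": 1, "commensalism": 1,
        }


class TestMonocultureSimulation:
    def test_noiseless_final_od_reaches_capacity(self, noiseless_design):
        for spec in noiseless_design.strains[:4]:
            curve = syn.simulate_monoculture(noiseless_design, spec.name, seed=1)
            assert curve.od[-1] == pytest.approx(spec.carrying_capacity, rel=0.01)

    def test_reduced_capacity_lowers_auc(self, noiseless_design):
        fresh = syn.simulate_monoculture(noiseless_design, "KB1", seed=1)
        i = noiseless_design.index("KB1")
        half = np.ones(noiseless_design.n_features)
        used = noiseless_design.feature_usage[i]
        half[used] = 0.5  # half of KB1's substrate pool gone
        sm = syn.simulate_monoculture(
            noiseless_design, "KB1", medium_state=half, seed=1, producer="YL58"
        )
        assert compute_auc(sm) < compute_auc(fresh)

    def test_rate_estimator_recovers_logistic_mu(self, noiseless_design):
        curve = syn.simulate_monoculture(noiseless_design, "YL27", seed=1)
        assert estimate_growth_rate(curve) == pytest.approx(1.2, rel=0.05)


class TestSpentMediaSimulation:
    def test_zero_overlap_zero_bacteriocin_pairs_unaffected(self, spent_media_results,
                                                            default_design):
        res, _ = spent_media_results
        names = default_design.strain_names
        shared = default_design.feature_usage @ default_design.feature_usage.T
        checked = 0
        for p in names:
            for c in names:
                if p == c:
                    continue
                i, j = names.index(p), names.index(c)
                if shared[i, j] == 0 and default_design.bacteriocin[i, j] == 0:
                    assert abs(res.inhibition.d_auc.loc[p, c]) < 0.1
                    checked += 1
        assert checked > 0

    def test_full_overlap_strongly_inhibits(self, spent_media_results, default_design):
        """A consumer whose resources are a subset of the producer's crashes."""
        res, _ = spent_media_results
        # every strain fully overlaps itself
        for s in default_design.strain_names:
            assert res.inhibition.d_auc.loc[s, s] < -0.5


class TestPhSimulation:
    def test_acidifiers_lower_sm_ph_and_deltas_telescope(self, default_design):
        from ommnet.growth import SpentMediaModel, compute_delta_ph
        from ommnet import synthetic as syn

        ph = syn.simulate_ph_table(default_design)
        by_producer = ph.groupby("medium")["ph_sm"].first()
        for spec in default_design.strains:
            assert by_producer[spec.name] == pytest.approx(7.0 + spec.acid_coef)
        # the pH table feeds the growth model and every record telescopes
        od, _ = syn.simulate_spent_media_experiment(default_design, seed=21,
                                                    replicates=2)
        res = SpentMediaModel(od, ph=ph).fit()
        assert len(res.ph_records) == len(ph)
        for rec in res.ph_records:
            assert rec.ph_fresh + rec.delta_ph_sm + rec.delta_ph_dsm == pytest.approx(
                rec.ph_dsm
            )
        # growth in an exhausted medium mutes the consumer's own pH shift
        one = ph[(ph.medium == "KB1") & (ph.strain == "KB1")].iloc[0]
        assert abs(one.ph_dsm - one.ph_sm) < abs(one.ph_sm - one.ph_fresh)
        assert compute_delta_ph(7.0, one.ph_sm, one.ph_dsm).delta_ph_sm == (
            pytest.approx(one.ph_sm - 7.0)
        )


class TestFeatureTableSimulation:
    def test_null_depth_false_positive_rate_near_alpha(self):
        d = small_decoupled_design([1.0], noise=syn.NoiseSpec(0, 0.1, 0, 0))
        d = syn.SyntheticDesign(
            strains=d.strains,
            feature_usage=np.zeros((1, 2000), dtype=bool),
            depletion_depth=np.zeros(2000),
            production_profile=np.zeros((1, 2000), dtype=bool),
            interactions=d.interactions, bacteriocin=d.bacteriocin,
            noise=syn.NoiseSpec(0, 0.1, 0, 0),
        )
        table = syn.simulate_feature_table(d, seed=9)
        from ommnet.metabolomics import call_feature_changes

        [prof] = call_feature_changes(table, alpha=0.05)
        rate = (len(prof.depleted) + len(prof.produced)) / 2000
        assert rate == pytest.approx(0.05, abs=0.025)

    def test_designed_worked_example_reproduced_from_truth_sets(self, default_design):
        """KB1/YL2 designed sets give the 8.9% / 25.8% asymmetric overlap."""
        from ommnet.metabolomics import DepletionProfile, overlap_matrix

        names = default_design.strain_names
        profiles = []
        for s in ("KB1", "YL2"):
            used = default_design.feature_usage[names.index(s)]
            profiles.append(
                DepletionProfile(s, frozenset(np.flatnonzero(used)), frozenset(),
                                 pd.DataFrame())
            )
        ov = overlap_matrix(profiles)
        assert ov.counts.loc["KB1", "YL2"] == 33
        assert ov.set_sizes.to_dict() == {"KB1": 370, "YL2": 128}
        assert ov.percent_rounded().loc["KB1", "YL2"] == 8.9
        assert ov.percent_rounded().loc["YL2", "KB1"] == 25.8

    def test_reproducible_given_seed(self, default_design):
        t1 = syn.simulate_feature_table(default_design, seed=5)
        t2 = syn.simulate_feature_table(default_design, seed=5)
        t3 = syn.simulate_feature_table(default_design, seed=6)
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
        assert not t1.intensities.equals(t3.intensities)


class TestCocultureSimulation:
    def test_decoupled_strains_have_unit_rbm(self):
        d = small_decoupled_design([1.0, 1.3, 0.9], caps=[0.8, 1.0, 0.6])
        obs, _ = syn.simulate_cocultures(d, seed=1, replicates=2)
        res = CocultureModel(obs).fit()
        rbm = res.rbm_matrix()
        off = rbm.values[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=0.05)

    def test_one_sided_suppression_classified_amensal(self):
        d = small_decoupled_design([1.2, 1.2])
        a = d.interactions.copy()
        a[1, 0] = -0.8 * 1.2  # strain S0 suppresses S1 to ~0.2 K
        d2 = syn.SyntheticDesign(
            strains=d.strains, feature_usage=d.feature_usage,
            depletion_depth=d.depletion_depth,
            production_profile=d.production_profile,
            interactions=a, bacteriocin=d.bacteriocin,
            noise=syn.NoiseSpec(0, 0, 0, 0.1),
        )
        obs, _ = syn.simulate_cocultures(d2, seed=2)
        edge = CocultureModel(obs).fit().edges[0]
        assert {edge.sign_a, edge.sign_b} == {"0", "-"}
        assert edge.type == "amensalism"

    def test_mutual_suppression_classified_competition(self):
        d = small_decoupled_design([1.2, 1.2])
        a = d.interactions.copy()
        a[1, 0] = a[0, 1] = -3.0 * 1.2  # strong symmetric competition
        d2 = syn.SyntheticDesign(
            strains=d.strains, feature_usage=d.feature_usage,
            depletion_depth=d.depletion_depth,
            production_profile=d.production_profile,
            interactions=a, bacteriocin=d.bacteriocin,
            noise=syn.NoiseSpec(0, 0, 0, 0.1),
        )
        obs, _ = syn.simulate_cocultures(d2, seed=3)
        edge = CocultureModel(obs).fit().edges[0]
        assert edge.type == "competition"

    def test_bit_reproducible(self, default_design):
        a, _ = syn.simulate_cocultures(default_design, seed=4)
        b, _ = syn.simulate_cocultures(default_design, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestGlvIntegrator:
    def _community(self):
        rng = np.random.default_rng(17)
        mus = np.array([1.9, 1.2, 0.8, 1.5])
        caps = np.array([1.0, 0.8, 0.5, 0.9])
        a = -np.diag(mus / caps)
        a[1, 0] = -0.8
        a[0, 3] = 0.4
        a[2, 1] = -1.1
        return np.full(4, 0.0025), mus, a

    def test_tiny_step_reference_agreement(self):
        n0, mus, a = self._community()
        coarse = syn.integrate_glv(n0, mus, a, hours=24.0, dt=0.01)
        fine = syn.integrate_glv(n0, mus, a, hours=24.0, dt=0.001)
        np.testing.assert_allclose(coarse, fine, rtol=1e-4)

    def test_agrees_with_scipy_adaptive_solver(self):
        from scipy.integrate import solve_ivp

        n0, mus, a = self._community()
        ours = syn.integrate_glv(n0, mus, a, hours=24.0, dt=0.01)
        ref = solve_ivp(
            lambda t, n: n * (mus + a @ n), (0.0, 24.0), n0,
            rtol=1e-10, atol=1e-14, method="RK45",
        ).y[:, -1]
        np.testing.assert_allclose(ours, ref, rtol=1e-6)

    def test_divergence_guard_trips(self):
        with pytest.raises(RuntimeError, match="diverged"):
            # runaway mutualism: positive feedback overwhelms self-limitation
            syn.integrate_glv(
                np.array([0.5, 0.5]),
                np.array([1.0, 1.0]),
                np.array([[-0.1, 50.0], [50.0, -0.1]]),
                hours=24.0,
            )


class TestCommunitySimulation:
    def test_neutral_design_stays_even(self):
        d = small_decoupled_design([1.2] * 4)
        df = syn.simulate_community(d, days=5, seed=1, replicates=1)
        final = df[df.day == 5].set_index("strain")["true_copies"]
        rel = final / final.sum()
        np.testing.assert_allclose(rel, 0.25, rtol=1e-6)

    def test_killer_dropout_releases_designed_targets(self):
        """Targets of a killer strain rebound when the killer is removed."""
        mus = [1.6, 1.2, 1.2, 1.0]
        d = small_decoupled_design(mus, noise=syn.NoiseSpec(0, 0, 0, 0.1))
        b = d.bacteriocin.copy()
        b[0, 1] = 0.8 * mus[1]  # S0 kills S1 and S2
        b[0, 2] = 0.8 * mus[2]
        d2 = syn.SyntheticDesign(
            strains=d.strains, feature_usage=d.feature_usage,
            depletion_depth=d.depletion_depth,
            production_profile=d.production_profile,
            interactions=d.interactions, bacteriocin=b,
            noise=syn.NoiseSpec(0, 0, 0, 0.1),
        )
        from ommnet.community import compare_dropout

        full = syn.simulate_community(d2, days=5, seed=2, replicates=6)
        drop = syn.simulate_community(d2, days=5, seed=3, replicates=6, dropout="S0")
        fmat = full[full.day == 5].pivot_table(index="strain", columns="replicate",
                                               values="copies")
        dmat = drop[drop.day == 5].pivot_table(index="strain", columns="replicate",
                                               values="copies")
        out = compare_dropout(fmat, dmat, "S0")
        assert out.loc["S1", "direction"] == "increase"
        assert out.loc["S2", "direction"] == "increase"
        assert out.loc["S3", "direction"] == "unchanged"

    def test_slow_strain_washes_out_below_detection(self):
        """mu * 24 h < ln(100) means dilution outpaces regrowth."""
        d = small_decoupled_design([1.5, 0.12], caps=[1.0, 1.0])
        df = syn.simulate_community(d, days=10, seed=1, replicates=1)
        final = df[df.day == 10].set_index("strain")["true_copies"]
        rel = final / final.sum()
        assert rel["S1"] < 1e-4

    def test_unknown_dropout_rejected(self, default_design):
        with pytest.raises(ValueError):
            syn.simulate_community(default_design, days=1, seed=0, dropout="nope")


class TestQpcrSimulation:
    def test_noiseless_round_trip_is_exact(self, default_design):
        curves = syn.default_standard_curves(default_design)
        df = pd.DataFrame(
            {"strain": ["KB1", "YL2"], "copies": [1.0e6, 3.3e4]}
        )
        out = syn.simulate_qpcr(df, curves, cq_sd=0.0, seed=0)
        for _, row in out.iterrows():
            back = quantify_from_cq(row["cq"], curves[row["strain"]]).copies
            assert back == pytest.approx(row["copies"], rel=1e-9)

    def test_direct_cq_evaluation(self):
        curve = syn.StandardCurve("A", slope=-3.5, intercept=38.0)
        df = pd.DataFrame({"strain": ["A"], "copies": [1.0e4]})
        out = syn.simulate_qpcr(df, {"A": curve}, cq_sd=0.0, seed=0)
        assert out.loc[0, "cq"] == pytest.approx(24.0)

    def test_zero_copies_censored(self):
        curve = syn.StandardCurve("A", slope=-3.5, intercept=38.0)
        df = pd.DataFrame({"strain": ["A"], "copies": [0.0]})
        out = syn.simulate_qpcr(df, {"A": curve}, cq_sd=0.1, seed=0)
        assert bool(out.loc[0, "censored"]) and out.loc[0, "cq"] == 40.0
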