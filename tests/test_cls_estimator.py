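"""Constrained least-squares fitting: exactness, optimality, modes."""

import numpy as np
import pytest

import jacquard as jq
from jacquard import cls_estimator as cls
from jacquard import genotype_io as gio
from jacquard import identity_core as ic


def unit(k):
    e = np.zeros(9)
    e[k - 1] = 1.0
    return e


class TestFitPairExact:
    def test_unrelated_input_recovered(self):
        m = ic.build_condensed_matrix(0.3)
        fit = cls.fit_pair(m.m @ unit(9), m)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.theta_hat.as_array(), 0.0, atol=1e-8)

    def test_parent_offspring_theta_recovered(self):
        """delta itself is non-unique but theta = Q delta is invariant."""
        m = ic.build_condensed_matrix(0.3)
        fit = cls.fit_pair(m.m @ unit(8), m)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(
            fit.theta_hat.as_array(), [0.25, 0, 0, 0.5, 0], atol=1e-7
        )

    def test_theta_recovery_over_averaged_systems(self):
        """Noiseless recovery of the identifiable parameters.

        For random true coefficient vectors and random 50-locus
        frequency sets, feeding the exact expected proportions returns
        the true theta to 1e-6, even though the fitted delta generally
        differs from the truth.
        """
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            delta_true = rng.dirichlet(np.ones(9))
            p = rng.uniform(0.01, 0.5, 50)
            mbar = gio.average_system(gio.FrequencyVector(p=p))
            fit = cls.fit_pair(mbar.m @ delta_true, mbar)
            err = np.abs(
                fit.theta_hat.as_array() - ic.Q_MATRIX @ delta_true
            ).max()
            worst = max(worst, err)
        assert worst < 1e-6

    def test_gbar_shape_error(self):
        m = ic.build_condensed_matrix(0.3)
        with pytest.raises(ValueError):
            cls.fit_pair(np.ones(5) / 5, m)


class TestSolverQuality:
    def test_rss_beats_random_simplex_points(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0.05, 0.5, 30)
        mbar = gio.average_system(gio.FrequencyVector(p=p))
        gbar = rng.dirichlet(np.ones(9))  # inconsistent data
        fit = cls.fit_pair(gbar, mbar)
        for _ in range(1000):
            x = rng.dirichlet(np.ones(9))
            r = mbar.m @ x - gbar
            assert fit.rss <= r @ r + 1e-10

    def test_nnls_matches_slsqp(self):
        rng = np.random.default_rng(19)
        mbar = gio.average_system(
            gio.FrequencyVector(p=rng.uniform(0.05, 0.5, 25))
        )
        for _ in range(10):
            gbar = rng.dirichlet(np.ones(9) * 3)
            f1 = cls.fit_pair(gbar, mbar, cls.FitConfig(solver="nnls"))
            f2 = cls.fit_pair(gbar, mbar, cls.FitConfig(solver="slsqp"))
            assert f1.rss == pytest.approx(f2.rss, abs=1e-6)
            assert np.allclose(
                f1.theta_hat.as_array(), f2.theta_hat.as_array(), atol=1e-3
            )

    def test_monotone_constraint_nesting(self):
        """Tighter parameter restrictions never lower the RSS."""
        rng = np.random.default_rng(29)
        mbar = gio.average_system(
            gio.FrequencyVector(p=rng.uniform(0.05, 0.5, 25))
        )
        for _ in range(10):
            gbar = rng.dirichlet(np.ones(9) * 2)
            r_full = cls.fit_pair(gbar, mbar, cls.FitConfig(mode="full9")).rss
            r_red = cls.fit_pair(gbar, mbar, cls.FitConfig(mode="reduced7")).rss
            r_cot = cls.fit_pair(gbar, mbar, cls.FitConfig(mode="cotterman")).rss
            assert r_full <= r_red + 1e-10
            assert r_red <= r_cot + 1e-10


class TestRestrictedModes:
    def test_cotterman_zeroes_inbred_states(self):
        rng = np.random.default_rng(31)
        mbar = gio.average_system(
            gio.FrequencyVector(p=rng.uniform(0.05, 0.5, 25))
        )
        fit = cls.fit_pair(
            rng.dirichlet(np.ones(9)), mbar, cls.FitConfig(mode="cotterman")
        )
        assert np.all(fit.delta_hat[:6] == 0.0)

    def test_unrelated_mode_support(self):
        rng = np.random.default_rng(37)
        mbar = gio.average_system(
            gio.FrequencyVector(p=rng.uniform(0.05, 0.5, 25))
        )
        fit = cls.fit_pair(
            rng.dirichlet(np.ones(9)), mbar, cls.FitConfig(mode="unrelated")
        )
        # related states 1, 3, 5, 7, 8 fixed at zero
        assert np.all(fit.delta_hat[[0, 2, 4, 6, 7]] == 0.0)

    def test_thompson_constraint_vs_grid_oracle(self):
        """Truth violating the feasibility condition is projected onto it.

        The true mixture (Delta7, Delta8, Delta9) = (1/2, 0, 1/2) has
        Delta8^2 < 4 Delta7 Delta9; the constrained fit must satisfy the
        inequality, pay an RSS premium over the unconstrained fit, and
        match a brute-force scan of the constrained region.
        """
        m = ic.build_condensed_matrix(0.3)
        gbar = m.m @ (0.5 * unit(7) + 0.5 * unit(9))
        free = cls.fit_pair(gbar, m, cls.FitConfig(mode="cotterman"))
        con = cls.fit_pair(
            gbar, m, cls.FitConfig(mode="cotterman", thompson_constraint=True)
        )
        d = con.delta_hat
        assert d[7] ** 2 >= 4 * d[6] * d[8] - 1e-8
        assert con.rss >= free.rss - 1e-12
        # brute force over the constrained part of the 3-simplex
        best = np.inf
        A = m.m[:, 6:9]
        for d7 in np.linspace(0, 1, 201):
            for d8 in np.linspace(0, 1 - d7, max(2, int(201 * (1 - d7)) + 1)):
                d9 = 1 - d7 - d8
                if d8 * d8 >= 4 * d7 * d9:
                    r = A @ np.array([d7, d8, d9]) - gbar
                    best = min(best, r @ r)
        assert con.rss <= best + 1e-4

    def test_thompson_requires_cotterman(self):
        with pytest.raises(ValueError):
            cls.FitConfig(mode="full9", thompson_constraint=True)

    def test_reduced_mode_reporting(self):
        rng = np.random.default_rng(41)
        mbar = gio.average_system(
            gio.FrequencyVector(p=rng.uniform(0.05, 0.5, 25))
        )
        fit = cls.fit_pair(
            rng.dirichlet(np.ones(9)), mbar, cls.FitConfig(mode="reduced7")
        )
        d = fit.delta_hat
        assert d[2] == pytest.approx(d[4])  # equal split of merged totals
        assert d[3] == pytest.approx(d[5])
        assert np.isnan(fit.theta_hat.theta2i)
        assert np.isnan(fit.theta_hat.theta4)
        assert np.isfinite(fit.theta_hat.theta1)


class TestFitSelf:
    def test_fully_inbred(self):
        m = ic.build_condensed_matrix(0.5)
        gbar = np.zeros(9)
        gbar[0] = gbar[8] = 0.5  # homozygous everywhere
        fit = cls.fit_self(gbar, m)
        assert fit.delta_hat[0] == pytest.approx(1.0)

    def test_hwe_not_inbred(self):
        m = ic.build_condensed_matrix(0.5)
        gbar = np.zeros(9)
        gbar[0], gbar[4], gbar[8] = 0.25, 0.5, 0.25
        fit = cls.fit_self(gbar, m)
        assert fit.delta_hat[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_is_clipped_projection(self):
        rng = np.random.default_rng(43)
        m = gio.average_system(gio.FrequencyVector(p=rng.uniform(0.05, 0.5, 20)))
        c1, c7 = m.m[:, 0], m.m[:, 6]
        for _ in range(20):
            gbar = np.zeros(9)
            gbar[[0, 4, 8]] = rng.dirichlet(np.ones(3))
            fit = cls.fit_self(gbar, m)
            d = c1 - c7
            alpha_ls = float((gbar - c7) @ d / (d @ d))
            assert fit.delta_hat[0] == pytest.approx(
                np.clip(alpha_ls, 0, 1), abs=1e-12
            )


class TestFitAll:
    def test_field_invariants_and_unrelated_founders(self):
        cfg = jq.SimConfig(
            n_founder_males=2,
            n_founder_females=2,
            n_generations=1,
            L=4000,
            seed=11,
        )
        rng = np.random.default_rng(11)
        ped = jq.generate_pedigree(cfg, rng)
        freqs = jq.draw_founder_frequencies(cfg, rng)
        genomes = jq.gene_drop(ped, freqs, cfg, rng)
        g = genomes.genotype_matrix()
        field = cls.fit_all(g, freqs)
        field.validate(atol=1e-6)
        theta1 = (
            field.deltas[0]
            + 0.5 * (field.deltas[2] + field.deltas[4] + field.deltas[6])
            + 0.25 * field.deltas[7]
        )
        off = ~np.eye(4, dtype=bool)
        assert np.abs(theta1[off]).max() < 0.05  # founders are unrelated

    def test_pairs_subset(self, small_sim):
        g = small_sim["genotypes"]
        freqs = jq.allele_frequencies(g)
        field = cls.fit_all(g, freqs, pairs=[(0, 1)])
        assert field.deltas[:, 0, 1].sum() == pytest.approx(1.0)
        assert field.deltas[:, 2, 3].sum() == 0.0  # untouched pair

    def test_relabeling_equivariance(self):
        cfg = jq.SimConfig(
            n_founder_males=3, n_founder_females=3, n_generations=2, L=500, seed=13
        )
        ped, freqs, genomes, g, gold = jq.simulate_dataset(cfg)
        freqs_est = jq.allele_frequencies(g)
        field = cls.fit_all(g, freqs_est)
        order = np.random.default_rng(1).permutation(g.n_individuals)
        g_perm = gio.GenotypeMatrix(
            dosages=g.dosages[order],
            sample_ids=[g.sample_ids[i] for i in order],
            variant_ids=g.variant_ids,
        )
        field_perm = cls.fit_all(g_perm, freqs_est)
        assert np.allclose(
            field_perm.deltas, field.permute(order).deltas, atol=1e-9
        )
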