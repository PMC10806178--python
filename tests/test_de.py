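"""Unit and property tests for normalization, dispersion and the NB GLM tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import octempo as oc
from octempo.de import _dispersion_given_mu, fit_nb_glm

from conftest import make_count_matrix


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_count_matrix(np.tile([[10], [20], [30]], (1, 4)), [1, 1, 2, 2], [0, 2, 0, 2])
        assert np.allclose(oc.size_factors(cm), 1.0)

    def test_doubled_sample_closed_form(self):
        cm = make_count_matrix(np.array([[10, 20], [20, 40], [30, 60]]), [1, 2], [0, 0])
        sf = oc.size_factors(cm)
        assert np.allclose(sf, [np.sqrt(0.5), np.sqrt(2.0)], atol=1e-4)
        assert np.allclose(sf, [0.7071, 1.4142], atol=1e-4)

    def test_single_sample_is_one(self):
        cm = make_count_matrix(np.array([[5], [9]]), [1], [0])
        assert np.allclose(oc.size_factors(cm), 1.0)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(40, 6)) + 1
        cm = make_count_matrix(counts, [1, 1, 2, 2, 3, 3], [0, 2, 0, 2, 0, 2])
        perm = rng.permutation(40)
        cm_perm = make_count_matrix(counts[perm], [1, 1, 2, 2, 3, 3], [0, 2, 0, 2, 0, 2])
        assert np.allclose(oc.size_factors(cm), oc.size_factors(cm_perm))

    def test_no_all_positive_gene_is_an_error(self):
        cm = make_count_matrix(np.array([[0, 5], [5, 0]]), [1, 2], [0, 0])
        with pytest.raises(ValueError, match="positive"):
            oc.size_factors(cm)

    def test_matches_pydeseq2_median_of_ratios(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.lognormal(4, 1, size=(60, 1)), size=(60, 8)) + 1
        cm = make_count_matrix(counts, [1, 2, 3, 4, 1, 2, 3, 4], [0, 0, 0, 0, 2, 2, 2, 2])
        _, ref = pydeseq2.deseq2_norm(counts.T)
        assert np.allclose(oc.size_factors(cm).to_numpy(), ref, rtol=1e-10)


# ---------------------------------------------------------------------------
# dispersion


class TestDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(200, size=(500, 16))
        cm = make_count_matrix(counts, [i % 8 + 1 for i in range(16)], [0] * 8 + [2] * 8)
        disp = oc.estimate_dispersion(cm, oc.size_factors(cm))
        assert disp["alpha"].median() < 0.01

    def test_nb_dispersion_calibration(self):
        rng = np.random.default_rng(2)
        alpha = 0.1
        mu = rng.lognormal(5, 1, size=(2000, 1))
        counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), size=(2000, 8))
        cm = make_count_matrix(counts, range(1, 9), [0] * 8)
        disp = oc.estimate_dispersion(cm, oc.size_factors(cm))
        assert 0.05 <= disp["alpha"].median() <= 0.2

    def test_constant_counts_floor(self):
        cm = make_count_matrix(np.full((5, 6), 50), [1, 2, 3, 1, 2, 3], [0, 0, 0, 2, 2, 2])
        disp = oc.estimate_dispersion(cm, oc.size_factors(cm))
        assert (disp["alpha"] <= 1e-6).all()

    def test_all_zero_gene_is_low_count(self):
        counts = np.vstack([np.zeros((1, 6), dtype=int), np.full((4, 6), 30)])
        cm = make_count_matrix(counts, [1, 2, 3, 1, 2, 3], [0, 0, 0, 2, 2, 2])
        disp = oc.estimate_dispersion(cm, oc.size_factors(cm))
        assert disp["status"].iloc[0] == "low_count"


# ---------------------------------------------------------------------------
# BH adjustment


class TestBH:
    def test_step_up_examples(self):
        assert np.allclose(oc.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(oc.bh_adjust([0.2]), [0.2])

    def test_na_excluded_from_m(self):
        out = oc.bh_adjust([np.nan, 0.05])
        assert np.isnan(out[0]) and out[1] == 0.05

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            oc.bh_adjust([0.5, 1.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_properties(self, pvals):
        adj = oc.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1 + 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order


# ---------------------------------------------------------------------------
# fold change


class TestLog2FC:
    def test_identical_groups_zero(self):
        cm = make_count_matrix(np.tile([[10], [30]], (1, 4)), [1, 2, 1, 2], [0, 0, 9, 9])
        sf = oc.size_factors(cm)
        assert np.allclose(oc.log2fc(cm, sf, 0, 9), 0.0)

    def test_pseudocount_arithmetic(self):
        counts = np.array([[10, 10, 40, 40], [7, 7, 7, 7]])
        cm = make_count_matrix(counts, [1, 2, 1, 2], [0, 0, 9, 9])
        sf = pd.Series(1.0, index=cm.samples)
        fc = oc.log2fc(cm, sf, 0, 9)
        assert np.isclose(fc.iloc[0], np.log2(41 / 11), atol=1e-10)
        assert np.isclose(fc.iloc[0], 1.898, atol=1e-3)

    def test_all_zero_gene_zero(self):
        counts = np.array([[0, 0, 0, 0], [9, 9, 9, 9]])
        cm = make_count_matrix(counts, [1, 2, 1, 2], [0, 0, 9, 9])
        assert oc.log2fc(cm, oc.size_factors(cm), 0, 9).iloc[0] == 0.0

    def test_unknown_day_rejected(self):
        cm = make_count_matrix(np.full((2, 4), 8), [1, 2, 1, 2], [0, 0, 9, 9])
        with pytest.raises(ValueError, match="day"):
            oc.log2fc(cm, oc.size_factors(cm), 0, 5)


# ---------------------------------------------------------------------------
# timepoint LRT


class TestLRT:
    def test_planted_genes_recovered(self, planted_world):
        _, cm, truth = planted_world
        sf = oc.size_factors(cm)
        disp = oc.estimate_dispersion(cm, sf)
        res = oc.lrt_timepoint(cm, sf, disp)
        signal = (truth["archetype"] != "null") & truth["donor_consistent"]
        assert res.loc[signal, "de"].mean() >= 0.95
        assert res.loc[truth["archetype"] == "null", "de"].mean() <= 0.001

    def test_donor_only_signal_is_null(self):
        # counts constant across timepoints within each donor: LRT ~ 0
        donor_level = np.array([50, 100, 200, 400])
        counts = np.tile(np.repeat(donor_level, 3)[None, :], (5, 1))
        cm = make_count_matrix(
            counts, np.repeat([1, 2, 3, 4], 3), list(np.tile([0, 2, 5], 4))
        )
        sf = pd.Series(1.0, index=cm.samples)
        disp = oc.estimate_dispersion(cm, sf)
        res = oc.lrt_timepoint(cm, sf, disp)
        assert (res["stat"] < 1e-4).all()
        assert (res["pvalue"] > 0.999).all()

    def test_scaled_sample_counts_scale_its_size_factor(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(50, 12))
        donors = np.repeat([1, 2, 3], 4)
        days = np.tile([0, 2, 5, 9], 3)
        sf1 = oc.size_factors(make_count_matrix(counts, donors, days))
        scaled = counts.copy()
        scaled[:, 0] *= 3
        sf2 = oc.size_factors(make_count_matrix(scaled, donors, days))
        # relative to the other samples the scaled sample's factor triples
        ratio = (sf2 / sf1).to_numpy()
        assert np.allclose(ratio[0] / ratio[1:], 3.0, rtol=1e-10)

    def test_size_factor_rescaling_leaves_statistics_unchanged(self):
        # a common factor in the size factors is absorbed by the model
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(50, 12))
        donors = np.repeat([1, 2, 3], 4)
        days = np.tile([0, 2, 5, 9], 3)
        cm = make_count_matrix(counts, donors, days)
        sf = oc.size_factors(cm)
        disp = oc.estimate_dispersion(cm, sf)
        r1 = oc.lrt_timepoint(cm, sf, disp)
        r2 = oc.lrt_timepoint(cm, sf * 7.5, disp)
        assert np.allclose(r1["stat"], r2["stat"], atol=1e-6)
        assert np.allclose(r1["pvalue"], r2["pvalue"], atol=1e-6)

    def test_poisson_lrt_matches_brute_force_likelihood(self):
        """IRLS deviance difference vs direct likelihood maximization (alpha=0)."""
        rng = np.random.default_rng(8)
        counts = rng.poisson([40, 80, 60, 120, 55, 110, 70, 140], size=(3, 8)).astype(float)
        donors = np.repeat([0, 1], 4)
        X_red = np.eye(2)[donors]
        X_full = np.hstack([X_red, np.tile(np.eye(2)[[0, 1, 0, 1]], (2, 1))[:, 1:]])
        offset = np.zeros(8)

        def neg_ll(beta, X, y):
            mu = np.exp(X @ beta)
            return -np.sum(y * np.log(mu) - mu)

        for g in range(3):
            y = counts[g]
            stats_irls = []
            for X in (X_full, X_red):
                fit = fit_nb_glm(y[None, :], X, offset, np.array([0.0]))
                stats_irls.append(fit["deviance"][0])
            lrt_irls = stats_irls[1] - stats_irls[0]
            lls = []
            for X in (X_full, X_red):
                res = optimize.minimize(
                    neg_ll, np.zeros(X.shape[1]) + 3, args=(X, y), method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
                )
                lls.append(-res.fun)
            lrt_direct = 2 * (lls[0] - lls[1])
            assert abs(lrt_irls - lrt_direct) < 1e-4


# ---------------------------------------------------------------------------
# phenotype association


class TestPhenotypeAssociation:
    def _world(self, seed=5):
        cfg = oc.SimulationConfig(
            n_genes=1000, n_donors=8, frac_null=1.0, effect_log2fc=0.0,
            frac_discordant=0.0, seed=seed,
        )
        return oc.generate_timecourse(cfg)

    def test_planted_signature_recovered(self):
        cm, _ = self._world()
        signature = list(cm.genes[:50])
        cm2, pheno = oc.generate_phenotype(cm, signature, slope_log2_per_unit=3.0, seed=6)
        sub = cm2.subset_samples(cm2.design.index[cm2.design["day"] == 9])
        sf = oc.size_factors(cm2)
        res = oc.phenotype_association(sub, sf.loc[sub.samples], None, pheno)
        assert res.loc[signature, "associated"].mean() >= 0.8

    def test_null_world_false_positives_bounded(self):
        total = 0
        n_runs, m = 50, 300
        for s in range(n_runs):
            cfg = oc.SimulationConfig(
                n_genes=m, n_donors=8, frac_null=1.0, effect_log2fc=0.0,
                frac_discordant=0.0, seed=200 + s,
            )
            cm, _ = oc.generate_timecourse(cfg)
            sub = cm.subset_samples(cm.design.index[cm.design["day"] == 9])
            sf = oc.size_factors(cm)
            pheno = pd.Series(
                np.random.default_rng(s).uniform(0, 1, 8), index=pd.unique(cm.design["donor"])
            )
            res = oc.phenotype_association(sub, sf.loc[sub.samples], None, pheno)
            total += int(res["associated"].sum())
        assert total / n_runs <= 0.01 * m

    def test_constant_phenotype_refused(self):
        cm, _ = self._world()
        sub = cm.subset_samples(cm.design.index[cm.design["day"] == 9])
        sf = oc.size_factors(cm)
        pheno = pd.Series(0.5, index=pd.unique(cm.design["donor"]))
        with pytest.raises(ValueError, match="constant"):
            oc.phenotype_association(sub, sf.loc[sub.samples], None, pheno)

    def test_missing_donor_refused(self):
        cm, _ = self._world()
        sub = cm.subset_samples(cm.design.index[cm.design["day"] == 9])
        sf = oc.size_factors(cm)
        donors = pd.unique(cm.design["donor"])
        pheno = pd.Series(np.linspace(0, 1, len(donors) - 1), index=donors[:-1])
        with pytest.raises(ValueError, match="missing"):
            oc.phenotype_association(sub, sf.loc[sub.samples], None, pheno)

    def test_residual_dispersion_estimator_consistent(self):
        rng = np.random.default_rng(9)
        mu = np.full((300, 16), 300.0)
        alpha = 0.08
        Y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * 300), size=(300, 16)).astype(float)
        est = _dispersion_given_mu(Y, np.full_like(Y, Y.mean(axis=1, keepdims=True)), 1)
        assert 0.04 <= np.median(est) <= 0.16
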