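"""Unit and property tests for the admixture-proportion MLE machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixpheno.ancestry import (
    MISSING,
    AIMPanel,
    GenotypeMatrix,
    PanelValidationError,
    _grid_loglik_matrix,
    clamp_frequencies,
    estimate_ancestry,
    estimate_cohort,
    fisher_se,
    genotype_prob,
    loglik,
    posterior_mean_ancestry,
    select_aims,
)
from admixpheno.simulate import simulate_genotypes, simulate_panel, simulate_true_pea


def make_panel(p_afr, p_eur, eps=0.001):
    p_afr = np.atleast_1d(np.asarray(p_afr, dtype=float))
    n = len(p_afr)
    return AIMPanel(
        np.array([f"m{i}" for i in range(n)], dtype=object),
        np.array(["A"] * n, dtype=object),
        p_afr, np.atleast_1d(np.asarray(p_eur, dtype=float)), eps=eps,
    )


class TestClampAndSelect:
    @pytest.mark.parametrize("p, eps, expected", [
        (0.0, 0.001, 0.001),
        (0.5, 0.001, 0.5),
        (1.0, 0.01, 0.99),
    ])
    def test_clamp_moves_frequencies_into_open_interval(self, p, eps, expected):
        panel = make_panel([p], [0.5])
        out = clamp_frequencies(panel, eps)
        assert out.p_afr[0] == pytest.approx(expected)
        assert out.p_eur[0] == pytest.approx(0.5)

    def test_out_of_range_frequency_names_marker(self):
        with pytest.raises(PanelValidationError, match="m1"):
            make_panel([0.1, 1.2], [0.5, 0.5])

    def test_select_threshold(self):
        panel = make_panel([0.6, 0.4, 0.5], [0.1, 0.2, 0.15])
        sel = select_aims(panel, 0.3)
        assert list(sel.marker_id) == ["m0", "m2"]
        assert select_aims(panel, 0.0).n_markers == 3

    def test_select_empty_is_error(self):
        panel = make_panel([0.5], [0.5])
        with pytest.raises(PanelValidationError, match="no informative"):
            select_aims(panel, 0.2)

    def test_select_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        pa, pe = rng.uniform(0.01, 0.99, (2, 1000))
        panel = make_panel(pa, pe)
        sel = select_aims(panel, 0.4)
        expected = [f"m{i}" for i in range(1000) if abs(pa[i] - pe[i]) >= 0.4]
        assert list(sel.marker_id) == expected


class TestGenotypeProb:
    @pytest.mark.parametrize("g, p1, p2, s, expected", [
        (1, 0.1, 0.9, 0.5, 0.5),        # p(s)=0.5, 2*0.5*0.5
        (2, 0.3, 0.3, 0.7, 0.09),       # s-invariant when p1=p2
        (2, 0.3, 0.3, 0.1, 0.09),
        (0, 0.1, 0.9, 1.0, 0.01),       # (1-0.9)^2
    ])
    def test_hardy_weinberg_values(self, g, p1, p2, s, expected):
        assert genotype_prob(g, p1, p2, s) == pytest.approx(expected)

    def test_missing_dosage_signals_skip(self):
        with pytest.raises(ValueError, match="skip"):
            genotype_prob(MISSING, 0.1, 0.9, 0.5)

    @settings(max_examples=200, deadline=None)
    @given(p1=st.floats(0.001, 0.999), p2=st.floats(0.001, 0.999),
           s=st.floats(0.0, 1.0))
    def test_probabilities_sum_to_one(self, p1, p2, s):
        total = sum(genotype_prob(g, p1, p2, s) for g in (0, 1, 2))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLoglik:
    def test_additive_over_loci(self):
        panel2 = make_panel([0.1, 0.3], [0.8, 0.7])
        g = np.array([2, 1])
        parts = [loglik(np.array([g[i], MISSING] if i == 0 else [MISSING, g[i]]),
                        panel2, 0.4) for i in range(2)]
        assert loglik(g, panel2, 0.4) == pytest.approx(sum(parts), abs=1e-12)

    def test_flat_when_frequencies_equal(self):
        panel = make_panel([0.3, 0.6], [0.3, 0.6])
        g = np.array([1, 2])
        vals = [loglik(g, panel, s) for s in (0.0, 0.25, 0.9)]
        assert np.ptp(vals) < 1e-12

    def test_matches_product_then_log_enumeration(self, tiny_panel):
        g = np.array([2, 1, 0, 2, 1])
        s = 0.3
        prod = 1.0
        for gi, pa, pe in zip(g, tiny_panel.p_afr, tiny_panel.p_eur):
            prod *= genotype_prob(int(gi), pa, pe, s)
        assert loglik(g, tiny_panel, s) == pytest.approx(np.log(prod), abs=1e-12)

    def test_all_missing_is_error(self, tiny_panel):
        with pytest.raises(ValueError, match="non-missing"):
            loglik(np.full(5, MISSING), tiny_panel, 0.5)

    def test_nonpositive(self, tiny_panel):
        assert loglik(np.array([2, 1, 0, 2, 1]), tiny_panel, 0.3) <= 0


class TestEstimateAncestry:
    def test_single_heterozygote_maximized_at_half(self):
        panel = make_panel([0.1], [0.9])
        est = estimate_ancestry(np.array([1]), panel)
        assert est.s_hat == pytest.approx(0.5, abs=1e-6)

    def test_boundary_mle_for_european_homozygote(self):
        panel = make_panel([0.01] * 20, [0.99] * 20)
        est = estimate_ancestry(np.full(20, 2), panel)
        assert est.s_hat == 1.0
        assert "boundary" in est.flags
        assert np.isnan(est.se)

    def test_flat_likelihood_flagged(self):
        panel = make_panel([0.3, 0.5], [0.3, 0.5])
        est = estimate_ancestry(np.array([1, 2]), panel)
        assert est.s_hat == 0.5
        assert "non-identifiable" in est.flags

    def test_matches_dense_grid_argmax(self, sim_panel, sim_cohort):
        """MLE within 1e-4 of a 10,000-point exhaustive grid search."""
        s_true, gm = sim_cohort
        sub = gm.dosage[:120]
        grid = np.linspace(0, 1, 10_001)
        ll = _grid_loglik_matrix(sub, sim_panel, grid)
        grid_argmax = grid[np.argmax(ll, axis=1)]
        mle = np.array([estimate_ancestry(sub[i], sim_panel).s_hat
                        for i in range(len(sub))])
        assert np.max(np.abs(mle - grid_argmax)) < 1e-4

    def test_population_swap_symmetry(self, tiny_panel):
        g = np.array([2, 1, 0, 1, 2])
        swapped = AIMPanel(tiny_panel.marker_id, tiny_panel.counted_allele,
                           tiny_panel.p_eur, tiny_panel.p_afr)
        s1 = estimate_ancestry(g, tiny_panel).s_hat
        s2 = estimate_ancestry(g, swapped).s_hat
        assert s1 == pytest.approx(1.0 - s2, abs=1e-5)


class TestPosteriorMean:
    def test_flat_likelihood_gives_half(self):
        panel = make_panel([0.4], [0.4])
        assert posterior_mean_ancestry(np.array([2]), panel) == pytest.approx(0.5)

    def test_three_point_grid_hand_computation(self):
        # single het locus, p_afr=0.2, p_eur=0.8: L(0)=L(1)=0.32, L(0.5)=0.5
        panel = make_panel([0.2], [0.8])
        got = posterior_mean_ancestry(np.array([1]), panel, grid_n=3)
        s = np.array([0.0, 0.5, 1.0])
        L = np.array([0.32, 0.5, 0.32])
        expected = np.trapezoid(L * s, s) / np.trapezoid(L, s)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_mle_on_dense_panels(self, sim_panel, sim_cohort):
        """Cross-estimator agreement: r > 0.99 on an informative panel."""
        s_true, gm = sim_cohort
        n = 150
        mle = np.array([estimate_ancestry(gm.dosage[i], sim_panel).s_hat
                        for i in range(n)])
        pm = np.array([posterior_mean_ancestry(gm.dosage[i], sim_panel)
                       for i in range(n)])
        assert np.corrcoef(mle, pm)[0, 1] > 0.99


class TestEstimateCohort:
    def test_drops_individuals_below_min_markers(self, tiny_panel):
        dosage = np.array([[2, 1, 0, 2, 1],
                           [MISSING] * 5,
                           [1, 1, MISSING, 0, 2]])
        gm = GenotypeMatrix(np.array(["a", "b", "c"], dtype=object), dosage,
                            tiny_panel.marker_id)
        ests, dropped = estimate_cohort(gm, tiny_panel, min_markers=1)
        assert len(ests) == 2
        assert list(dropped["individual_id"]) == ["b"]

    def test_duplicate_individuals_get_identical_estimates(self, tiny_panel):
        row = np.array([2, 1, 0, 2, 1])
        gm = GenotypeMatrix(np.array(["a", "b"], dtype=object),
                            np.vstack([row, row]), tiny_panel.marker_id)
        ests, _ = estimate_cohort(gm, tiny_panel)
        assert ests[0].s_hat == ests[1].s_hat

    def test_empty_cohort_is_error(self, tiny_panel):
        gm = GenotypeMatrix(np.array([], dtype=object),
                            np.empty((0, 5), dtype=np.int8),
                            tiny_panel.marker_id)
        with pytest.raises(ValueError, match="empty"):
            estimate_cohort(gm, tiny_panel)

    def test_efficiency_close_to_fisher_bound(self, sim_panel, sim_cohort):
        """RMSE within 1.2x the mean information-bound SE at the truth."""
        s_true, gm = sim_cohort
        ests, _ = estimate_cohort(gm, sim_panel)
        s_hat = np.array([e.s_hat for e in ests])
        rmse = np.sqrt(np.mean((s_hat - s_true) ** 2))
        assert rmse <= 1.2 * fisher_se(sim_panel, s_true).mean()

    def test_rmse_decreases_with_marker_count(self):
        """Paired simulation: more markers, no worse recovery."""
        s = simulate_true_pea(200, seed=7)
        rmses = []
        big = simulate_panel(1000, 0.4, seed=8)
        gm = simulate_genotypes(big, s, seed=9)
        for m in (50, 200, 1000):
            panel_m = AIMPanel(big.marker_id[:m], big.counted_allele[:m],
                               big.p_afr[:m], big.p_eur[:m])
            gsub = GenotypeMatrix(gm.individual_id, gm.dosage[:, :m],
                                  big.marker_id[:m])
            ests, _ = estimate_cohort(gsub, panel_m)
            rmses.append(np.sqrt(np.mean(
                (np.array([e.s_hat for e in ests]) - s) ** 2)))
        # allow a sliver of Monte-Carlo noise on each comparison
        assert rmses[1] <= rmses[0] + 0.005
        assert rmses[2] <= rmses[1] + 0.005
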