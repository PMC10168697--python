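"""Bounded power-law (MLEbin) size-spectrum estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatfish import size_spectrum as ss


class TestBinProbabilities:
    def test_uniform_density_proportional_to_width(self):
        p = ss.plb_bin_probabilities(0.0, np.array([1.0, 2.0, 4.0]), 1.0, 4.0)
        assert np.allclose(p, [1 / 3, 2 / 3])

    def test_inverse_square_hand_integration(self):
        # integral of x^-2: [1,2] -> 1/2, [2,4] -> 1/4; normalized over [1,4]
        p = ss.plb_bin_probabilities(-2.0, np.array([1.0, 2.0, 4.0]), 1.0, 4.0)
        assert np.allclose(p, [2 / 3, 1 / 3])

    def test_b_minus_one_log_form(self):
        p = ss.plb_bin_probabilities(-1.0, np.array([1.0, 2.0, 4.0]), 1.0, 4.0)
        assert np.allclose(p, [0.5, 0.5])

    @given(
        b=st.floats(-4.0, 2.0),
        split=st.floats(0.1, 0.9),
        xmax=st.floats(5.0, 500.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one(self, b, split, xmax):
        xmin = 1.0
        mid = xmin + split * (xmax - xmin)
        edges = np.array([xmin, mid, 0.5 * (mid + xmax), xmax])
        p = ss.plb_bin_probabilities(b, edges, xmin, xmax)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            ss.plb_bin_probabilities(-2.0, np.array([1.0, 2.0]), 0.0, 2.0)
        with pytest.raises(ValueError):
            ss.plb_bin_probabilities(-2.0, np.array([1.0, 5.0]), 1.0, 2.0)


class TestMlebinFit:
    def test_counts_200_100_give_minus_two(self):
        """Observed proportions (2/3, 1/3) on edges (1,2,4) equal the PLB
        proportions at b = -2 exactly, so the MLE is -2."""
        binned = ss.BinnedSizes(np.array([1.0, 2.0, 4.0]), np.array([200.0, 100.0]))
        fit = ss.mlebin_fit(binned)
        assert fit.gamma_hat == pytest.approx(-2.0, abs=1e-3)
        assert fit.ci95[0] < -2.0 < fit.ci95[1]

    def test_counts_proportional_to_width_give_zero(self):
        binned = ss.BinnedSizes(
            np.array([1.0, 2.0, 4.0, 8.0]), np.array([10.0, 20.0, 40.0])
        )
        fit = ss.mlebin_fit(binned)
        assert fit.gamma_hat == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_grid(self, rng):
        """Optimizer agrees with a 1e-3 grid search on random instances."""
        for _ in range(25):
            n_bins = rng.integers(3, 8)
            edges = np.cumsum(rng.uniform(0.5, 3.0, size=n_bins + 1))
            counts = rng.integers(1, 500, size=n_bins).astype(float)
            binned = ss.BinnedSizes(edges, counts)
            fit = ss.mlebin_fit(binned)
            grid = np.arange(-8.0, 4.0, 1e-3)
            lls = np.array(
                [ss.plb_loglik(b, binned, edges[0], edges[-1]) for b in grid]
            )
            b_grid = grid[np.argmax(lls)]
            assert fit.gamma_hat == pytest.approx(b_grid, abs=2e-3)

    def test_simulated_plb_recovery(self, rng):
        """Draws from a bounded power law, binned coarsely, recover b."""
        x = ss.draw_plb(rng, 10_000, b=-2.0, xmin=1.0, xmax=100.0)
        edges = np.arange(1.0, 101.0, 2.5)
        edges = np.append(edges, 100.0) if edges[-1] < 100 else edges
        counts, _ = np.histogram(x, bins=edges)
        fit = ss.mlebin_fit(ss.BinnedSizes(edges, counts.astype(float)))
        assert fit.ci95[0] <= -2.0 <= fit.ci95[1] or abs(fit.gamma_hat + 2.0) < 0.1
        assert abs(fit.gamma_hat + 2.0) < 0.1

    def test_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n in (500, 50_000):
            x = ss.draw_plb(rng, n, b=-2.0, xmin=1.0, xmax=50.0)
            edges = np.linspace(1.0, 50.0, 15)
            counts, _ = np.histogram(x, bins=edges)
            fit = ss.mlebin_fit(ss.BinnedSizes(edges, counts.astype(float)))
            widths.append(fit.ci95[1] - fit.ci95[0])
        assert widths[1] < widths[0]

    def test_single_nonempty_bin_raises(self):
        binned = ss.BinnedSizes(np.array([1.0, 2.0, 4.0]), np.array([50.0, 0.0]))
        with pytest.raises(ValueError, match="nonempty"):
            ss.mlebin_fit(binned)


class TestLengthMassConversion:
    def test_identity_when_linear(self):
        edges = np.array([1.0, 2.0, 3.0])
        assert np.allclose(ss.lengths_to_mass_bins(edges, 1.0, 1.0), edges)

    def test_cubic_hand_value(self):
        out = ss.lengths_to_mass_bins(np.array([10.0, 12.5]), 0.01, 3.0)
        assert out[0] == pytest.approx(10.0)
        assert out[1] == pytest.approx(19.53, abs=0.01)

    @given(lw_b=st.floats(0.5, 4.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone(self, lw_b):
        edges = np.array([2.0, 5.0, 9.0, 20.0])
        out = ss.lengths_to_mass_bins(edges, 0.02, lw_b)
        assert np.all(np.diff(out) > 0)


class TestRebinning:
    def test_1cm_to_2p5cm_conserves_total(self, rng):
        lowers = np.arange(5.0, 40.0, 1.0)
        counts = rng.uniform(0, 50, size=lowers.size)
        new_lowers, new_counts = ss.rebin_1cm_to_2p5cm(lowers, counts)
        assert new_counts.sum() == pytest.approx(counts.sum(), rel=1e-12)
        assert np.all(new_lowers % 2.5 == 0)

    def test_overlap_split_proportional(self):
        # the 1 cm class [2, 3) straddles 2.5: half a unit to each 2.5 class
        lowers, counts = ss.rebin_1cm_to_2p5cm(np.array([2.0]), np.array([10.0]))
        assert lowers.tolist() == [0.0, 2.5]
        assert np.allclose(counts, [5.0, 5.0])
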