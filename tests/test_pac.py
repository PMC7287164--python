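"""Mean-vector-length PAC: normalization, MVL oracle, surrogates, z-scoring,
comodulograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assrpac.pac import (
    ComodulogramEngine,
    PacParams,
    comodulogram_pair,
    minmax_normalize,
    mvl_pac,
    surrogate_pac,
    z_score_pac,
)
from assrpac.synth import TrialEnsemble
from assrpac.timefreq import WaveletParams, morlet_transform

# 4 trials x 2 samples, complex mean per sample then time average,
# worked out by hand with the brute-force per-sample complex arithmetic
HAND_A = np.array([[1, 0.5], [0.2, 1], [0.8, 0.3], [0.4, 0.9]])
HAND_PHI = np.array(
    [[0, np.pi / 2], [np.pi, 0], [np.pi / 2, np.pi], [0, 3 * np.pi / 2]]
)
HAND_MVL = 0.28105578562693134


def brute_force_mvl(phase, amp):
    per_sample = []
    for s in range(phase.shape[1]):
        z = 0j
        for t in range(phase.shape[0]):
            z += amp[t, s] * np.exp(1j * phase[t, s])
        per_sample.append(abs(z / phase.shape[0]))
    return float(np.mean(per_sample))


class TestMinmaxNormalize:
    def test_series_spanning_unit_interval_unchanged(self):
        x = np.linspace(0, 1, 50)[None, :]
        mask = np.ones(50, bool)
        assert np.allclose(minmax_normalize(x, mask), x)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal((3, 100))
        mask = np.ones(100, bool)
        assert np.allclose(
            minmax_normalize(7.0 * x - 3.0, mask), minmax_normalize(x, mask)
        )

    def test_constant_series_zeros_with_warning(self):
        x = np.full((1, 40), 2.0)
        with pytest.warns(RuntimeWarning, match="constant"):
            out = minmax_normalize(x, np.ones(40, bool))
        assert np.allclose(out, 0.0)

    def test_window_restricted_extrema(self):
        x = np.concatenate([np.linspace(0, 1, 50), [5.0]])[None, :]
        mask = np.zeros(51, bool)
        mask[:50] = True
        out = minmax_normalize(x, mask)
        assert out[0, :50].max() == pytest.approx(1.0)
        assert out[0, 50] == pytest.approx(5.0)  # outside window may exceed 1


class TestMvl:
    def test_aligned_unit_vectors(self):
        phase = np.zeros((4, 10))
        amp = np.ones((4, 10))
        assert mvl_pac(phase, amp) == pytest.approx(1.0)

    def test_balanced_phases_cancel(self):
        n = 6
        phase = np.tile((2 * np.pi * np.arange(n) / n)[:, None], (1, 5))
        assert mvl_pac(phase, np.ones((n, 5))) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fixture(self):
        assert mvl_pac(HAND_PHI, HAND_A) == pytest.approx(HAND_MVL, abs=1e-14)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(50):
            n, s = rng.integers(2, 12), rng.integers(1, 20)
            phase = rng.uniform(-np.pi, np.pi, (n, s))
            amp = rng.uniform(0, 2, (n, s))
            assert mvl_pac(phase, amp) == pytest.approx(
                brute_force_mvl(phase, amp), abs=1e-12
            )

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_modulus_homogeneity(self, c):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, (5, 8))
        amp = rng.uniform(0, 1, (5, 8))
        assert mvl_pac(phase, c * amp) == pytest.approx(c * mvl_pac(phase, amp))

    def test_single_trial_errors(self):
        with pytest.raises(ValueError, match="2 trials"):
            mvl_pac(np.zeros((1, 5)), np.ones((1, 5)))


class TestZScore:
    def test_observed_at_mean_is_zero(self, rng):
        s = rng.uniform(0, 1, 250)
        assert z_score_pac(s.mean(), s) == pytest.approx(0.0)

    def test_two_sd_above(self, rng):
        s = rng.uniform(0, 1, 250)
        obs = s.mean() + 2 * s.std(ddof=1)
        assert z_score_pac(obs, s) == pytest.approx(2.0)

    def test_degenerate_surrogates_error(self):
        with pytest.raises(ValueError, match="sd"):
            z_score_pac(0.5, np.full(10, 0.25))


class TestSurrogates:
    def test_deterministic_from_seed(self, tiny_ensemble):
        mask = np.zeros(tiny_ensemble.n_times, bool)
        mask[300:500] = True
        amp = np.abs(np.random.default_rng(0).standard_normal((8, tiny_ensemble.n_times)))
        kw = dict(n_surrogates=8, seed=42)
        a = surrogate_pac(tiny_ensemble.data, amp, 6.0, 250.0, mask, **kw)
        b = surrogate_pac(tiny_ensemble.data, amp, 6.0, 250.0, mask, **kw)
        assert np.array_equal(a, b)
        assert np.all(a > 0)  # MVL is a modulus

    def test_segment_swap_preserves_spectrum_and_values(self, rng):
        from assrpac.pac import _segment_shuffle

        x = rng.standard_normal((3, 500))
        cuts = np.array([100, 250, 399])
        out = _segment_shuffle(x, cuts, rng, 2)
        for tr in range(3):
            assert np.allclose(np.sort(out[tr]), np.sort(x[tr]))
            # swap == circular shift -> power spectrum exactly preserved
            assert np.allclose(
                np.abs(np.fft.rfft(out[tr])), np.abs(np.fft.rfft(x[tr])), atol=1e-9
            )

    def test_short_window_errors(self, tiny_ensemble):
        mask = np.zeros(tiny_ensemble.n_times, bool)
        mask[300:302] = True
        with pytest.raises(ValueError, match="3 samples"):
            surrogate_pac(
                tiny_ensemble.data, np.ones_like(tiny_ensemble.data), 6.0, 250.0, mask
            )


class TestComodulogram:
    def _params(self, n_surrogates=30):
        return PacParams(
            phase_freqs_hz=np.array([5.0, 6.0, 7.0]),
            amp_freqs_hz=np.array([30.0, 40.0, 50.0]),
            n_surrogates=n_surrogates,
            seed=0,
        )

    def test_engine_raw_matches_public_mvl(self, coupled_ensemble):
        params = self._params()
        eng = ComodulogramEngine(coupled_ensemble, params)
        c = eng.compute("stimulus")
        win = np.zeros(coupled_ensemble.n_times, bool)
        idx = coupled_ensemble.window_indices(params.stim_window_s)
        win[idx] = True
        i, j = 1, 1  # (6 Hz, 40 Hz)
        manual = mvl_pac(
            np.angle(eng.unit_phase[i]), eng.norm_amp[j].astype(float), win
        )
        assert c.raw_mvl[i, j] == pytest.approx(manual, rel=1e-5)

    def test_circular_engine_agrees_with_literal_retransform(self, coupled_ensemble):
        """Shift-trick surrogates and literal re-transform surrogates give
        statistically indistinguishable z-grids on the same ensemble."""
        params = self._params(n_surrogates=60)
        fast = ComodulogramEngine(coupled_ensemble, params, transform="circular").compute(
            "stimulus"
        )
        slow = ComodulogramEngine(coupled_ensemble, params, transform="linear").compute(
            "stimulus"
        )
        # raw MVL: same statistic up to edge handling of the transform
        assert np.allclose(fast.raw_mvl, slow.raw_mvl, rtol=0.05)
        # strong coupling cell detected by both routes
        assert fast.values[1, 1] > 3.0
        assert slow.values[1, 1] > 3.0

    def test_true_cell_dominates_off_frequency_cells(self, coupled_ensemble):
        # strong z at the (6, 40) truth; fA cells 10 Hz away stay near null
        c = ComodulogramEngine(coupled_ensemble, self._params()).compute("stimulus")
        assert c.values[1, 1] > 3.0
        assert np.all(c.values[:, [0, 2]] < 2.0)

    def test_baseline_window_is_null_for_stimulus_coupling(self, coupled_ensemble):
        stim, base = comodulogram_pair(coupled_ensemble, self._params())
        assert stim.values[1, 1] > 3.0
        assert abs(base.values[1, 1]) < 3.0

    def test_same_seed_reproducible(self, coupled_ensemble):
        params = self._params()
        a = ComodulogramEngine(coupled_ensemble, params).compute("stimulus", seed=5)
        b = ComodulogramEngine(coupled_ensemble, params).compute("stimulus", seed=5)
        assert np.array_equal(a.values, b.values)

    def test_argmax_cell_reports_frequencies(self, coupled_ensemble):
        c = ComodulogramEngine(coupled_ensemble, self._params()).compute("stimulus")
        fp, fa = c.argmax_cell()
        assert fp in (5.0, 6.0, 7.0) and fa in (30.0, 40.0, 50.0)
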