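"""Band-pass filtering, analytic signal, MVL coupling, power residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetanav.coupling import (
    ZeroAmplitudeError,
    _analytic_bandpassed,
    analytic_signal,
    bandpass_zero_phase,
    mvl_pac,
    notch_zero_phase,
    pac_table,
    residualize_pac,
)
from thetanav.signals import EpochSet, SignalParams, generate_epoch


FS = 600.0


def sinusoid(freq, duration=20.0, fs=FS, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


@pytest.mark.parametrize("family", ["fir", "butterworth"])
@pytest.mark.parametrize("band,f_in", [((2.0, 5.0), 3.5), ((30.0, 70.0), 50.0)])
def test_passband_preserves_amplitude_and_phase(family, band, f_in):
    x = sinusoid(f_in)
    y, mask = bandpass_zero_phase(x[None, :], band, FS, family=family)
    seg = slice(*np.flatnonzero(mask)[[0, -1]])
    amp = np.abs(analytic_signal(y)[1][0, seg]).mean()
    assert amp == pytest.approx(1.0, abs=0.05)
    # zero net phase: filtered output aligns with the input sample-for-sample
    r = np.corrcoef(x[seg], y[0, seg])[0, 1]
    assert r > 0.999


@pytest.mark.parametrize("band,f_out", [((2.0, 5.0), 1.0), ((30.0, 70.0), 15.0)])
def test_stopband_attenuation_one_octave_out(band, f_out):
    """An octave outside the band the forward-backward FIR attenuates >= 40 dB."""
    x = sinusoid(f_out, duration=40.0)
    y, mask = bandpass_zero_phase(x[None, :], band, FS, family="fir")
    ratio = np.sqrt(np.mean(y[0, mask] ** 2) / np.mean(x[mask] ** 2))
    assert 20 * np.log10(ratio) < -40.0


def test_disjoint_passbands_decorrelate_white_noise(rng):
    x = rng.standard_normal((1, 24000))
    lo, m1 = bandpass_zero_phase(x, (2.0, 5.0), FS)
    hi, m2 = bandpass_zero_phase(x, (30.0, 70.0), FS)
    mask = m1 & m2
    r = np.corrcoef(lo[0, mask], hi[0, mask])[0, 1]
    assert abs(r) < 0.05


def test_bandpass_input_validation():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_zero_phase(np.zeros((1, 6000)), (2.0, 400.0), FS)
    with pytest.raises(ValueError, match="filter lengths"):
        bandpass_zero_phase(np.zeros((1, 600)), (2.0, 5.0), FS)


def test_analytic_signal_recovers_phase_and_envelope():
    t = np.arange(0, 10.0, 1 / FS)
    x = np.sin(2 * np.pi * 4.0 * t)
    phase, amp = analytic_signal(x[None, :])
    mid = slice(600, 5400)
    assert np.allclose(amp[0, mid], 1.0, atol=0.01)
    dphi = np.diff(np.unwrap(phase[0, mid]))
    assert dphi.mean() * FS == pytest.approx(2 * np.pi * 4.0, rel=1e-3)

    # slow amplitude modulation is tracked by the envelope
    a_t = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
    phase, amp = analytic_signal((a_t * np.sin(2 * np.pi * 8.0 * t))[None, :])
    assert np.allclose(amp[0, mid], a_t[mid], atol=0.02)


def test_analytic_signal_rejects_all_masked():
    with pytest.raises(ValueError, match="masked"):
        analytic_signal(np.zeros((1, 100)), mask=np.zeros(100, dtype=bool))


def test_fused_analytic_path_matches_composed_operations(rng):
    """One-FFT analytic band-pass equals band-pass followed by Hilbert."""
    x = rng.standard_normal((3, 4800))
    fused = _analytic_bandpassed(x, {"theta": (2.0, 5.0)}, FS)
    an, mask = fused["theta"]
    y, mask2 = bandpass_zero_phase(x, (2.0, 5.0), FS)
    phase, amp = analytic_signal(y)
    np.testing.assert_array_equal(mask, mask2)
    inner = mask.copy()
    inner[:600] = False
    inner[-600:] = False
    # both paths approximate the ideal analytic extension; they differ only in
    # the circular-Hilbert padding, so agree within a few % of a typical envelope
    scale = np.abs(an[:, inner]).mean()
    np.testing.assert_allclose(
        np.abs(an[:, inner]), amp[:, inner], atol=0.05 * scale
    )
    # the real part of the fused analytic output is exactly the filtered signal
    assert np.abs(np.real(an[:, inner]) - y[:, inner]).max() < 1e-9


def test_notch_removes_mains_but_not_theta():
    t = np.arange(0, 10.0, 1 / FS)
    mains = np.sin(2 * np.pi * 50.0 * t)
    theta = np.sin(2 * np.pi * 4.0 * t)
    out = notch_zero_phase((mains + theta)[None, :], FS)
    mid = slice(1200, 4800)
    assert np.sqrt(np.mean((out[0, mid] - theta[mid]) ** 2)) < 0.05


# ---------------------------------------------------------------------------
# MVL
# ---------------------------------------------------------------------------

def test_mvl_degenerate_cases():
    # uniform phase coverage with constant amplitude: symmetry gives ~0
    phi = np.linspace(-np.pi, np.pi, 10_000, endpoint=False)
    assert mvl_pac(phi, np.ones_like(phi)) == pytest.approx(0.0, abs=1e-12)
    # all amplitude at one phase: maximum coupling
    amp = np.zeros_like(phi)
    amp[1234] = 3.0
    assert mvl_pac(phi, amp) == pytest.approx(1.0)


def test_mvl_cosine_modulation_closed_form():
    """a(phi) = 1 + cos(phi - phi0) under uniform phase gives exactly 1/2."""
    phi = np.linspace(-np.pi, np.pi, 100_000, endpoint=False)
    for phi0 in (0.0, 1.0, -2.5):
        amp = 1.0 + np.cos(phi - phi0)
        assert mvl_pac(phi, amp) == pytest.approx(0.5, abs=1e-12)


def test_mvl_zero_amplitude_is_distinct_error():
    phi = np.linspace(-np.pi, np.pi, 100)
    with pytest.raises(ZeroAmplitudeError):
        mvl_pac(phi, np.zeros_like(phi))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    rotation=st.floats(-10.0, 10.0),
    scale=st.floats(0.01, 100.0),
)
def test_mvl_invariances(seed, rotation, scale):
    """Normalized MVL is exactly invariant to phase rotation and amplitude scaling."""
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-np.pi, np.pi, 500)
    amp = rng.gamma(2.0, 1.0, 500)
    base = mvl_pac(phi, amp)
    assert mvl_pac(phi + rotation, amp) == pytest.approx(base, rel=1e-12)
    assert mvl_pac(phi, scale * amp) == pytest.approx(base, rel=1e-12)
    assert 0.0 <= base <= 1.0


def test_mvl_wrapped_normal_resultant_oracle(rng):
    """Sampled wrapped-normal phase concentration matches exp(-sigma^2/2)."""
    for sigma in (0.3, 0.7, 1.2):
        phi = rng.normal(0.0, sigma, 200_000)
        mvl = mvl_pac(phi, np.ones_like(phi))
        assert mvl == pytest.approx(np.exp(-(sigma**2) / 2.0), abs=0.01)


def test_generator_single_item_mvl_matches_wrapped_normal_model():
    """Measured MVL of a clean one-item epoch sits near the burst-model resultant."""
    p = SignalParams(sample_rate=600.0, noise_scale=0.0, theta_high_amp_slope=0.0)
    _, x = generate_epoch(p, n_items=1, duration=40.0, seed=4)
    labels = pd.DataFrame({"trial_number": [1]})
    epochs = EpochSet(
        data=x[None, :], times=np.arange(x.size) / 600.0,
        sample_rate=600.0, labels=labels,
    )
    table = pac_table(epochs, theta_band=(2.0, 5.0), gamma_band=(70.0, 140.0))
    # wrapped-normal resultant of jitter plus the burst envelope's phase width
    sigma_j = 1.0 / np.sqrt(p.coupling_base_kappa - p.dispersion_slope)
    sigma_env = 2 * np.pi * p.theta_freq * p.burst_width_cycles / (4 * p.gamma_freqs[1])
    expected = np.exp(-(sigma_j**2 + sigma_env**2) / 2.0)
    assert table["raw_mvl"].iloc[0] == pytest.approx(expected, abs=0.05)


def test_mvl_decreases_with_item_count():
    """More items disperse gamma across the cycle: expected MVL strictly falls."""
    p = SignalParams(sample_rate=600.0, noise_scale=0.0, theta_high_amp_slope=0.0)
    mvls = []
    for n in (1, 3, 5):
        vals = []
        for seed in range(5):
            _, x = generate_epoch(p, n_items=n, duration=30.0, seed=seed)
            epochs = EpochSet(
                data=x[None, :], times=np.arange(x.size) / 600.0,
                sample_rate=600.0, labels=pd.DataFrame({"trial_number": [1]}),
            )
            t = pac_table(epochs, gamma_band=(70.0, 140.0))
            vals.append(t["raw_mvl"].iloc[0])
        mvls.append(np.mean(vals))
    assert mvls[0] > mvls[1] > mvls[2]


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def _pac_frame(n, rng):
    return pd.DataFrame(
        {
            "raw_mvl": rng.uniform(0.1, 0.6, n),
            "theta_power": rng.gamma(2.0, 1.0, n),
            "gamma_power": rng.gamma(2.0, 0.5, n),
        }
    )


def test_residualization_orthogonality_and_centering(rng):
    table = residualize_pac(_pac_frame(200, rng))
    r = table["residual_pac"].to_numpy()
    assert abs(r.mean()) < 1e-12
    for cov in ("theta_power", "gamma_power"):
        c = table[cov].to_numpy()
        assert abs(np.dot(r, c - c.mean())) < 1e-8


def test_residualization_exact_linear_fit(rng):
    table = _pac_frame(100, rng)
    table["raw_mvl"] = 0.3 + 0.1 * table["theta_power"]
    out = residualize_pac(table)
    assert np.max(np.abs(out["residual_pac"])) < 1e-12


def test_residualization_collinear_covariate_dropped(rng):
    table = _pac_frame(50, rng)
    table["gamma_power"] = 2.0 * table["theta_power"]  # rank-deficient design
    with pytest.warns(RuntimeWarning, match="collinear"):
        out = residualize_pac(table)
    assert "residual_pac" in out


def test_residualization_independent_powers_recovers_centered_mvl(rng):
    table = _pac_frame(5000, rng)
    out = residualize_pac(table)
    y = table["raw_mvl"].to_numpy()
    np.testing.assert_allclose(out["residual_pac"], y - y.mean(), atol=0.02)
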