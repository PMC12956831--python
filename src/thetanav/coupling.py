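"""Theta-gamma phase-amplitude coupling with power residualization.

PAC per epoch is the mean vector length (MVL): the modulus of the
amplitude-weighted circular mean of theta phase,

    MVL = | sum_t a_t exp(i phi_t) | / sum_t a_t ,

with theta phase and gamma amplitude from the Hilbert analytic signal of
zero-phase band-passed data.  The amplitude-normalized form (bounded in
[0, 1], invariant to amplitude scaling and phase rotation) is primary; the
unnormalized mean vector |sum a e^{i phi}| / N is also reported.  Because raw
MVL leaks trial-by-trial oscillatory power, each participant's epochs are
residualized by an ordinary-least-squares fit of MVL on theta and gamma band
power before any regression against task variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .signals import EpochSet

__all__ = [
    "ZeroAmplitudeError",
    "bandpass_zero_phase",
    "analytic_signal",
    "mvl_pac",
    "pac_table",
    "residualize_pac",
]


class ZeroAmplitudeError(ValueError):
    """Total amplitude weight is zero: MVL undefined (distinct from domain errors)."""


def design_fir_bandpass(
    band: tuple[float, float], sample_rate: float, cycles: float = 3.0
) -> np.ndarray:
    """Odd-length windowed-sinc band-pass, ~``cycles`` cycles of the band's low edge."""
    low, high = band
    numtaps = int(round(cycles * sample_rate / low))
    numtaps += 1 - numtaps % 2  # odd -> symmetric, integer group delay
    return scipy.signal.firwin(
        numtaps, [low, high], pass_zero=False, fs=sample_rate, window="hamming"
    )


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR via FFT: multiply by the squared (real) response.

    The taps are symmetric, so one centered pass is already zero-phase;
    applying the squared magnitude response equals filtering forward then
    backward, doubling the stopband attenuation.
    """
    n = data.shape[-1]
    n_fft = scipy.fft.next_fast_len(n + 2 * taps.size)
    L = taps.size
    half = L // 2
    buf = np.zeros(n_fft)
    buf[: L - half] = taps[half:]
    buf[-half:] = taps[:half]
    H = np.fft.fft(buf)  # real up to rounding for a centered symmetric kernel
    X = np.fft.fft(data, n_fft, axis=-1)
    out = np.fft.ifft(X * (H.real**2), axis=-1)[..., :n]
    return out.real


def bandpass_zero_phase(
    data: np.ndarray | EpochSet,
    band: tuple[float, float],
    sample_rate: float | None = None,
    family: str = "fir",
    order: int = 4,
    cycles: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-net-phase band-pass; returns ``(filtered, valid_mask)``.

    ``family='fir'`` is a forward-backward windowed-sinc (the PAC filter);
    ``family='butterworth'`` is a forward-backward Butterworth (the waveform
    asymmetry filter).  The mask excludes half the effective filter length at
    each end, where edge transients live.
    """
    if isinstance(data, EpochSet):
        sample_rate = data.sample_rate
        data = data.data
    data = np.asarray(data, dtype=float)
    if sample_rate is None:
        raise ValueError("sample_rate required for raw-array input")
    low, high = band
    nyq = sample_rate / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:.1f} Hz)"
        )
    n = data.shape[-1]
    if family == "fir":
        taps = design_fir_bandpass(band, sample_rate, cycles)
        if n < 2 * taps.size:
            raise ValueError(
                f"epoch ({n} samples) shorter than two filter lengths "
                f"({taps.size} taps at {sample_rate:g} Hz for band {band})"
            )
        filtered = _zero_phase_fir(data, taps)
        edge = taps.size // 2
    elif family in ("butter", "butterworth"):
        sos = scipy.signal.butter(order, band, btype="bandpass", fs=sample_rate, output="sos")
        edge = int(round(1.5 * sample_rate / low))
        if n < 2 * edge:
            raise ValueError(
                f"epoch ({n} samples) too short for the {band} Butterworth "
                f"edge region ({edge} samples per end)"
            )
        filtered = scipy.signal.sosfiltfilt(sos, data, axis=-1)
    else:
        raise ValueError(f"unknown filter family {family!r}")
    mask = np.ones(n, dtype=bool)
    mask[:edge] = False
    mask[n - edge:] = False
    return filtered, mask


def notch_zero_phase(
    data: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (48.0, 52.0),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-stop for mains noise in imported recordings.

    Not applied to synthetic data (no line noise is generated); note that a
    48-52 Hz notch bites into the 30-70 Hz slow-gamma band.
    """
    sos = scipy.signal.butter(
        order, band, btype="bandstop", fs=sample_rate, output="sos"
    )
    return scipy.signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def _analytic_bandpassed(
    data: np.ndarray,
    bands: dict[str, tuple[float, float]],
    sample_rate: float,
    cycles: float = 3.0,
    dtype=np.complex128,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Analytic signal of the forward-backward FIR output, one forward FFT.

    Multiplying the spectrum by the squared (real) response of the centered
    symmetric FIR *and* the Hilbert step function yields, in a single inverse
    FFT per band, exactly the analytic extension of the zero-phase-filtered
    signal.  Returns ``{name: (analytic, valid_mask)}``.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    taps = {name: design_fir_bandpass(band, sample_rate, cycles) for name, band in bands.items()}
    for name, tp in taps.items():
        if n < 2 * tp.size:
            raise ValueError(
                f"epoch ({n} samples) shorter than two filter lengths for band "
                f"{bands[name]} ({tp.size} taps)"
            )
    n_fft = scipy.fft.next_fast_len(n + 2 * max(tp.size for tp in taps.values()))
    X = scipy.fft.fft(data.astype(dtype, copy=False), n_fft, axis=-1)
    step = np.zeros(n_fft)
    step[0] = 1.0
    if n_fft % 2 == 0:
        step[1 : n_fft // 2] = 2.0
        step[n_fft // 2] = 1.0
    else:
        step[1 : (n_fft + 1) // 2] = 2.0
    out = {}
    for name, tp in taps.items():
        L = tp.size
        half = L // 2
        buf = np.zeros(n_fft)
        buf[: L - half] = tp[half:]
        buf[-half:] = tp[:half]
        H = scipy.fft.fft(buf).real  # centered symmetric kernel -> real response
        analytic = scipy.fft.ifft(
            X * (H**2 * step).astype(dtype, copy=False), axis=-1
        )[..., :n]
        mask = np.ones(n, dtype=bool)
        mask[:half] = False
        mask[n - half:] = False
        out[name] = (analytic, mask)
    return out


def analytic_signal(
    filtered: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude from the Hilbert analytic extension."""
    filtered = np.asarray(filtered, dtype=float)
    if mask is not None and not np.asarray(mask).any():
        raise ValueError("all samples masked; analytic signal undefined")
    analytic = scipy.signal.hilbert(filtered, axis=-1)
    return np.angle(analytic), np.abs(analytic)


def mvl_pac(
    phase: np.ndarray,
    amplitude: np.ndarray,
    mask: np.ndarray | None = None,
    normalized: bool = True,
    axis: int = -1,
) -> np.ndarray | float:
    """Amplitude-weighted resultant of phase: the MVL coupling statistic.

    Normalized: ``|sum a e^{i phi}| / sum a`` in [0, 1].  Unnormalized:
    ``|sum a e^{i phi}| / N`` (the raw mean vector).  Raises
    :class:`ZeroAmplitudeError` when the total amplitude is zero.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must share a shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        phase = np.compress(mask, phase, axis=axis)
        amplitude = np.compress(mask, amplitude, axis=axis)
    if phase.shape[axis] == 0:
        raise ValueError("no valid samples")
    resultant = np.abs(np.sum(amplitude * np.exp(1j * phase), axis=axis))
    if normalized:
        total = np.sum(amplitude, axis=axis)
        if np.any(total == 0):
            raise ZeroAmplitudeError("total amplitude is zero; MVL undefined")
        return resultant / total
    return resultant / phase.shape[axis]


def pac_table(
    epochs: EpochSet,
    theta_band: tuple[float, float] = (2.0, 5.0),
    gamma_band: tuple[float, float] = (70.0, 140.0),
    window: tuple[float, float] | None = None,
    family: str = "fir",
    cycles: float = 3.0,
    min_theta_cycles: float = 5.0,
    dtype=np.complex128,
) -> pd.DataFrame:
    """Per-epoch PAC table: raw MVL (both normalizations) plus power covariates.

    Theta phase and gamma amplitude come from zero-phase filtering and the
    Hilbert transform; the statistic is computed over the valid samples of
    ``window`` (the same window of interest as the power analyses).  Band
    powers are raw (not baseline-corrected) mean squared envelopes from the
    same window, the GLM covariates for residualization.
    """
    if family == "fir":
        fused = _analytic_bandpassed(
            epochs.data, {"theta": theta_band, "gamma": gamma_band},
            epochs.sample_rate, cycles=cycles, dtype=dtype,
        )
        (th_an, th_mask), (gm_an, gm_mask) = fused["theta"], fused["gamma"]
        phase, th_amp = np.angle(th_an), np.abs(th_an)
        gm_amp = np.abs(gm_an)
    else:
        th, th_mask = bandpass_zero_phase(epochs, theta_band, family=family, cycles=cycles)
        gm, gm_mask = bandpass_zero_phase(epochs, gamma_band, family=family, cycles=cycles)
        phase, th_amp = analytic_signal(th)
        _, gm_amp = analytic_signal(gm)

    valid = th_mask & gm_mask
    if window is not None:
        t = epochs.times
        valid = valid & (t >= window[0]) & (t <= window[1])
    n_valid = int(valid.sum())
    if n_valid < min_theta_cycles * epochs.sample_rate / theta_band[1]:
        raise ValueError(
            f"only {n_valid} valid samples; need >= {min_theta_cycles} theta cycles"
        )
    table = epochs.labels.copy()
    table["raw_mvl"] = mvl_pac(phase[:, valid], gm_amp[:, valid], normalized=True)
    table["raw_mvl_unnorm"] = mvl_pac(
        phase[:, valid], gm_amp[:, valid], normalized=False
    )
    table["theta_power"] = np.mean(th_amp[:, valid] ** 2, axis=-1)
    table["gamma_power"] = np.mean(gm_amp[:, valid] ** 2, axis=-1)
    table.attrs.update(
        theta_band=tuple(theta_band), gamma_band=tuple(gamma_band),
        window=None if window is None else tuple(window),
    )
    return table


def residualize_pac(
    table: pd.DataFrame,
    outcome: str = "raw_mvl",
    covariates: tuple[str, ...] = ("theta_power", "gamma_power"),
    out_col: str = "residual_pac",
) -> pd.DataFrame:
    """OLS residuals of PAC on band powers (one participant's epochs at a time).

    Fits ``outcome ~ 1 + covariates`` and stores observed minus fitted, which
    is zero-mean and orthogonal to every covariate by construction.  A
    rank-deficient (collinear) design drops trailing covariates with a warning.
    """
    y = table[outcome].to_numpy(dtype=float)
    n = y.size
    cols = list(covariates)
    X = np.column_stack([np.ones(n)] + [table[c].to_numpy(dtype=float) for c in cols])
    if n < X.shape[1] + 3:
        raise ValueError(
            f"need at least {X.shape[1] + 3} epochs for residualization, got {n}"
        )
    while np.linalg.matrix_rank(X) < X.shape[1] and len(cols) > 0:
        dropped = cols.pop()
        warnings.warn(
            f"collinear covariate {dropped!r} dropped from PAC residualization",
            RuntimeWarning,
            stacklevel=2,
        )
        X = X[:, :-1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = table.copy()
    out[out_col] = y - X @ beta
    return out
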