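"""Time-frequency power: Morlet wavelet TFR, baseline correction, band power, Welch PSD.

Power is estimated by convolving with five-cycle complex Morlet wavelets at 20
logarithmically spaced frequencies between 1 and 30 Hz, log-transformed
(natural log) and optionally baseline-corrected by subtracting the mean log
power in a pre-event window per frequency.  Samples within half a wavelet of
either epoch edge are invalid (NaN) and never enter statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .signals import EpochSet

__all__ = [
    "TFR",
    "default_freqs",
    "morlet_wavelet",
    "morlet_tfr",
    "baseline_correct",
    "band_power",
    "band_power_raw",
    "welch_psd",
]


def default_freqs(fmin: float = 1.0, fmax: float = 30.0, n: int = 20) -> np.ndarray:
    """Log-spaced analysis frequencies including both endpoints."""
    return np.logspace(np.log10(fmin), np.log10(fmax), n)


def morlet_wavelet(
    freq: float, sample_rate: float, n_cycles: float = 5.0, sigma_cutoff: float = 3.0
) -> np.ndarray:
    """L2-normalized complex Morlet wavelet, truncated at ``sigma_cutoff`` SDs.

    A complex exponential under a Gaussian with ``sigma_t = n_cycles / (2 pi f)``.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(sigma_cutoff * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def _centered_kernel_fft(kernel: np.ndarray, n_fft: int) -> np.ndarray:
    """FFT of a kernel laid out so circular convolution is center-aligned."""
    L = kernel.size
    half = L // 2
    buf = np.zeros(n_fft, dtype=complex)
    buf[: L - half] = kernel[half:]
    buf[-half:] = kernel[:half]
    return scipy.fft.fft(buf)


def _morlet_coefficients(
    data: np.ndarray,
    freqs: np.ndarray,
    sample_rate: float,
    n_cycles: float,
    dtype=np.complex128,
):
    """Yield (freq, complex coefficients, half_support) with one shared forward FFT."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[-1]
    kernels = [morlet_wavelet(f, sample_rate, n_cycles) for f in freqs]
    for f, k in zip(freqs, kernels):
        if k.size > n:
            raise ValueError(
                f"epoch ({n} samples) shorter than one wavelet at {f:.3g} Hz "
                f"({k.size} samples)"
            )
    n_fft = scipy.fft.next_fast_len(n + max(k.size for k in kernels))
    X = scipy.fft.fft(data.astype(dtype, copy=False), n_fft, axis=-1)
    for f, k in zip(freqs, kernels):
        K = _centered_kernel_fft(k, n_fft).astype(dtype, copy=False)
        coef = scipy.fft.ifft(X * K, axis=-1)[..., :n]
        yield f, coef, k.size // 2


@dataclass
class TFR:
    """Trials x frequency x time log-power with edge-invalid samples as NaN."""

    values: np.ndarray  # (n_epochs, n_freqs, n_times), natural-log power
    freqs: np.ndarray
    times: np.ndarray
    sample_rate: float
    labels: pd.DataFrame | None = None
    baseline: tuple[float, float] | None = None

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "TFR":
        return TFR(
            values=self.values.copy(),
            freqs=self.freqs.copy(),
            times=self.times.copy(),
            sample_rate=self.sample_rate,
            labels=None if self.labels is None else self.labels.copy(),
            baseline=self.baseline,
        )

    def save(self, path) -> None:
        """HDF5 container holding values/freqs/times plus label and baseline metadata."""
        import json
        from pathlib import Path

        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            f.attrs["sample_rate"] = self.sample_rate
            f.attrs["baseline"] = "" if self.baseline is None else json.dumps(self.baseline)
            if self.labels is not None:
                f.attrs["labels"] = self.labels.to_json(orient="split")

    @classmethod
    def load(cls, path) -> "TFR":
        import io
        import json

        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][()]
            freqs = f["freqs"][()]
            times = f["times"][()]
            sample_rate = float(f.attrs["sample_rate"])
            baseline = f.attrs.get("baseline", "")
            labels_json = f.attrs.get("labels")
        labels = (
            pd.read_json(io.StringIO(labels_json), orient="split")
            if labels_json is not None
            else None
        )
        return cls(
            values=values, freqs=freqs, times=times, sample_rate=sample_rate,
            labels=labels,
            baseline=None if not baseline else tuple(json.loads(baseline)),
        )


def morlet_tfr(
    epochs: EpochSet | np.ndarray,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
    sample_rate: float | None = None,
    times: np.ndarray | None = None,
) -> TFR:
    """Uncorrected log-power TFR of an epoch set.

    Power is the squared magnitude of the wavelet transform; zero power maps
    to ``-inf``.  Samples within half a wavelet of either edge are NaN.
    """
    if isinstance(epochs, EpochSet):
        data = epochs.data
        sample_rate = epochs.sample_rate
        times = epochs.times
        labels = epochs.labels
    else:
        data = np.atleast_2d(np.asarray(epochs, dtype=float))
        if sample_rate is None:
            raise ValueError("sample_rate required for raw-array input")
        if times is None:
            times = np.arange(data.shape[-1]) / sample_rate
        labels = None
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)

    n_epochs, n = data.shape
    values = np.empty((n_epochs, freqs.size, n))
    for i, (f, coef, half) in enumerate(
        _morlet_coefficients(data, freqs, sample_rate, n_cycles)
    ):
        power = np.abs(coef) ** 2
        with np.errstate(divide="ignore"):
            lp = np.log(power)
        if half > 0:
            lp[..., :half] = np.nan
            lp[..., -half:] = np.nan
        values[:, i, :] = lp
    return TFR(
        values=values,
        freqs=freqs,
        times=np.asarray(times, dtype=float),
        sample_rate=sample_rate,
        labels=None if labels is None else labels.copy(),
    )


def baseline_correct(
    tfr: TFR,
    baseline: tuple[float, float],
    crop: tuple[float, float] | None = None,
) -> TFR:
    """Subtract per-frequency mean log power in ``baseline``; optionally crop.

    Raises if the baseline window is empty or touches wavelet-invalid edge
    samples at any frequency (names the offending frequencies).
    """
    t = tfr.times
    bmask = (t >= baseline[0]) & (t <= baseline[1])
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    seg = tfr.values[:, :, bmask]
    bad = np.isnan(seg).any(axis=(0, 2))
    if bad.any():
        raise ValueError(
            "baseline overlaps wavelet-invalid edges at frequencies: "
            + ", ".join(f"{f:.3g} Hz" for f in tfr.freqs[bad])
        )
    corrected = tfr.values - seg.mean(axis=2, keepdims=True)
    times = t
    if crop is not None:
        cmask = (t >= crop[0]) & (t <= crop[1])
        if not cmask.any():
            raise ValueError("crop window contains no samples")
        corrected = corrected[:, :, cmask]
        times = t[cmask]
    out = TFR(
        values=corrected,
        freqs=tfr.freqs.copy(),
        times=times.copy(),
        sample_rate=tfr.sample_rate,
        labels=None if tfr.labels is None else tfr.labels.copy(),
        baseline=tuple(baseline),
    )
    return out


def _band_freq_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"no computed frequency falls in band {band}")
    return mask


def band_power(
    tfr: TFR, band: tuple[float, float], window: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Per-epoch mean log power over a closed band and time window.

    Averages only wavelet-valid samples; raises if an epoch has none.  The
    returned table carries the epoch labels plus band/window metadata and a
    ``corrected`` flag recording whether the TFR was baseline-corrected.
    """
    fmask = _band_freq_mask(tfr.freqs, band)
    t = tfr.times
    if window is None:
        tmask = np.ones(t.size, dtype=bool)
    else:
        tmask = (t >= window[0]) & (t <= window[1])
    if not tmask.any():
        raise ValueError("empty time window")
    seg = tfr.values[:, fmask][:, :, tmask]
    valid = ~np.isnan(seg)
    if not valid.any(axis=(1, 2)).all():
        raise ValueError("some epochs have no valid samples in the band/window")
    power = np.nanmean(seg, axis=(1, 2))
    table = (
        tfr.labels.copy() if tfr.labels is not None else pd.DataFrame(index=range(tfr.n_epochs))
    )
    table["power"] = power
    table.attrs.update(
        band=tuple(band),
        window=None if window is None else tuple(window),
        corrected=tfr.baseline is not None,
    )
    return table


def band_power_raw(
    epochs: EpochSet,
    band: tuple[float, float],
    window: tuple[float, float] | None = None,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
) -> pd.DataFrame:
    """Uncorrected band power straight from raw epochs.

    Computes the Morlet transform only at the grid frequencies inside the
    band (cheaper than a full TFR); this is the regression input, which is
    deliberately not baseline-corrected.
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    fmask = _band_freq_mask(freqs, band)
    tfr = morlet_tfr(epochs, freqs=freqs[fmask], n_cycles=n_cycles)
    return band_power(tfr, band=band, window=window)


def band_power_multi(
    epochs: EpochSet,
    bands: dict[str, tuple[float, float]],
    window: tuple[float, float] | None = None,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
    dtype=np.complex128,
) -> pd.DataFrame:
    """Uncorrected band power for several bands with one shared forward FFT.

    Equivalent to calling :func:`band_power_raw` per band (same grid
    frequencies, same valid-sample averaging) but transforms the data once.
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    t = epochs.times
    if window is None:
        tmask = np.ones(t.size, dtype=bool)
    else:
        tmask = (t >= window[0]) & (t <= window[1])
    if not tmask.any():
        raise ValueError("empty time window")
    tidx = np.flatnonzero(tmask)

    band_freqs: dict[str, np.ndarray] = {
        name: freqs[_band_freq_mask(freqs, band)] for name, band in bands.items()
    }
    union = np.unique(np.concatenate(list(band_freqs.values())))
    n = epochs.n_times
    sums = {name: np.zeros(epochs.n_epochs) for name in bands}
    counts = {name: np.zeros(epochs.n_epochs) for name in bands}
    for f, coef, half in _morlet_coefficients(
        epochs.data, union, epochs.sample_rate, n_cycles, dtype=dtype
    ):
        valid = tidx[(tidx >= half) & (tidx < n - half)]
        if valid.size == 0:
            continue
        power = np.abs(coef[..., valid]) ** 2
        with np.errstate(divide="ignore"):
            lp = np.log(power)
        for name in bands:
            if np.any(np.isclose(band_freqs[name], f)):
                sums[name] += lp.sum(axis=-1)
                counts[name] += valid.size
    table = epochs.labels.copy()
    for name in bands:
        if np.any(counts[name] == 0):
            raise ValueError(f"no valid samples in band {name!r} over the window")
        table[name] = sums[name] / counts[name]
    table.attrs.update(bands={k: tuple(v) for k, v in bands.items()},
                       window=None if window is None else tuple(window),
                       corrected=False)
    return table


def welch_psd(
    epochs: EpochSet | np.ndarray,
    sample_rate: float | None = None,
    fmin: float = 1.0,
    fmax: float = 150.0,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density per epoch over ``[fmin, fmax]``.

    Default segment length is two seconds (1 Hz-ish resolution after the
    range cut), half-overlapping Hann tapers.  Requires at least two segments.
    """
    if isinstance(epochs, EpochSet):
        data = epochs.data
        sample_rate = epochs.sample_rate
    else:
        data = np.atleast_2d(np.asarray(epochs, dtype=float))
        if sample_rate is None:
            raise ValueError("sample_rate required for raw-array input")
    n = data.shape[-1]
    if nperseg is None:
        # two-second segments, shortened when the epoch cannot hold two of them
        nperseg = min(int(round(2.0 * sample_rate)), (2 * n) // 3)
    if noverlap is None:
        noverlap = nperseg // 2
    if n < nperseg + (nperseg - noverlap):
        raise ValueError(
            f"epoch too short for Welch: need >= {nperseg + nperseg - noverlap} "
            f"samples (2 segments), got {n}"
        )
    f, p = scipy.signal.welch(
        data, fs=sample_rate, nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    mask = (f >= fmin) & (f <= fmax)
    return f[mask], p[..., mask]
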