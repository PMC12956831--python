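"""Confound controls: aperiodic (1/f) slope, evoked theta amplitude, waveform asymmetry.

Each control asks whether an apparent distance effect in power or coupling
could instead be produced by (a) a change in the aperiodic background slope,
(b) the phase-locked evoked response, or (c) a non-sinusoidal theta waveform.
Every control reduces to a per-participant regression of its summary statistic
on goal distance, followed by the same group-level test as the main analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import bandpass_zero_phase
from .signals import EpochSet
from .spectral import _band_freq_mask, _morlet_coefficients, default_freqs, welch_psd
from .stats import RegressionResult, epoch_regression

__all__ = [
    "AperiodicFit",
    "AsymmetryResult",
    "EvokedProfile",
    "fit_aperiodic",
    "aperiodic_by_distance",
    "aperiodic_vs_distance",
    "evoked_amplitude_by_distance",
    "evoked_vs_distance",
    "find_extrema",
    "asymmetry_index",
    "asymmetry_per_epoch",
    "asymmetry_vs_distance",
]


# ---------------------------------------------------------------------------
# aperiodic slope
# ---------------------------------------------------------------------------

@dataclass
class AperiodicFit:
    """Robust log-log line fit of a PSD with oscillatory peaks excluded.

    ``exponent`` is the negative of the log-log slope (chi in 1/f^chi);
    ``offset`` the log10-power intercept.  ``excluded`` flags the frequency
    points treated as peaks.
    """

    offset: float
    exponent: float
    freq_range: tuple[float, float]
    excluded: np.ndarray
    converged: bool
    n_points: int


def fit_aperiodic(
    freqs: np.ndarray,
    power: np.ndarray,
    freq_range: tuple[float, float] = (1.0, 150.0),
    k_mad: float = 3.0,
    min_height: float = 0.05,
    max_iter: int = 20,
) -> AperiodicFit:
    """Iterative peak-excluding line fit in log-frequency / log-power space.

    Fit a line, flag points lying more than ``k_mad`` robust SDs (and at
    least ``min_height`` log10 units) above it as oscillatory peaks, refit
    without them, and repeat until the exclusion set stabilizes.  Only
    upward outliers are excluded: peaks add power, they never remove it.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1]) & (freqs > 0)
    if not (power[sel] > 0).all():
        raise ValueError("PSD must be strictly positive on the fit range")
    x = np.log10(freqs[sel])
    y = np.log10(power[sel])
    if x.size < 10:
        raise ValueError(f"need >= 10 frequency points in range, got {x.size}")

    excluded = np.zeros(x.size, dtype=bool)
    converged = False
    slope = intercept = 0.0
    for _ in range(max_iter):
        keep = ~excluded
        if keep.sum() < 10:
            warnings.warn(
                "peak exclusion left < 10 points; keeping previous fit",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        slope, intercept = np.polyfit(x[keep], y[keep], 1)
        resid = y - (slope * x + intercept)
        mad_sigma = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
        thresh = max(k_mad * mad_sigma, min_height)
        new_excluded = resid > thresh
        if np.array_equal(new_excluded, excluded):
            converged = True
            break
        excluded = new_excluded
    else:
        warnings.warn("aperiodic fit did not stabilize; flagged unstable",
                      RuntimeWarning, stacklevel=2)

    full_excluded = np.zeros(freqs.size, dtype=bool)
    full_excluded[np.flatnonzero(sel)] = excluded
    return AperiodicFit(
        offset=float(intercept),
        exponent=float(-slope),
        freq_range=tuple(freq_range),
        excluded=full_excluded,
        converged=converged,
        n_points=int((~excluded).sum()),
    )


def aperiodic_by_distance(
    epochs: EpochSet,
    distance_col: str = "goal_distance",
    freq_range: tuple[float, float] = (1.0, 150.0),
    window: tuple[float, float] | None = None,
    k_mad: float = 3.0,
    equalize: bool = False,
    min_epochs: int = 2,
    **welch_kwargs,
) -> pd.DataFrame:
    """Aperiodic exponent per goal distance: Welch PSDs averaged within distance.

    Mirrors the control's recipe: estimate per-epoch spectra over the window
    of interest, average across all trials with the same distance, then fit
    the peak-excluding line to each averaged spectrum.  ``equalize`` averages
    the same number of epochs at every distance (the first ``m`` in session
    order, with ``m`` the smallest retained level count) so the averaged
    spectra share their noise level; otherwise unequal trial counts make the
    log spectrum slightly noisier at rare distances.  Levels with fewer than
    ``min_epochs`` trials are dropped with a warning.
    """
    data = epochs.data
    if window is not None:
        t = epochs.times
        sel = (t >= window[0]) & (t <= window[1])
        data = data[:, sel]
    freqs, psd = welch_psd(
        data, sample_rate=epochs.sample_rate,
        fmin=freq_range[0], fmax=freq_range[1], **welch_kwargs,
    )
    dist = epochs.labels[distance_col].to_numpy()
    counts = {d: int((dist == d).sum()) for d in np.unique(dist)}
    levels = [d for d, c in counts.items() if c >= min_epochs]
    if len(levels) < len(counts):
        warnings.warn(
            f"distance levels with < {min_epochs} epochs dropped from the "
            "aperiodic control",
            RuntimeWarning,
            stacklevel=2,
        )
    m = min(counts[d] for d in levels) if equalize else None
    rows = []
    for d in levels:
        idx = np.flatnonzero(dist == d)
        if m is not None:
            idx = idx[:m]
        mean_psd = psd[idx].mean(axis=0)
        fit = fit_aperiodic(freqs, mean_psd, freq_range=freq_range, k_mad=k_mad)
        rows.append(
            {
                "distance": d,
                "exponent": fit.exponent,
                "offset": fit.offset,
                "n_epochs": int(len(idx)),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def aperiodic_vs_distance(
    epochs: EpochSet,
    distance_col: str = "goal_distance",
    freq_range: tuple[float, float] = (1.0, 150.0),
    window: tuple[float, float] | None = None,
    equalize: bool = False,
    min_epochs: int = 2,
    **welch_kwargs,
) -> RegressionResult:
    """Per-participant slope of the aperiodic exponent on goal distance."""
    table = aperiodic_by_distance(
        epochs, distance_col=distance_col, freq_range=freq_range,
        window=window, equalize=equalize, min_epochs=min_epochs, **welch_kwargs,
    )
    if table["distance"].nunique() < 2:
        raise ValueError("need >= 2 distance levels to regress the exponent")
    return epoch_regression(
        table, outcome="exponent", distance_col="distance", nuisance=()
    )


# ---------------------------------------------------------------------------
# evoked theta amplitude
# ---------------------------------------------------------------------------

@dataclass
class EvokedProfile:
    """Evoked band amplitude per distance, from trial-count-matched subsampling."""

    distances: np.ndarray
    amplitude: np.ndarray  # mean over iterations
    band: tuple[float, float]
    n_per_distance: int
    n_iter: int
    dropped: tuple = ()


def evoked_amplitude_by_distance(
    epochs: EpochSet,
    band: tuple[float, float] = (2.0, 5.0),
    window: tuple[float, float] | None = None,
    distance_col: str = "goal_distance",
    max_distance: int = 4,
    n_iter: int = 100,
    seed: int | np.random.Generator | None = None,
    n_cycles: float = 5.0,
) -> EvokedProfile:
    """Theta-band amplitude of the evoked (trial-averaged) response per distance.

    Per iteration, an equal number of trials is subsampled at every distance,
    the raw signals are averaged *before* the time-frequency transform (so
    only phase-locked activity survives), and mean band amplitude over the
    window is extracted; results average across iterations.  Distances above
    ``max_distance`` (few trials) are excluded; singleton distances dropped
    with a warning.
    """
    rng = np.random.default_rng(seed)
    dist = epochs.labels[distance_col].to_numpy()
    levels = [d for d in np.unique(dist) if d <= max_distance]
    counts = {d: int((dist == d).sum()) for d in levels}
    dropped = tuple(d for d in levels if counts[d] < 2)
    if dropped:
        warnings.warn(
            f"distances {dropped} have a single trial and were dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    levels = [d for d in levels if counts[d] >= 2]
    if len(levels) < 2:
        raise ValueError("need >= 2 distance levels with >= 2 trials each")
    m = min(counts[d] for d in levels)

    freqs = default_freqs()
    fmask = _band_freq_mask(freqs, band)
    band_freqs = freqs[fmask]
    t = epochs.times
    if window is None:
        wmask = np.ones(t.size, dtype=bool)
    else:
        wmask = (t >= window[0]) & (t <= window[1])

    amps = np.zeros((n_iter, len(levels)))
    for it in range(n_iter):
        averages = np.stack([
            epochs.data[rng.choice(np.flatnonzero(dist == d), size=m, replace=False)]
            .mean(axis=0)
            for d in levels
        ])
        cols = []
        for f, coef, half in _morlet_coefficients(
            averages, band_freqs, epochs.sample_rate, n_cycles
        ):
            a = np.abs(coef)
            a[..., :half] = np.nan
            a[..., -half:] = np.nan
            cols.append(np.nanmean(a[:, wmask], axis=-1))
        amps[it] = np.mean(cols, axis=0)
    return EvokedProfile(
        distances=np.asarray(levels),
        amplitude=amps.mean(axis=0),
        band=tuple(band),
        n_per_distance=m,
        n_iter=n_iter,
        dropped=dropped,
    )


def evoked_vs_distance(profile: EvokedProfile) -> RegressionResult:
    """Slope of evoked band amplitude on goal distance."""
    table = pd.DataFrame(
        {"distance": profile.distances, "amplitude": profile.amplitude}
    )
    return epoch_regression(
        table, outcome="amplitude", distance_col="distance", nuisance=()
    )


# ---------------------------------------------------------------------------
# waveform asymmetry
# ---------------------------------------------------------------------------

@dataclass
class AsymmetryResult:
    """Per-epoch asymmetry index: (ascend - descend) / (ascend + descend)."""

    ai: float
    n_cycles: int
    per_cycle: np.ndarray = field(default_factory=lambda: np.empty(0))


def find_extrema(
    filtered: np.ndarray, sample_rate: float, t_start: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating trough/peak timestamps on a narrowband signal.

    Zero-crossing bracketing: exactly one peak between each up- and
    down-crossing and one trough between each down- and up-crossing, which
    prevents noise-induced double extrema.  Returns ``(times, kinds)`` with
    kind +1 for peaks, -1 for troughs; partial cycles at the edges are
    discarded.
    """
    x = np.asarray(filtered, dtype=float)
    s = np.sign(x)
    s[s == 0] = 1
    flips = np.flatnonzero(np.diff(s))
    if flips.size < 2:
        raise ValueError("no alternating extrema found (no zero crossings)")
    times = []
    kinds = []
    for a, b in zip(flips[:-1], flips[1:]):
        seg = x[a + 1 : b + 1]
        if s[a] < 0:  # up-crossing at a: a peak lies before the next down-crossing
            idx = a + 1 + int(np.argmax(seg))
            kinds.append(1)
        else:
            idx = a + 1 + int(np.argmin(seg))
            kinds.append(-1)
        times.append(t_start + idx / sample_rate)
    times = np.asarray(times)
    kinds = np.asarray(kinds)
    if not (np.diff(kinds) != 0).all():  # guaranteed by construction
        raise ValueError("extrema do not alternate")
    return times, kinds


def asymmetry_index(
    signal: np.ndarray | None = None,
    sample_rate: float | None = None,
    band: tuple[float, float] = (2.0, 5.0),
    window: tuple[float, float] | None = None,
    t_start: float = 0.0,
    family: str = "butterworth",
    filtered: bool = False,
    min_cycles: int = 3,
) -> AsymmetryResult:
    """Theta waveform asymmetry of one epoch.

    The signal is band-passed (zero-phase Butterworth by default), extrema are
    located, and per cycle the index is the difference between ascending
    (trough to peak) and descending (peak to trough) durations over their sum.
    The epoch value is the mean across cycles; NaN when fewer than
    ``min_cycles`` full cycles are detected.
    """
    x = np.asarray(signal, dtype=float)
    if not filtered:
        x, mask = bandpass_zero_phase(x[None, :], band, sample_rate, family=family)
        x = x[0]
    if window is not None:
        t = t_start + np.arange(x.size) / sample_rate
        sel = (t >= window[0]) & (t <= window[1])
        x = x[sel]
        t_start = t[sel][0]
    times, kinds = find_extrema(x, sample_rate, t_start)
    # start at the first trough so each triple is (trough, peak, trough)
    start = int(np.flatnonzero(kinds == -1)[0]) if (kinds == -1).any() else None
    if start is None or times.size - start < 3:
        return AsymmetryResult(ai=np.nan, n_cycles=0)
    times = times[start:]
    ai = []
    for i in range(0, times.size - 2, 2):
        trough0, peak, trough1 = times[i : i + 3]
        ascend = peak - trough0
        descend = trough1 - peak
        ai.append((ascend - descend) / (ascend + descend))
    ai = np.asarray(ai)
    if ai.size < min_cycles:
        return AsymmetryResult(ai=np.nan, n_cycles=int(ai.size), per_cycle=ai)
    return AsymmetryResult(ai=float(ai.mean()), n_cycles=int(ai.size), per_cycle=ai)


def asymmetry_per_epoch(
    epochs: EpochSet,
    band: tuple[float, float] = (2.0, 5.0),
    window: tuple[float, float] | None = None,
    family: str = "butterworth",
    min_cycles: int = 3,
) -> pd.DataFrame:
    """Asymmetry index for every epoch, filtering all epochs in one pass."""
    filt, mask = bandpass_zero_phase(epochs, band, family=family)
    t = epochs.times
    sel = mask.copy()
    if window is not None:
        sel &= (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError("no valid samples in the analysis window")
    t0 = t[sel][0]
    table = epochs.labels.copy()
    vals = np.empty(epochs.n_epochs)
    ncyc = np.empty(epochs.n_epochs, dtype=int)
    for e in range(epochs.n_epochs):
        res = asymmetry_index(
            filt[e, sel], epochs.sample_rate, filtered=True,
            t_start=t0, min_cycles=min_cycles,
        )
        vals[e] = res.ai
        ncyc[e] = res.n_cycles
    table["ai"] = vals
    table["ai_n_cycles"] = ncyc
    return table


def asymmetry_vs_distance(
    table: pd.DataFrame,
    distance_col: str = "goal_distance",
    nuisance: tuple[str, ...] = ("trial_number",),
) -> RegressionResult:
    """Per-participant slope of the asymmetry index on goal distance."""
    return epoch_regression(
        table.dropna(subset=["ai"]), outcome="ai",
        distance_col=distance_col, nuisance=nuisance,
    )
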