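"""Synthetic virtual-channel signals under the theta-gamma sequence-coding model.

The generative model follows the hypothesis that upcoming sequence items
(remaining path locations) are represented by gamma bursts at successive
phases of the theta cycle:

* theta carrier amplitude grows linearly with the number of remaining items,
  ``A(n) = theta_amp_base + theta_amp_slope * n``;
* each theta cycle carries one gamma burst per item, at preferred phases
  equally spaced over an interval that widens with the item count (saturating
  at the full cycle), with wrapped-normal phase jitter whose concentration
  falls with the item count -- so measured phase-amplitude coupling decreases
  as more items are maintained;
* a 1/f^chi aperiodic background, an optional phase-locked evoked transient,
  and an optional non-sinusoidal (skewed) theta waveform provide the confounds
  the analysis controls must reject.

Everything is reproducible from a seed, and every knob that downstream
analyses regress on (amplitude slope, dispersion slope, asymmetry, aperiodic
exponent) can be held constant or varied with item count for null and
recovery studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .task import SessionLog, manhattan_distance

__all__ = [
    "SignalParams",
    "EpochSet",
    "generate_epoch",
    "generate_participant",
    "inject_asymmetry",
    "inject_evoked",
    "powerlaw_noise",
]


@dataclass(frozen=True)
class SignalParams:
    """Generative constants for one synthetic participant.

    Units: frequencies in Hz, amplitudes in arbitrary units, phases in
    radians, durations in seconds.  ``dispersion_slope`` lowers the burst
    phase concentration per additional item; ``phase_span_per_item`` widens
    the preferred-phase fan per item (capped at a full cycle).
    """

    sample_rate: float = 600.0
    theta_freq: float = 4.0
    theta_amp_base: float = 1.0
    theta_amp_slope: float = 0.12
    theta_high_freq: float = 7.5  # secondary, load-dependent high-theta carrier
    theta_high_amp_slope: float = 0.15  # amplitude per remaining item (0 at rest)
    gamma_freqs: tuple[float, float] = (50.0, 100.0)  # slow, fast band centers
    gamma_burst_amp: float = 0.5
    burst_width_cycles: float = 2.0
    coupling_base_kappa: float = 6.0
    dispersion_slope: float = 0.8
    kappa_floor: float = 0.5
    phase_span_per_item: float = np.pi / 3
    burst_phase_center: float = np.pi  # fan centered on the theta trough
    noise_exponent: float = 1.0
    noise_exponent_slope: float = 0.0  # exponent change per remaining item
    noise_scale: float = 1.0
    asymmetry: float = 0.0
    asymmetry_slope: float = 0.0  # asymmetry change per remaining item
    coupled: bool = True  # False: burst phases uniform over the cycle
    n_bursts_override: int | None = None  # fixed bursts/cycle, decoupled from load
    evoked_amp: float = 0.0
    evoked_latency: float = 0.2
    evoked_width: float = 0.12

    def __post_init__(self) -> None:
        if self.sample_rate <= 2.0 * max(self.gamma_freqs):
            raise ValueError("sample_rate must exceed twice the highest gamma frequency")
        if self.theta_amp_base <= 0:
            raise ValueError("theta_amp_base must be positive")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if not 0.0 <= self.asymmetry < 1.0:
            raise ValueError("asymmetry must lie in [0, 1)")


@dataclass
class EpochSet:
    """Trials x time array for one virtual channel, with per-epoch labels.

    ``times`` is seconds relative to the alignment event (cue onset or button
    press).  ``labels`` carries one row per epoch; all epochs share a length.
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_epochs, n_times)")
        if self.data.shape[1] != self.times.size:
            raise ValueError("times length must match data's time axis")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise ValueError("select expects a boolean mask over epochs")
        return EpochSet(
            data=self.data[mask],
            times=self.times.copy(),
            sample_rate=self.sample_rate,
            labels=self.labels.loc[mask].reset_index(drop=True),
        )

    def save(self, path: str | Path) -> None:
        """HDF5 container (data/times) plus a JSON sidecar with labels + metadata."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.attrs["sample_rate"] = self.sample_rate
        sidecar = {
            "sample_rate": self.sample_rate,
            "labels": json.loads(self.labels.to_json(orient="split")),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            sample_rate = float(f.attrs["sample_rate"])
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        import io

        labels = pd.read_json(
            io.StringIO(json.dumps(sidecar["labels"])), orient="split"
        )
        return cls(data=data, times=times, sample_rate=sample_rate, labels=labels)


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _warp_cycle_fraction(u: np.ndarray, a) -> np.ndarray:
    """Monotone within-cycle warp producing a skewed wave.

    ``u`` is the linear cycle fraction in [0, 1) (0 = peak of the cosine);
    the descending half (peak -> trough) is compressed to a fraction
    ``(1 - a) / 2`` of the period and the ascending half stretched to
    ``(1 + a) / 2``, so the asymmetry index of the output equals ``a``.
    Returns the warped fraction ``v`` with the waveform ``cos(2*pi*v)``.
    """
    a = np.asarray(a, dtype=float)
    d = (1.0 - a) / 2.0  # duration fraction of the descending phase
    v = np.where(u < d, 0.5 * u / d, 0.5 + 0.5 * (u - d) / (1.0 - d))
    return v


def _unwarp_cycle_fraction(v: np.ndarray, a) -> np.ndarray:
    """Inverse of :func:`_warp_cycle_fraction` (observable phase -> linear time)."""
    a = np.asarray(a, dtype=float)
    d = (1.0 - a) / 2.0
    return np.where(v < 0.5, 2.0 * v * d, d + (v - 0.5) * 2.0 * (1.0 - d))


def powerlaw_noise(
    shape: tuple[int, ...],
    sample_rate: float,
    exponent: float = 1.0,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """1/f^chi noise by spectral shaping of white noise (exact target slope).

    White Gaussian noise is filtered in the frequency domain by f^(-chi/2)
    (the DC bin is zeroed) and rescaled analytically so the expected standard
    deviation equals ``scale``.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    # expected variance of the shaped series, from Parseval on the gain
    expected_var = np.sum(gain[1:] ** 2 * np.where(
        (np.arange(1, gain.size) == gain.size - 1) & (n % 2 == 0), 1.0, 2.0
    )) / n
    if expected_var > 0:
        shaped *= scale / np.sqrt(expected_var)
    return shaped


def _burst_preferred_phases(n_items: int, params: SignalParams) -> np.ndarray:
    """Preferred burst phases (radians): an equally spaced fan that widens with n."""
    span = min(2.0 * np.pi, params.phase_span_per_item * n_items)
    offsets = (np.arange(n_items) + 0.5) / n_items - 0.5
    return params.burst_phase_center + span * offsets


def _phase_sigma(n_items: int, params: SignalParams) -> float:
    """Wrapped-normal jitter SD from the item-dependent concentration."""
    kappa = max(params.kappa_floor, params.coupling_base_kappa - params.dispersion_slope * n_items)
    return 1.0 / np.sqrt(kappa)


def _generate_epochs(
    params: SignalParams,
    n_items: np.ndarray,
    n_samples: int,
    t_start: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized core: one row per epoch, driven by that epoch's item count."""
    n_items = np.asarray(n_items, dtype=int)
    n_epochs = n_items.size
    fs = params.sample_rate
    f0 = params.theta_freq
    t = t_start + np.arange(n_samples) / fs

    out = np.zeros((n_epochs, n_samples))

    # --- theta carrier (optionally skewed), random phase per epoch ----------
    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=n_epochs)
    asym = np.clip(
        params.asymmetry + params.asymmetry_slope * n_items, 0.0, 0.95
    )
    cycles = f0 * t[None, :] + phi0[:, None] / (2.0 * np.pi)
    u = np.mod(cycles, 1.0)
    v = _warp_cycle_fraction(u, asym[:, None])
    amp = params.theta_amp_base + params.theta_amp_slope * n_items
    out += amp[:, None] * np.cos(2.0 * np.pi * v)

    # secondary high-theta carrier: amplitude proportional to load, absent at rest
    if params.theta_high_amp_slope > 0 and np.any(n_items > 0):
        amp2 = params.theta_high_amp_slope * n_items
        phi2 = rng.uniform(0.0, 2.0 * np.pi, size=n_epochs)
        out += amp2[:, None] * np.cos(
            2.0 * np.pi * params.theta_high_freq * t[None, :] + phi2[:, None]
        )

    # --- gamma bursts at theta phases ---------------------------------------
    if params.gamma_burst_amp > 0:
        first_cycle = np.floor(f0 * t[0] + phi0 / (2.0 * np.pi)).astype(int) - 1
        n_cycles = int(np.ceil(f0 * (t[-1] - t[0]))) + 3
        for f_gamma in params.gamma_freqs:
            sigma_b = params.burst_width_cycles / (4.0 * f_gamma)
            half = int(np.ceil(3.0 * sigma_b * fs))
            offs = np.arange(-half, half + 1)
            burst_rows = []
            burst_times = []
            for e in range(n_epochs):
                k = int(n_items[e])
                if params.n_bursts_override is not None:
                    k = params.n_bursts_override
                if k == 0:
                    continue
                mu = _burst_preferred_phases(k, params)  # (k,)
                m = first_cycle[e] + np.arange(n_cycles)  # cycle indices
                if params.coupled:
                    jitter = rng.normal(
                        0.0, _phase_sigma(k, params), size=(n_cycles, k)
                    )
                    ph = mu[None, :] + jitter
                else:
                    ph = rng.uniform(0.0, 2.0 * np.pi, size=(n_cycles, k))
                vfrac = np.mod(ph / (2.0 * np.pi), 1.0)
                ufrac = _unwarp_cycle_fraction(vfrac, asym[e])
                tb = (m[:, None] + ufrac - phi0[e] / (2.0 * np.pi)) / f0
                tb = tb.ravel()
                keep = (tb > t[0] - 3.0 * sigma_b) & (tb < t[-1] + 3.0 * sigma_b)
                tb = tb[keep]
                burst_rows.append(np.full(tb.size, e))
                burst_times.append(tb)
            if not burst_times:
                continue
            rows = np.concatenate(burst_rows)
            tb = np.concatenate(burst_times)
            xi = rng.uniform(0.0, 2.0 * np.pi, size=tb.size)  # carrier phase
            s0 = np.round((tb - t[0]) * fs).astype(int)
            idx = s0[:, None] + offs[None, :]
            dt = t[0] + idx / fs - tb[:, None]
            vals = (
                params.gamma_burst_amp
                * np.exp(-(dt**2) / (2.0 * sigma_b**2))
                * np.cos(2.0 * np.pi * f_gamma * dt + xi[:, None])
            )
            inside = (idx >= 0) & (idx < n_samples)
            flat = rows[:, None] * n_samples + np.clip(idx, 0, n_samples - 1)
            np.add.at(out.ravel(), flat[inside], vals[inside])

    # --- aperiodic background ------------------------------------------------
    if params.noise_scale > 0:
        chi = params.noise_exponent + params.noise_exponent_slope * n_items
        for c in np.unique(chi):
            rows = np.flatnonzero(chi == c)
            out[rows] += powerlaw_noise(
                (rows.size, n_samples), fs, exponent=float(c),
                scale=params.noise_scale, rng=rng,
            )

    # --- phase-locked evoked transient --------------------------------------
    if params.evoked_amp > 0:
        out += _evoked_transient(
            t, params.evoked_amp, params.evoked_latency, params.evoked_width, f0
        )[None, :]

    return out


def _evoked_transient(
    t: np.ndarray, amplitude: float, latency: float, width: float, freq: float
) -> np.ndarray:
    dt = t - latency
    return amplitude * np.exp(-(dt**2) / (2.0 * width**2)) * np.cos(2.0 * np.pi * freq * dt)


def generate_epoch(
    params: SignalParams,
    n_items: int,
    duration: float,
    seed: int | np.random.Generator | None = None,
    t_start: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One epoch of the generative model; returns ``(times, signal)``.

    ``n_items`` is the number of sequence items (remaining path locations)
    represented in the epoch.  With ``n_items = 0`` and ``noise_scale = 0``
    the output degenerates to a pure theta sinusoid.
    """
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    if duration < 1.0 / params.theta_freq:
        raise ValueError("duration must cover at least one theta cycle")
    if n_items > 0:
        span = min(2.0 * np.pi, params.phase_span_per_item * n_items)
        if n_items > 1 and span / n_items < 2.0 * np.pi * params.theta_freq * (
            params.burst_width_cycles / max(params.gamma_freqs)
        ):
            warnings.warn(
                "gamma bursts overlap substantially at this item count",
                RuntimeWarning,
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * params.sample_rate))
    t = t_start + np.arange(n_samples) / params.sample_rate
    x = _generate_epochs(params, np.array([n_items]), n_samples, t_start, rng)[0]
    return t, x


def inject_asymmetry(
    signal: np.ndarray,
    level: float,
    sample_rate: float,
    theta_freq: float = 4.0,
    t_start: float = 0.0,
) -> np.ndarray:
    """Skew a waveform by monotone time-warping within each nominal theta cycle.

    Ascending and descending phase durations end up in ratio
    ``(1 + level) / (1 - level)`` while the period is preserved.  ``level = 0``
    returns the signal unchanged.  The warp assumes cycles of ``1/theta_freq``
    seconds aligned to t = 0 of the *nominal* carrier; it is exact for
    sinusoids and a good approximation for narrowband theta.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    signal = np.asarray(signal, dtype=float)
    if level == 0.0:
        return signal.copy()
    n = signal.shape[-1]
    t = t_start + np.arange(n) / sample_rate
    cyc = theta_freq * t
    m = np.floor(cyc)
    u = cyc - m
    # the output at cycle fraction u shows the input's phase warp(u): resample
    v = _warp_cycle_fraction(u, level)
    t_src = (m + v) / theta_freq
    return np.interp(t_src, t, signal, left=signal[..., 0], right=signal[..., -1])


def inject_evoked(
    epochs: EpochSet,
    amplitude: float,
    latency: float,
    width: float,
    freq: float = 4.0,
    target_mask=None,
) -> EpochSet:
    """Add an identical (phase-locked) theta-frequency transient to every epoch.

    The transient is a Gaussian-windowed cosine at fixed post-event latency;
    being identical across epochs it survives trial averaging by construction.
    """
    t = epochs.times
    if not (t[0] <= latency <= t[-1]) or latency + width > t[-1]:
        raise ValueError("transient (latency + width) must lie inside the epoch")
    data = epochs.data.copy()
    transient = _evoked_transient(t, amplitude, latency, width, freq)
    if target_mask is None:
        data += transient[None, :]
    else:
        data[np.asarray(target_mask)] += transient[None, :]
    return EpochSet(
        data=data, times=t.copy(), sample_rate=epochs.sample_rate,
        labels=epochs.labels.copy(),
    )


# ---------------------------------------------------------------------------
# session -> epochs
# ---------------------------------------------------------------------------

def generate_participant(
    params: SignalParams,
    session: SessionLog,
    cue_window: tuple[float, float] = (-5.0, 8.0),
    move_window: tuple[float, float] = (-3.0, 3.0),
    seed: int | np.random.Generator | None = None,
    make_cue: bool = True,
    make_move: bool = True,
) -> tuple[EpochSet | None, EpochSet | None]:
    """Bind task labels to signals for one synthetic participant.

    Returns ``(cue_epochs, move_epochs)``.  Cue epochs are aligned to cue
    onset and driven by the trial's shortest distance; move epochs are aligned
    to each button press and driven by the remaining shortest distance from
    the pre-press cell.  The final press of each trial (goal visible on
    screen) is flagged ``is_final_step`` for downstream exclusion.
    """
    if session.n_trials == 0:
        raise ValueError("session has no trials")
    if any(t.chosen_path is None for t in session.trials) and make_move:
        raise ValueError("session skeleton has no walked paths; run simulate_agent first")
    rng = np.random.default_rng(seed)
    side = session.grid.side
    fs = params.sample_rate

    cue_set = None
    move_set = None

    if make_cue:
        n_cue = int(round((cue_window[1] - cue_window[0]) * fs))
        items = np.array([t.shortest_distance for t in session.trials])
        data = _generate_epochs(params, items, n_cue, cue_window[0], rng)
        labels = pd.DataFrame(
            {
                "event_type": "cue",
                "trial_number": [t.trial_index for t in session.trials],
                "block": [t.block for t in session.trials],
                "goal_distance": items,
                "steps_remaining": items,
                "correct": [t.correct for t in session.trials],
                "novel": [t.novel for t in session.trials],
                "familiarity": [t.familiarity for t in session.trials],
                "first_of_block": [t.first_of_block for t in session.trials],
                "is_final_step": False,
            }
        )
        times = cue_window[0] + np.arange(n_cue) / fs
        cue_set = EpochSet(data=data, times=times, sample_rate=fs, labels=labels)

    if make_move:
        n_move = int(round((move_window[1] - move_window[0]) * fs))
        items = []
        rows = []
        for t in session.trials:
            path = t.chosen_path
            n_steps = len(path) - 1
            for k in range(1, n_steps + 1):
                pre_cell = path[k - 1]
                remaining = manhattan_distance(pre_cell, t.goal, side)
                items.append(remaining)
                rows.append(
                    {
                        "event_type": "move",
                        "trial_number": t.trial_index,
                        "block": t.block,
                        "goal_distance": t.shortest_distance,
                        "steps_remaining": n_steps - k + 1,
                        "shortest_remaining": remaining,
                        "correct": t.correct,
                        "novel": t.novel,
                        "familiarity": t.familiarity,
                        "first_of_block": t.first_of_block,
                        "is_final_step": k == n_steps,
                        "step_in_trial": k,
                    }
                )
        items = np.array(items)
        data = _generate_epochs(params, items, n_move, move_window[0], rng)
        labels = pd.DataFrame(rows)
        times = move_window[0] + np.arange(n_move) / fs
        move_set = EpochSet(data=data, times=times, sample_rate=fs, labels=labels)

    return cue_set, move_set
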