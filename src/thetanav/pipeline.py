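"""Orchestration: per-participant outcome tables, condition slices, group reports.

Reproduces the analysis logic end to end on any epoch set: extract per-epoch
outcomes (theta band power, residualized PAC, asymmetry index), regress each
on distance to goal within condition slices (correct/incorrect; novel vs.
previously traversed, defined on correct trials), and test the
per-participant coefficients at the group level.  A cohort simulator binds
the task generator and signal generator into synthetic participants so the
whole chain is testable by parameter recovery.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import controls, coupling, spectral, stats, task
from .signals import EpochSet, SignalParams, generate_participant

__all__ = [
    "AnalysisConfig",
    "cue_outcome_table",
    "move_outcome_table",
    "slice_masks",
    "participant_slope",
    "run_cue_analysis",
    "run_navigation_analysis",
    "simulate_cohort",
    "cohort_group_stats",
    "write_report",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants: bands, windows, exclusion rules, test level."""

    theta_low: tuple[float, float] = (2.0, 5.0)
    theta_high: tuple[float, float] = (6.0, 9.0)
    gamma_slow: tuple[float, float] = (30.0, 70.0)
    gamma_fast: tuple[float, float] = (70.0, 140.0)
    cue_window: tuple[float, float] = (0.0, 3.0)
    cue_baseline: tuple[float, float] = (-1.5, -0.5)
    move_window: tuple[float, float] = (-1.0, 1.0)
    move_baseline: tuple[float, float] = (-1.0, -0.5)
    distance_bins: tuple[int, ...] = (3, 4, 5)
    alpha: float = 0.05
    exclude_final_step: bool = True
    exclude_first_of_block_cues: bool = False
    filter_family: str = "fir"
    n_cycles: float = 5.0
    mvl_normalized: bool = True
    nuisance: tuple[str, ...] = ("trial_number",)
    apply_notch: bool = False  # 48-52 Hz band-stop for imported real data
    single_precision: bool = False  # float32 FFT pipeline for large recovery runs

    @property
    def fft_dtype(self):
        return np.complex64 if self.single_precision else np.complex128

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _maybe_notch(epochs: EpochSet, config: AnalysisConfig) -> EpochSet:
    if not config.apply_notch:
        return epochs
    return EpochSet(
        data=coupling.notch_zero_phase(epochs.data, epochs.sample_rate),
        times=epochs.times.copy(),
        sample_rate=epochs.sample_rate,
        labels=epochs.labels.copy(),
    )


def cue_outcome_table(
    epochs: EpochSet, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Per-cue-epoch outcomes: raw theta band powers over the cue window."""
    epochs = _maybe_notch(epochs, config)
    table = epochs.labels.copy()
    for name, band in (("power_low", config.theta_low), ("power_high", config.theta_high)):
        bp = spectral.band_power_raw(
            epochs, band=band, window=config.cue_window, n_cycles=config.n_cycles
        )
        table[name] = bp["power"].to_numpy()
    if config.exclude_first_of_block_cues and "first_of_block" in table:
        table = table.loc[~table["first_of_block"]].reset_index(drop=True)
    return table


def move_outcome_table(
    epochs: EpochSet,
    config: AnalysisConfig = AnalysisConfig(),
    outcomes: tuple[str, ...] = (
        "power_low", "power_high", "pac_fast", "pac_slow", "ai",
    ),
) -> pd.DataFrame:
    """Per-move-epoch outcomes over the window around each button press.

    Band powers are raw (regression convention); PAC columns are the raw MVL
    plus its power-residualized version, fit on this participant's epochs;
    ``ai`` is the theta waveform asymmetry index.
    """
    epochs = _maybe_notch(epochs, config)
    table = epochs.labels.copy()
    bands = {"power_low": config.theta_low, "power_high": config.theta_high}
    power_wanted = {n: bands[n] for n in outcomes if n in bands}
    if power_wanted:
        bp = spectral.band_power_multi(
            epochs, power_wanted, window=config.move_window,
            n_cycles=config.n_cycles, dtype=config.fft_dtype,
        )
        for name in power_wanted:
            table[name] = bp[name].to_numpy()
    for name in outcomes:
        if name in bands:
            continue
        elif name in ("pac_fast", "pac_slow"):
            gamma = config.gamma_fast if name == "pac_fast" else config.gamma_slow
            pac = coupling.pac_table(
                epochs, theta_band=config.theta_low, gamma_band=gamma,
                window=config.move_window, family=config.filter_family,
                dtype=config.fft_dtype,
            )
            pac = coupling.residualize_pac(pac)
            mvl_col = "raw_mvl" if config.mvl_normalized else "raw_mvl_unnorm"
            table[name] = pac[mvl_col].to_numpy()
            table[f"residual_{name}"] = pac["residual_pac"].to_numpy()
            table[f"theta_power_{name}"] = pac["theta_power"].to_numpy()
            table[f"gamma_power_{name}"] = pac["gamma_power"].to_numpy()
        elif name == "ai":
            ai = controls.asymmetry_per_epoch(
                epochs, band=config.theta_low, window=config.move_window
            )
            table["ai"] = ai["ai"].to_numpy()
        else:
            raise ValueError(f"unknown outcome {name!r}")
    return table


def slice_masks(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Condition slices: correct/incorrect on all trials; novel/traversed on correct.

    Slices are disjoint within each pair and conserve epoch counts:
    correct + incorrect = all retained; novel + traversed = correct.
    """
    correct = table["correct"].to_numpy(dtype=bool)
    novel = table["novel"].to_numpy(dtype=bool)
    return {
        "correct": correct,
        "incorrect": ~correct,
        "novel": correct & novel,
        "traversed": correct & ~novel,
    }


def _retained(table: pd.DataFrame, config: AnalysisConfig, move: bool) -> pd.DataFrame:
    out = table
    if move and config.exclude_final_step and "is_final_step" in out:
        out = out.loc[~out["is_final_step"].astype(bool)]
    return out.reset_index(drop=True)


def participant_slope(
    table: pd.DataFrame,
    outcome: str,
    distance_col: str,
    config: AnalysisConfig = AnalysisConfig(),
    slice_name: str | None = None,
) -> stats.RegressionResult:
    """Distance coefficient for one outcome in one condition slice."""
    if slice_name is not None:
        table = table.loc[slice_masks(table)[slice_name]]
    return stats.epoch_regression(
        table, outcome=outcome, distance_col=distance_col,
        nuisance=config.nuisance, slice_name=slice_name,
    )


def _group_section(
    tables: list[pd.DataFrame],
    outcomes: tuple[str, ...],
    distance_col: str,
    config: AnalysisConfig,
    slices: tuple[str, ...] = ("correct", "incorrect", "novel", "traversed"),
) -> dict:
    """Per-slice group tests + distance profiles across participants."""
    beta_rows = []
    for pid, table in enumerate(tables):
        for outcome in outcomes:
            for sl in slices:
                try:
                    res = participant_slope(
                        table, outcome, distance_col, config, slice_name=sl
                    )
                except ValueError:
                    continue  # slice empty or single-level for this participant
                beta_rows.append(
                    {
                        "participant": pid,
                        "outcome": outcome,
                        "slice": sl,
                        "beta_distance": res.beta_distance,
                        "n_epochs": res.n,
                    }
                )
    betas = pd.DataFrame(beta_rows)
    group_rows = []
    for (outcome, sl), grp in betas.groupby(["outcome", "slice"]):
        if len(grp) < 3:
            continue
        try:
            g = stats.group_test(grp["beta_distance"].to_numpy())
        except ValueError:  # degenerate (e.g. duplicated participants)
            continue
        group_rows.append(
            {
                "outcome": outcome,
                "slice": sl,
                "test": "one_sample",
                "mean_beta": g.mean,
                "t": g.t,
                "df": g.df,
                "p": g.p,
                "cohens_d": g.cohens_d,
                "n_participants": g.n,
                "significant": g.p < config.alpha,
            }
        )
    # paired contrasts between matched slices
    for a, b in (("correct", "incorrect"), ("novel", "traversed")):
        for outcome in outcomes:
            wa = betas.query("outcome == @outcome and slice == @a").set_index("participant")
            wb = betas.query("outcome == @outcome and slice == @b").set_index("participant")
            common = wa.index.intersection(wb.index)
            if len(common) < 3:
                continue
            g = stats.group_test(
                wa.loc[common, "beta_distance"].to_numpy(),
                mode="paired",
                other=wb.loc[common, "beta_distance"].to_numpy(),
            )
            group_rows.append(
                {
                    "outcome": outcome,
                    "slice": f"{a}_vs_{b}",
                    "test": "paired",
                    "mean_beta": g.mean,
                    "t": g.t,
                    "df": g.df,
                    "p": g.p,
                    "cohens_d": g.cohens_d,
                    "n_participants": g.n,
                    "significant": g.p < config.alpha,
                }
            )
    profiles = []
    for pid, table in enumerate(tables):
        sub = table.loc[slice_masks(table)["correct"]]
        for outcome in outcomes:
            prof = stats.distance_profile(
                sub, outcome, distance_col=distance_col,
                bins=config.distance_bins, descending=True,
            )
            prof["participant"] = pid
            prof["outcome"] = outcome
            profiles.append(prof)
    profile = (
        pd.concat(profiles, ignore_index=True)
        .groupby(["outcome", "distance"], as_index=False)
        .agg(mean=("mean", "mean"), sem=("mean", "sem"), n_participants=("mean", "count"))
    )
    return {"betas": betas, "group": pd.DataFrame(group_rows), "profile": profile}


def run_cue_analysis(
    participants: list[EpochSet],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Cue-period report: theta power vs. shortest distance, sliced and tested."""
    tables = [
        _retained(cue_outcome_table(ep, config), config, move=False)
        for ep in participants
    ]
    section = _group_section(
        tables, ("power_low", "power_high"), "goal_distance", config
    )
    section["meta"] = {"config_hash": config.hash(), "kind": "cue"}
    return section


def run_navigation_analysis(
    participants: list[EpochSet],
    config: AnalysisConfig = AnalysisConfig(),
    outcomes: tuple[str, ...] = (
        "power_low", "power_high", "residual_pac_fast", "residual_pac_slow",
    ),
) -> dict:
    """Navigation report: band power and residual PAC vs. steps remaining.

    The final step of each trial (goal visible) is excluded before any
    regression; distance is the remaining shortest distance from the
    pre-press cell.
    """
    compute = tuple(
        {"residual_pac_fast": "pac_fast", "residual_pac_slow": "pac_slow"}.get(o, o)
        for o in outcomes
    )
    tables = [
        _retained(move_outcome_table(ep, config, outcomes=compute), config, move=True)
        for ep in participants
    ]
    section = _group_section(tables, outcomes, "shortest_remaining", config)
    section["meta"] = {"config_hash": config.hash(), "kind": "navigation"}
    return section


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    params: SignalParams,
    n_participants: int = 23,
    n_trials: int = 100,
    n_blocks: int = 3,
    p_correct: float = 0.85,
    seed: int | None = None,
    cue_window: tuple[float, float] = (-5.0, 8.0),
    move_window: tuple[float, float] = (-3.0, 3.0),
    make_cue: bool = True,
    make_move: bool = True,
) -> list[dict]:
    """Simulate a cohort of synthetic participants (task + signals).

    Returns one record per participant with the session log and the cue/move
    epoch sets; seeds are spawned deterministically from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    out = []
    for pid, ss in enumerate(root.spawn(n_participants)):
        rng = np.random.default_rng(ss)
        session = task.generate_session(
            n_trials=n_trials, n_blocks=n_blocks, seed=rng
        )
        session = task.simulate_agent(session, p_correct=p_correct, seed=rng)
        cue, move = generate_participant(
            params, session, cue_window=cue_window, move_window=move_window,
            seed=rng, make_cue=make_cue, make_move=make_move,
        )
        out.append({"participant": pid, "session": session, "cue": cue, "move": move})
    return out


def cohort_group_stats(
    cohort: list[dict],
    outcomes: tuple[str, ...],
    config: AnalysisConfig = AnalysisConfig(),
    slice_name: str = "correct",
) -> pd.DataFrame:
    """Group-level distance-slope test per outcome on a simulated cohort's move epochs.

    Epochs outside the analyzed slice (and final steps, when excluded) are
    dropped before outcome extraction, so the PAC residualization GLM is fit
    on exactly the epochs entering the regression.  ``outcomes`` may also
    include the control statistics ``"ai"`` and ``"exponent"``.
    """
    rows = []
    betas = {o: [] for o in outcomes}
    compute = tuple(
        {"residual_pac_fast": "pac_fast", "residual_pac_slow": "pac_slow"}.get(o, o)
        for o in outcomes
        if o != "exponent"
    )
    for rec in cohort:
        epochs = rec["move"]
        keep = np.ones(epochs.n_epochs, dtype=bool)
        if slice_name is not None:
            keep &= slice_masks(epochs.labels)[slice_name]
        if config.exclude_final_step:
            keep &= ~epochs.labels["is_final_step"].to_numpy(dtype=bool)
        epochs = epochs.select(keep)
        table = move_outcome_table(epochs, config, outcomes=compute)
        for o in outcomes:
            if o == "exponent":
                res = controls.aperiodic_vs_distance(
                    epochs, distance_col="shortest_remaining",
                    freq_range=(1.0, min(150.0, epochs.sample_rate / 2.0 * 0.95)),
                    equalize=True, min_epochs=10,
                )
            else:
                res = participant_slope(
                    table, o, "shortest_remaining", config, slice_name=None
                )
            betas[o].append(res.beta_distance)
    for o in outcomes:
        g = stats.group_test(np.asarray(betas[o]))
        rows.append(
            {
                "outcome": o,
                "mean_beta": g.mean,
                "t": g.t,
                "df": g.df,
                "p": g.p,
                "cohens_d": g.cohens_d,
                "significant": g.p < config.alpha,
            }
        )
    return pd.DataFrame(rows)


def run_controls(
    participants: list[EpochSet],
    config: AnalysisConfig = AnalysisConfig(),
    which: tuple[str, ...] = ("aperiodic", "evoked", "asymmetry"),
    distance_col: str = "shortest_remaining",
    seed: int | None = 0,
) -> dict:
    """Confound-control report: per-participant distance slopes + group tests.

    ``aperiodic`` regresses the peak-excluded 1/f exponent on distance
    (trial counts equalized across distances); ``evoked`` the trial-averaged
    theta band amplitude (count-matched subsampling); ``asymmetry`` the
    per-epoch waveform asymmetry index with the trial-number nuisance.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    for pid, (epochs, ss) in enumerate(zip(participants, root.spawn(len(participants)))):
        epochs = _maybe_notch(epochs, config)
        dist_col = distance_col if distance_col in epochs.labels else "goal_distance"
        for name in which:
            if name == "aperiodic":
                res = controls.aperiodic_vs_distance(
                    epochs, distance_col=dist_col,
                    freq_range=(1.0, min(150.0, epochs.sample_rate / 2.0 * 0.95)),
                    window=config.move_window, equalize=True, min_epochs=10,
                )
                beta = res.beta_distance
            elif name == "evoked":
                prof = controls.evoked_amplitude_by_distance(
                    epochs, band=config.theta_low, window=config.move_window,
                    distance_col=dist_col, seed=np.random.default_rng(ss),
                )
                beta = controls.evoked_vs_distance(prof).beta_distance
            elif name == "asymmetry":
                table = controls.asymmetry_per_epoch(
                    epochs, band=config.theta_low, window=config.move_window
                )
                beta = controls.asymmetry_vs_distance(
                    table, distance_col=dist_col, nuisance=config.nuisance
                ).beta_distance
            else:
                raise ValueError(f"unknown control {name!r}")
            rows.append({"participant": pid, "control": name, "beta_distance": beta})
    betas = pd.DataFrame(rows)
    group_rows = []
    for name, grp in betas.groupby("control"):
        if len(grp) < 3:
            continue
        try:
            g = stats.group_test(grp["beta_distance"].to_numpy())
        except ValueError:
            continue
        group_rows.append(
            {
                "control": name, "mean_beta": g.mean, "t": g.t, "df": g.df,
                "p": g.p, "cohens_d": g.cohens_d,
                "significant": g.p < config.alpha,
            }
        )
    return {
        "betas": betas,
        "group": pd.DataFrame(group_rows),
        "meta": {"config_hash": config.hash(), "kind": "controls"},
    }


def null_signal_params(sample_rate: float = 600.0) -> SignalParams:
    """Generator with every distance-linked effect switched off.

    Theta amplitude, burst count and phase dispersion, waveform asymmetry and
    the aperiodic exponent are all constant in the item count, and gamma
    bursts carry no theta-phase preference -- the signal statistics are fully
    independent of distance, so any distance slope the pipeline finds is a
    false positive.  Asymmetry is left at a nonzero constant level (0.2) so
    the non-sinusoidal-theta-without-coupling confound is present.
    """
    return SignalParams(
        sample_rate=sample_rate,
        theta_amp_slope=0.0,
        theta_high_amp_slope=0.0,
        dispersion_slope=0.0,
        coupled=False,
        asymmetry=0.2,
        n_bursts_override=3,
    )


def recovery_experiment(
    n_cohorts: int,
    seed: int,
    params: SignalParams | None = None,
    outcomes: tuple[str, ...] = ("power_low", "power_high", "residual_pac_fast"),
    config: AnalysisConfig = AnalysisConfig(),
    n_participants: int = 23,
    n_trials: int = 100,
    p_correct: float = 0.85,
    move_window: tuple[float, float] = (-3.0, 3.0),
) -> pd.DataFrame:
    """Repeat the full pipeline over independent synthetic cohorts.

    For each cohort: simulate the task and signals, run the navigation
    regressions on correct non-final move epochs, and record the group test
    per outcome.  One row per (cohort, outcome); the caller summarizes sign
    recovery or type-I rates.
    """
    params = SignalParams() if params is None else params
    root = np.random.SeedSequence(seed)
    rows = []
    for c, ss in enumerate(root.spawn(n_cohorts)):
        cohort_seed = int(ss.generate_state(1)[0] % (2**31))
        cohort = simulate_cohort(
            params, n_participants=n_participants, n_trials=n_trials,
            p_correct=p_correct, seed=cohort_seed, make_cue=False,
            move_window=move_window,
        )
        g = cohort_group_stats(cohort, outcomes=outcomes, config=config)
        g.insert(0, "cohort", c)
        rows.append(g)
    return pd.concat(rows, ignore_index=True)


def write_report(report: dict, outdir: str | Path) -> None:
    """Write a report section as CSV tables plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, value in report.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{key}.csv", index=False)
    meta = report.get("meta", {})
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
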