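"""End-to-end simulated experiments.

Three virtual studies close the loop between synthetic gaze, the
compensation policies, and the simulated observers:

* ``exp1`` — two-alternative preference over the event-triggered
  threshold policy at nine screen-frame angular velocities (-2.0 to 2.0
  deg/s in 0.5 steps) for CW and CCW arrangements; reports per-condition
  selection rates of the compensated image (lower = more effective).
* ``exp2`` — interleaved PEST staircases recover each virtual subject's
  nulling amplitude (PSE) for half-sine compensation pulses at
  timescales 100/150/250/500/1000 ms and constant rotation (inf).
* ``exp3`` — adjustment-method calibration of the proportionality
  constants for policies A/B/C/U per virtual subject, followed by a
  round-robin paired comparison (12 trials per pair) scored with the
  Thurstone probit pipeline.

Every random component is seeded from the session seed, so a session is
reproducible from its configuration alone; all timestamps are simulated.
In exp3 the calibration and evaluation phases use different gaze
statistics (active provocation vs natural viewing), which is what makes
gaze-blind uniform compensation miscalibrate — see the package methods
note for the rationale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_gaze
from .compensation import (
    CompensationPolicy,
    TemporalFunction,
    simulate_trial,
)
from .gaze import DetectorConfig
from .observer import PreferenceObserver, PsychometricObserver, choose_side
from .psychophysics import PestConfig, run_adjustment, run_pest_pair
from .scoring import (
    ALGORITHMS,
    PairedComparisonMatrix,
    pairwise_pvalues,
    subject_scores,
    summarize,
)
from .stimulus import build_layout

__all__ = ["SessionConfig", "run_session"]

#: Magnitude of the transient temporal illusion profile, per timescale.
EQ1_AMPLITUDES = {100.0: 2.56, 150.0: 1.66, 250.0: 1.80, 500.0: 0.830, 1000.0: 0.554}
EQ1_CONSTANT = 0.277
EXP2_TIMESCALES = (100.0, 150.0, 250.0, 500.0, 1000.0, math.inf)


@dataclass(frozen=True)
class SessionConfig:
    experiment: str = "exp3"  # exp1 | exp2 | exp3
    n_subjects: int = 7
    seed: int = 0
    trial_duration_ms: float = 10_000.0
    trials_per_condition: int = 10  # exp1 (after as many training tasks)
    training_per_condition: int = 10
    trials_per_pair: int = 12  # exp3-2
    velocities: tuple[float, ...] = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0)
    response_sd: float = 1.0  # exp2 observer decision noise (deg/s)
    choice_sd: float = 0.15  # preference observer decision noise (deg)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2", "exp3"):
            raise ValueError(f"unknown experiment: {self.experiment!r}")
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("subject and trial counts must be positive")


def _natural_gaze_config(seed: int) -> synthetic_gaze.GazeSimConfig:
    """Free viewing during evaluation: sparse saccades plus blinks."""
    return synthetic_gaze.GazeSimConfig(
        saccade_rate_per_s=0.4,
        saccade_amplitude_range_deg=(3.0, 10.0),
        blink_rate_per_min=12.0,
        jitter_sd_deg=0.05,
        seed=seed,
    )


def _active_gaze_config(seed: int) -> synthetic_gaze.GazeSimConfig:
    """Deliberate illusion provocation during adjustment: rapid scanning."""
    return synthetic_gaze.GazeSimConfig(
        saccade_rate_per_s=4.5,
        saccade_amplitude_range_deg=(3.0, 10.0),
        blink_rate_per_min=0.0,
        jitter_sd_deg=0.05,
        seed=seed,
    )


def _preference_observer(rng: np.random.Generator, choice_sd: float) -> PreferenceObserver:
    """A virtual subject whose illusion favors gaze-contingent nulling.

    The transient component dominates (the reference temporal profile
    scaled to ~0.3, jittered per subject) over a mild sustained spatial
    gradient and a small baseline, and unmasked physical rotation is
    salient (veridical_salience 4): compensation that keeps turning
    while the illusion is quiescent is conspicuous, so only policies
    that track gaze state can null the percept without being seen.
    """
    tgain = max(0.1, rng.normal(0.30, 0.05))
    temporal = TemporalFunction(
        components=tuple((tgain * a, dt) for dt, a in EQ1_AMPLITUDES.items()),
        constant=0.0,
    )
    return PreferenceObserver(
        spatial_gain=max(0.02, rng.normal(0.05, 0.008)),
        temporal=temporal,
        baseline=max(0.0, rng.normal(0.02, 0.005)),
        choice_sd=choice_sd,
        veridical_salience=4.0,
        seed=int(rng.integers(2**31)),
    )


def _run_exp1(cfg: SessionConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    detector = DetectorConfig()
    records = []
    for subj in range(cfg.n_subjects):
        obs = _preference_observer(rng, cfg.choice_sd)
        for direction, dirname in ((+1, "cw"), (-1, "ccw")):
            layout = build_layout("exp1_pair", direction)
            for v_screen in cfg.velocities:
                chosen_comp = 0
                for trial in range(cfg.trials_per_condition):
                    stream, _ = synthetic_gaze.generate(
                        _natural_gaze_config(int(rng.integers(2**31))),
                        cfg.trial_duration_ms,
                    )
                    # Screen-frame velocity -> illusory frame of this pattern.
                    policy = CompensationPolicy(
                        kind="EXP1_THRESHOLD",
                        delta_theta_deg_per_s=v_screen * direction,
                    )
                    still = CompensationPolicy(kind="O")
                    comp_side = "left" if rng.random() < 0.5 else "right"
                    traces = {}
                    for side in ("left", "right"):
                        pol = policy if side == comp_side else still
                        traces[side] = simulate_trial(
                            layout, pol, stream, detector, disks=layout.disks_on(side)
                        )
                    choice = choose_side(obs, traces["left"], traces["right"])
                    chosen_comp += int(choice == comp_side)
                records.append(
                    {
                        "subject": subj,
                        "direction": dirname,
                        "velocity_deg_per_s": v_screen,
                        "selection_rate": chosen_comp / cfg.trials_per_condition,
                    }
                )
    df = pd.DataFrame(records)
    mean_sr = (
        df.groupby(["direction", "velocity_deg_per_s"])["selection_rate"].mean().reset_index()
    )
    return {"trials": df, "mean_selection_rate": mean_sr}


def _run_exp2(cfg: SessionConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    pest = PestConfig()
    true_pse = {dt: -a for dt, a in EQ1_AMPLITUDES.items()}
    true_pse[math.inf] = -EQ1_CONSTANT
    records = []
    # Counterbalancing: half the subjects run the illusion block first.
    for subj in range(cfg.n_subjects):
        block_order = ("illusion", "control") if subj % 2 == 0 else ("control", "illusion")
        for block in block_order:
            pses = true_pse if block == "illusion" else {dt: 0.0 for dt in true_pse}
            for dt in EXP2_TIMESCALES:
                obs = PsychometricObserver(
                    pse_by_timescale=pses,
                    response_sd=cfg.response_sd,
                    seed=int(rng.integers(2**31)),
                )
                est = run_pest_pair(obs, dt, pest, seed=int(rng.integers(2**31)))
                records.append(
                    {
                        "subject": subj,
                        "block": block,
                        "block_order": "->".join(block_order),
                        "dt_ms": dt,
                        "pse_true": pses[dt],
                        "pse_est": est,
                    }
                )
    df = pd.DataFrame(records)
    mean_pse = (
        df[df.block == "illusion"].groupby("dt_ms")["pse_est"].mean().reset_index()
    )
    return {"trials": df, "mean_pse": mean_pse}


def _run_exp3(cfg: SessionConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    layout = build_layout("exp1_pair", +1)
    detector = DetectorConfig()
    kinds = [k for k in ALGORITHMS if k != "O"]

    def make_cal_stream(seed: int):
        stream, _ = synthetic_gaze.generate(_active_gaze_config(seed), cfg.trial_duration_ms)
        return stream

    constants_rows = []
    score_rows = []
    all_counts = np.zeros((len(ALGORITHMS), len(ALGORITHMS)))
    for subj in range(cfg.n_subjects):
        obs = _preference_observer(rng, cfg.choice_sd)
        # --- 3-1: adjustment-method calibration per policy kind ---
        constants = {"O": 0.0}
        for kind in kinds:
            constants[kind] = run_adjustment(
                obs,
                CompensationPolicy(kind=kind),
                layout,
                make_cal_stream,
                seed=int(rng.integers(2**20)),
                detector=detector,
            )
        constants_rows.append({"subject": subj, **constants})
        # --- 3-2: round-robin paired comparison under natural viewing ---
        m = PairedComparisonMatrix(trials_per_pair=cfg.trials_per_pair)
        policies = {
            k: CompensationPolicy(kind=k).with_constant(constants[k]) for k in ALGORITHMS
        }
        for a, b in combinations(ALGORITHMS, 2):
            for trial in range(cfg.trials_per_pair):
                stream, _ = synthetic_gaze.generate(
                    _natural_gaze_config(int(rng.integers(2**31))),
                    cfg.trial_duration_ms,
                )
                first_left = rng.random() < 0.5
                side_of = {a: "left" if first_left else "right"}
                side_of[b] = "right" if first_left else "left"
                traces = {
                    k: simulate_trial(
                        layout, policies[k], stream, detector, disks=layout.disks_on(s)
                    )
                    for k, s in side_of.items()
                }
                left_k = a if first_left else b
                right_k = b if first_left else a
                moved_more = choose_side(obs, traces[left_k], traces[right_k])
                # The algorithm perceived as *more stationary* wins.
                winner = right_k if moved_more == "left" else left_k
                loser = a if winner == b else b
                m.record(winner, loser)
        all_counts += m.counts
        score_rows.append({"subject": subj, **subject_scores(m)})

    scores = pd.DataFrame(score_rows).set_index("subject")
    consts = pd.DataFrame(constants_rows).set_index("subject")
    summary = summarize(scores, consts)
    pvals = pairwise_pvalues(scores)
    return {
        "constants": consts,
        "scores": scores,
        "summary": summary,
        "pairwise_p": pvals,
        "pooled_counts": pd.DataFrame(all_counts, index=ALGORITHMS, columns=ALGORITHMS),
    }


def run_session(config: SessionConfig) -> dict:
    """Run the configured experiment and (optionally) write its artifacts.

    Returns a results bundle of data frames; with ``out_dir`` set, trial
    logs are written as CSV and a JSON summary alongside.
    """
    runner = {"exp1": _run_exp1, "exp2": _run_exp2, "exp3": _run_exp3}[config.experiment]
    bundle = runner(config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg_dict = dataclasses.asdict(config)
        cfg_dict.pop("out_dir")  # environmental, not part of the session identity
        summary = {"config": cfg_dict}
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.csv", lineterminator="\n")
                summary[name] = json.loads(obj.replace({math.inf: "inf"}).to_json(orient="split"))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return bundle
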