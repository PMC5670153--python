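"""Developmental runs, calibration, discrepancy scoring and comparisons.

A developmental run trains the network under one stimulus diet and, at each
checkpoint (every 500 exposures = 1 simulated year by default), freezes the
weights and runs the assessment battery: A / V / AV recognition accuracy,
optionally recognition times and the McGurk battery.  Reference behavioral
curves (age vs % correct per condition, e.g. for a TD or ASD cohort) are
user-supplied delimited text and are only ever compared against, never
generated; the discrepancy metric is the mean absolute error between model
and reference at matched ages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig
from .dynamics import Network
from .plasticity import (
    EPOCHS_PER_YEAR,
    TrainingResult,
    TrainingSchedule,
    epoch_to_age,
    make_schedule,
    train,
)
from .stimuli import Condition
from .tasks import (
    AccuracyCurve,
    McGurkResult,
    accuracy_curve,
    mcgurk_battery,
    run_trial,
)

__all__ = [
    "BatteryConfig",
    "RunConfig",
    "DevelopmentalTrajectory",
    "ReferenceCurves",
    "CalibrationAnchors",
    "run_development",
    "discrepancy",
    "calibrate",
    "run_rt_experiment",
    "rt_table",
    "compare_perturbations",
]

DEFAULT_CHECKPOINTS = tuple(range(0, 8501, EPOCHS_PER_YEAR))


@dataclass(frozen=True)
class BatteryConfig:
    """Sizes of the per-checkpoint assessment batteries.

    The full tier mirrors the standard protocol (100 trials per efficacy
    level, 20 McGurk repetitions per phoneme and level); the fast tier (25
    trials, 4 reps) is for quick exploration and CI.
    """

    n_trials: int = 100
    mcgurk_reps: int = 20
    run_mcgurk: bool = False
    run_rt: bool = False
    rt_trials: int = 100

    @classmethod
    def fast(cls, **kw) -> "BatteryConfig":
        kw.setdefault("n_trials", 25)
        kw.setdefault("mcgurk_reps", 4)
        kw.setdefault("rt_trials", 25)
        return cls(**kw)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one developmental run."""

    model: ModelConfig = ModelConfig()
    schedule_kind: str = "TD"
    schedule_params: dict = field(default_factory=dict)
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS
    battery: BatteryConfig = BatteryConfig()
    seed: int = 0

    def schedule(self) -> TrainingSchedule:
        return make_schedule(self.schedule_kind, **self.schedule_params)


@dataclass
class DevelopmentalTrajectory:
    """Per-checkpoint behavioral summaries of one developmental run."""

    table: pd.DataFrame  # epoch, age_years, pct_A, pct_V, pct_AV, gain, sums
    accuracy: dict[int, dict[str, AccuracyCurve]]   # epoch -> condition -> curve
    mcgurk: dict[int, McGurkResult]
    rt: dict[int, pd.DataFrame]
    training: TrainingResult
    config: RunConfig

    def at_age(self, years: float) -> pd.Series:
        idx = (self.table["age_years"] - years).abs().idxmin()
        return self.table.loc[idx]


def _battery_at_checkpoint(
    net: Network,
    config: ModelConfig,
    battery: BatteryConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, AccuracyCurve], Optional[McGurkResult], Optional[pd.DataFrame]]:
    curves = {
        c.value: accuracy_curve(net, c, config, rng, n_trials=battery.n_trials)
        for c in (Condition.A, Condition.V, Condition.AV)
    }
    mcgurk = mcgurk_battery(net, config, rng, reps=battery.mcgurk_reps) if battery.run_mcgurk else None
    rt = rt_table(net, config, rng, n_trials=battery.rt_trials) if battery.run_rt else None
    return curves, mcgurk, rt


def run_development(run: RunConfig, progress: bool = False) -> DevelopmentalTrajectory:
    """Train under the configured diet and assess at every checkpoint.

    One master seed derives independent streams for the training noise and
    for each checkpoint battery, so runs are reproducible end to end.
    """
    ss = np.random.SeedSequence(run.seed)
    train_seed, battery_seed = ss.spawn(2)
    schedule = run.schedule()
    result = train(
        run.model,
        schedule,
        checkpoints=list(run.checkpoints),
        rng=np.random.default_rng(train_seed),
        progress=progress,
    )
    rows = []
    accuracy: dict[int, dict[str, AccuracyCurve]] = {}
    mcgurk: dict[int, McGurkResult] = {}
    rt: dict[int, pd.DataFrame] = {}
    battery_children = battery_seed.spawn(len(result.checkpoints))
    sums = result.synaptic_sums.set_index("epoch")
    for child, (epoch, net) in zip(battery_children, sorted(result.checkpoints.items())):
        rng = np.random.default_rng(child)
        curves, mg, rt_df = _battery_at_checkpoint(net, run.model, run.battery, rng)
        accuracy[epoch] = curves
        if mg is not None:
            mcgurk[epoch] = mg
        if rt_df is not None:
            rt[epoch] = rt_df
        row = {
            "epoch": epoch,
            "age_years": epoch_to_age(epoch),
            "pct_A": curves["A"].mean,
            "pct_V": curves["V"].mean,
            "pct_AV": curves["AV"].mean,
        }
        row["gain"] = row["pct_AV"] - row["pct_A"]
        for col in ("sum_va", "sum_av", "sum_sa", "sum_sv"):
            row[col] = sums.loc[epoch, col] if epoch in sums.index else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("epoch").reset_index(drop=True)
    return DevelopmentalTrajectory(
        table=table,
        accuracy=accuracy,
        mcgurk=mcgurk,
        rt=rt,
        training=result,
        config=run,
    )


# ---------------------------------------------------------------------------
# reference curves and discrepancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceCurves:
    """Behavioral reference (age vs % correct per condition) for one cohort."""

    table: pd.DataFrame  # columns: age_years, condition, pct_correct

    @classmethod
    def from_file(cls, path: str | Path, sep: str = ",") -> "ReferenceCurves":
        df = pd.read_csv(path, sep=sep)
        required = {"age_years", "condition", "pct_correct"}
        if not required.issubset(df.columns):
            raise ValueError(f"reference table must have columns {sorted(required)}")
        if df["pct_correct"].lt(0).any() or df["pct_correct"].gt(100).any():
            raise ValueError("reference percentages must lie in [0, 100]")
        return cls(table=df)


def discrepancy(
    traj: DevelopmentalTrajectory | pd.DataFrame,
    ref: ReferenceCurves,
    condition: Condition | str,
) -> float:
    """Mean absolute model-reference error, in percentage points.

    Each reference age is matched to the nearest checkpoint age (exact under
    the 500-epochs-per-year mapping).
    """
    condition = Condition(condition)
    table = traj.table if isinstance(traj, DevelopmentalTrajectory) else traj
    ref_rows = ref.table[ref.table["condition"] == condition.value]
    if ref_rows.empty:
        raise ValueError(f"reference has no rows for condition {condition.value}")
    col = f"pct_{condition.value}"
    errors = []
    for _, row in ref_rows.iterrows():
        idx = (table["age_years"] - row["age_years"]).abs().idxmin()
        errors.append(abs(table.loc[idx, col] - row["pct_correct"]))
    return float(np.mean(errors))


# ---------------------------------------------------------------------------
# recognition times
# ---------------------------------------------------------------------------

def rt_table(
    net: Network,
    config: ModelConfig,
    rng: np.random.Generator,
    n_trials: int = 100,
    conditions: Sequence[Condition] = (Condition.A, Condition.AV),
) -> pd.DataFrame:
    """Mean correct-recognition time per condition and efficacy level.

    Only correctly recognized trials contribute; cells with no resolved
    trials report NaN (the immature network resolves no auditory-alone
    trials at the lowest efficacies).
    """
    lo, hi = config.space.test_range
    rows = []
    for condition in conditions:
        for level in config.stimulus.levels:
            times = []
            for _ in range(n_trials):
                phoneme = int(rng.integers(lo, hi + 1))
                result = run_trial(net, condition, phoneme, level, config, rng)
                if result.correct and result.recognition_time is not None:
                    times.append(result.recognition_time)
            rows.append(
                {
                    "condition": condition.value,
                    "efficacy": level,
                    "mean_rt_ms": float(np.mean(times)) if times else np.nan,
                    "n_resolved": len(times),
                }
            )
    return pd.DataFrame(rows)


def run_rt_experiment(
    networks: dict[int, Network],
    config: ModelConfig,
    rng: np.random.Generator,
    n_trials: int = 100,
) -> pd.DataFrame:
    """RT battery at several developmental stages (epoch -> network)."""
    frames = []
    for epoch, net in sorted(networks.items()):
        df = rt_table(net, config, rng, n_trials=n_trials)
        df.insert(0, "epoch", epoch)
        df.insert(1, "age_years", epoch_to_age(epoch))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationAnchors:
    """Behavioral anchors the committed configuration must satisfy.

    Adult = fully trained TD network.  Units are % correct.
    """

    level1_a_max: float = 2.0        # adult A-alone at efficacy 1 is ~0%
    level7_a_min: float = 80.0       # adult A-alone at efficacy 7 exceeds 80%
    v_alone_band: tuple[float, float] = (5.0, 25.0)   # adult V-alone is poor
    mcgurk_correct_band: tuple[float, float] = (15.0, 35.0)  # adult correct-auditory


def _anchor_score(metrics: dict[str, float], anchors: CalibrationAnchors) -> float:
    """Sum of squared hinge violations of the anchors (0 = all satisfied)."""

    def above(x, lo):
        return max(0.0, lo - x)

    def below(x, hi):
        return max(0.0, x - hi)

    v = 0.0
    v += below(metrics["a_level1"], anchors.level1_a_max) ** 2
    v += above(metrics["a_level7"], anchors.level7_a_min) ** 2
    v += above(metrics["v_mean"], anchors.v_alone_band[0]) ** 2
    v += below(metrics["v_mean"], anchors.v_alone_band[1]) ** 2
    v += above(metrics["mcgurk_correct"], anchors.mcgurk_correct_band[0]) ** 2
    v += below(metrics["mcgurk_correct"], anchors.mcgurk_correct_band[1]) ** 2
    return v


def evaluate_anchors(
    config: ModelConfig,
    rng: np.random.Generator,
    n_trials: int = 100,
    mcgurk_reps: int = 5,
    total_epochs: int = 8500,
) -> dict[str, float]:
    """Train a TD network and measure the anchor quantities."""
    schedule = make_schedule("TD", total_epochs=total_epochs)
    result = train(config, schedule, checkpoints=[], rng=rng)
    net = result.network
    a = accuracy_curve(net, Condition.A, config, rng, n_trials=n_trials)
    v = accuracy_curve(net, Condition.V, config, rng, n_trials=n_trials)
    mg = mcgurk_battery(net, config, rng, reps=mcgurk_reps)
    return {
        "a_level1": a.per_level[1],
        "a_level7": a.per_level[7],
        "v_mean": v.mean,
        "mcgurk_correct": mg.pct["correct_auditory"],
    }


def _with_overrides(config: ModelConfig, overrides: dict[str, float]) -> ModelConfig:
    """Rebuild a config with dotted-path overrides, e.g. 'stimulus.a_max'."""
    groups: dict[str, dict[str, float]] = {}
    top: dict[str, float] = {}
    for path, value in overrides.items():
        if "." in path:
            group, name = path.split(".", 1)
            groups.setdefault(group, {})[name] = value
        else:
            top[path] = value
    kwargs = {}
    for group, changes in groups.items():
        sub = getattr(config, group)
        kwargs[group] = dataclasses.replace(sub, **changes)
    kwargs.update(top)
    return dataclasses.replace(config, **kwargs)


def calibrate(
    config: ModelConfig,
    anchors: CalibrationAnchors,
    search_space: dict[str, tuple[float, float]],
    budget: int,
    rng: np.random.Generator,
    evaluate_fn: Optional[Callable[[ModelConfig, np.random.Generator], dict[str, float]]] = None,
) -> tuple[ModelConfig, dict]:
    """Seeded random search over ``search_space`` minimizing anchor violation.

    ``search_space`` maps dotted parameter paths (e.g. ``"stimulus.a_max"``,
    ``"feedforward.w_max"``) to (low, high) bounds.  The seed configuration
    is evaluated first and returned unchanged when it already satisfies
    every anchor.  Exhausting the budget without satisfying the hard anchors
    reports a calibration failure together with the best configuration
    found.
    """
    if evaluate_fn is None:
        evaluate_fn = evaluate_anchors
    report: dict = {"evaluations": []}
    metrics = evaluate_fn(config, np.random.default_rng(rng.integers(2**31)))
    best_score = _anchor_score(metrics, anchors)
    best_config = config
    report["evaluations"].append({"overrides": {}, "metrics": metrics, "score": best_score})
    if best_score == 0.0:
        report["status"] = "seed config satisfies all anchors"
        return config, report
    for _ in range(budget):
        overrides = {
            path: float(rng.uniform(lo, hi)) for path, (lo, hi) in search_space.items()
        }
        try:
            candidate = _with_overrides(config, overrides)
        except ValueError:
            continue  # invalid combination (e.g. w_max ordering)
        metrics = evaluate_fn(candidate, np.random.default_rng(rng.integers(2**31)))
        score = _anchor_score(metrics, anchors)
        report["evaluations"].append(
            {"overrides": overrides, "metrics": metrics, "score": score}
        )
        if score < best_score:
            best_score, best_config = score, candidate
        if score == 0.0:
            break
    report["status"] = (
        "anchors satisfied" if best_score == 0.0 else "calibration failure: budget exhausted"
    )
    report["best_score"] = best_score
    return best_config, report


# ---------------------------------------------------------------------------
# perturbation comparison
# ---------------------------------------------------------------------------

def compare_perturbations(
    base: RunConfig,
    seeds: Sequence[int],
    arms: Sequence[str] = ("TD", "attentional", "plasticity", "connectivity"),
    reference: Optional[ReferenceCurves] = None,
    progress: bool = False,
) -> dict[str, list[DevelopmentalTrajectory]]:
    """Run each training regime over a shared seed bank.

    Arms share seeds so the exposure randomness is matched where the
    schedules allow; per-arm trajectories can then be averaged or compared
    against a reference cohort with :func:`discrepancy`.
    """
    out: dict[str, list[DevelopmentalTrajectory]] = {}
    for arm in arms:
        runs = []
        for seed in seeds:
            run = dataclasses.replace(base, schedule_kind=arm, seed=seed)
            runs.append(run_development(run, progress=progress))
        out[arm] = runs
    if reference is not None:
        for arm, runs in out.items():
            for traj in runs:
                traj.table.attrs["discrepancy"] = {
                    c.value: discrepancy(traj, reference, c)
                    for c in (Condition.A, Condition.V, Condition.AV)
                    if (reference.table["condition"] == c.value).any()
                }
    return out


def mean_trajectory(runs: Sequence[DevelopmentalTrajectory]) -> pd.DataFrame:
    """Average the checkpoint tables of several same-arm runs."""
    stacked = pd.concat([r.table for r in runs])
    return stacked.groupby("epoch", as_index=False).mean(numeric_only=True)
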