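"""Assessment battery: detection, barycenter decoding, timing, McGurk.

A presented speech event counts as detected when multisensory activity
crosses a fixed threshold (30% of the activation ceiling).  The recognized
phoneme is the integer position closest to the activity barycenter computed
over the suprathreshold units only — subthreshold activity is treated as
noise.  Detection and the barycenter are evaluated on each neuron's maximum
activity over the trial window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ModelConfig, ReadoutParams
from .dynamics import ActivityRecord, Network, simulate_trial
from .stimuli import Condition, make_trial

__all__ = [
    "TrialResult",
    "AccuracyCurve",
    "McGurkResult",
    "barycenter",
    "recognize",
    "recognition_time",
    "run_trial",
    "accuracy_curve",
    "multisensory_gain",
    "classify_mcgurk",
    "mcgurk_battery",
]

MCGURK_CATEGORIES = ("correct_auditory", "fusion", "visual", "other", "no_detection")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one stimulation."""

    detected: bool
    barycenter: Optional[float]
    recognized_phoneme: Optional[int]
    correct: bool
    recognition_time: Optional[float]
    mcgurk_category: Optional[str] = None


def barycenter(activity: np.ndarray, p: ReadoutParams) -> Optional[float]:
    """Activity-weighted mean position of the suprathreshold units.

    Returns ``None`` when nothing crosses the detection threshold — a valid
    "no detection" outcome, not an error.
    """
    activity = np.asarray(activity, dtype=float)
    mask = activity >= p.threshold
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    w = activity[idx]
    return float(np.dot(idx, w) / w.sum())


def _round_to_position(x: float) -> int:
    """Nearest integer position; exact ties (x.5) go to the lower position."""
    return int(np.ceil(x - 0.5))


def recognize(
    record: ActivityRecord, stimulus_phoneme: int, p: ReadoutParams
) -> TrialResult:
    """Decode the trial: barycenter readout of the multisensory maxima."""
    z_max = record.max_activity("multisensory")
    b = barycenter(z_max, p)
    if b is None:
        return TrialResult(
            detected=False,
            barycenter=None,
            recognized_phoneme=None,
            correct=False,
            recognition_time=None,
            mcgurk_category="no_detection",
        )
    phoneme = _round_to_position(b)
    return TrialResult(
        detected=True,
        barycenter=b,
        recognized_phoneme=phoneme,
        correct=phoneme == stimulus_phoneme,
        recognition_time=recognition_time(record, stimulus_phoneme, p),
    )


def recognition_time(
    record: ActivityRecord, stimulus_phoneme: int, p: ReadoutParams
) -> Optional[float]:
    """First threshold crossing of the target multisensory neuron.

    Reported relative to auditory stimulus onset (the visual stimulus leads
    it by 50 ms); falls back to the earliest stimulus onset for trials with
    no auditory component.  ``None`` if the target neuron never crosses.
    """
    trace = record.activity["multisensory"][:, stimulus_phoneme]
    above = np.flatnonzero(trace >= p.threshold)
    if above.size == 0:
        return None
    t_cross = float(record.times[above[0]])
    trial = record.trial
    if trial.auditory is not None:
        reference = trial.auditory.onset
    elif trial.visual is not None:
        reference = trial.visual.onset
    else:
        reference = 0.0
    return t_cross - reference


def run_trial(
    net: Network,
    condition: Condition | str,
    phoneme: int,
    efficacy_level: int,
    config: ModelConfig,
    rng: np.random.Generator,
) -> TrialResult:
    """Convenience: build, simulate and decode one trial."""
    trial = make_trial(condition, phoneme, efficacy_level, config.space, config.stimulus)
    record = simulate_trial(net, trial, rng, dt=config.dt)
    return recognize(record, phoneme, config.readout)


@dataclass(frozen=True)
class AccuracyCurve:
    """% correct per auditory efficacy level plus their unweighted mean."""

    condition: Condition
    per_level: dict[int, float]   # efficacy level -> % correct
    n_trials: int                 # trials per level

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_level.values())))

    def to_frame(self, **extra) -> pd.DataFrame:
        rows = [
            {"condition": self.condition.value, "efficacy": lvl, "pct_correct": pct, **extra}
            for lvl, pct in self.per_level.items()
        ]
        return pd.DataFrame(rows)


def accuracy_curve(
    net: Network,
    condition: Condition | str,
    config: ModelConfig,
    rng: np.random.Generator,
    n_trials: int = 100,
) -> AccuracyCurve:
    """Speech-recognition battery: ``n_trials`` random phonemes per level.

    The auditory amplitude sweeps the 7 efficacy levels; the visual
    amplitude is a constant, so for the visual-alone condition the same
    battery is replicated across the 7 cells (the mean then equals the
    single-cell value, which keeps condition means comparable).
    """
    condition = Condition(condition)
    if condition is Condition.MCGURK:
        raise ValueError("use mcgurk_battery for incongruent trials")
    lo, hi = config.space.test_range
    per_level: dict[int, float] = {}
    for level in config.stimulus.levels:
        n_correct = 0
        for _ in range(n_trials):
            phoneme = int(rng.integers(lo, hi + 1))
            result = run_trial(net, condition, phoneme, level, config, rng)
            n_correct += int(result.correct)
        per_level[level] = 100.0 * n_correct / n_trials
    return AccuracyCurve(condition=condition, per_level=per_level, n_trials=n_trials)


def multisensory_gain(av: AccuracyCurve, a: AccuracyCurve) -> dict[int, float]:
    """Multisensory gain AV - A, per efficacy level (mean via np.mean)."""
    if set(av.per_level) != set(a.per_level):
        raise ValueError("efficacy grids differ between the two curves")
    return {lvl: av.per_level[lvl] - a.per_level[lvl] for lvl in av.per_level}


def classify_mcgurk(
    recognized: Optional[int], auditory_phoneme: int, visual_phoneme: int
) -> str:
    """Categorize a McGurk-trial percept.

    correct_auditory = the auditory input; visual = the shifted visual
    input; fusion = strictly between them; other = outside the pair;
    no_detection = nothing crossed threshold.
    """
    if visual_phoneme <= auditory_phoneme:
        raise ValueError("visual phoneme must be the auditory phoneme plus a positive shift")
    if recognized is None:
        return "no_detection"
    if recognized == auditory_phoneme:
        return "correct_auditory"
    if recognized == visual_phoneme:
        return "visual"
    if auditory_phoneme < recognized < visual_phoneme:
        return "fusion"
    return "other"


@dataclass(frozen=True)
class McGurkResult:
    """Category percentages and the histogram of recognized offsets.

    Percentages are reported with two denominators: over detected trials
    (``pct``, the headline numbers; detected-trial categories sum to 100)
    and over all trials including no-detections (``pct_all``, which sums to
    100 across the five categories).
    """

    pct: dict[str, float]          # over detected trials
    pct_all: dict[str, float]      # over all trials, incl. no_detection
    histogram: pd.DataFrame        # columns: relative_position, pct_of_detected
    n_trials: int
    n_detected: int


def mcgurk_battery(
    net: Network,
    config: ModelConfig,
    rng: np.random.Generator,
    reps: int = 20,
) -> McGurkResult:
    """Incongruent-pairing battery over all phonemes and efficacy levels.

    Every phoneme whose 4-position visual partner stays in range is
    presented ``reps`` times at each auditory efficacy level, paired with
    the shifted visual stimulus; percepts are classified relative to the
    auditory/visual pair and pooled over phonemes and levels.
    """
    shift = config.space.mcgurk_shift
    phonemes = config.space.mcgurk_phonemes
    counts = {c: 0 for c in MCGURK_CATEGORIES}
    offsets: list[int] = []
    n_trials = 0
    for level in config.stimulus.levels:
        for phoneme in phonemes:
            for _ in range(reps):
                result = run_trial(net, Condition.MCGURK, int(phoneme), level, config, rng)
                category = classify_mcgurk(
                    result.recognized_phoneme, int(phoneme), int(phoneme) + shift
                )
                counts[category] += 1
                if result.detected:
                    offsets.append(result.recognized_phoneme - int(phoneme))
                n_trials += 1
    n_detected = n_trials - counts["no_detection"]
    pct_all = {c: 100.0 * counts[c] / n_trials for c in MCGURK_CATEGORIES}
    if n_detected > 0:
        pct = {
            c: 100.0 * counts[c] / n_detected
            for c in MCGURK_CATEGORIES
            if c != "no_detection"
        }
    else:
        pct = {c: 0.0 for c in MCGURK_CATEGORIES if c != "no_detection"}
    if offsets:
        vals, freq = np.unique(offsets, return_counts=True)
        hist = pd.DataFrame(
            {"relative_position": vals, "pct_of_detected": 100.0 * freq / n_detected}
        )
    else:
        hist = pd.DataFrame({"relative_position": [], "pct_of_detected": []})
    return McGurkResult(
        pct=pct, pct_all=pct_all, histogram=hist, n_trials=n_trials, n_detected=n_detected
    )
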