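"""Hebbian maturation of the inter-areal projections.

All four inter-areal matrices (cross-sensory W_av/W_va and feedforward
W_sa/W_sv) are learnable; lateral kernels are fixed.  One discrete update is
applied per stimulus exposure, using each neuron's maximum activity over the
exposure trial as its pre/post term:

    w <- w + gamma * z_post * z_pre - (gamma / w_max) * z_post * w

The decay is proportional to post-synaptic activity and carries the scaling
factor that fixes the saturation: the rule's fixed point is w = w_max *
z_pre, so full saturation requires a fully active presynaptic unit.  The two
projection classes use separate (gamma, w_max) pairs — cross-sensory links
stay modulatory with a much lower saturation — while the auditory and visual
branches of each class share parameters: asymmetries between the branches
emerge purely from the stimulus diet.

The typical-development (TD) diet is 65% congruent audiovisual and 35%
auditory-alone exposures (never visual-alone) at the highest auditory
efficacy, 8,500 exposures in total, with 500 exposures standing for one year
of experience.  Three perturbed diets model candidate ASD mechanisms:
``attentional`` (fewer AV exposures early, recovering with age),
``plasticity`` (all learning factors halved) and ``connectivity`` (a random
10% of inter-areal synapses permanently absent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ModelConfig, ProjectionConfig, build_network
from .dynamics import Network, simulate_trial
from .stimuli import Condition, make_trial

__all__ = [
    "PlasticityParams",
    "TrainingSchedule",
    "ConnectivityMask",
    "TrainingResult",
    "hebbian_update",
    "make_connectivity_mask",
    "training_exposure",
    "make_schedule",
    "train",
    "epoch_to_age",
    "age_to_epoch",
    "lesion_cross_sensory",
]

EPOCHS_PER_YEAR = 500

# projection -> (post area, pre area); 'av' means visual -> auditory
_PROJECTION_AREAS = {
    "av": ("auditory", "visual"),
    "va": ("visual", "auditory"),
    "sa": ("multisensory", "auditory"),
    "sv": ("multisensory", "visual"),
}


@dataclass(frozen=True)
class PlasticityParams:
    """Learning factor and saturation of one projection class."""

    gamma: float
    w_max: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.w_max <= 0:
            raise ValueError("w_max must be > 0")

    @classmethod
    def from_projection(cls, pc: ProjectionConfig, gamma_scale: float = 1.0) -> "PlasticityParams":
        return cls(gamma=pc.gamma * gamma_scale, w_max=pc.w_max)


def hebbian_update(
    w: np.ndarray | float,
    z_pre: np.ndarray | float,
    z_post: np.ndarray | float,
    p: PlasticityParams,
) -> np.ndarray | float:
    """One Hebbian step with activity-gated decay, clipped to [0, w_max].

    Scalar in, scalar out; with a matrix ``w`` and activity vectors the rule
    is applied elementwise via the outer product z_post (x) z_pre.
    """
    w_arr = np.asarray(w, dtype=float)
    pre = np.asarray(z_pre, dtype=float)
    post = np.asarray(z_post, dtype=float)
    if np.any(w_arr < 0) or np.any(w_arr > p.w_max):
        raise ValueError("weight outside [0, w_max]")
    if np.any(pre < 0) or np.any(pre > 1) or np.any(post < 0) or np.any(post > 1):
        raise ValueError("activities must lie in [0, 1]")
    if w_arr.ndim == 2:
        post = post[:, None]
        pre = pre[None, :]
    out = w_arr + p.gamma * post * pre - (p.gamma / p.w_max) * post * w_arr
    out = np.clip(out, 0.0, p.w_max)
    if np.isscalar(w) or np.ndim(w) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class TrainingSchedule:
    """Stochastic stimulus diet plus perturbation switches.

    ``p_av(epoch)`` gives the probability that an exposure is a congruent AV
    event; the complement is auditory-alone (visual-alone events never occur
    in training).  ``gamma_scale`` rescales every learning factor;
    ``connectivity_fraction`` is the proportion of inter-areal synapses
    clamped to zero for the whole run.
    """

    kind: str = "TD"
    total_epochs: int = 8500
    base_p_av: float = 0.65
    start_p_av: float = 0.40
    increment: float = 0.015
    block: int = EPOCHS_PER_YEAR
    gamma_scale: float = 1.0
    connectivity_fraction: float = 0.0
    training_efficacy: int = 7

    def p_av(self, epoch: int) -> float:
        if self.kind == "attentional":
            return min(self.base_p_av, self.start_p_av + self.increment * (epoch // self.block))
        return self.base_p_av


def make_schedule(kind: str, **params) -> TrainingSchedule:
    """Build one of the four training regimes.

    TD            constant 65% AV / 35% A.
    attentional   40% AV at the start, +1.5 percentage points every 500
                  epochs, capped at the TD proportion; learning untouched.
    plasticity    TD proportions with all learning factors scaled by
                  ``gamma_scale`` (default 0.5; 0.7 also studied).
    connectivity  TD proportions with ``fraction`` (default 0.10; 0.30/0.50
                  also studied) of inter-areal synapses removed for good.
    """
    if kind == "TD":
        return TrainingSchedule(kind="TD", **params)
    if kind == "attentional":
        return TrainingSchedule(kind="attentional", **params)
    if kind == "plasticity":
        scale = params.pop("gamma_scale", 0.5)
        return TrainingSchedule(kind="plasticity", gamma_scale=scale, **params)
    if kind == "connectivity":
        fraction = params.pop("fraction", params.pop("connectivity_fraction", 0.10))
        return TrainingSchedule(kind="connectivity", connectivity_fraction=fraction, **params)
    raise ValueError(f"unknown schedule kind {kind!r}")


@dataclass
class ConnectivityMask:
    """Binary masks marking which inter-areal synapses exist (1) or not (0)."""

    masks: dict[str, np.ndarray]
    fraction_removed: float

    def apply(self, net: Network) -> None:
        for key, mask in self.masks.items():
            net.projections[key].weights *= mask


def make_connectivity_mask(
    fraction: float, n: int, rng: np.random.Generator
) -> ConnectivityMask:
    """Remove a random ``fraction`` of entries in each projection matrix."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    masks = {}
    for key in _PROJECTION_AREAS:
        masks[key] = (rng.random((n, n)) >= fraction).astype(float)
    return ConnectivityMask(masks=masks, fraction_removed=fraction)


def exposure_update(
    net: Network,
    maxima: dict[str, np.ndarray],
    params: dict[str, PlasticityParams],
    mask: Optional[ConnectivityMask] = None,
) -> None:
    """Apply the Hebbian rule to all learnable projections in place.

    ``maxima`` holds each area's per-neuron maximum activity over the
    exposure trial; ``params`` maps projection class ('feedforward' /
    'cross_sensory') to its plasticity parameters.
    """
    for key, (post_area, pre_area) in _PROJECTION_AREAS.items():
        proj = net.projections[key]
        if not proj.learnable:
            continue
        cls = "feedforward" if key in ("sa", "sv") else "cross_sensory"
        proj.weights = hebbian_update(
            proj.weights, maxima[pre_area], maxima[post_area], params[cls]
        )
    if mask is not None:
        mask.apply(net)


def _plasticity_params(config: ModelConfig, schedule: TrainingSchedule) -> dict[str, PlasticityParams]:
    return {
        "feedforward": PlasticityParams.from_projection(config.feedforward, schedule.gamma_scale),
        "cross_sensory": PlasticityParams.from_projection(
            config.cross_sensory, schedule.gamma_scale
        ),
    }


def training_exposure(
    net: Network,
    config: ModelConfig,
    schedule: TrainingSchedule,
    epoch: int,
    rng: np.random.Generator,
    mask: Optional[ConnectivityMask] = None,
) -> dict[str, np.ndarray]:
    """One training exposure: draw a stimulus, simulate, update weights.

    The condition is AV with probability p_av(epoch), else auditory-alone;
    the phoneme is uniform over the test range; auditory efficacy is the
    schedule's training level.  Returns the per-area activity maxima that
    entered the update (the one-step oracle in the tests replays them).
    """
    if epoch >= schedule.total_epochs:
        raise ValueError("epoch beyond schedule")
    condition = Condition.AV if rng.random() < schedule.p_av(epoch) else Condition.A
    lo, hi = config.space.test_range
    phoneme = int(rng.integers(lo, hi + 1))
    trial = make_trial(condition, phoneme, schedule.training_efficacy, config.space, config.stimulus)
    record = simulate_trial(net, trial, rng, dt=config.dt)
    maxima = {area: record.max_activity(area) for area in record.activity}
    exposure_update(net, maxima, _plasticity_params(config, schedule), mask)
    return maxima


@dataclass
class TrainingResult:
    """Final network plus per-checkpoint snapshots and synaptic sums."""

    network: Network
    checkpoints: dict[int, Network]
    synaptic_sums: pd.DataFrame  # columns: epoch, age_years, sum_va, sum_av, sum_sa, sum_sv
    mask: Optional[ConnectivityMask] = None


def train(
    config: ModelConfig,
    schedule: TrainingSchedule,
    checkpoints: list[int],
    rng: np.random.Generator,
    network: Optional[Network] = None,
    progress: bool = False,
) -> TrainingResult:
    """Run the full training and checkpoint weight bundles.

    A checkpoint at epoch e snapshots the network after e exposures
    (checkpoint 0 is the immature network).  Deterministic given the
    generator state.
    """
    checkpoints = sorted(set(checkpoints))
    if checkpoints and (checkpoints[0] < 0 or checkpoints[-1] > schedule.total_epochs):
        raise ValueError("checkpoints must lie in [0, total_epochs]")
    net = network.copy() if network is not None else build_network(config)
    mask = None
    if schedule.connectivity_fraction > 0:
        mask = make_connectivity_mask(schedule.connectivity_fraction, net.n, rng)
        mask.apply(net)

    snapshots: dict[int, Network] = {}
    rows = []

    def record(epoch: int) -> None:
        if epoch in checkpoints:
            snapshots[epoch] = net.copy()
        sums = net.synaptic_sums()
        rows.append(
            {
                "epoch": epoch,
                "age_years": epoch_to_age(epoch),
                "sum_va": sums["va"],
                "sum_av": sums["av"],
                "sum_sa": sums["sa"],
                "sum_sv": sums["sv"],
            }
        )

    record(0)
    iterator = range(schedule.total_epochs)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=f"train[{schedule.kind}]")
        except ImportError:
            pass
    for epoch in iterator:
        training_exposure(net, config, schedule, epoch, rng, mask)
        if (epoch + 1) % EPOCHS_PER_YEAR == 0 or (epoch + 1) in checkpoints:
            record(epoch + 1)

    sums = pd.DataFrame(rows).drop_duplicates(subset="epoch").reset_index(drop=True)
    return TrainingResult(network=net, checkpoints=snapshots, synaptic_sums=sums, mask=mask)


def epoch_to_age(epoch: int) -> float:
    """Simulated age in years: 500 exposures stand for one year."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return epoch / EPOCHS_PER_YEAR


def age_to_epoch(years: float) -> int:
    return int(round(years * EPOCHS_PER_YEAR))


def lesion_cross_sensory(net: Network) -> Network:
    """Copy of the network with both cross-sensory matrices zeroed."""
    out = net.copy()
    out.projections["av"].weights[:] = 0.0
    out.projections["va"].weights[:] = 0.0
    return out
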