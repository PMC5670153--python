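"""External inputs to the network: phoneme space, Gaussian profiles, noise.

Speech events are abstract positions on a 1-D topologically organized array
shared by the auditory, visual and multisensory layers: similar phonemes
occupy nearby positions.  An auditory or visual presentation of phoneme ``p``
is a Gaussian spatial profile centred on ``p`` whose amplitude encodes
stimulus efficacy (a stand-in for signal-to-noise ratio) and whose standard
deviation encodes representational uncertainty.  Articulatory gestures lead
the acoustics: the visual stimulus starts 50 ms before the auditory one and
lasts longer (130 ms vs 80 ms).  Each input is corrupted by additive uniform
noise, redrawn at every integration step.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Condition",
    "PhonemeSpace",
    "StimulusParams",
    "StimulusSpec",
    "TrialInput",
    "efficacy_amplitude",
    "gaussian_profile",
    "apply_noise",
    "stimulus_profile",
    "external_drive",
    "make_trial",
]


class Condition(str, Enum):
    """Stimulation condition of one trial."""

    A = "A"          # auditory alone
    V = "V"          # visual alone
    AV = "AV"        # congruent audiovisual
    MCGURK = "McGurk"  # incongruent audiovisual (visual shifted)


@dataclass(frozen=True)
class PhonemeSpace:
    """The 1-D array of speech-unit positions shared by all layers.

    Parameters
    ----------
    n_units:
        Number of positions per layer.
    test_range:
        Inclusive interval from which training/test phonemes are drawn;
        keeps all stimulus profiles away from the array edges so the linear
        (non-circular) topology never truncates an activation bubble.
    mcgurk_shift:
        Offset, in positions, between the visual and auditory phoneme in an
        incongruent (McGurk) pairing.
    """

    n_units: int = 100
    test_range: tuple[int, int] = (20, 80)
    mcgurk_shift: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.test_range
        if self.n_units < 10:
            raise ValueError("n_units must be >= 10")
        if not (0 < lo < hi < self.n_units - 1):
            raise ValueError(
                f"test_range {self.test_range} must lie strictly inside "
                f"[0, {self.n_units - 1}]"
            )
        if self.mcgurk_shift < 0:
            raise ValueError("mcgurk_shift must be >= 0")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.n_units)

    @property
    def test_phonemes(self) -> np.ndarray:
        lo, hi = self.test_range
        return np.arange(lo, hi + 1)

    @property
    def mcgurk_phonemes(self) -> np.ndarray:
        """Phonemes whose shifted visual partner still lies in test_range."""
        lo, hi = self.test_range
        return np.arange(lo, hi - self.mcgurk_shift + 1)

    def check_margin(self, input_sigma: float) -> None:
        """Require an edge margin of at least mcgurk_shift + 3*sigma."""
        lo, hi = self.test_range
        margin = self.mcgurk_shift + 3.0 * input_sigma
        if lo < margin or (self.n_units - 1 - hi) < margin:
            raise ValueError(
                f"test_range {self.test_range} leaves less than "
                f"{margin:.1f} positions of edge margin for sigma={input_sigma}"
            )


@dataclass(frozen=True)
class StimulusParams:
    """Shared stimulus-generation parameters.

    ``a_min``/``a_max`` span the 7 auditory efficacy levels; level 1 is below
    the sigmoid's effective range (no recognition) and level 7 saturates the
    driven units.  The visual amplitude is a single constant chosen so that
    mature visual-alone recognition stays poor.  Amplitudes are in the input
    units of the membrane equation; times in ms; widths in positions.
    """

    input_sigma: float = 1.5
    a_min: float = 6.0
    a_max: float = 24.0
    n_levels: int = 7
    visual_amplitude: float = 9.22
    noise_amplitude: float = 7.5
    auditory_duration: float = 80.0
    visual_duration: float = 130.0
    visual_lead: float = 50.0
    trial_duration: float = 300.0

    def __post_init__(self) -> None:
        if self.a_min >= self.a_max:
            raise ValueError("a_min must be < a_max")
        if self.n_levels < 2:
            raise ValueError("need at least two efficacy levels")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.input_sigma <= 0:
            raise ValueError("input_sigma must be > 0")

    @property
    def auditory_onset(self) -> float:
        """Auditory onset when the visual stimulus starts at t = 0."""
        return self.visual_lead

    @property
    def levels(self) -> range:
        return range(1, self.n_levels + 1)


@dataclass(frozen=True)
class StimulusSpec:
    """One modality's input in one trial."""

    modality: str  # "auditory" | "visual"
    phoneme: int
    amplitude: float
    onset: float
    duration: float
    spatial_sigma: float
    noise_amplitude: float

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


@dataclass(frozen=True)
class TrialInput:
    """Fully specified stimulation of one trial."""

    condition: Condition
    auditory: Optional[StimulusSpec]
    visual: Optional[StimulusSpec]
    trial_duration: float

    def __post_init__(self) -> None:
        c = self.condition
        if c is Condition.A and self.visual is not None:
            raise ValueError("auditory-alone trial must not carry a visual stimulus")
        if c is Condition.V and self.auditory is not None:
            raise ValueError("visual-alone trial must not carry an auditory stimulus")
        if c in (Condition.AV, Condition.MCGURK):
            if self.auditory is None or self.visual is None:
                raise ValueError(f"{c.value} trial needs both modalities")
            if c is Condition.AV and self.auditory.phoneme != self.visual.phoneme:
                raise ValueError("congruent AV trial must use one phoneme")


def efficacy_amplitude(level: int, params: StimulusParams) -> float:
    """Map a discrete auditory efficacy level (1..7) to an input amplitude.

    The map is linear: 7 equally spaced amplitudes from ``a_min`` to
    ``a_max``; it is strictly increasing, the only constraint the recognition
    anchors impose.
    """
    if not 1 <= level <= params.n_levels:
        raise ValueError(f"efficacy level {level} outside 1..{params.n_levels}")
    frac = (level - 1) / (params.n_levels - 1)
    return params.a_min + frac * (params.a_max - params.a_min)


def gaussian_profile(center: float, sigma: float, amplitude: float, n: int) -> np.ndarray:
    """Spatial input profile amplitude*exp(-(i-center)^2 / (2 sigma^2)).

    The array is linear (no wraparound); callers keep stimuli inside
    ``test_range`` so the profile never touches an edge.
    """
    if not 0 <= center <= n - 1:
        raise ValueError(f"center {center} outside [0, {n - 1}]")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    i = np.arange(n, dtype=float)
    return amplitude * np.exp(-((i - center) ** 2) / (2.0 * sigma**2))


def apply_noise(profile: np.ndarray, noise_amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Uniform(-a, +a) noise and clip below at zero.

    External drives are non-negative; the clip implements that without
    touching the noiseless profile when ``noise_amplitude == 0``.
    """
    if noise_amplitude < 0:
        raise ValueError("noise_amplitude must be >= 0")
    if noise_amplitude == 0:
        return profile.copy()
    u = rng.uniform(-noise_amplitude, noise_amplitude, size=profile.shape)
    return np.clip(profile + u, 0.0, None)


def stimulus_profile(spec: StimulusSpec, n: int) -> np.ndarray:
    """Noiseless spatial profile of one stimulus."""
    return gaussian_profile(spec.phoneme, spec.spatial_sigma, spec.amplitude, n)


def external_drive(
    trial: TrialInput, t: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy external drive to the (auditory, visual) layers at time ``t``.

    Inside a stimulus window the drive is the Gaussian profile plus fresh
    uniform noise; outside it is exactly zero.  Noise is redrawn on every
    call (every integration step).
    """
    if not 0 <= t <= trial.trial_duration:
        raise ValueError(f"t={t} outside [0, {trial.trial_duration}]")
    drives = []
    for spec in (trial.auditory, trial.visual):
        if spec is not None and spec.active(t):
            drives.append(apply_noise(stimulus_profile(spec, n), spec.noise_amplitude, rng))
        else:
            drives.append(np.zeros(n))
    return drives[0], drives[1]


def make_trial(
    condition: Condition | str,
    phoneme: int,
    efficacy_level: int,
    space: PhonemeSpace,
    params: StimulusParams,
) -> TrialInput:
    """Build a fully populated trial for the given condition.

    Visual onset is t = 0 and the auditory stimulus follows after
    ``visual_lead`` ms; a McGurk trial pairs the auditory phoneme with a
    visual phoneme shifted ``mcgurk_shift`` positions upward.
    """
    condition = Condition(condition)
    lo, hi = space.test_range
    if not lo <= phoneme <= hi:
        raise ValueError(f"phoneme {phoneme} outside test_range [{lo}, {hi}]")
    space.check_margin(params.input_sigma)

    visual_phoneme = phoneme
    if condition is Condition.MCGURK:
        visual_phoneme = phoneme + space.mcgurk_shift
        if visual_phoneme > hi:
            raise ValueError(
                f"McGurk visual phoneme {visual_phoneme} outside test_range "
                f"[{lo}, {hi}]; use phonemes <= {hi - space.mcgurk_shift}"
            )

    auditory = None
    if condition in (Condition.A, Condition.AV, Condition.MCGURK):
        auditory = StimulusSpec(
            modality="auditory",
            phoneme=phoneme,
            amplitude=efficacy_amplitude(efficacy_level, params),
            onset=params.auditory_onset,
            duration=params.auditory_duration,
            spatial_sigma=params.input_sigma,
            noise_amplitude=params.noise_amplitude,
        )
    visual = None
    if condition in (Condition.V, Condition.AV, Condition.MCGURK):
        visual = StimulusSpec(
            modality="visual",
            phoneme=visual_phoneme,
            amplitude=params.visual_amplitude,
            onset=0.0,
            duration=params.visual_duration,
            spatial_sigma=params.input_sigma,
            noise_amplitude=params.noise_amplitude,
        )
    return TrialInput(
        condition=condition,
        auditory=auditory,
        visual=visual,
        trial_duration=params.trial_duration,
    )
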