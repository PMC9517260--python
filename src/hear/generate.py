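"""Synthetic labeled multi-sensor activity signals with controllable imbalance.

Real recordings of daily activities (cooking, keyboarding, reading,
brushing teeth, washing one's face, washing dishes, writing) are private;
this generator emulates the statistical structure such a classifier
exploits: per-channel quasi-periodic oscillation, cross-sensor correlation
(both wrists move with correlated rhythm but different gain), inter-class
similarity (two deliberately similar class pairs), and Gaussian sensor
noise. Class imbalance scenarios follow the 708-vs-200 window pattern of
the study design (S1 balanced; S2-S5 each starve two classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import N_CHANNELS, WindowedDataset

#: the seven everyday activities emulated by the default profiles
ACTIVITY_NAMES = (
    "cooking",
    "keyboarding",
    "reading",
    "brushing_teeth",
    "washing_face",
    "washing_dishes",
    "writing",
)

#: per-scenario minority classes (all other classes stay at the majority count)
_SCENARIO_MINORITIES = {
    "S1": (),
    "S2": ("cooking", "keyboarding"),
    "S3": ("reading", "brushing_teeth"),
    "S4": ("washing_face", "washing_dishes"),
    "S5": ("cooking", "writing"),
}

DEFAULT_MAJORITY = 708
DEFAULT_MINORITY = 200

#: minimum base-frequency separation between dissimilar classes (cycles/window)
DEFAULT_FREQ_MARGIN = 0.8
#: base-frequency gap inside a deliberately similar pair (< margin / 2)
DEFAULT_SIMILAR_GAP = 0.25


@dataclass(frozen=True)
class Scenario:
    """Named per-class window counts."""

    name: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("scenario counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)


def scenario(
    name: str,
    majority: int = DEFAULT_MAJORITY,
    minority: int = DEFAULT_MINORITY,
    class_names: tuple[str, ...] = ACTIVITY_NAMES,
) -> Scenario:
    """Build one of the named imbalance scenarios S1..S5.

    S1 gives every class the majority count; S2-S5 reduce two designated
    classes to the minority count. ``majority``/``minority`` may be scaled
    down jointly to run the same design at reduced size.
    """
    if name not in _SCENARIO_MINORITIES:
        raise ValueError(f"unknown scenario {name!r}; expected S1..S5")
    minorities = _SCENARIO_MINORITIES[name]
    counts = tuple(
        minority if c in minorities else majority for c in class_names
    )
    return Scenario(name=name, counts=counts)


def minority_classes(s: Scenario) -> list[int]:
    """Indices of classes whose count is below the scenario maximum."""
    mx = max(s.counts)
    return [i for i, c in enumerate(s.counts) if c < mx]


@dataclass(frozen=True)
class ActivityProfile:
    """Class-conditional signal recipe for one activity.

    Each channel oscillates at ``base_freq * channel_mults[k]`` cycles per
    window with a weaker first harmonic, scaled per sensor by
    ``sensor_gains``; windows of the class share base phases up to
    Gaussian phase jitter, and i.i.d. Gaussian noise is added per sample.
    """

    class_id: int
    name: str
    base_freq: float  # cycles per window
    channel_mults: tuple[float, ...]  # (C,)
    channel_amps: tuple[float, ...]  # (C,)
    channel_phases: tuple[float, ...]  # (C,)
    sensor_gains: tuple[float, ...]  # (S,)
    harmonic_amp: float = 0.3
    phase_jitter: float = 0.8  # rad, std of per-window phase offset
    noise_std: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise std must be >= 0")


def make_profiles(
    M: int = 7,
    seed: int = 0,
    n_sensors: int = 2,
    n_channels: int = N_CHANNELS,
    freq_margin: float = DEFAULT_FREQ_MARGIN,
    similar_gap: float = DEFAULT_SIMILAR_GAP,
    noise_std: float = 1.0,
    phase_jitter: float = 0.8,
) -> list[ActivityProfile]:
    """Deterministic class profiles with two deliberately similar pairs.

    Base frequencies are spaced ``freq_margin`` apart except inside the
    designated similar pairs, whose gap is ``similar_gap`` (< margin/2) and
    whose amplitudes, phases and sensor gains are shared up to a small
    perturbation — these pairs supply the "hard" samples that a focusing
    loss is meant to rescue. Profiles are reproducible given ``seed``.
    """
    if M < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    pairs = similar_pairs(M)
    second_of_pair = {b: a for a, b in pairs}

    # shared per-channel frequency multipliers keep pair similarity intact
    mults = tuple(rng.uniform(0.85, 1.15, size=n_channels).tolist())

    profiles: list[ActivityProfile] = []
    freq = 1.2
    for c in range(M):
        if c > 0:
            gap = similar_gap if second_of_pair.get(c) == c - 1 else freq_margin
            freq = freq + gap
        if c in second_of_pair:
            base = profiles[second_of_pair[c]]
            amps = tuple(
                float(a + d)
                for a, d in zip(
                    base.channel_amps, rng.uniform(-0.08, 0.08, size=n_channels)
                )
            )
            phases = base.channel_phases
            gains = base.sensor_gains
        else:
            amps = tuple(rng.uniform(0.6, 1.4, size=n_channels).tolist())
            phases = tuple(rng.uniform(0, 2 * np.pi, size=n_channels).tolist())
            gains = (1.0,) + tuple(
                rng.uniform(0.5, 0.9, size=n_sensors - 1).tolist()
            )
        name = ACTIVITY_NAMES[c] if M == len(ACTIVITY_NAMES) else f"class_{c}"
        profiles.append(
            ActivityProfile(
                class_id=c,
                name=name,
                base_freq=float(freq),
                channel_mults=mults,
                channel_amps=amps,
                channel_phases=phases,
                sensor_gains=gains,
                phase_jitter=phase_jitter,
                noise_std=noise_std,
            )
        )
    return profiles


def similar_pairs(M: int) -> list[tuple[int, int]]:
    """The deliberately hard-to-separate class index pairs for ``M`` classes."""
    pairs = []
    if M >= 3:
        pairs.append((0, 1))
    if M >= 6:
        pairs.append((4, 5))
    return pairs


def _window_batch(
    p: ActivityProfile, n: int, T: int, S: int, C: int, rng: np.random.Generator
) -> np.ndarray:
    """Generate ``n`` windows of shape (T, S, C) for one profile."""
    t = np.arange(T) / T  # fractions of a window
    jitter = rng.normal(0.0, p.phase_jitter, size=n) if p.phase_jitter > 0 else np.zeros(n)
    freqs = p.base_freq * np.asarray(p.channel_mults[:C])  # (C,)
    amps = np.asarray(p.channel_amps[:C])
    phases = np.asarray(p.channel_phases[:C])
    # phase angle per (window, time, channel)
    ang = (
        2 * np.pi * freqs[None, None, :] * t[None, :, None]
        + phases[None, None, :]
        + jitter[:, None, None]
    )
    base = amps[None, None, :] * np.sin(ang)
    harm = (p.harmonic_amp * amps)[None, None, :] * np.sin(2 * ang)
    clean = base + harm  # (n, T, C)
    gains = np.asarray(p.sensor_gains[:S])  # (S,)
    out = clean[:, :, None, :] * gains[None, None, :, None]  # (n, T, S, C)
    if p.noise_std > 0:
        out = out + rng.normal(0.0, p.noise_std, size=out.shape)
    return out


def generate_dataset(
    profiles: list[ActivityProfile],
    scen: Scenario,
    T: int = 50,
    S: int = 2,
    seed: int = 0,
    shuffle: bool = True,
) -> WindowedDataset:
    """Draw a labeled window dataset whose class counts match ``scen`` exactly."""
    if scen.n_classes != len(profiles):
        raise ValueError(
            f"scenario has {scen.n_classes} classes but {len(profiles)} profiles given"
        )
    rng = np.random.default_rng(seed)
    C = len(profiles[0].channel_mults)
    blocks, labels = [], []
    for p, count in zip(profiles, scen.counts):
        if count:
            blocks.append(_window_batch(p, count, T, S, C, rng))
            labels.append(np.full(count, p.class_id, dtype=int))
    X = (
        np.concatenate(blocks)
        if blocks
        else np.empty((0, T, S, C), dtype=float)
    )
    y = np.concatenate(labels) if labels else np.empty(0, dtype=int)
    if shuffle and len(y):
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
    ds = WindowedDataset(
        X, y, [p.name for p in profiles], T, step=T, metadata={"scenario": scen.name}
    )
    return ds
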