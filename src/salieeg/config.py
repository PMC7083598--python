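"""Configuration objects for the synthetic study and the analysis pipeline.

The simulation defaults describe the study conditions this package emulates:
twenty natural-scene trials of roughly two minutes, a 440 Hz tone stream at
2.6 Hz with 3-5 amplitude-modulated targets per trial, 351 behaviorally
defined salient events split into strength tertiles, and twelve subjects of
128-channel EEG carrying a steady-state response at the tone rate, high-gamma
(70-110 Hz) bursts, and an envelope-following component, embedded in 1/f and
line noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Salience strength tiers, strongest first.
TIERS = ("high", "mid", "low")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Amplitudes are in microvolts; gains on the steady-state response (SSR)
    and envelope-following response (EFR) are dimensionless multipliers on
    the injected component amplitude, gamma gains are dB offsets on band
    power. Tier gains must be ordered so that the deviation from neutral is
    largest for ``high`` and smallest for ``low``.
    """

    # stimulus / session geometry
    n_scenes: int = 20
    scene_dur: float = 120.0            # s
    n_subjects: int = 12
    n_channels: int = 128
    fs_raw: float = 512.0               # Hz; 2048 in the original recordings
    tone_rate: float = 2.6              # Hz
    tone_freq: float = 440.0            # Hz
    tone_dur: float = 0.3               # s
    am_rate: float = 64.0               # Hz
    am_depth: float = 0.0               # dB (0 = easy task)
    n_targets_per_scene: tuple[int, int] = (3, 5)
    min_target_event_gap: float = 1.5   # s
    min_target_sep: float = 6.0         # s, between targets
    # salience structure
    n_events_total: int = 351
    min_event_gap: float = 4.5          # s (>= 4 so scoring windows do not overlap)
    edge_margin: float = 5.0            # s, keep events/targets away from scene edges
    fs_curve: float = 10.0              # Hz, behavioral salience curve rate
    # injected neural effects
    ssr_amp: float = 1.0                # uV, 2.6 Hz component amplitude
    ssr_target_gain: float = 1.3
    ssr_event_gain: dict[str, float] = field(
        default_factory=lambda: {"high": 0.6, "mid": 0.8, "low": 1.0})
    gamma_amp: float = 3.5              # uV RMS, baseline 70-110 Hz activity
    gamma_target_gain: float = 3.0      # dB
    gamma_event_gain: dict[str, float] = field(
        default_factory=lambda: {"high": -3.0, "mid": -1.5, "low": 0.0})
    gamma_burst_window: tuple[float, float] = (0.5, 3.5)   # s post-onset
    efr_amp: float = 1.0                # uV, envelope-following component
    efr_gain_high: float = 2.0
    efr_lag: float = 0.1                # s, neural lag of the EFR
    efr_boost_dur: float = 1.5          # s of boosted gain after high events
    ssr_phase_jitter: float = 0.0       # rad SD, per-scene phase jitter
    # noise and artifacts
    noise_amp: float = 5.0              # uV RMS broadband 1/f noise
    noise_exponent: float = 1.0         # PSD ~ 1/f**exponent
    line_freq: float = 60.0             # Hz
    line_amp: float = 2.0               # uV
    n_bad_channels: int = 0
    blink_rate: float = 0.05            # blinks per second (0 disables)
    blink_amp: float = 80.0             # uV on the virtual EOG channel
    offgroup_gain: float = 0.3          # effect amplitude outside central/frontal
    # acoustic feature tracks
    event_feature_shift: float = 0.0    # SDs; 0 keeps event/background overlap ~1
    # simulated behavior
    hit_rate: float = 0.754             # target detection probability
    false_alarms_per_scene: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scene_dur", "tone_rate", "tone_dur", "fs_raw", "fs_curve"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.n_targets_per_scene
        if not (0 <= lo <= hi):
            raise ValueError("n_targets_per_scene must be an ordered range")
        if self.min_event_gap < 4.0:
            raise ValueError("min_event_gap must be >= 4 s (scoring window)")
        _check_tier_order({t: abs(1.0 - g) for t, g in self.ssr_event_gain.items()},
                          "ssr_event_gain")
        _check_tier_order({t: abs(g) for t, g in self.gamma_event_gain.items()},
                          "gamma_event_gain")

    # -- derived quantities -------------------------------------------------
    @property
    def tones_per_scene(self) -> int:
        """Number of tone onsets fitting in one scene at the tone rate."""
        import math
        return int(math.floor((self.scene_dur - self.tone_dur) * self.tone_rate)) + 1

    @property
    def six_tone_dur(self) -> float:
        """Duration of a six-tone segment (one analysis window)."""
        return 6.0 / self.tone_rate

    def events_per_scene(self) -> list[int]:
        base, extra = divmod(self.n_events_total, self.n_scenes)
        return [base + (1 if i < extra else 0) for i in range(self.n_scenes)]

    def replace(self, **kw: Any) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["n_targets_per_scene"] = list(d["n_targets_per_scene"])
        d["gamma_burst_window"] = list(d["gamma_burst_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("n_targets_per_scene", "gamma_burst_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _check_tier_order(mag: dict[str, float], name: str) -> None:
    missing = [t for t in TIERS if t not in mag]
    if missing:
        raise ValueError(f"{name} missing tiers {missing}")
    if not (mag["high"] >= mag["mid"] >= mag["low"]):
        raise ValueError(f"{name} magnitudes must be ordered high >= mid >= low")


def neutral_gains(cfg: SimConfig) -> SimConfig:
    """Copy of a config with every injected effect switched off (null
    generator): SSR/EFR gains 1, gamma offsets 0 dB."""
    return cfg.replace(
        ssr_target_gain=1.0,
        ssr_event_gain={"high": 1.0, "mid": 1.0, "low": 1.0},
        gamma_target_gain=0.0,
        gamma_event_gain={"high": 0.0, "mid": 0.0, "low": 0.0},
        efr_gain_high=1.0)


def locking_study_config(seed: int = 0, **overrides: Any) -> SimConfig:
    """Desk-scale preset for phase-locking recovery studies.

    Keeps the full-length 2 min scenes and twelve subjects but uses five
    scenes, an eight-channel montage, and 105 events (35 per tier): the
    normalized peak-power statistic needs >= ~20 concatenated six-tone
    segments per pool before its main spectral lobe is narrower than the
    2.55-2.65 Hz normalization band, and per-tier pools benefit from every
    additional segment. Gamma and envelope components are switched off;
    they do not enter this statistic.
    """
    base = dict(
        n_scenes=5, scene_dur=120.0, n_subjects=12, n_channels=8,
        fs_raw=256.0, n_events_total=105, min_event_gap=4.5,
        min_target_sep=6.0, gamma_amp=0.0, efr_amp=0.0, blink_rate=0.0,
        seed=seed)
    base.update(overrides)
    return SimConfig(**base)


def gamma_study_config(seed: int = 0, **overrides: Any) -> SimConfig:
    """Desk-scale preset for high-gamma dB recovery studies.

    Events are kept sparse (two per 60 s scene, >= 15 s apart) and targets
    at least 6 s from events so that no burst of one onset reaches into
    the [-2.5, -0.5] s baseline window of another; otherwise spill-over
    biases the recovered dB offsets.
    """
    base = dict(
        n_scenes=6, scene_dur=60.0, n_subjects=12, n_channels=8,
        fs_raw=256.0, n_events_total=12, min_event_gap=15.0,
        min_target_event_gap=6.0, min_target_sep=6.0,
        n_targets_per_scene=(3, 4), efr_amp=0.0, blink_rate=0.0, seed=seed)
    base.update(overrides)
    return SimConfig(**base)


def decoding_study_config(seed: int = 0, **overrides: Any) -> SimConfig:
    """Desk-scale preset for envelope-decoding recovery studies.

    Accuracy pairs are averaged over subjects (whose errors share the
    scene envelope) and paired at the event level: eighteen events per
    tier give the high-salience contrast its sample size. The
    envelope-following component is raised to 1.5 uV and its
    post-high-event gain to 2.5 because the 1 s sliding-correlation
    accuracy is an intrinsically noisy per-event measure (a handful of
    effective samples per window); weaker settings leave the contrast
    under-powered at desk scale.
    """
    base = dict(
        n_scenes=10, scene_dur=60.0, n_subjects=4, n_channels=8,
        fs_raw=256.0, n_events_total=54, min_event_gap=6.0,
        min_target_sep=6.0, gamma_amp=0.0, efr_amp=1.5,
        efr_gain_high=2.5, blink_rate=0.0, seed=seed)
    base.update(overrides)
    return SimConfig(**base)


def desk_config(**overrides: Any) -> SimConfig:
    """A reduced-size configuration for laptop-scale runs and tests.

    Keeps the twelve-subject design and all injected effect sizes of the
    default study conditions but shortens scenes, and trims the montage to
    sixteen channels, so that a full multi-session recovery study runs in
    minutes on one CPU.
    """
    base = dict(
        n_scenes=6, scene_dur=40.0, n_subjects=12, n_channels=16,
        fs_raw=256.0, n_events_total=24, blink_rate=0.0,
        min_target_sep=4.0,
    )
    base.update(overrides)
    return SimConfig(**base)
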