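"""Simulation configuration: design sizes, planted effects, behaviour model.

The configuration describes a two-group, multi-phase experiment: two groups
of ``n_per_group`` participants, ``n_channels`` virtual channels, a set of
frequency bands, a trial timeline, and 204 trials per participant. Effects
are planted as shifts of condition-cell mean log power expressed in units of
the within-cell noise SD, so magnitudes are scale-free. Brain-behaviour
coupling ties a designated power contrast to response time through a shared
per-subject latent factor at a configured target correlation.

Configurations load from YAML or JSON mappings; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .bands import BandDefinition, standard_bands, validate_bands
from .timeline import TrialTimeline, Window

__all__ = [
    "EffectSpec",
    "CouplingSpec",
    "GroupBehaviour",
    "BehaviourModel",
    "SimulationConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class EffectSpec:
    """A planted group x phase power effect.

    ``magnitude_sd`` is the signed shift of mean log power in the listed
    channels/bands for ``group`` in window ``phase``, in units of the
    within-cell noise SD (negative = power decrease, i.e. ERD-like).
    """

    group: str
    channels: tuple[int, ...]
    bands: tuple[str, ...]
    phase: str
    magnitude_sd: float

    def __post_init__(self) -> None:
        if not np_isfinite(self.magnitude_sd):
            raise ValueError("effect magnitude must be finite")
        if len(self.channels) == 0 or len(self.bands) == 0:
            raise ValueError("effect must reference at least one channel and one band")


@dataclass(frozen=True)
class CouplingSpec:
    """A planted brain-power <-> RT correlation for one group.

    A latent u ~ N(0,1) per subject loads +beta/2 on ``phase`` and -beta/2 on
    ``baseline_phase`` log power in the listed channels/bands, with beta
    chosen so the per-channel observed contrast correlates with u at exactly
    ``r``; the subject's log-RT location loads on the same latent.
    """

    group: str
    channels: tuple[int, ...]
    bands: tuple[str, ...]
    phase: str
    baseline_phase: str
    r: float

    def __post_init__(self) -> None:
        if not (-1.0 < self.r < 1.0):
            raise ValueError(f"coupling r must satisfy |r| < 1, got {self.r}")


@dataclass(frozen=True)
class GroupBehaviour:
    """Behavioural generating model for one group.

    accuracy in %, RT as a log-normal (location/scale on the log-ms scale)
    with between-subject SD of the location, hippocampal volume in mm^3.
    """

    accuracy_mean_pct: float = 82.0
    accuracy_sd_pct: float = 9.0
    rt_log_location: float = 7.3  # exp(7.3) ~ 1480 ms
    rt_log_scale: float = 0.25  # within-subject trial-to-trial
    rt_subject_sd: float = 0.12  # between-subject SD of the location
    volume_mean_mm3: float = 7500.0
    volume_sd_mm3: float = 900.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy_mean_pct <= 100.0):
            raise ValueError("accuracy mean must lie in [0, 100] %")
        for name in ("rt_log_scale", "rt_subject_sd", "volume_sd_mm3", "accuracy_sd_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class BehaviourModel:
    groups: dict[str, GroupBehaviour] = field(
        default_factory=lambda: {
            "younger": GroupBehaviour(
                accuracy_mean_pct=82.5, rt_log_location=7.32, volume_mean_mm3=7595.0
            ),
            "older": GroupBehaviour(
                accuracy_mean_pct=81.3, rt_log_location=7.60, volume_mean_mm3=7322.0
            ),
        }
    )
    #: fraction of trials whose RT is drawn below 1 s, so the response-locked
    #: RT > 1 s filter removes a non-trivial share of trials
    fast_rt_fraction: float = 0.10
    #: planted practice effect: mean RT difference (ms) between the first and
    #: last half of trials, applied as a linear drift (0 = none)
    practice_effect_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fast_rt_fraction < 1.0):
            raise ValueError("fast_rt_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    n_per_group: int = 16
    n_channels: int = 90
    n_trials: int = 204
    group_names: tuple[str, ...] = ("younger", "older")
    bands: tuple[BandDefinition, ...] = field(default_factory=standard_bands)
    timeline: TrialTimeline = field(default_factory=TrialTimeline)
    conditions: tuple[str, ...] = (
        "pre_stimulus",
        "first_study",
        "first_study_short",
        "delay",
        "test",
        "response_locked",
    )
    effects: tuple[EffectSpec, ...] = ()
    coupling: tuple[CouplingSpec, ...] = ()
    behaviour: BehaviourModel = field(default_factory=BehaviourModel)
    noise_sd: float = 1.0
    log_power: bool = True  # noise Gaussian on log power (flag for linear)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        validate_bands(self.bands)
        band_names = {b.name for b in self.bands}
        for spec in list(self.effects) + list(self.coupling):
            for ch in spec.channels:
                if not (0 <= ch < self.n_channels):
                    raise ValueError(f"effect references channel {ch} outside 0..{self.n_channels - 1}")
            for b in spec.bands:
                if b not in band_names:
                    raise ValueError(f"effect references unknown band {b!r}")
            if spec.group not in self.group_names:
                raise ValueError(f"effect references unknown group {spec.group!r}")
            phases = [spec.phase] + (
                [spec.baseline_phase] if isinstance(spec, CouplingSpec) else []
            )
            for ph in phases:
                if ph not in self.conditions:
                    raise ValueError(f"effect references unknown condition {ph!r}")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)


def np_isfinite(x: float) -> bool:
    import math

    return math.isfinite(x)


# ---------------------------------------------------------------------------
# strict (de)serialisation

def _check_keys(data: Mapping[str, Any], allowed: Sequence[str], where: str) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def _band_from(d: Mapping[str, Any]) -> BandDefinition:
    _check_keys(d, ["name", "f_lo", "f_hi"], "band")
    return BandDefinition(str(d["name"]), float(d["f_lo"]), float(d["f_hi"]))


def _window_from(d: Mapping[str, Any]) -> Window:
    _check_keys(d, ["t0", "t1", "relative_to_response"], "window")
    return Window(float(d["t0"]), float(d["t1"]), bool(d.get("relative_to_response", False)))


def _timeline_from(d: Mapping[str, Any]) -> TrialTimeline:
    allowed = ["study_onsets", "delay_onset", "test_onset", "trial_end", "epoch_start", "windows"]
    _check_keys(d, allowed, "timeline")
    kwargs: dict[str, Any] = {}
    if "study_onsets" in d:
        kwargs["study_onsets"] = tuple(float(x) for x in d["study_onsets"])
    for key in ("delay_onset", "test_onset", "trial_end", "epoch_start"):
        if key in d:
            kwargs[key] = float(d[key])
    if "windows" in d:
        kwargs["windows"] = {k: _window_from(v) for k, v in d["windows"].items()}
    return TrialTimeline(**kwargs)


def _effect_from(d: Mapping[str, Any]) -> EffectSpec:
    _check_keys(d, ["group", "channels", "bands", "phase", "magnitude_sd"], "effect")
    return EffectSpec(
        group=str(d["group"]),
        channels=tuple(int(c) for c in d["channels"]),
        bands=tuple(str(b) for b in d["bands"]),
        phase=str(d["phase"]),
        magnitude_sd=float(d["magnitude_sd"]),
    )


def _coupling_from(d: Mapping[str, Any]) -> CouplingSpec:
    _check_keys(d, ["group", "channels", "bands", "phase", "baseline_phase", "r"], "coupling")
    return CouplingSpec(
        group=str(d["group"]),
        channels=tuple(int(c) for c in d["channels"]),
        bands=tuple(str(b) for b in d["bands"]),
        phase=str(d["phase"]),
        baseline_phase=str(d["baseline_phase"]),
        r=float(d["r"]),
    )


def _group_behaviour_from(d: Mapping[str, Any]) -> GroupBehaviour:
    fields = [
        "accuracy_mean_pct", "accuracy_sd_pct", "rt_log_location", "rt_log_scale",
        "rt_subject_sd", "volume_mean_mm3", "volume_sd_mm3",
    ]
    _check_keys(d, fields, "behaviour group")
    return GroupBehaviour(**{k: float(v) for k, v in d.items()})


def _behaviour_from(d: Mapping[str, Any]) -> BehaviourModel:
    _check_keys(d, ["groups", "fast_rt_fraction", "practice_effect_ms"], "behaviour")
    kwargs: dict[str, Any] = {}
    if "groups" in d:
        kwargs["groups"] = {k: _group_behaviour_from(v) for k, v in d["groups"].items()}
    if "fast_rt_fraction" in d:
        kwargs["fast_rt_fraction"] = float(d["fast_rt_fraction"])
    if "practice_effect_ms" in d:
        kwargs["practice_effect_ms"] = float(d["practice_effect_ms"])
    return BehaviourModel(**kwargs)


def config_from_dict(data: Mapping[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from a plain mapping; unknown keys rejected."""
    allowed = [
        "n_per_group", "n_channels", "n_trials", "group_names", "bands", "timeline",
        "conditions", "effects", "coupling", "behaviour", "noise_sd", "log_power", "seed",
    ]
    _check_keys(data, allowed, "config")
    kwargs: dict[str, Any] = {}
    for key in ("n_per_group", "n_channels", "n_trials", "seed"):
        if key in data:
            kwargs[key] = int(data[key])
    if "group_names" in data:
        kwargs["group_names"] = tuple(str(g) for g in data["group_names"])
    if "bands" in data:
        kwargs["bands"] = tuple(_band_from(b) for b in data["bands"])
    if "timeline" in data:
        kwargs["timeline"] = _timeline_from(data["timeline"])
    if "conditions" in data:
        kwargs["conditions"] = tuple(str(c) for c in data["conditions"])
    if "effects" in data:
        kwargs["effects"] = tuple(_effect_from(e) for e in data["effects"])
    if "coupling" in data:
        kwargs["coupling"] = tuple(_coupling_from(c) for c in data["coupling"])
    if "behaviour" in data:
        kwargs["behaviour"] = _behaviour_from(data["behaviour"])
    if "noise_sd" in data:
        kwargs["noise_sd"] = float(data["noise_sd"])
    if "log_power" in data:
        kwargs["log_power"] = bool(data["log_power"])
    return SimulationConfig(**kwargs)


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    d = asdict(config)
    d["group_names"] = list(config.group_names)
    d["conditions"] = list(config.conditions)
    d["bands"] = [asdict(b) for b in config.bands]
    d["timeline"]["windows"] = {k: asdict(w) for k, w in config.timeline.windows.items()}
    d["timeline"]["study_onsets"] = list(config.timeline.study_onsets)
    d["effects"] = [
        {**asdict(e), "channels": list(e.channels), "bands": list(e.bands)}
        for e in config.effects
    ]
    d["coupling"] = [
        {**asdict(c), "channels": list(c.channels), "bands": list(c.bands)}
        for c in config.coupling
    ]
    d["behaviour"] = {
        "groups": {k: asdict(v) for k, v in config.behaviour.groups.items()},
        "fast_rt_fraction": config.behaviour.fast_rt_fraction,
        "practice_effect_ms": config.behaviour.practice_effect_ms,
    }
    return d


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
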