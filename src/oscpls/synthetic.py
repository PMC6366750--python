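"""Synthetic two-group task data with known planted effects.

The generator emulates the statistical structure of a two-group (younger /
older), multi-phase visuospatial memory experiment: 16 participants per
group, 90 virtual channels, three frequency bands, 204 trials, and named
task windows (pre-stimulus, study, delay, test, response-locked). It
produces

* a band-power tensor drawn as cell mean + planted group x phase effects +
  Gaussian noise on log power (linear-power mode by flag),
* trial-level behaviour (per-trial binomial accuracy, log-normal RTs with a
  configurable fraction faster than 1 s), summarised downstream by the
  behaviour module, and
* raw per-trial virtual-channel signals (1/f background plus band-limited
  carriers with per-window amplitude gains) so the spectral stage can be
  exercised end to end.

Brain-behaviour coupling uses one standard-normal latent per subject that
loads on both the designated power contrast and the subject's log-RT
location; the loading is chosen so the population correlation between the
observed per-channel contrast and the latent equals the configured r
exactly. A GroundTruth record of everything planted accompanies each
dataset so recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .channels import channel_table
from .config import CouplingSpec, EffectSpec, SimulationConfig
from .datamatrix import PowerTensor

__all__ = [
    "GroundTruth",
    "generate_power_dataset",
    "generate_trials",
    "generate_timecourses",
    "coupling_loading",
]


def coupling_loading(r: float, noise_sd: float) -> float:
    """Latent loading beta giving corr(contrast, latent) = r exactly.

    The observed contrast in a coupled channel is beta*u + (eps_a - eps_b)
    with eps ~ N(0, noise_sd^2), so corr = beta / sqrt(beta^2 + 2 sd^2) and
    beta = |r| sd sqrt(2 / (1 - r^2)), signed like r.
    """
    return float(np.sign(r) * abs(r) * noise_sd * np.sqrt(2.0 / (1.0 - r**2)))


@dataclass
class GroundTruth:
    """Record of planted effects and couplings for recovery tests."""

    effects: list[dict] = field(default_factory=list)
    coupling: list[dict] = field(default_factory=list)
    subject_latent: dict[str, float] = field(default_factory=dict)
    groups: tuple[str, ...] = ()
    conditions: tuple[str, ...] = ()
    bands: tuple[str, ...] = ()
    n_channels: int = 0

    def design_contrast(self, conditions: list[str] | None = None) -> np.ndarray:
        """Planted cell pattern over (group, condition) cells, group-major.

        Each cell receives the summed planted magnitude (SD units) of the
        effects targeting that group and phase. This is the vector a task-PLS
        design salience should recover (up to centering and scale).
        """
        conds = list(conditions) if conditions is not None else list(self.conditions)
        vec = np.zeros(len(self.groups) * len(conds))
        for eff in self.effects:
            if eff["phase"] not in conds:
                continue
            gi = self.groups.index(eff["group"])
            ci = conds.index(eff["phase"])
            vec[gi * len(conds) + ci] += eff["magnitude_sd"]
        return vec

    def planted_columns(self, kind: str = "effects") -> np.ndarray:
        """Flat channel x band column indices touched by planted effects
        (``kind="effects"``) or couplings (``kind="coupling"``)."""
        specs = self.effects if kind == "effects" else self.coupling
        n_b = len(self.bands)
        cols: set[int] = set()
        for sp in specs:
            for ch in sp["channels"]:
                for b in sp["bands"]:
                    cols.add(ch * n_b + self.bands.index(b))
        return np.array(sorted(cols), dtype=int)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["groups"] = tuple(d["groups"])
        d["conditions"] = tuple(d["conditions"])
        d["bands"] = tuple(d["bands"])
        return cls(**d)


def _subject_ids(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    subjects: list[str] = []
    group_of: dict[str, str] = {}
    for g in config.group_names:
        for i in range(config.n_per_group):
            sid = f"{g}_{i + 1:02d}"
            subjects.append(sid)
            group_of[sid] = g
    return subjects, group_of


def _band_index(config: SimulationConfig, names: tuple[str, ...]) -> list[int]:
    all_names = list(config.band_names)
    return [all_names.index(n) for n in names]


def generate_power_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[PowerTensor, pd.DataFrame, GroundTruth]:
    """Draw a band-power tensor, a behaviour table and the ground truth.

    Power for subject s, condition c, channel ch, band b is
    ``mu + planted(group, c, ch, b) + (beta/2) * u_s * coupling_sign(c) +
    noise`` on the log scale, with noise ~ N(0, noise_sd). The behaviour
    table is computed from generated trial records via the behaviour
    module's summarisation path and includes hippocampal volumes.
    """
    from .behaviour import summarize_trials  # local import to avoid a cycle

    if seed is None:
        seed = config.seed
    subjects, group_of = _subject_ids(config)
    n_s = len(subjects)
    n_c = len(config.conditions)
    n_ch = config.n_channels
    n_b = len(config.bands)
    rng = substream(seed, "power")

    values = np.zeros((n_s, n_c, n_ch, n_b))

    # planted group x phase effects, magnitudes in within-cell SD units
    for eff in config.effects:
        ci = config.conditions.index(eff.phase)
        bands = _band_index(config, eff.bands)
        shift = eff.magnitude_sd * config.noise_sd
        for si, s in enumerate(subjects):
            if group_of[s] != eff.group:
                continue
            for ch in eff.channels:
                values[si, ci, ch, bands] += shift

    # shared latent per subject: drives coupled power contrast and log-RT
    latent = {s: float(u) for s, u in zip(subjects, substream(seed, "latent").standard_normal(n_s))}
    for cp in config.coupling:
        beta = coupling_loading(cp.r, config.noise_sd)
        ci_hi = config.conditions.index(cp.phase)
        ci_lo = config.conditions.index(cp.baseline_phase)
        bands = _band_index(config, cp.bands)
        for si, s in enumerate(subjects):
            if group_of[s] != cp.group:
                continue
            u = latent[s]
            for ch in cp.channels:
                values[si, ci_hi, ch, bands] += beta / 2.0 * u
                values[si, ci_lo, ch, bands] -= beta / 2.0 * u

    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    if not config.log_power:
        values = np.exp(values)

    tensor = PowerTensor(
        values=values,
        subjects=tuple(subjects),
        conditions=config.conditions,
        channels=tuple(channel_table(n_ch)["channel"]),
        bands=config.band_names,
        group_of=group_of,
        log_power=config.log_power,
    )

    trials = generate_trials(config, seed, latent=latent)
    behaviour = summarize_trials(trials)
    vol_rng = substream(seed, "volumes")
    vols = []
    for s in subjects:
        gb = config.behaviour.groups[group_of[s]]
        vols.append(vol_rng.normal(gb.volume_mean_mm3, gb.volume_sd_mm3))
    behaviour = behaviour.set_index("subject")
    behaviour["hipp_volume_mm3"] = pd.Series(dict(zip(subjects, vols)))
    behaviour = behaviour.reset_index()

    truth = GroundTruth(
        effects=[
            {**asdict(e), "channels": list(e.channels), "bands": list(e.bands)}
            for e in config.effects
        ],
        coupling=[
            {
                **asdict(c),
                "channels": list(c.channels),
                "bands": list(c.bands),
                "beta": coupling_loading(c.r, config.noise_sd),
            }
            for c in config.coupling
        ],
        subject_latent=latent,
        groups=config.group_names,
        conditions=config.conditions,
        bands=config.band_names,
        n_channels=n_ch,
    )
    return tensor, behaviour, truth


def generate_trials(
    config: SimulationConfig,
    seed: int | None = None,
    latent: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Trial records: subject, group, trial_index, condition, response, rt_ms.

    Accuracy is Bernoulli per trial around a per-subject rate (group mean
    plus between-subject spread); RTs are log-normal per trial around a
    per-subject location that loads on the coupling latent in coupled
    groups. A configurable fraction of RTs is drawn below 1 s so the
    response-locked RT > 1 s filter removes a non-trivial share. RTs beyond
    the 4 s response window become non-responses. An optional linear
    practice effect makes later trials faster.
    """
    if seed is None:
        seed = config.seed
    subjects, group_of = _subject_ids(config)
    if latent is None:
        latent = {
            s: float(u)
            for s, u in zip(subjects, substream(seed, "latent").standard_normal(len(subjects)))
        }
    coupled_groups = {cp.group for cp in config.coupling}
    rng = substream(seed, "trials")
    n_t = config.n_trials
    rows: list[pd.DataFrame] = []
    for s in subjects:
        g = group_of[s]
        gb = config.behaviour.groups[g]
        u = latent[s]
        z = u if g in coupled_groups else float(rng.standard_normal())
        acc = np.clip(rng.normal(gb.accuracy_mean_pct, gb.accuracy_sd_pct) / 100.0, 0.02, 0.995)
        loc = gb.rt_log_location + gb.rt_subject_sd * z
        correct = rng.random(n_t) < acc
        rt = np.exp(rng.normal(loc, gb.rt_log_scale, size=n_t))
        fast = rng.random(n_t) < config.behaviour.fast_rt_fraction
        rt[fast] = rng.uniform(400.0, 999.0, size=int(fast.sum()))
        practice = config.behaviour.practice_effect_ms
        if practice:
            idx = np.arange(1, n_t + 1)
            rt = rt + 2.0 * practice * (0.5 - (idx - 0.5) / n_t)
            rt = np.clip(rt, 150.0, None)
        responded = rt <= 4000.0
        response = np.where(responded, np.where(correct, "correct", "incorrect"), "none")
        condition = np.array(["intact", "manipulated"])[
            rng.permutation(np.repeat([0, 1], (n_t + 1) // 2))[:n_t]
        ]
        rows.append(
            pd.DataFrame(
                {
                    "subject": s,
                    "group": g,
                    "trial_index": np.arange(1, n_t + 1),
                    "condition": condition,
                    "response": response,
                    "rt_ms": np.where(responded, rt, np.nan),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# raw signal generation


def _band_limited_noise(
    rng: np.random.Generator, n_samples: int, fs: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to [f_lo, f_hi] via FFT masking."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-amplitude background."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    with np.errstate(divide="ignore"):
        spec = spec / np.sqrt(np.maximum(freqs, freqs[1]))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_timecourses(
    config: SimulationConfig,
    seed: int | None = None,
    fs: float = 160.0,
    n_trials: int | None = None,
    n_channels: int | None = None,
    background_gain: float = 1.0,
    carrier_gains: dict[str, dict[str, float]] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-trial virtual-channel signals over the full epoch.

    Signals are 1/f background plus one band-limited carrier per configured
    band. ``carrier_gains[band]`` maps window names (from the timeline) to
    amplitude gains applied within that window; the key ``"default"`` sets
    the amplitude outside any listed window (1.0 if omitted, 0.0 silences
    the carrier). Expected band power in a window scales with the squared
    amplitude gain, which is the analytic target recovery tests check.

    Returns (signals, fs, t_start) with signals trial x channel x sample.
    """
    if seed is None:
        seed = config.seed
    tl = config.timeline
    nyquist = fs / 2.0
    for band in config.bands:
        if band.f_hi >= nyquist:
            raise ValueError(
                f"band {band.name!r} upper edge {band.f_hi} Hz at or above Nyquist {nyquist} Hz"
            )
    n_trials = n_trials if n_trials is not None else config.n_trials
    n_channels = n_channels if n_channels is not None else config.n_channels
    n_samples = int(round(tl.epoch_duration * fs))
    t = tl.epoch_start + np.arange(n_samples) / fs
    gains = carrier_gains or {}

    envelopes = {}
    for band in config.bands:
        g = gains.get(band.name, {})
        env = np.full(n_samples, float(g.get("default", 1.0)))
        for win_name, amp in g.items():
            if win_name == "default":
                continue
            w = tl.window(win_name)
            if w.relative_to_response:
                raise ValueError(
                    f"carrier gain for response-locked window {win_name!r} is not supported"
                )
            env[(t >= w.t0) & (t <= w.t1)] = float(amp)
        envelopes[band.name] = env

    rng = substream(seed, "timecourses")
    signals = np.zeros((n_trials, n_channels, n_samples))
    for trial in range(n_trials):
        for ch in range(n_channels):
            x = np.zeros(n_samples)
            if background_gain != 0.0:
                x += background_gain * _pink_noise(rng, n_samples, fs)
            for band in config.bands:
                env = envelopes[band.name]
                if np.all(env == 0.0):
                    continue
                x += env * _band_limited_noise(rng, n_samples, fs, band.f_lo, band.f_hi)
            signals[trial, ch] = x
    return signals, fs, tl.epoch_start
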