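"""Pipeline orchestration: simulate -> band power -> PLS -> behaviour -> report.

``run_pipeline`` executes a named set of window contrasts as mean-centered
task PLS analyses (across groups and per group), runs the behavioural PLS
of each contrast block against accuracy / RT / hippocampal volume, computes
the behavioural summary statistics, and assembles everything into a
machine-readable RunReport. Every stage draws from a substream of one
top-level seed, so a run is deterministic end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .behaviour import group_summary, select_response_locked, summarize_trials
from .config import SimulationConfig, config_to_dict
from .datamatrix import PowerTensor, build_task_matrix
from .pls import BehaviouralPLSResult, PLSResult, behavioural_pls, run_task_pls
from .synthetic import GroundTruth, generate_power_dataset, generate_trials

logger = logging.getLogger("oscpls")

__all__ = ["Contrast", "AnalysisPlan", "RunReport", "run_pipeline", "export_report"]

BEHAVIOUR_MEASURES = ("accuracy_pct", "mean_rt_ms", "hipp_volume_mm3")


@dataclass(frozen=True)
class Contrast:
    """A task-window comparison: ``window`` versus ``baseline`` condition."""

    name: str
    window: str
    baseline: str


def default_contrasts() -> tuple[Contrast, ...]:
    return (
        Contrast("delay", "delay", "pre_stimulus"),
        Contrast("test_stimulus_locked", "test", "first_study"),
        Contrast("response_locked", "response_locked", "first_study_short"),
    )


@dataclass(frozen=True)
class AnalysisPlan:
    contrasts: tuple[Contrast, ...] = field(default_factory=default_contrasts)
    groups: str = "both"  # both | younger-only | older-only
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    centering: str = "grand"
    perm_scheme: str = "cells"
    per_group_reruns: bool = True
    behavioural: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.groups not in ("both", "younger-only", "older-only"):
            raise ValueError(f"unknown group selection {self.groups!r}")


@dataclass
class RunReport:
    provenance: dict[str, Any]
    behaviour_summary: pd.DataFrame | None = None
    task_results: dict[str, PLSResult] = field(default_factory=dict)
    behavioural_results: dict[str, BehaviouralPLSResult] = field(default_factory=dict)
    response_locked_counts: pd.Series | None = None
    ground_truth: GroundTruth | None = None

    def summary_dict(self) -> dict[str, Any]:
        """Numeric summary of every analysis, JSON-serialisable."""
        out: dict[str, Any] = {"provenance": self.provenance}
        task = {}
        for name, res in self.task_results.items():
            entry = {
                "singular_values": res.singular_values.tolist(),
                "crossblock_pct": res.crossblock_pct.tolist(),
                "perm_p": None if res.perm_p is None else res.perm_p.tolist(),
                "cells": ["|".join(c) for c in res.cell_labels],
                "design_salience_lv1": res.design_saliences[:, 0].tolist(),
                "n_reliable_lv1": (
                    int(res.boot.reliable[:, 0].sum()) if res.boot is not None else None
                ),
                "degenerate": res.degenerate,
                "meta": res.meta,
            }
            task[name] = entry
        out["task_pls"] = task
        beh = {}
        for name, res in self.behavioural_results.items():
            beh[name] = {
                "singular_values": res.singular_values.tolist(),
                "crossblock_pct": res.crossblock_pct.tolist(),
                "perm_p": None if res.perm_p is None else res.perm_p.tolist(),
                "correlation_rows": ["|".join(r) for r in res.correlation_rows],
                "behaviour_saliences_lv1": res.behaviour_saliences[:, 0].tolist(),
                "score_correlations_lv1": res.score_correlations[..., 0].tolist(),
                "score_corr_reliable_lv1": (
                    None
                    if res.score_corr_reliable is None
                    else res.score_corr_reliable[..., 0].tolist()
                ),
                "groups": list(res.groups),
                "measures": list(res.measures),
                "meta": res.meta,
            }
        out["behavioural_pls"] = beh
        if self.behaviour_summary is not None:
            out["behaviour_summary"] = self.behaviour_summary.to_dict(orient="records")
        if self.response_locked_counts is not None:
            out["response_locked_counts"] = {
                str(k): int(v) for k, v in self.response_locked_counts.items()
            }
        return out


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name: str, t0: float, **info: Any) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, extras)


def run_pipeline(
    config: SimulationConfig,
    plan: AnalysisPlan,
    seed: int,
    power: PowerTensor | None = None,
    behaviour: pd.DataFrame | None = None,
) -> RunReport:
    """Execute the full analysis plan on simulated (or supplied) data.

    With ``power``/``behaviour`` omitted, a synthetic dataset is generated
    from ``config`` at ``seed``. Each contrast is analysed with a task PLS
    across the included groups plus (optionally) one per group; the contrast
    block per subject feeds the behavioural PLS against the three
    behavioural measures.
    """
    t0 = time.perf_counter()
    truth = None
    trials = None
    if power is None:
        power, behaviour, truth = generate_power_dataset(config, seed)
        trials = generate_trials(config, seed)
        _stage("simulate", t0, subjects=len(power.subjects), channels=len(power.channels))
    if behaviour is None:
        raise ValueError("behaviour table required when power tensor is supplied")

    if plan.groups == "both":
        groups = list(power.groups)
    else:
        want = plan.groups.removesuffix("-only")
        if want not in power.groups:
            raise ValueError(f"group {want!r} not present in data")
        groups = [want]

    report = RunReport(
        provenance={
            "seed": seed,
            "config_hash": _config_hash(config),
            "n_per_group": config.n_per_group,
            "n_channels": config.n_channels,
            "bands": list(config.band_names),
            "groups": groups,
            "plan": {
                "n_perm": plan.n_perm,
                "n_boot": plan.n_boot,
                "alpha": plan.alpha,
                "centering": plan.centering,
                "perm_scheme": plan.perm_scheme,
                "contrasts": [
                    {"name": c.name, "window": c.window, "baseline": c.baseline}
                    for c in plan.contrasts
                ],
            },
        },
        ground_truth=truth,
    )

    # behavioural summary statistics
    beh = behaviour.copy()
    report.behaviour_summary = group_summary(beh, groups=list(power.groups))
    if trials is not None:
        _, counts = select_response_locked(trials)
        report.response_locked_counts = counts
    _stage("behaviour", t0, measures=len(BEHAVIOUR_MEASURES))

    beh = beh.set_index("subject")
    for contrast in plan.contrasts:
        for c in (contrast.window, contrast.baseline):
            if c not in power.conditions:
                raise ValueError(
                    f"stage=task_pls contrast={contrast.name!r}: condition {c!r} "
                    f"missing from tensor (has {power.conditions})"
                )
        scopes = [("all", groups)]
        if plan.per_group_reruns and len(groups) > 1:
            scopes += [(g, [g]) for g in groups]
        for scope_name, scope_groups in scopes:
            sub = power.restrict_groups(scope_groups)
            data = build_task_matrix(sub, [contrast.baseline, contrast.window], scope_groups)
            res = run_task_pls(
                data,
                n_perm=plan.n_perm,
                n_boot=plan.n_boot,
                seed=seed,
                centering=plan.centering,
                scheme=plan.perm_scheme,
                alpha=plan.alpha,
            )
            res.meta["contrast"] = contrast.name
            res.meta["scope"] = scope_name
            report.task_results[f"{contrast.name}/{scope_name}"] = res
            _stage("task_pls", t0, contrast=contrast.name, scope=scope_name, rows=data.X.shape[0])

        if plan.behavioural and len(groups) >= 1:
            sub = power.restrict_groups(groups)
            block = sub.contrast(contrast.window, contrast.baseline).reshape(
                len(sub.subjects), -1
            )
            subject_groups = [sub.group_of[s] for s in sub.subjects]
            B = beh.loc[list(sub.subjects), list(BEHAVIOUR_MEASURES)].to_numpy()
            bres = behavioural_pls(
                block,
                subject_groups,
                B,
                measures=BEHAVIOUR_MEASURES,
                groups=groups,
                n_perm=plan.n_perm,
                n_boot=plan.n_boot,
                seed=seed,
                alpha=plan.alpha,
            )
            bres.meta["contrast"] = contrast.name
            report.behavioural_results[contrast.name] = bres
            _stage("behavioural_pls", t0, contrast=contrast.name, subjects=block.shape[0])

    return report


# ---------------------------------------------------------------------------
# export


def _human_summary(report: RunReport, alpha: float) -> str:
    lines = ["oscpls run report", "=" * 17, ""]
    prov = report.provenance
    lines.append(f"seed {prov['seed']}  config {prov['config_hash']}  groups {prov['groups']}")
    lines.append("")
    for name, res in report.task_results.items():
        p = res.perm_p[0] if res.perm_p is not None else float("nan")
        lines.append(
            f"[task PLS] {name}: LV1 {res.crossblock_pct[0]:.1f}% of crossblock covariance, "
            f"perm p = {p:.4g}" + ("  *significant*" if p <= alpha else "")
        )
        if res.boot is not None:
            table = res.reliable_table(0)
            lines.append(f"  reliable channel x band elements (95% CI excludes zero): {len(table)}")
            for _, row in table.iterrows():
                lines.append(
                    f"    {row['sign']} {row['channel']} {row['band']} "
                    f"(BSR {row['bootstrap_ratio']:.2f})"
                )
    lines.append("")
    for name, res in report.behavioural_results.items():
        p = res.perm_p[0] if res.perm_p is not None else float("nan")
        lines.append(
            f"[behavioural PLS] {name}: LV1 {res.crossblock_pct[0]:.1f}%, perm p = {p:.4g}"
        )
        for gi, g in enumerate(res.groups):
            for mi, m in enumerate(res.measures):
                r = res.score_correlations[gi, mi, 0]
                rel = ""
                if res.score_corr_reliable is not None:
                    rel = "  reliable" if res.score_corr_reliable[gi, mi, 0] else ""
                lines.append(f"    {g} {m}: r = {r:+.2f}{rel}")
    return "\n".join(lines) + "\n"


def export_report(report: RunReport, path: str | Path) -> list[Path]:
    """Write the report: JSON summary, salience tables, human-readable text.

    Returns the list of files written. Numeric fields round-trip exactly
    through the JSON (written with full repr precision).
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = out / "report.json"
    with open(summary, "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2)
    written.append(summary)

    for name, res in report.task_results.items():
        tag = name.replace("/", "_")
        tab = res.cols.copy()
        for lv in range(res.n_lv):
            tab[f"salience_lv{lv + 1}"] = res.brain_saliences[:, lv]
            if res.boot is not None:
                tab[f"bsr_lv{lv + 1}"] = res.boot.ratio[:, lv]
                tab[f"ci_lo_lv{lv + 1}"] = res.boot.ci_lo[:, lv]
                tab[f"ci_hi_lv{lv + 1}"] = res.boot.ci_hi[:, lv]
                tab[f"reliable_lv{lv + 1}"] = res.boot.reliable[:, lv]
        f = out / f"saliences_{tag}.tsv"
        tab.to_csv(f, sep="\t", index=False)
        written.append(f)
        scores = res.rows.copy()
        for lv in range(res.n_lv):
            scores[f"brain_score_lv{lv + 1}"] = res.brain_scores[:, lv]
        f = out / f"brain_scores_{tag}.tsv"
        scores.to_csv(f, sep="\t", index=False)
        written.append(f)

    if report.behaviour_summary is not None:
        f = out / "behaviour_summary.tsv"
        report.behaviour_summary.to_csv(f, sep="\t", index=False)
        written.append(f)

    if report.ground_truth is not None:
        f = out / "ground_truth.json"
        report.ground_truth.to_json(f)
        written.append(f)

    alpha = report.provenance.get("plan", {}).get("alpha", 0.05)
    f = out / "summary.txt"
    f.write_text(_human_summary(report, alpha))
    written.append(f)
    return written


def load_report_summary(path: str | Path) -> dict[str, Any]:
    """Read back the JSON summary written by :func:`export_report`."""
    with open(Path(path) / "report.json") as fh:
        return json.load(fh)
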