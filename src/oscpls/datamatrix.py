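"""Band-power containers and the stacked data matrix submitted to task PLS.

``PowerTensor`` holds per-subject, per-condition, per-channel, per-band
oscillatory power with full axis labels. ``build_task_matrix`` flattens a
pair (or more) of conditions into the canonical 2-D layout used by
mean-centered PLS: participants within conditions within groups in the
rows, channel x band in the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PowerTensor",
    "TaskDataMatrix",
    "build_task_matrix",
    "read_power_tensor",
]


@dataclass
class PowerTensor:
    """subject x condition x channel x band power, with axis labels.

    ``group_of`` maps each subject id to its group label. Values are mean
    log power by default (linear power if produced with ``log_power=False``).
    """

    values: np.ndarray
    subjects: tuple[str, ...]
    conditions: tuple[str, ...]
    channels: tuple[str, ...]
    bands: tuple[str, ...]
    group_of: dict[str, str]
    log_power: bool = True

    def __post_init__(self) -> None:
        expected = (len(self.subjects), len(self.conditions), len(self.channels), len(self.bands))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != labels {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("power tensor contains non-finite entries")
        missing = [s for s in self.subjects if s not in self.group_of]
        if missing:
            raise ValueError(f"subjects without group label: {missing[:5]}")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.subjects:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def condition(self, name: str) -> np.ndarray:
        """subject x channel x band slice for one condition."""
        try:
            i = self.conditions.index(name)
        except ValueError:
            raise KeyError(f"unknown condition {name!r}") from None
        return self.values[:, i]

    def contrast(self, a: str, b: str) -> np.ndarray:
        """Per-subject elementwise difference ``a - b`` (positive = increase in a)."""
        return self.condition(a) - self.condition(b)

    def restrict_groups(self, groups: Sequence[str]) -> "PowerTensor":
        keep = [i for i, s in enumerate(self.subjects) if self.group_of[s] in groups]
        subjects = tuple(self.subjects[i] for i in keep)
        return PowerTensor(
            values=self.values[keep],
            subjects=subjects,
            conditions=self.conditions,
            channels=self.channels,
            bands=self.bands,
            group_of={s: self.group_of[s] for s in subjects},
            log_power=self.log_power,
        )

    # -- long-format text IO -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long format: subject, group, condition, channel, band, power."""
        n_s, n_c, n_ch, n_b = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.conditions, self.channels, self.bands],
            names=["subject", "condition", "channel", "band"],
        )
        df = pd.DataFrame({"power": self.values.reshape(-1)}, index=idx).reset_index()
        df.insert(1, "group", df["subject"].map(self.group_of))
        return df

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, log_power: bool = True) -> "PowerTensor":
        required = {"subject", "group", "condition", "channel", "band", "power"}
        if not required.issubset(df.columns):
            raise ValueError(f"long-format frame needs columns {sorted(required)}")
        subjects = tuple(pd.unique(df["subject"]))
        conditions = tuple(pd.unique(df["condition"]))
        channels = tuple(pd.unique(df["channel"]))
        bands = tuple(pd.unique(df["band"]))
        group_of = dict(zip(df["subject"], df["group"]))
        pivot = df.set_index(["subject", "condition", "channel", "band"])["power"]
        expected = len(subjects) * len(conditions) * len(channels) * len(bands)
        if len(pivot) != expected or pivot.index.duplicated().any():
            raise ValueError("long-format frame has missing or duplicate cells")
        full = pd.MultiIndex.from_product([subjects, conditions, channels, bands])
        values = pivot.reindex(full).to_numpy().reshape(
            len(subjects), len(conditions), len(channels), len(bands)
        )
        return cls(values, subjects, conditions, channels, bands, group_of, log_power)


def read_power_tensor(path: str | Path, sep: str = "\t", log_power: bool = True) -> PowerTensor:
    return PowerTensor.from_frame(pd.read_csv(path, sep=sep), log_power=log_power)


@dataclass
class TaskDataMatrix:
    """The 2-D stack submitted to mean-centered PLS.

    Rows are ordered group-major, condition within group, subject within
    condition; columns channel-major, band within channel. ``rows`` carries
    (subject, group, condition) per row; ``cols`` carries (channel, band).
    """

    X: np.ndarray
    rows: pd.DataFrame
    cols: pd.DataFrame
    groups: tuple[str, ...]
    conditions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.rows), len(self.cols)):
            raise ValueError("X shape does not match row/column metadata")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("task data matrix contains non-finite values")
        pairs = self.rows[["subject", "condition"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate subject-condition pair in rows")

    @property
    def n_cells(self) -> int:
        return len(self.groups) * len(self.conditions)

    def cell_index(self) -> list[np.ndarray]:
        """Row indices per (group, condition) cell, group-major order."""
        out = []
        for g in self.groups:
            for c in self.conditions:
                mask = (self.rows["group"] == g) & (self.rows["condition"] == c)
                idx = np.flatnonzero(mask.to_numpy())
                if idx.size == 0:
                    raise ValueError(f"empty cell (group={g!r}, condition={c!r})")
                out.append(idx)
        return out

    def cell_labels(self) -> list[tuple[str, str]]:
        return [(g, c) for g in self.groups for c in self.conditions]


def build_task_matrix(
    power: PowerTensor,
    conditions: Sequence[str],
    groups: Sequence[str] | None = None,
) -> TaskDataMatrix:
    """Stack the requested conditions into the canonical PLS data matrix.

    Row order is deterministic regardless of input record order: groups in
    the given order, conditions within group, subjects (tensor order) within
    condition. Columns are channel-major with bands nested within channel.
    """
    groups = tuple(groups) if groups is not None else power.groups
    conditions = tuple(conditions)
    for c in conditions:
        if c not in power.conditions:
            raise KeyError(f"condition {c!r} not in tensor (has {power.conditions})")
    for g in groups:
        if g not in power.groups:
            raise KeyError(f"group {g!r} not in tensor (has {power.groups})")

    n_ch, n_b = len(power.channels), len(power.bands)
    rows: list[dict[str, str]] = []
    blocks: list[np.ndarray] = []
    for g in groups:
        members = [i for i, s in enumerate(power.subjects) if power.group_of[s] == g]
        if not members:
            raise ValueError(f"group {g!r} has no subjects")
        for c in conditions:
            ci = power.conditions.index(c)
            for si in members:
                rows.append({"subject": power.subjects[si], "group": g, "condition": c})
                blocks.append(power.values[si, ci].reshape(n_ch * n_b))
    X = np.vstack(blocks)
    cols = pd.DataFrame(
        {
            "channel": np.repeat(power.channels, n_b),
            "band": np.tile(power.bands, n_ch),
        }
    )
    return TaskDataMatrix(
        X=X,
        rows=pd.DataFrame(rows),
        cols=cols,
        groups=groups,
        conditions=conditions,
    )
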