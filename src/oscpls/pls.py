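"""Mean-centered task PLS and behavioural PLS with resampling inference.

Task (mean-centered) PLS decomposes the grand-mean-centered matrix of
group x condition cell means with an SVD. Each latent variable (LV)
comprises a design salience (the contrast over cells), a brain salience
(the weighting over channel x band columns) and a singular value; the
squared singular values, as percentages, give the crossblock covariance
accounted for by each LV. Behavioural PLS decomposes the stacked
within-group correlation matrix between behavioural measures and brain
columns.

Inference follows the standard two-pronged resampling scheme: permutation
tests on the singular values (rows randomly reassigned to cells) and
bootstrap estimation of salience reliability (subjects resampled with
replacement within group, each bootstrap SVD aligned to the original LVs
by an orthogonal Procrustes rotation to absorb sign/order indeterminacy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .datamatrix import TaskDataMatrix

__all__ = [
    "PLSResult",
    "BootstrapEstimates",
    "BehaviouralPLSResult",
    "mean_centered_pls",
    "crossblock_pct",
    "permutation_test",
    "bootstrap_saliences",
    "behavioural_pls",
    "run_task_pls",
]

_SV_TOL = 1e-12
_BOOT_RETRY_CAP = 100


# ---------------------------------------------------------------------------
# result containers


@dataclass
class BootstrapEstimates:
    """Per-element bootstrap summaries for the brain saliences (p x k)."""

    se: np.ndarray
    ratio: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    reliable: np.ndarray
    design_se: np.ndarray
    design_ci_lo: np.ndarray
    design_ci_hi: np.ndarray
    n_boot: int
    degenerate: bool = False


@dataclass
class PLSResult:
    singular_values: np.ndarray
    design_saliences: np.ndarray  # cells x k
    brain_saliences: np.ndarray  # columns x k
    brain_scores: np.ndarray  # rows x k
    crossblock_pct: np.ndarray
    cell_labels: list[tuple[str, str]]
    cols: pd.DataFrame
    rows: pd.DataFrame
    degenerate: bool = False
    perm_p: np.ndarray | None = None
    boot: BootstrapEstimates | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)

    def reliable_table(self, lv: int = 0) -> pd.DataFrame:
        """Channel x band elements whose bootstrap 95% CI excludes zero."""
        if self.boot is None:
            raise ValueError("bootstrap estimates not computed")
        mask = self.boot.reliable[:, lv]
        out = self.cols.loc[mask].copy()
        out["salience"] = self.brain_saliences[mask, lv]
        out["bootstrap_ratio"] = self.boot.ratio[mask, lv]
        out["sign"] = np.where(out["salience"] >= 0, "+", "-")
        return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# core decomposition


def _cell_mean_operator(data: TaskDataMatrix) -> np.ndarray:
    """(n_cells x n_rows) averaging matrix A with A @ X = cell means."""
    n_rows = data.X.shape[0]
    cells = data.cell_index()
    A = np.zeros((len(cells), n_rows))
    for i, idx in enumerate(cells):
        A[i, idx] = 1.0 / idx.size
    return A


def _center_cells(M: np.ndarray, data: TaskDataMatrix, centering: str) -> np.ndarray:
    """Center the cell-mean matrix.

    "grand": remove the unweighted grand mean of the cell means (both group
    and condition effects remain expressible). "condition": remove each
    condition's mean across groups (only group and interaction effects
    remain).
    """
    if centering == "grand":
        return M - M.mean(axis=0, keepdims=True)
    if centering == "condition":
        n_g, n_c = len(data.groups), len(data.conditions)
        Mr = M.reshape(n_g, n_c, -1)
        return (Mr - Mr.mean(axis=0, keepdims=True)).reshape(M.shape)
    raise ValueError(f"unknown centering {centering!r} (use 'grand' or 'condition')")


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: the largest-|.| brain-salience element
    of each LV is positive."""
    U, V = U.copy(), V.copy()
    for i in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] *= -1
            U[:, i] *= -1
    return U, V


def crossblock_pct(singular_values: np.ndarray) -> np.ndarray:
    """100 * sigma_i^2 / sum sigma_j^2. Raises on an all-zero spectrum."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("all singular values are zero; crossblock percentages undefined")
    return 100.0 * s**2 / total


def mean_centered_pls(data: TaskDataMatrix, centering: str = "grand") -> PLSResult:
    """SVD of the centered group x condition cell-mean matrix.

    Brain scores are the projections of the subject rows, centered by the
    same grand mean as the cell means, onto the brain saliences. On a
    constant matrix all singular values are zero and the result carries a
    degeneracy flag (crossblock percentages are then zero, not NaN).
    """
    if data.n_cells < 2:
        raise ValueError("mean-centered PLS needs at least 2 group x condition cells")
    A = _cell_mean_operator(data)
    M = A @ data.X
    Mc = _center_cells(M, data, centering)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)
    degenerate = bool(np.all(s < _SV_TOL))
    pct = np.zeros_like(s) if degenerate else crossblock_pct(s)
    grand = M.mean(axis=0, keepdims=True)
    scores = (data.X - grand) @ V
    return PLSResult(
        singular_values=s,
        design_saliences=U,
        brain_saliences=V,
        brain_scores=scores,
        crossblock_pct=pct,
        cell_labels=data.cell_labels(),
        cols=data.cols.copy(),
        rows=data.rows.copy(),
        degenerate=degenerate,
        meta={"centering": centering, "n_cells": data.n_cells},
    )


# ---------------------------------------------------------------------------
# permutation test


def permutation_test(
    data: TaskDataMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "cells",
    centering: str = "grand",
    smoothing: bool = False,
) -> np.ndarray:
    """Permutation p-value per LV from random reassignment of rows to cells.

    scheme "cells" reassigns rows to every (group, condition) cell; scheme
    "within_group" shuffles rows only within each group, reassigning
    conditions but never group membership. The p-value uses the literal
    counting rule #{sigma_perm >= sigma_obs} / n_perm; ``smoothing`` switches
    to the add-one rule (+1 numerator and denominator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    base = mean_centered_pls(data, centering=centering)
    s_obs = base.singular_values
    A = _cell_mean_operator(data)
    # pre-fold the centering into the averaging operator: sigma of C @ X[perm]
    M_shape_fix = _center_cells(np.eye(A.shape[0]), data, centering)
    C = M_shape_fix @ A

    rng = substream(seed, "task-permutation")
    n_rows = data.X.shape[0]
    group_blocks = None
    if scheme == "within_group":
        group_blocks = [
            np.flatnonzero((data.rows["group"] == g).to_numpy()) for g in data.groups
        ]
    elif scheme != "cells":
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        if group_blocks is None:
            perm = rng.permutation(n_rows)
        else:
            perm = np.arange(n_rows)
            for idx in group_blocks:
                perm[idx] = idx[rng.permutation(idx.size)]
        s_perm = np.linalg.svd(C @ data.X[perm], compute_uv=False)
        exceed += s_perm >= s_obs
    if smoothing:
        return (exceed + 1) / (n_perm + 1)
    return exceed / n_perm


# ---------------------------------------------------------------------------
# bootstrap


def _procrustes_rotation(V_ref: np.ndarray, V_boot: np.ndarray) -> np.ndarray:
    """Orthogonal rotation R minimising ||V_boot R - V_ref||_F."""
    U_, _, Vt_ = np.linalg.svd(V_boot.T @ V_ref, full_matrices=False)
    return U_ @ Vt_


def _quantile_ci(draws: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Percentile CI from order statistics (lower/higher rule), so two draws
    give exactly their min and max."""
    lo = np.quantile(draws, alpha / 2, axis=0, method="lower")
    hi = np.quantile(draws, 1 - alpha / 2, axis=0, method="higher")
    return lo, hi


def _subject_rows(data: TaskDataMatrix) -> tuple[list[list[str]], dict[str, np.ndarray]]:
    """Per-group subject lists and, per subject, their row indices in
    condition order (all of a subject's rows move together when resampled)."""
    per_group: list[list[str]] = []
    row_of: dict[str, np.ndarray] = {}
    for g in data.groups:
        seen: list[str] = []
        for s in data.rows.loc[data.rows["group"] == g, "subject"]:
            if s not in seen:
                seen.append(s)
        per_group.append(seen)
        for s in seen:
            mask = (data.rows["subject"] == s).to_numpy()
            order = data.rows.loc[mask, "condition"].to_numpy()
            idx = np.flatnonzero(mask)
            pos = [int(idx[list(order).index(c)]) for c in data.conditions]
            row_of[s] = np.asarray(pos)
    return per_group, row_of


def bootstrap_saliences(
    data: TaskDataMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    centering: str = "grand",
    alpha: float = 0.05,
    base: PLSResult | None = None,
) -> BootstrapEstimates:
    """Bootstrap SE, ratio and percentile CI for every brain-salience element.

    Subjects are resampled with replacement within their group; condition
    assignment stays fixed, so all of a subject's rows enter together. Each
    bootstrap SVD is aligned to the original LVs with an orthogonal
    Procrustes rotation computed from the brain saliences. A draw whose cell
    means are totally degenerate (all-zero spectrum) is redrawn, up to a
    retry cap. ``reliable`` marks elements whose (1-alpha) CI excludes zero.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if base is None:
        base = mean_centered_pls(data, centering=centering)
    per_group, row_of = _subject_rows(data)
    for g, subs in zip(data.groups, per_group):
        if len(subs) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    k = max(int(np.sum(base.singular_values > _SV_TOL)), 1)
    V0 = base.brain_saliences[:, :k]

    n_cells, n_cond = data.n_cells, len(data.conditions)
    rng = substream(seed, "task-bootstrap")
    V_draws = np.empty((n_boot, V0.shape[0], k))
    U_draws = np.empty((n_boot, n_cells, k))
    any_degenerate = False
    for b in range(n_boot):
        for attempt in range(_BOOT_RETRY_CAP + 1):
            M = np.empty((n_cells, data.X.shape[1]))
            cell = 0
            for subs in per_group:
                take = rng.integers(0, len(subs), size=len(subs))
                rows = np.array([row_of[subs[t]] for t in take])  # n_subj x n_cond
                for c in range(n_cond):
                    M[cell + c] = data.X[rows[:, c]].mean(axis=0)
                cell += n_cond
            Mc = _center_cells(M, data, centering)
            Ub, sb, Vbt = np.linalg.svd(Mc, full_matrices=False)
            if np.any(sb > _SV_TOL) or base.degenerate:
                break
        else:
            any_degenerate = True
        R = _procrustes_rotation(V0, Vbt.T[:, :k])
        V_draws[b] = Vbt.T[:, :k] @ R
        U_draws[b] = Ub[:, :k] @ R

    se = V_draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(se > 0, V0 / np.where(se > 0, se, 1.0), 0.0)
    ci_lo, ci_hi = _quantile_ci(V_draws, alpha)
    d_se = U_draws.std(axis=0, ddof=1)
    d_lo, d_hi = _quantile_ci(U_draws, alpha)
    if np.all(se < 1e-12):
        any_degenerate = True
    reliable = (ci_lo > 0) | (ci_hi < 0)
    full_k = base.n_lv

    def _pad(arr: np.ndarray, fill: float = 0.0) -> np.ndarray:
        if arr.shape[1] == full_k:
            return arr
        out = np.full((arr.shape[0], full_k), fill)
        out[:, :k] = arr
        return out

    return BootstrapEstimates(
        se=_pad(se),
        ratio=_pad(ratio),
        ci_lo=_pad(ci_lo),
        ci_hi=_pad(ci_hi),
        reliable=_pad(reliable).astype(bool),
        design_se=_pad(d_se),
        design_ci_lo=_pad(d_lo),
        design_ci_hi=_pad(d_hi),
        n_boot=n_boot,
        degenerate=any_degenerate,
    )


def run_task_pls(
    data: TaskDataMatrix,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    centering: str = "grand",
    scheme: str = "cells",
    alpha: float = 0.05,
) -> PLSResult:
    """Mean-centered PLS with permutation and bootstrap inference attached."""
    result = mean_centered_pls(data, centering=centering)
    if n_perm >= 1:
        result.perm_p = permutation_test(
            data, n_perm=n_perm, seed=seed, scheme=scheme, centering=centering
        )
    if n_boot >= 2:
        result.boot = bootstrap_saliences(
            data, n_boot=n_boot, seed=seed, centering=centering, alpha=alpha, base=result
        )
    result.meta.update(
        {"seed": seed, "n_perm": n_perm, "n_boot": n_boot, "scheme": scheme, "alpha": alpha}
    )
    return result


# ---------------------------------------------------------------------------
# behavioural PLS


@dataclass
class BehaviouralPLSResult:
    singular_values: np.ndarray
    behaviour_saliences: np.ndarray  # (group x measure) x k
    brain_saliences: np.ndarray  # columns x k
    brain_scores: np.ndarray  # subjects x k
    crossblock_pct: np.ndarray
    correlation_rows: list[tuple[str, str]]  # (group, measure) per R row
    score_correlations: np.ndarray  # group x measure x k
    score_corr_ci_lo: np.ndarray | None = None
    score_corr_ci_hi: np.ndarray | None = None
    score_corr_reliable: np.ndarray | None = None
    perm_p: np.ndarray | None = None
    boot: BootstrapEstimates | None = None
    groups: tuple[str, ...] = ()
    measures: tuple[str, ...] = ()
    meta: dict[str, Any] = field(default_factory=dict)


def _group_corr(Xg: np.ndarray, Bg: np.ndarray) -> np.ndarray:
    """Pearson correlations (measures x brain columns) within one group."""
    n = Xg.shape[0]
    Xs = Xg.std(axis=0, ddof=1)
    Bs = Bg.std(axis=0, ddof=1)
    if np.any(Xs == 0) or np.any(Bs == 0):
        raise ValueError("zero-variance brain column or behaviour measure within a group")
    Zx = (Xg - Xg.mean(axis=0)) / Xs
    Zb = (Bg - Bg.mean(axis=0)) / Bs
    return (Zb.T @ Zx) / (n - 1)


def behavioural_pls(
    X: np.ndarray,
    subject_groups: Sequence[str],
    behaviour: np.ndarray,
    measures: Sequence[str],
    groups: Sequence[str] | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    cols: pd.DataFrame | None = None,
) -> BehaviouralPLSResult:
    """PLS on the stacked within-group behaviour-brain correlation matrix.

    ``X`` has one brain row per subject (typically a window contrast);
    ``behaviour`` is subjects x measures. Correlations are Pearson, computed
    within group and stacked group-wise (groups x measures rows). The SVD of
    that matrix yields LVs whose behaviour saliences show which group/measure
    combinations drive each brain pattern. Permutation reassigns behaviour
    rows relative to brain rows within group; the bootstrap resamples
    subjects within group and also yields CIs for the per-group correlation
    between brain scores and each measure.
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(behaviour, dtype=float)
    subject_groups = np.asarray(subject_groups)
    if X.ndim != 2 or B.ndim != 2 or X.shape[0] != B.shape[0]:
        raise ValueError("X and behaviour must be 2-D with one row per subject")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite values in brain or behaviour block")
    if groups is None:
        groups = list(dict.fromkeys(subject_groups.tolist()))
    groups = tuple(groups)
    measures = tuple(measures)
    g_idx = [np.flatnonzero(subject_groups == g) for g in groups]
    for g, idx in zip(groups, g_idx):
        if idx.size < 3:
            raise ValueError(f"group {g!r} needs >= 3 subjects for correlations")

    def corr_matrix(Xf: np.ndarray, Bf: np.ndarray, idx_list: list[np.ndarray]) -> np.ndarray:
        return np.vstack([_group_corr(Xf[idx], Bf[idx]) for idx in idx_list])

    R = corr_matrix(X, B, g_idx)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)
    scores = X @ V
    k = len(s)

    # observed per-group correlation of brain scores with each measure
    score_r = np.empty((len(groups), len(measures), k))
    for gi, idx in enumerate(g_idx):
        # _group_corr returns measures x columns; columns here are the LV scores
        score_r[gi] = _group_corr(scores[idx], B[idx])

    result = BehaviouralPLSResult(
        singular_values=s,
        behaviour_saliences=U,
        brain_saliences=V,
        brain_scores=scores,
        crossblock_pct=crossblock_pct(s) if np.any(s > _SV_TOL) else np.zeros_like(s),
        correlation_rows=[(g, m) for g in groups for m in measures],
        score_correlations=score_r,
        groups=groups,
        measures=measures,
        meta={"seed": seed, "n_perm": n_perm, "n_boot": n_boot, "alpha": alpha},
    )

    # permutation: shuffle behaviour rows within group
    if n_perm >= 1:
        rng = substream(seed, "behavioural-permutation")
        exceed = np.zeros(k)
        for _ in range(n_perm):
            perm = np.arange(X.shape[0])
            for idx in g_idx:
                perm[idx] = idx[rng.permutation(idx.size)]
            s_perm = np.linalg.svd(corr_matrix(X, B[perm], g_idx), compute_uv=False)
            exceed += s_perm >= s
        result.perm_p = exceed / n_perm

    # bootstrap: resample subjects within group
    if n_boot >= 2:
        rng = substream(seed, "behavioural-bootstrap")
        k_eff = max(int(np.sum(s > _SV_TOL)), 1)
        V0 = V[:, :k_eff]
        V_draws = np.empty((n_boot, V.shape[0], k_eff))
        U_draws = np.empty((n_boot, U.shape[0], k_eff))
        r_draws = np.empty((n_boot, len(groups), len(measures), k_eff))
        degenerate = False
        for b in range(n_boot):
            for attempt in range(_BOOT_RETRY_CAP + 1):
                boot_idx = [idx[rng.integers(0, idx.size, size=idx.size)] for idx in g_idx]
                try:
                    Rb = np.vstack([_group_corr(X[bi], B[bi]) for bi in boot_idx])
                except ValueError:
                    continue  # zero-variance draw: redraw
                break
            else:
                degenerate = True
                Rb = R
                boot_idx = g_idx
            Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
            Rrot = _procrustes_rotation(V0, Vbt.T[:, :k_eff])
            Vb = Vbt.T[:, :k_eff] @ Rrot
            V_draws[b] = Vb
            U_draws[b] = Ub[:, :k_eff] @ Rrot
            sb_scores = X @ Vb
            for gi, bi in enumerate(boot_idx):
                try:
                    r_draws[b, gi] = _group_corr(sb_scores[bi], B[bi])
                except ValueError:
                    r_draws[b, gi] = np.nan
        se = V_draws.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(se > 0, V0 / np.where(se > 0, se, 1.0), 0.0)
        ci_lo, ci_hi = _quantile_ci(V_draws, alpha)
        d_se = U_draws.std(axis=0, ddof=1)
        d_lo, d_hi = _quantile_ci(U_draws, alpha)
        rv = np.where(np.isfinite(r_draws), r_draws, 0.0)
        r_lo, r_hi = _quantile_ci(rv, alpha)
        result.boot = BootstrapEstimates(
            se=se,
            ratio=ratio,
            ci_lo=ci_lo,
            ci_hi=ci_hi,
            reliable=((ci_lo > 0) | (ci_hi < 0)),
            design_se=d_se,
            design_ci_lo=d_lo,
            design_ci_hi=d_hi,
            n_boot=n_boot,
            degenerate=degenerate,
        )
        result.score_corr_ci_lo = r_lo
        result.score_corr_ci_hi = r_hi
        result.score_corr_reliable = (r_lo > 0) | (r_hi < 0)
    return result
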