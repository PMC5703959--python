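"""Conditional Q-Q curves, fold-enrichment curves and Manhattan plot data.

All computation is separated from rendering: the ``conditional_qq``,
``fold_enrichment`` and ``manhattan_data`` functions return plain data that
the ``plot_*`` functions merely draw.

A conditional Q-Q plot stratifies the principal trait's p-values by nested
cutoffs on the conditioning trait (p2 <= t); enrichment shows as the
stringent strata deflecting up/left of the all-SNPs curve.  Fold enrichment
quantifies the same signal: the proportion of a stratum exceeding a
-log10(p1) cutoff divided by the same proportion among all SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import EmptyInputError

log = logging.getLogger(__name__)

#: -log10 p cap applied when *plotting* only; tables keep full values
PLOT_LOG10_CAP = 300.0

#: conventional decade strata for conditional Q-Q plots
DEFAULT_LEVELS = (1.0, 0.1, 0.01, 0.001)

#: -log10 of the genome-wide significance level 5e-8, the headline
#: comparison point for fold-enrichment curves
GENOME_WIDE_LOG10 = 7.3


@dataclass(frozen=True)
class ConditioningLevels:
    """Descending p2 cutoffs; the first (1.0) is the all-SNPs stratum."""

    thresholds: tuple = DEFAULT_LEVELS

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if not t or t[0] != 1.0:
            raise ValueError("first conditioning level must be 1.0 (all SNPs)")
        if any(not (0.0 < x <= 1.0) for x in t):
            raise ValueError("conditioning levels must lie in (0, 1]")
        if any(t[i] <= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("conditioning levels must be strictly decreasing")


class QQCurve(NamedTuple):
    size: int
    x: np.ndarray  # empirical quantiles k/|S_t|, ascending
    y: np.ndarray  # -log10 p1 order statistics (descending along x)


@dataclass
class QQCurveSet:
    """One Q-Q curve per conditioning threshold."""

    curves: dict = field(default_factory=dict)  # threshold -> QQCurve

    @property
    def thresholds(self):
        return sorted(self.curves, reverse=True)

    def y_at(self, threshold: float, x) -> np.ndarray:
        """Curve height (-log10 p1 quantile) interpolated at fractions x."""
        c = self.curves[threshold]
        return np.interp(np.atleast_1d(x), c.x, c.y)

    def max_gap(self, t_ref: float, t_cmp: float, x_lo: float, x_hi: float,
                n_grid: int = 50) -> float:
        """Largest |vertical gap| between two curves over [x_lo, x_hi]."""
        grid = np.linspace(x_lo, x_hi, n_grid)
        return float(np.max(np.abs(self.y_at(t_cmp, grid) - self.y_at(t_ref, grid))))


def conditional_qq(merged: pd.DataFrame,
                   levels: ConditioningLevels | None = None,
                   p_col: str = "p1", cond_col: str = "p2") -> QQCurveSet:
    """Conditional Q-Q curves of ``p_col`` stratified by ``cond_col``.

    For each threshold t the stratum S_t = {i : p2_i <= t} is sorted by p1
    ascending; x_k = k/|S_t| and y_k = -log10(p1_(k)).  Empty strata are
    dropped with a warning; with only the 1.0 stratum this is the ordinary
    Q-Q plot of the principal trait.
    """
    if merged is None or len(merged) == 0:
        raise EmptyInputError("conditional_qq: empty input")
    levels = levels or ConditioningLevels()
    p1 = merged[p_col].to_numpy(float)
    p2 = merged[cond_col].to_numpy(float)
    out = QQCurveSet()
    for t in levels.thresholds:
        sel = p2 <= t
        size = int(sel.sum())
        if size == 0:
            warnings.warn(f"conditioning level {t} yields an empty stratum; dropped")
            continue
        ps = np.sort(p1[sel])
        x = np.arange(1, size + 1) / size
        y = -np.log10(ps)
        out.curves[t] = QQCurve(size=size, x=x, y=y)
    if list(out.curves) == [1.0] and len(levels.thresholds) > 1:
        warnings.warn("all strata below 1.0 empty; returning the all-SNPs curve only")
    return out


def fold_enrichment(merged: pd.DataFrame,
                    levels: ConditioningLevels | None = None,
                    grid=None, p_col: str = "p1",
                    cond_col: str = "p2") -> pd.DataFrame:
    """Fold-enrichment curves over a -log10(p1) grid.

    ``fold(t, x) = prop(S_t, -log10 p1 >= x) / prop(all, -log10 p1 >= x)``;
    grid points where the all-SNPs proportion is zero are omitted.  Returns
    a long frame: threshold, x, n_stratum, k_stratum, prop_stratum,
    prop_all, fold.
    """
    if merged is None or len(merged) == 0:
        raise EmptyInputError("fold_enrichment: empty input")
    levels = levels or ConditioningLevels()
    if grid is None:
        grid = np.arange(0.0, 10.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    neglog = -np.log10(merged[p_col].to_numpy(float))
    p2 = merged[cond_col].to_numpy(float)
    n_all = len(neglog)
    # counts of -log10 p1 >= x via sorted search
    s_all = np.sort(neglog)
    k_all = n_all - np.searchsorted(s_all, grid, side="left")
    prop_all = k_all / n_all
    rows = []
    for t in levels.thresholds:
        sel = p2 <= t
        n_t = int(sel.sum())
        if n_t == 0:
            warnings.warn(f"conditioning level {t} yields an empty stratum; dropped")
            continue
        s_t = np.sort(neglog[sel])
        k_t = n_t - np.searchsorted(s_t, grid, side="left")
        with np.errstate(invalid="ignore", divide="ignore"):
            fold = (k_t / n_t) / prop_all
        for xi, ki, pa, fi, ka in zip(grid, k_t, prop_all, fold, k_all):
            if pa == 0:
                continue  # fold undefined where the denominator is empty
            rows.append((t, xi, n_t, int(ki), ki / n_t, pa, fi))
    return pd.DataFrame(
        rows,
        columns=["threshold", "x", "n_stratum", "k_stratum",
                 "prop_stratum", "prop_all", "fold"],
    )


def fold_at(curves: pd.DataFrame, threshold: float, x: float) -> float:
    """Fold value at one (threshold, grid point); NaN if omitted/undefined."""
    sel = curves[(curves["threshold"] == threshold)
                 & (np.isclose(curves["x"], x))]
    if sel.empty:
        return float("nan")
    return float(sel["fold"].iloc[0])


@dataclass
class ManhattanData:
    """Plot-ready Manhattan data: per-SNP genome coordinate and -log10 FDR."""

    frame: pd.DataFrame       # chrom, pos, genome_x, y (= -log10 field)
    line: float               # -log10(alpha) significance line
    chrom_ticks: pd.DataFrame  # chrom, center genome_x (axis labels)


def manhattan_data(table: pd.DataFrame, field: str = "cfdr",
                   alpha: float = 0.05) -> ManhattanData:
    """-log10 FDR values with cumulative per-chromosome x offsets.

    At the default alpha the significance line sits at
    -log10(0.05) ~ 1.301 (the "1.3 line" of conditional Manhattan plots).
    """
    if field not in table.columns:
        raise ValueError(f"field {field!r} not present in table")
    df = table[["chrom", "pos"]].reset_index(drop=True)
    df["y"] = -np.log10(table[field].to_numpy(float))
    offset = 0
    genome_x = np.empty(len(df), dtype=float)
    ticks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        genome_x[sub.index.to_numpy()] = sub["pos"].to_numpy() + offset
        ticks.append((chrom, offset + sub["pos"].to_numpy().mean()))
        offset += int(sub["pos"].max()) + 1
    df["genome_x"] = genome_x
    return ManhattanData(
        frame=df,
        line=-np.log10(alpha),
        chrom_ticks=pd.DataFrame(ticks, columns=["chrom", "center"]),
    )


# ---------------------------------------------------------------------------
# rendering (presentation only — no computation beyond the -log10 cap)


def _require_nonempty(obj) -> None:
    if isinstance(obj, QQCurveSet):
        if not obj.curves:
            raise EmptyInputError("no Q-Q curves to plot")
    elif isinstance(obj, ManhattanData):
        if len(obj.frame) == 0:
            raise EmptyInputError("no SNPs to plot")
    elif obj is None or len(obj) == 0:
        raise EmptyInputError("empty curve data")


def plot_qq(qq: QQCurveSet, path) -> None:
    """Render a conditional Q-Q curve set to an image file."""
    _require_nonempty(qq)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for t in qq.thresholds:
        c = qq.curves[t]
        y = np.minimum(c.y, PLOT_LOG10_CAP)
        label = "all SNPs" if t == 1.0 else f"p2 <= {t:g}"
        ax.plot(-np.log10(c.x), y, lw=1.2, label=label)
    ax.plot([0, 6], [0, 6], ls="--", c="grey", lw=0.8, label="null")
    ax.set_xlabel("empirical -log10 quantile")
    ax.set_ylabel("nominal -log10 p (principal trait)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fold_enrichment(curves: pd.DataFrame, path) -> None:
    """Render fold-enrichment curves (one line per conditioning level)."""
    _require_nonempty(curves)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    for t, sub in curves.groupby("threshold"):
        label = "all SNPs" if t == 1.0 else f"p2 <= {t:g}"
        ax.plot(sub["x"], sub["fold"], lw=1.2, label=label)
    ax.axhline(1.0, color="purple", lw=1.0)
    ax.set_xlabel("nominal -log10 p (principal trait)")
    ax.set_ylabel("fold enrichment")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_manhattan(md: ManhattanData, path) -> None:
    """Render a conditional/conjunction Manhattan plot."""
    _require_nonempty(md)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.5))
    for k, (_, sub) in enumerate(md.frame.groupby("chrom", sort=False)):
        color = "#1f77b4" if k % 2 == 0 else "#7fb3d5"
        y = np.minimum(sub["y"], PLOT_LOG10_CAP)
        ax.scatter(sub["genome_x"], y, s=3, c=color, linewidths=0)
    ax.axhline(md.line, color="red", lw=1.0)
    ax.set_xticks(md.chrom_ticks["center"])
    ax.set_xticklabels(md.chrom_ticks["chrom"], fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
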