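"""Sliding-window, MAF-aware LD pruning of merged summary statistics.

The procedure walks each chromosome with a window of ``window`` surviving
SNPs; within a window every pair's squared Pearson correlation of reference
dosages (composite LD on unphased 0/1/2 genotypes) is examined in ascending
position order, and for any pair with r^2 above the threshold the member
with the smaller reference-panel MAF is removed immediately.  The window
then slides ``step`` SNPs forward; whole-chromosome passes repeat until a
pass removes nothing, so no pair of survivors within any window-length run
remains in high LD (checkable with :func:`verify_pruned`).

Conventions the procedure needs but that are genuinely free choices:
removals take effect immediately inside a window; equal-MAF ties remove the
SNP at the larger position; SNPs absent from the panel (or with constant
dosages, where r is undefined) are retained unconditionally and their pairs
skipped.  All are deterministic — pruning involves no randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ReferencePanel

log = logging.getLogger(__name__)


class ConstantGenotypeError(ValueError):
    """Correlation requested for a constant dosage vector."""


@dataclass(frozen=True)
class PruneParams:
    """window: SNPs per window; step: SNPs to slide; r2_threshold: exclusion cutoff."""

    window: int = 50
    step: int = 5
    r2_threshold: float = 0.2

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not (1 <= self.step <= self.window):
            raise ValueError("step must satisfy 1 <= step <= window")
        if not (0.0 < self.r2_threshold < 1.0):
            raise ValueError("r2_threshold must be in (0, 1)")


def compute_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Raises :class:`ConstantGenotypeError` when either vector is constant
    (callers treat such pairs as unlinked and log them).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or len(g1) < 2:
        raise ValueError("dosage vectors must be 1-D, equal length >= 2")
    d1 = g1 - g1.mean()
    d2 = g2 - g2.mean()
    n1 = np.sqrt((d1 * d1).sum())
    n2 = np.sqrt((d2 * d2).sum())
    if n1 == 0.0 or n2 == 0.0:
        raise ConstantGenotypeError("correlation undefined for constant dosages")
    r = float((d1 * d2).sum() / (n1 * n2))
    return min(r * r, 1.0)


def _standardized_rows(dosages: np.ndarray):
    """Rows centered and scaled to unit norm; returns (Z, valid mask).

    With unit-norm rows, r between two SNPs is simply the row dot product.
    """
    d = dosages.astype(np.float64)
    d -= d.mean(axis=1, keepdims=True)
    norms = np.sqrt((d * d).sum(axis=1))
    valid = norms > 0
    d[valid] /= norms[valid, None]
    d[~valid] = 0.0
    return d, valid


class _ChromView:
    """Per-chromosome working state: panel rows aligned to the merged SNPs."""

    def __init__(self, sub: pd.DataFrame, panel: ReferencePanel, panel_index: dict):
        self.ids = sub["snp_id"].to_numpy()
        self.pos = sub["pos"].to_numpy()
        rows = np.array([panel_index.get(s, -1) for s in self.ids])
        self.in_panel = rows >= 0
        n_samples = panel.n_samples
        dos = np.zeros((len(self.ids), n_samples), dtype=np.float64)
        dos[self.in_panel] = panel.dosages[rows[self.in_panel]]
        self.z, nonconst = _standardized_rows(dos)
        # usable for LD: present in panel and non-constant
        self.usable = self.in_panel & nonconst
        self.maf = np.full(len(self.ids), np.nan)
        self.maf[self.in_panel] = panel.maf[rows[self.in_panel]]

    def r2(self, i: int, j: int) -> float:
        r = float(self.z[i] @ self.z[j])
        return min(r * r, 1.0)


def _prune_window(view: _ChromView, win: list, alive: np.ndarray,
                  params: PruneParams, removals: list) -> bool:
    """Greedy pass over one window; mutates ``alive``; True if removed any."""
    changed = False
    for a_idx in range(len(win)):
        i = win[a_idx]
        if not alive[i]:
            continue
        for b_idx in range(a_idx + 1, len(win)):
            j = win[b_idx]
            if not alive[i]:
                break
            if not alive[j]:
                continue
            if not (view.usable[i] and view.usable[j]):
                continue
            r2 = view.r2(i, j)
            if r2 <= params.r2_threshold:
                continue
            mi, mj = view.maf[i], view.maf[j]
            if np.isnan(mi) or np.isnan(mj):
                # panel-less member: skip the pair (logged at summary level)
                continue
            if mi < mj:
                drop, keep = i, j
            elif mj < mi:
                drop, keep = j, i
            else:  # equal MAF: remove the larger position
                drop, keep = (j, i) if view.pos[j] > view.pos[i] else (i, j)
            alive[drop] = False
            removals.append((view.ids[drop], view.ids[keep], r2))
            changed = True
    return changed


def ld_prune(snps: pd.DataFrame, panel: ReferencePanel,
             params: PruneParams | None = None, return_log: bool = False):
    """Prune a (chrom, pos)-sorted merged table against a reference panel.

    Returns the surviving rows (order preserved); with ``return_log=True``
    also a removal log frame (``removed``, ``kept_because_of``, ``r2``).
    """
    params = params or PruneParams()
    panel_index = panel.row_index()
    keep_mask = np.ones(len(snps), dtype=bool)
    removals: list = []

    for _, sub in snps.groupby("chrom", sort=False):
        view = _ChromView(sub, panel, panel_index)
        n = len(view.ids)
        local_alive = np.ones(n, dtype=bool)
        n_no_panel = int((~view.in_panel).sum())
        if n_no_panel:
            log.info("chrom %s: %d SNPs absent from panel, retained unconditionally",
                     sub["chrom"].iloc[0], n_no_panel)
        while True:
            pass_changed = False
            order = np.flatnonzero(local_alive)  # survivors at pass start
            start = 0
            while start < len(order):
                win = [k for k in order[start:start + params.window] if local_alive[k]]
                if len(win) >= 2:
                    if _prune_window(view, win, local_alive, params, removals):
                        pass_changed = True
                start += params.step
            if not pass_changed:
                break
        keep_mask[sub.index.to_numpy()] = local_alive

    pruned = snps.loc[keep_mask].reset_index(drop=True)
    log.info("LD pruning: %d -> %d SNPs (%d removed)",
             len(snps), len(pruned), len(removals))
    if return_log:
        log_df = pd.DataFrame(removals, columns=["removed", "kept_because_of", "r2"])
        return pruned, log_df
    return pruned


def verify_pruned(snps: pd.DataFrame, panel: ReferencePanel,
                  params: PruneParams | None = None) -> bool:
    """True iff no pair of SNPs within any window-length run on one
    chromosome has r^2 above the threshold (pairs without usable panel
    genotypes are skipped, as in pruning)."""
    params = params or PruneParams()
    panel_index = panel.row_index()
    for _, sub in snps.groupby("chrom", sort=False):
        view = _ChromView(sub.reset_index(drop=True), panel, panel_index)
        n = len(view.ids)
        z = np.where(view.usable[:, None], view.z, 0.0)
        for lag in range(1, min(params.window, n)):
            r = np.einsum("ij,ij->i", z[:-lag], z[lag:])
            both = view.usable[:-lag] & view.usable[lag:]
            if (np.square(r)[both] > params.r2_threshold).any():
                return False
    return True
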