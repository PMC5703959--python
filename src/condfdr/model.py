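"""Model/results front end for the conditional-FDR analysis.

:class:`ConditionalFdr` is built from two harmonized GWAS summary-statistic
tables (plus an optional genotype reference panel for LD pruning);
``fit()`` runs pruning and both conditioning directions of the cFDR
estimator and returns a :class:`ConditionalFdrResults` carrying the
directional tables, the conjunction table, significance calls, a text
``summary()`` and the diagnostic curves/plots.

Typical use::

    model = ConditionalFdr.from_summary_stats(stats_bmi, stats_t2d, panel=panel)
    res = model.fit(alpha=0.05)
    print(res.summary())
    hits = res.significant("conjunction")
    res.plot_conditional_qq("qq.png")
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import cfdr as _cfdr
from . import enrichment as _enr
from . import io as _io
from . import pruning as _pruning

log = logging.getLogger(__name__)


class ConditionalFdr:
    """Pleiotropy-informed conditional FDR model for two traits.

    Parameters
    ----------
    merged
        Merged stats frame (``snp_id, chrom, pos, p1, p2``; p1 = trait A).
    panel
        Optional :class:`~condfdr.io.ReferencePanel` enabling LD pruning.
    trait_names
        Labels used in summaries, default ``("A", "B")``.
    """

    def __init__(self, merged: pd.DataFrame, panel: _io.ReferencePanel | None = None,
                 trait_names=("A", "B")):
        missing = [c for c in _io.MERGED_COLUMNS if c not in merged.columns]
        if missing:
            raise ValueError(f"merged table missing columns {missing}")
        if len(merged) == 0:
            raise _io.EmptyInputError("merged table is empty")
        self.merged = merged.reset_index(drop=True)
        self.panel = panel
        self.trait_names = tuple(trait_names)

    @classmethod
    def from_summary_stats(cls, a: pd.DataFrame, b: pd.DataFrame,
                           panel: _io.ReferencePanel | None = None,
                           trait_names=("A", "B")) -> "ConditionalFdr":
        """Build the model from two per-trait summary-stat frames."""
        return cls(_io.merge_common_snps(a, b), panel=panel, trait_names=trait_names)

    @classmethod
    def from_files(cls, path_a, path_b, panel_path=None,
                   column_map: dict | None = None,
                   trait_names=("A", "B")) -> "ConditionalFdr":
        """Build the model from summary-stat TSVs (and optional panel TSV)."""
        a = _io.read_summary_stats(path_a, column_map)
        b = _io.read_summary_stats(path_b, column_map)
        panel = _io.ReferencePanel.from_tsv(panel_path) if panel_path else None
        return cls.from_summary_stats(a, b, panel=panel, trait_names=trait_names)

    def fit(self, prune: bool | None = None,
            prune_params: _pruning.PruneParams | None = None,
            alpha: float = 0.05) -> "ConditionalFdrResults":
        """Run pruning (when a panel is available) and both cFDR directions.

        Parameters
        ----------
        prune
            Force pruning on/off; default prunes iff a panel was supplied.
            (Computing on the unpruned merged set is available for
            comparison by passing ``prune=False``.)
        prune_params
            Sliding-window parameters (default 50/5/0.2).
        alpha
            Significance level for the default calls (strict ``<``).
        """
        if prune is None:
            prune = self.panel is not None
        if prune and self.panel is None:
            raise ValueError("pruning requested but no reference panel supplied")
        prune_log = None
        if prune:
            prune_params = prune_params or _pruning.PruneParams()
            working, prune_log = _pruning.ld_prune(
                self.merged, self.panel, prune_params, return_log=True
            )
        else:
            working = self.merged
        table_ab = _cfdr.cfdr_estimate(working, "A|B")
        table_ba = _cfdr.cfdr_estimate(working, "B|A")
        conjunction = _cfdr.conjunction_fdr(table_ab, table_ba)
        return ConditionalFdrResults(
            model=self, working=working, prune_log=prune_log,
            table_ab=table_ab, table_ba=table_ba,
            conjunction=conjunction, alpha=alpha,
            prune_params=prune_params if prune else None,
        )


class ConditionalFdrResults:
    """Fitted conditional-FDR tables plus calls, diagnostics and plots."""

    def __init__(self, model, working, prune_log, table_ab, table_ba,
                 conjunction, alpha, prune_params):
        self.model = model
        self.working = working          #: SNP set the estimates were computed on
        self.prune_log = prune_log
        self.prune_params = prune_params
        self.table_ab = table_ab
        self.table_ba = table_ba
        self.conjunction = conjunction
        self.alpha = float(alpha)

    # -- calls --------------------------------------------------------------

    def significant(self, direction: str = "conjunction",
                    alpha: float | None = None) -> pd.DataFrame:
        """Significant SNPs for ``"A|B"``, ``"B|A"`` or ``"conjunction"``."""
        params = _cfdr.SignificanceParams(alpha if alpha is not None else self.alpha)
        if direction == "conjunction":
            return _cfdr.call_significant(self.conjunction, params, "conj_fdr")
        if direction == "A|B":
            return _cfdr.call_significant(self.table_ab, params, "cfdr")
        if direction == "B|A":
            return _cfdr.call_significant(self.table_ba, params, "cfdr")
        raise ValueError(f"unknown direction {direction!r}")

    # -- diagnostics --------------------------------------------------------

    def conditional_qq(self, trait: str = "A",
                       levels: _enr.ConditioningLevels | None = None):
        """Conditional Q-Q curves for one trait stratified by the other."""
        p_col, cond_col = ("p1", "p2") if trait == "A" else ("p2", "p1")
        return _enr.conditional_qq(self.working, levels, p_col=p_col, cond_col=cond_col)

    def fold_enrichment(self, trait: str = "A",
                        levels: _enr.ConditioningLevels | None = None,
                        grid=None) -> pd.DataFrame:
        p_col, cond_col = ("p1", "p2") if trait == "A" else ("p2", "p1")
        return _enr.fold_enrichment(self.working, levels, grid,
                                    p_col=p_col, cond_col=cond_col)

    def manhattan(self, direction: str = "conjunction",
                  alpha: float | None = None) -> _enr.ManhattanData:
        alpha = alpha if alpha is not None else self.alpha
        if direction == "conjunction":
            return _enr.manhattan_data(self.conjunction, "conj_fdr", alpha)
        table = self.table_ab if direction == "A|B" else self.table_ba
        return _enr.manhattan_data(table, "cfdr", alpha)

    def plot_conditional_qq(self, path, trait: str = "A", levels=None) -> None:
        _enr.plot_qq(self.conditional_qq(trait, levels), path)

    def plot_fold_enrichment(self, path, trait: str = "A", levels=None) -> None:
        _enr.plot_fold_enrichment(self.fold_enrichment(trait, levels), path)

    def plot_manhattan(self, path, direction: str = "conjunction",
                       alpha: float | None = None) -> None:
        _enr.plot_manhattan(self.manhattan(direction, alpha), path)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Text summary of stage sizes and significant-call counts."""
        a, b = self.model.trait_names
        n0 = len(self.model.merged)
        n1 = len(self.working)
        lines = [
            "Conditional FDR analysis",
            "=" * 44,
            f"traits                      : {a} (principal=p1), {b} (p2)",
            f"merged SNPs                 : {n0}",
            f"after LD pruning            : {n1}"
            + ("" if self.prune_params is None else
               f"  (window={self.prune_params.window},"
               f" step={self.prune_params.step},"
               f" r2>{self.prune_params.r2_threshold})"),
            f"alpha                       : {self.alpha:g}"
            f"  (-log10 line {-np.log10(self.alpha):.4f})",
            f"significant {a}|{b}             : {len(self.significant('A|B'))}",
            f"significant {b}|{a}             : {len(self.significant('B|A'))}",
            f"conjunction (both traits)   : {len(self.significant('conjunction'))}",
        ]
        return "\n".join(lines)

    def save_tables(self, outdir) -> dict:
        """Write the per-direction and conjunction tables as TSVs."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cfdr_a_given_b": outdir / "cfdr_a_given_b.tsv",
            "cfdr_b_given_a": outdir / "cfdr_b_given_a.tsv",
            "conjunction": outdir / "conjunction.tsv",
        }
        _io.write_results_table(self.table_ab, paths["cfdr_a_given_b"])
        _io.write_results_table(self.table_ba, paths["cfdr_b_given_a"])
        _io.write_results_table(self.conjunction, paths["conjunction"])
        return {k: str(v) for k, v in paths.items()}
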