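"""Per-SNP conditional FDR from paired GWAS p-values.

For SNP *i* with principal-trait p-value ``p1_i`` and conditioning-trait
p-value ``p2_i``, the conditional empirical cdf is

    ccdf_i = #{j : p1_j <= p1_i and p2_j <= p2_i} / #{j : p2_j <= p2_i}

with both counts self-inclusive (j = i counts, so no denominator is ever
zero) and ties counted inclusively on both sides.  The conditional FDR
estimate is then

    cfdr_i = min(1, p1_i / ccdf_i)

— the model-free empirical-cdf estimator: the observed p-value divided by
the fraction of SNPs, among those at least as associated with the
conditioning trait, that are at least as associated with the principal
trait.  When the conditioning trait is uninformative (all p2 equal) this
reduces to the usual Benjamini–Hochberg-style quantity ``p_i * N / rank_i``.
Because ``ccdf <= 1``, always ``cfdr_i >= p1_i``: conditioning can only make
the estimate smaller than the unconditional one through genuine enrichment,
and the estimator is conservative by construction.

The conjunction FDR — evidence of association with *both* traits — is the
maximum of the two directional cFDR values for a SNP.

Counting is done exactly (integer counts) in O(N log N) with a Fenwick tree
over p1-ranks, sweeping SNPs in order of p2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EmptyInputError

log = logging.getLogger(__name__)

DIRECTIONS = ("A|B", "B|A")


class AlignmentError(ValueError):
    """Two per-direction tables do not cover the same SNPs."""


@dataclass(frozen=True)
class SignificanceParams:
    """alpha: cFDR / conjunction-FDR significance threshold (strict <)."""

    alpha: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def _check_pvalues(p: np.ndarray, name: str) -> None:
    if len(p) == 0:
        raise EmptyInputError(f"{name}: empty p-value array")
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError(f"{name}: p-values must lie in (0, 1]")


class _Fenwick:
    """Binary indexed tree over ranks 1..n; prefix counts in O(log n)."""

    def __init__(self, n: int):
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def joint_counts(p1, p2):
    """Self-inclusive dominance counts for every SNP.

    Returns ``(n_cond, n_joint)`` integer arrays with
    ``n_cond[i] = #{j : p2[j] <= p2[i]}`` and
    ``n_joint[i] = #{j : p1[j] <= p1[i] and p2[j] <= p2[i]}``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p1 and p2 must have equal length")
    _check_pvalues(p1, "p1")
    _check_pvalues(p2, "p2")
    n = len(p1)

    # dense ranks of p1 (ties share a rank)
    _, r1 = np.unique(p1, return_inverse=True)
    n_ranks = int(r1.max()) + 1

    order = np.argsort(p2, kind="mergesort")
    n_cond = np.empty(n, dtype=np.int64)
    n_joint = np.empty(n, dtype=np.int64)
    bit = _Fenwick(n_ranks)

    start = 0
    p2_sorted = p2[order]
    while start < n:
        stop = start
        while stop < n and p2_sorted[stop] == p2_sorted[start]:
            stop += 1
        group = order[start:stop]
        for i in group:  # insert the whole p2-tie group before querying
            bit.add(int(r1[i]))
        for i in group:
            n_joint[i] = bit.prefix(int(r1[i]))
            n_cond[i] = stop
        start = stop
    return n_cond, n_joint


def conditional_cdf(p1, p2, i: int):
    """Counts and conditional empirical cdf for one SNP (direct O(N)).

    Returns ``(n_cond, n_joint, ccdf)`` for index ``i``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    _check_pvalues(p1, "p1")
    _check_pvalues(p2, "p2")
    in_cond = p2 <= p2[i]
    n_cond = int(in_cond.sum())
    n_joint = int((in_cond & (p1 <= p1[i])).sum())
    return n_cond, n_joint, n_joint / n_cond


def cfdr_estimate(merged: pd.DataFrame, direction: str = "A|B") -> pd.DataFrame:
    """Per-SNP cFDR table for one conditioning direction.

    Parameters
    ----------
    merged
        Merged stats frame (``snp_id, chrom, pos, p1, p2`` with p1 = trait A).
    direction
        ``"A|B"``: trait A is principal, conditioned on trait B.
        ``"B|A"``: roles swapped.

    Returns a frame with ``p1``/``p2`` in their *directional* roles
    (p1 = principal) plus ``n_cond``, ``n_joint``, ``ccdf`` and ``cfdr``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if merged is None or len(merged) == 0:
        raise EmptyInputError("cfdr_estimate: empty merged table")
    p_a = merged["p1"].to_numpy(float)
    p_b = merged["p2"].to_numpy(float)
    p1, p2 = (p_a, p_b) if direction == "A|B" else (p_b, p_a)
    n_cond, n_joint = joint_counts(p1, p2)
    ccdf = n_joint / n_cond
    cfdr = np.minimum(1.0, p1 * n_cond / n_joint)
    return pd.DataFrame(
        {
            "snp_id": merged["snp_id"].to_numpy(),
            "chrom": merged["chrom"].to_numpy(),
            "pos": merged["pos"].to_numpy(),
            "p1": p1,
            "p2": p2,
            "n_cond": n_cond,
            "n_joint": n_joint,
            "ccdf": ccdf,
            "cfdr": cfdr,
        }
    )


def conjunction_fdr(table_ab: pd.DataFrame, table_ba: pd.DataFrame) -> pd.DataFrame:
    """Combine the two directional tables into a conjunction-FDR table.

    ``conj_fdr_i = max(cfdr_i[A|B], cfdr_i[B|A])`` — significance requires
    the association to survive conditioning in *both* directions.  Output
    columns ``p1``/``p2`` are trait A's / trait B's p-values.
    """
    ids_ab = set(table_ab["snp_id"])
    ids_ba = set(table_ba["snp_id"])
    if ids_ab != ids_ba:
        offending = sorted(ids_ab.symmetric_difference(ids_ba))
        raise AlignmentError(
            f"directional tables cover different SNPs ({len(offending)} mismatched, "
            f"e.g. {offending[:5]})"
        )
    ba = table_ba.set_index("snp_id").loc[table_ab["snp_id"]]
    out = pd.DataFrame(
        {
            "snp_id": table_ab["snp_id"].to_numpy(),
            "chrom": table_ab["chrom"].to_numpy(),
            "pos": table_ab["pos"].to_numpy(),
            "p1": table_ab["p1"].to_numpy(),
            "p2": table_ab["p2"].to_numpy(),
            "cfdr_ab": table_ab["cfdr"].to_numpy(),
            "cfdr_ba": ba["cfdr"].to_numpy(),
        }
    )
    out["conj_fdr"] = np.maximum(out["cfdr_ab"], out["cfdr_ba"])
    return out


def call_significant(table: pd.DataFrame,
                     params: SignificanceParams | None = None,
                     field: str = "cfdr") -> pd.DataFrame:
    """Rows with ``field`` strictly below alpha, sorted ascending by it."""
    params = params or SignificanceParams()
    if field not in table.columns:
        raise ValueError(f"field {field!r} not present in table")
    hits = table.loc[table[field] < params.alpha]
    return hits.sort_values(field, kind="mergesort").reset_index(drop=True)
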