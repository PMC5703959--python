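"""Readers, writers and harmonization for GWAS summary statistics.

Tabular data is carried in plain :class:`pandas.DataFrame` objects with
canonical column names rather than bespoke containers:

``summary stats``
    columns ``snp_id`` (str, unique), ``chrom`` (str, no ``chr`` prefix),
    ``pos`` (int, 1-based), ``pvalue`` (float in (0, 1]) and optionally
    ``maf`` (float in (0, 0.5]).  Rows sorted by (chrom, pos).

``merged stats``
    columns ``snp_id``, ``chrom``, ``pos``, ``p1`` (principal trait, "A"),
    ``p2`` (conditioning trait, "B"); the inner join of two summary-stat
    tables on ``snp_id``.  This is the unit of all cFDR computation.

The reference genotype panel, used only for LD pruning, is the
:class:`ReferencePanel` dataclass (dosage matrix plus derived MAF).

Allele harmonization (strand flips, effect-allele alignment) is deliberately
not performed: the cFDR method consumes p-values only, which are invariant to
allele orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: p-values of exactly 0 (seen in downloaded summary files) are clamped here;
#: the estimator needs p strictly positive.
P_FLOOR = 1e-300

#: default logical -> physical column names for summary-statistic files
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "pvalue": "P",
    "maf": "MAF",
}

SUMMARY_COLUMNS = ["snp_id", "chrom", "pos", "pvalue"]
MERGED_COLUMNS = ["snp_id", "chrom", "pos", "p1", "p2"]


class ConfigurationError(ValueError):
    """A column mapping or parameter set does not match the data."""


class EmptyInputError(ValueError):
    """An operation received (or produced) zero usable rows."""


def normalize_chrom(values) -> pd.Series:
    """Chromosome labels as strings with any leading ``chr`` stripped."""
    s = pd.Series(values).astype(str).str.strip()
    return s.str.replace(r"^chr", "", regex=True, case=False)


def _chrom_rank(chrom: pd.Series) -> pd.Series:
    """Sortable rank: numeric chromosomes first in numeric order, rest lexical."""
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(np.inf)


def sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    """Sort a table by (chrom, pos) with numeric chromosome ordering."""
    key = _chrom_rank(df["chrom"])
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def validate_summary_stats(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a summary-stats frame violates its contract."""
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()[:5]
        raise ValueError(f"duplicate snp_id values, e.g. {dups}")
    p = df["pvalue"].to_numpy(float)
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("pvalue outside (0, 1]")
    if (df["pos"].to_numpy() <= 0).any():
        raise ValueError("non-positive base-pair position")


def read_summary_stats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate one trait's GWAS summary-statistic table.

    Parameters
    ----------
    path
        Whitespace/tab-delimited file with a header line.
    column_map
        Mapping of logical names (``snp_id``, ``chrom``, ``pos``, ``pvalue``,
        optionally ``maf``) to the physical column names in the file.  Keys
        omitted fall back to :data:`DEFAULT_COLUMN_MAP`.

    Rules applied while loading: p = 0 is clamped to :data:`P_FLOOR` and the
    row kept (with a warning); rows with non-numeric p, p < 0 or p > 1 are
    dropped (count logged); duplicate SNP ids keep the first occurrence; rows
    are sorted by (chrom, pos).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    # canonical logical names in the header are accepted as-is unless the
    # caller explicitly mapped that column elsewhere
    for logical in DEFAULT_COLUMN_MAP:
        explicit = column_map and logical in column_map
        if not explicit and cmap[logical] not in raw.columns and logical in raw.columns:
            cmap[logical] = logical
    required = {k: cmap[k] for k in ("snp_id", "chrom", "pos", "pvalue")}
    missing = [phys for phys in required.values() if phys not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped columns {missing} not found in header {list(raw.columns)}"
        )
    df = pd.DataFrame(
        {
            "snp_id": raw[cmap["snp_id"]].astype(str),
            "chrom": normalize_chrom(raw[cmap["chrom"]]),
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "pvalue": pd.to_numeric(raw[cmap["pvalue"]], errors="coerce"),
        }
    )
    if cmap.get("maf") in raw.columns:
        df["maf"] = pd.to_numeric(raw[cmap["maf"]], errors="coerce")

    n_zero = int((df["pvalue"] == 0).sum())
    if n_zero:
        log.warning("%s: clamped %d zero p-values to %.0e", path, n_zero, P_FLOOR)
        df.loc[df["pvalue"] == 0, "pvalue"] = P_FLOOR

    ok = (
        df["pvalue"].notna()
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & df["pos"].notna()
        & (df["pos"] > 0)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("%s: dropped %d rows with invalid p-value or position", path, n_dropped)
    df = df.loc[ok].copy()

    n_dup = int(df["snp_id"].duplicated().sum())
    if n_dup:
        log.warning("%s: dropped %d duplicate snp_id rows (kept first)", path, n_dup)
        df = df.loc[~df["snp_id"].duplicated()].copy()

    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after filtering")

    df["pos"] = df["pos"].astype(np.int64)
    df = sort_by_position(df)
    validate_summary_stats(df)
    return df


def merge_common_snps(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two summary-stat tables on ``snp_id``.

    Positions and chromosomes are taken from table ``a``; ``p1`` is trait A's
    p-value, ``p2`` trait B's.  Raises :class:`EmptyInputError` when the id
    sets are disjoint.
    """
    validate_summary_stats(a)
    validate_summary_stats(b)
    merged = a[["snp_id", "chrom", "pos", "pvalue"]].merge(
        b[["snp_id", "pvalue"]], on="snp_id", suffixes=("_a", "_b")
    )
    if merged.empty:
        raise EmptyInputError("no SNP ids common to the two summary-statistic tables")
    merged = merged.rename(columns={"pvalue_a": "p1", "pvalue_b": "p2"})
    log.info(
        "merged %d + %d SNPs -> %d common", len(a), len(b), len(merged)
    )
    return sort_by_position(merged)


def write_results_table(table: pd.DataFrame, path) -> None:
    """Write a results table (cFDR/conjunction) as TSV at full float precision.

    17 significant digits round-trip IEEE doubles bit-identically.
    """
    if table is None or len(table) == 0:
        raise EmptyInputError("refusing to write an empty results table")
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# reference genotype panel


@dataclass
class ReferencePanel:
    """Genotype dosage panel used only for LD pruning.

    Parameters
    ----------
    snp_id, chrom, pos
        Per-SNP identifiers and coordinates (parallel arrays).
    dosages
        ``(n_snps, n_samples)`` integer matrix with entries in {0, 1, 2}
        (minor-allele dosage per sample).

    The per-SNP minor allele frequency is derived from the dosages:
    ``maf = min(f, 1 - f)`` with ``f = mean(dosages) / 2``.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    maf: np.ndarray = field(init=False)

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.snp_id):
            raise ValueError("dosages must be (n_snps, n_samples)")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosage entries must be 0, 1 or 2")
        f = self.dosages.mean(axis=1) / 2.0
        self.maf = np.minimum(f, 1.0 - f)

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def row_index(self) -> dict:
        """Map snp_id -> row number."""
        return {s: i for i, s in enumerate(self.snp_id)}

    def to_tsv(self, path) -> None:
        """Write as TSV: snp_id, chrom, pos, then one dosage column per sample."""
        cols = {"snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos}
        for j in range(self.n_samples):
            cols[f"s{j}"] = self.dosages[:, j]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferencePanel":
        """Read the panel format written by :meth:`to_tsv`.

        Contract for external exporters: a header-bearing TSV whose first
        three columns are ``snp_id``, ``chrom``, ``pos`` and whose remaining
        columns are per-sample dosages in {0, 1, 2}.
        """
        df = pd.read_csv(path, sep="\t")
        for c in ("snp_id", "chrom", "pos"):
            if c not in df.columns:
                raise ConfigurationError(f"panel file {path} lacks column {c!r}")
        sample_cols = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
        if not sample_cols:
            raise ConfigurationError(f"panel file {path} has no dosage columns")
        return cls(
            snp_id=df["snp_id"].astype(str).to_numpy(),
            chrom=normalize_chrom(df["chrom"]).to_numpy(),
            pos=df["pos"].to_numpy(),
            dosages=df[sample_cols].to_numpy(dtype=np.int8),
        )


def read_gene_intervals(path) -> pd.DataFrame:
    """Read a 4-column BED-like gene table: chrom, start, end, gene_name.

    BED input is 0-based half-open; the returned frame is 1-based inclusive
    (``start`` incremented), sorted by (chrom, start).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_name"],
        dtype={"chrom": str, "gene_name": str},
    )
    df["chrom"] = normalize_chrom(df["chrom"])
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] > df["end"]).any():
        raise ValueError("gene interval with start > end after 1-based conversion")
    key = _chrom_rank(df["chrom"])
    order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)
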