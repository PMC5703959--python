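"""SNP-to-gene assignment by interval logic.

A SNP inside one or more gene intervals is ``within_gene`` and reports the
smallest enclosing interval (alphabetical on ties); otherwise it is
``intergenic`` and reports up to two flanking genes (nearest upstream and
nearest downstream within ``flank_limit``), nearer first.  Distances are
measured from the SNP position to the nearest interval edge on 1-based
inclusive coordinates.  Sub-genic roles (intronic/UTR/ncRNA) need transcript
models and are out of scope here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _annotate_one(pos: int, starts, ends, names, flank_limit: int):
    inside = (starts <= pos) & (pos <= ends)
    if inside.any():
        widths = ends[inside] - starts[inside]
        cand = sorted(zip(widths, names[inside]))  # smallest, then alphabetical
        return "within_gene", [cand[0][1]]
    genes = []
    left = np.flatnonzero(ends < pos)
    if left.size:
        d = pos - ends[left]
        best = d.min()
        if best <= flank_limit:
            tied = sorted(names[left[d == best]])
            genes.append((int(best), tied[0]))
    right = np.flatnonzero(starts > pos)
    if right.size:
        d = starts[right] - pos
        best = d.min()
        if best <= flank_limit:
            tied = sorted(names[right[d == best]])
            genes.append((int(best), tied[0]))
    genes.sort()  # nearer first; distance ties resolve alphabetically
    return "intergenic", [g for _, g in genes]


def annotate_snps(snps: pd.DataFrame, genes: pd.DataFrame,
                  flank_limit: int = 1_000_000) -> pd.DataFrame:
    """Annotate each SNP with a role and gene list.

    Parameters
    ----------
    snps
        Frame with ``snp_id``, ``chrom``, ``pos`` (merged stats or a cFDR
        table).
    genes
        Gene-interval frame (``gene_name, chrom, start, end``; 1-based
        inclusive, as returned by :func:`condfdr.io.read_gene_intervals`).
    flank_limit
        Maximum distance (bp) at which a flanking gene is still reported.

    Returns a frame with ``snp_id``, ``role`` and ``genes`` (a
    comma-joined string, empty when no gene is within reach).  SNPs on
    chromosomes absent from the gene table get an empty annotation (logged).
    """
    if flank_limit <= 0:
        raise ValueError("flank_limit must be positive")
    by_chrom = {
        c: (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["gene_name"].to_numpy(object),
        )
        for c, sub in genes.groupby("chrom", sort=False)
    }
    missing_chroms = set()
    records = []
    for snp_id, chrom, pos in zip(snps["snp_id"], snps["chrom"], snps["pos"]):
        entry = by_chrom.get(str(chrom))
        if entry is None:
            missing_chroms.add(str(chrom))
            records.append((snp_id, "intergenic", ""))
            continue
        starts, ends, names = entry
        role, gene_list = _annotate_one(int(pos), starts, ends, names, flank_limit)
        records.append((snp_id, role, ",".join(gene_list)))
    if missing_chroms:
        log.warning("no gene intervals on chromosome(s) %s; empty annotations",
                    sorted(missing_chroms))
    return pd.DataFrame(records, columns=["snp_id", "role", "genes"])
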