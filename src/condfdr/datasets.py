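"""Bundled reference data.

:func:`load_pleiotropic_loci` returns the published reference table of 23
pleiotropic loci jointly associated with BMI (trait A) and type 2 diabetes
(trait B) from a conditional-FDR analysis of the GIANT BMI and trans-ethnic
T2D GWAS meta-analyses.  It carries, per locus, the nominal p-values in each
trait, the two directional cFDR estimates and the published conjunction FDR,
and serves as the package's worked example and as a fixed regression surface
for the conjunction arithmetic (``conj_fdr = max(cfdr_ab, cfdr_ba)`` and the
conservativeness identity ``cfdr >= p``).
"""

from __future__ import annotations

import io as _io

import pandas as pd

_PLEIOTROPIC_LOCI_TSV = """\
snp_id\trole\tgenes\tchrom\tp_a\tp_b\tcfdr_ab\tcfdr_ba\tconj_fdr
rs9930506\tintronic\tFTO\t16\t2.52E-124\t1.90E-10\t1.01E-123\t1.90E-10\t1.90E-10
rs10787472\tintronic\tTCF7L2\t10\t3.25E-07\t1.30E-36\t3.25E-07\t6.63E-35\t3.25E-07
rs2881654\tintronic\tPPARG\t3\t1.40E-06\t3.40E-09\t4.19E-06\t7.82E-08\t4.19E-06
rs849135\tintronic\tJAZF1\t7\t1.45E-05\t1.70E-09\t3.85E-05\t7.08E-08\t3.85E-05
rs4481184\tintronic\tIGF2BP2\t3\t0.0002524\t4.50E-22\t0.0003786\t6.55E-20\t0.0003786
rs7141420\tintronic\tNRXN3\t14\t8.66E-15\t0.00025\t4.68E-13\t0.001125\t0.001125
rs6795735\tncRNA_intronic\tADAMTS9-AS2\t3\t2.92E-05\t2.00E-04\t0.000555\t0.00604\t0.00604
rs12895330\tintergenic\tAKAP6,NPAS3\t14\t9.72E-05\t0.00021\t0.0016041\t0.007245\t0.007245
rs2334255\tUTR3\tGIPR\t19\t0.0008051\t0.00034\t0.0114503\t0.0176422\t0.0176422
rs1783598\tintronic\tFCHSD2\t11\t0.0003666\t0.00052\t0.0064359\t0.0193556\t0.0193556
rs12245680\tintronic\tTCF7L2\t10\t0.01444\t1.10E-09\t0.02527\t6.70E-07\t0.02527
rs17584208\tintergenic\tPSRC1,MYBPHL\t1\t4.58E-06\t0.0016\t0.000306\t0.02976\t0.02976
rs2488071\tintergenic\tHHEX,EXOC6\t10\t0.006642\t4.70E-06\t0.032103\t0.0011194\t0.032103
rs11979110\tintergenic\tKLF14,MIR29A\t7\t0.00288\t9.70E-05\t0.03456\t0.0140973\t0.03456
rs1473\tintronic\tPUM1\t1\t0.0004889\t0.00092\t0.0114403\t0.03542\t0.03542
rs10898868\tintronic\tARAP1\t11\t0.002589\t0.00044\t0.0370227\t0.03608\t0.0370227
rs1996023\tintergenic\tGNPDA2,GABRG1\t4\t1.11E-20\t0.025\t1.93E-17\t0.0375\t0.0375
rs825461\tintronic\tZNF664,FAM101A\t12\t0.0003917\t0.0013\t0.0114376\t0.04472\t0.04472
rs16945088\tintronic\tFTO\t16\t5.30E-09\t0.0072\t1.48E-06\t0.045\t0.045
rs9540493\tintergenic\tLOC10272396,LINC01052\t13\t3.95E-09\t0.0057\t1.22E-06\t0.0456\t0.0456
rs4238585\tintergenic\tGPR139,GP2\t16\t1.12E-08\t0.0069\t3.02E-06\t0.0483\t0.0483
rs12454712\tintronic\tBCL2\t18\t6.04E-06\t0.0034\t0.0004955\t0.0485714\t0.0485714
rs4474658\tintergenic\tC2CD4A,C2CD4B\t15\t0.009024\t9.60E-06\t0.0489874\t0.0023849\t0.0489874
"""


def load_pleiotropic_loci() -> pd.DataFrame:
    """The 23 published BMI/T2D pleiotropic loci.

    Columns: ``snp_id``, ``role`` (published sub-genic role), ``genes``,
    ``chrom``, ``p_a`` (BMI p-value), ``p_b`` (T2D p-value), ``cfdr_ab``
    (BMI conditioned on T2D), ``cfdr_ba`` (T2D conditioned on BMI) and the
    published ``conj_fdr``.
    """
    return pd.read_csv(
        _io.StringIO(_PLEIOTROPIC_LOCI_TSV),
        sep="\t",
        dtype={"chrom": str},
    )
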