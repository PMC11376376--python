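"""Small bundled reference tables.

The structural-polymorphism survey around the maize *PIP2;5* locus lists,
for 14 panel accessions plus the common tester UH007, the lead-SNP allele of
the local eQTL (dosage of the B73-like allele), the presence/absence of the
promoter MITE-containing indel (457 bp), the last-intron indel (235 bp), the
large upstream indel (~6 kb; "partial" where only part is conserved), the
putative splice-site variant, and the accession's measured log2 relative
expression in the leaf mature zone. It is the worked example for
haplotype-concordance analysis: across the homozygous accessions the MITE
indel segregates with the low-expression haplotype except in B100.
"""
from __future__ import annotations

import pandas as pd

_PIP25_ROWS = [
    # accession, expr MZ, lead allele, MITE indel, intron indel, large indel, splice variant
    ("PHK76", -5.31, 0, "+", "+", "-", "+"),
    ("NC358", -5.16, 0, "+", "-", "-", "+"),
    ("MS71", -4.66, 0, "+", "+", "-", "+"),
    ("F894", -4.39, 0, "+", "+", "-", "+"),
    ("PH207", -3.89, 0, "+", "+", "-", "+"),
    ("Mo17", -3.51, 0, "+", "+", "-", "+"),
    ("B100", -1.59, 0, "-", "-", "-", "+"),
    ("A374", -1.45, 0, "+", "+", "-", "+"),
    ("B97", -1.20, 1, "+", "+", "-", "+"),
    ("EP52", -1.26, 2, "-", "+", "+", "+"),
    ("F98902", -0.39, 2, "-", "-", "+", "-"),
    ("B104", 0.24, 2, "-", "-", "+", "-"),
    ("Oh43", 0.43, 2, "-", "-", "partial", "+"),
    ("B73", 0.70, 2, "-", "-", "+", "-"),
    ("UH007", None, 2, "-", "-", "partial", None),
]


def pip25_structural_survey() -> pd.DataFrame:
    """Published survey of structural polymorphisms around maize *PIP2;5*.

    Indexed by accession, with columns ``expression_mz`` (log2 relative
    expression, leaf mature zone; NaN where unmeasured), ``lead_allele``
    (dosage 0/1/2 at the local-eQTL lead SNP, counting the B73-like allele),
    and presence/absence strings for ``mite_indel``, ``intron_indel``,
    ``large_indel`` and ``splice_variant``.
    """
    df = pd.DataFrame(
        _PIP25_ROWS,
        columns=[
            "accession",
            "expression_mz",
            "lead_allele",
            "mite_indel",
            "intron_indel",
            "large_indel",
            "splice_variant",
        ],
    ).set_index("accession")
    df["expression_mz"] = df["expression_mz"].astype(float)
    return df
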