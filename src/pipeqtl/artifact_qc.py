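"""Detection and correction of qPCR-specific mapping artifacts.

Two mechanisms can fake an eQTL when expression is measured by RT-qPCR:

* a *reference-gene eQTL* — a genetic effect on an endogenous control gene
  propagates, through the delta-Ct normalization, into every target trait as
  a spurious association at the reference-gene locus;
* a *primer-site polymorphism* — an allele under a primer binding site
  perturbs amplification in carrier lines, shifting their apparent
  expression and creating a spurious local eQTL at the target gene.

QC never edits association statistics; it only changes inputs (the reference
set, the covariate list, or the line mask) so corrected scans are reproducible
from the logged configuration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import GeneModel, GenotypeMatrix
from .eqtl_windows import EQTL
from .exceptions import ConfigurationError
from . import expression_quant

logger = logging.getLogger(__name__)

ACTIONS = ("renormalize_without", "covariate_adjust", "none")


@dataclass
class ReferenceGeneCheck:
    """Overlap report between one reference gene and one trait's eQTLs."""

    reference_gene: str
    gene_model: GeneModel
    trait: str
    overlapping_eqtls: list = field(default_factory=list)
    flagged_lead: Optional[str] = None
    recommended_action: str = "none"

    @property
    def flagged(self) -> bool:
        return bool(self.overlapping_eqtls)


def check_reference_gene_eqtl(
    eqtls_by_trait: dict,
    reference_gene_models: Sequence[GeneModel],
    default_action: str = "covariate_adjust",
) -> list[ReferenceGeneCheck]:
    """Flag eQTLs whose interval overlaps a reference gene's transcribed region.

    Returns one check per (reference gene, trait); a flagged check carries
    the overlapping eQTLs, the lead SNP of the strongest one, and the
    recommended correction (covariate adjustment by default, which keeps the
    expression data consistent across traits; renormalization without the
    contaminated reference is the alternative).
    """
    if default_action not in ACTIONS:
        raise ConfigurationError(f"default_action: must be one of {ACTIONS}")
    checks = []
    for gm in reference_gene_models:
        for trait, eqtls in eqtls_by_trait.items():
            hits = [
                q
                for q in eqtls
                if str(q.chrom) == str(gm.chrom) and q.start <= gm.end and gm.start <= q.end
            ]
            check = ReferenceGeneCheck(
                reference_gene=gm.gene_id, gene_model=gm, trait=trait
            )
            if hits:
                strongest = max(hits, key=lambda q: q.lead["logp"])
                check.overlapping_eqtls = hits
                check.flagged_lead = str(strongest.lead["marker"])
                check.recommended_action = default_action
                logger.warning(
                    "trait %s: eQTL %s overlaps reference gene %s (lead %s, logp %.2f)",
                    trait, strongest.eqtl_id, gm.gene_id, check.flagged_lead,
                    strongest.lead["logp"],
                )
            checks.append(check)
    return checks


def renormalize_excluding_reference(
    ct: pd.DataFrame, reference_genes: Sequence[str], drop: str
) -> pd.DataFrame:
    """Recompute relative expression without one contaminated reference gene."""
    reference_genes = list(reference_genes)
    if drop not in reference_genes:
        raise ConfigurationError(f"drop: {drop!r} is not one of the reference genes")
    remaining = [g for g in reference_genes if g != drop]
    if not remaining:
        raise ConfigurationError("drop: cannot remove the last reference gene")
    return expression_quant.relative_expression(ct, remaining)


@dataclass
class PrimerSiteCheck:
    """Genotyped polymorphisms inside a target gene's primer intervals."""

    target_gene: str
    intervals: list  # (chrom, start, end) 1-based inclusive
    markers: list
    favorable_allele: dict  # marker -> homozygous dosage class retained
    carrier_lines: list  # unfavorable homozygotes
    het_lines: list
    missing_lines: list

    @property
    def polymorphic(self) -> bool:
        return bool(self.markers)


def primer_polymorphism_filter(
    genotypes: GenotypeMatrix,
    primer_intervals: dict,
    favorable_allele: Optional[dict] = None,
) -> tuple[list[PrimerSiteCheck], pd.Series]:
    """Partition lines by their genotype under qPCR primer sites.

    ``primer_intervals`` maps a target gene to its primer intervals
    ``(chrom, start, end)`` in genome coordinates. For every marker found
    inside an interval, lines split into favorable homozygotes (kept),
    unfavorable homozygotes and heterozygotes (masked out). The favorable
    class defaults to the majority homozygote and can be forced per marker
    via ``favorable_allele``. Returns the checks and a boolean keep-mask
    indexed by line; with no polymorphism under any primer the mask retains
    all lines and a notice is logged.
    """
    favorable_allele = dict(favorable_allele or {})
    mask = pd.Series(True, index=genotypes.lines, name="keep")
    checks = []
    markers = genotypes.markers
    for gene, intervals in primer_intervals.items():
        hit_cols: list[int] = []
        for chrom, start, end in intervals:
            inside = (
                (markers["chrom"].astype(str) == str(chrom))
                & (markers["pos"] >= start)
                & (markers["pos"] <= end)
            )
            hit_cols.extend(np.flatnonzero(inside.to_numpy()))
        hit_ids = [markers["marker"].iloc[j] for j in sorted(set(hit_cols))]
        fav: dict = {}
        carriers: set = set()
        hets: set = set()
        missing: set = set()
        for mid in hit_ids:
            dos = pd.Series(genotypes.dosage(mid), index=genotypes.lines)
            n0 = int((dos == 0).sum())
            n2 = int((dos == 2).sum())
            keep_class = favorable_allele.get(mid, 0 if n0 >= n2 else 2)
            fav[mid] = keep_class
            carriers |= set(dos.index[dos == (2 - keep_class)])
            hets |= set(dos.index[dos == 1])
            missing |= set(dos.index[dos.isna()])
        check = PrimerSiteCheck(
            target_gene=gene,
            intervals=list(intervals),
            markers=hit_ids,
            favorable_allele=fav,
            carrier_lines=sorted(carriers),
            het_lines=sorted(hets),
            missing_lines=sorted(missing),
        )
        if not hit_ids:
            logger.info("no genotyped polymorphism under the primers of %s; full panel retained", gene)
        else:
            drop = carriers | hets | missing
            mask[mask.index.isin(drop)] = False
        checks.append(check)
    return checks, mask
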