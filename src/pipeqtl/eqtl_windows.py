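"""Kinship-corrected LD windows and eQTL definition.

Raw genotype correlation overstates linkage in a structured panel: related
lines share alleles genome-wide. The r2K statistic is the squared Pearson
correlation of two dosage vectors after whitening by K^(-1/2), i.e. LD
corrected for cryptic relatedness. Each significant SNP gets an LD window by
scanning outward until the correction stays below threshold; significant
SNPs with overlapping windows form one eQTL whose interval is the union of
the member windows, led by its most significant SNP (ties broken by smallest
physical position). An eQTL is "local" when the trait's transcribed gene
interval lies entirely within its borders, "distant" otherwise — terms
deliberately agnostic to cis/trans mechanism.

Coordinates are 1-based inclusive throughout; interval overlap at a single
shared bp counts as overlap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import GeneModel, GenotypeMatrix
from .exceptions import ConfigurationError, DesignError, EstimationError

logger = logging.getLogger(__name__)


@dataclass
class LDParams:
    """Window-scan parameters."""

    r2k_threshold: float = 0.1
    scan_radius_bp: int = 2_000_000
    min_run: int = 3  # consecutive sub-threshold markers that end a window

    def __post_init__(self) -> None:
        if not (0.0 < self.r2k_threshold < 1.0):
            raise ConfigurationError("r2k_threshold: must lie in (0, 1)")
        if self.scan_radius_bp <= 0:
            raise ConfigurationError("scan_radius_bp: must be positive")
        if self.min_run < 1:
            raise ConfigurationError("min_run: must be >= 1")


@dataclass(frozen=True)
class LDWindow:
    focal_marker: str
    chrom: object
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError("LDWindow: start > end")


@dataclass
class EQTL:
    """A merged cluster of significant SNPs with overlapping LD windows."""

    eqtl_id: str
    trait: str
    chrom: object
    start: int
    end: int
    members: list
    lead: pd.Series  # association record of the lead SNP
    is_local: bool = False
    genes_overlapped: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.members)


class KinshipWhitener:
    """Whitening transform K^(-1/2) with an eigenvalue floor.

    Correlations are computed between whitened vectors after projecting out
    the whitened intercept (the GLS analogue of mean-centering), so with
    K = I the statistic is exactly the classical squared Pearson correlation.
    """

    def __init__(self, kinship: np.ndarray, floor: float = 1e-6):
        k = (kinship + kinship.T) / 2.0
        lam, u = np.linalg.eigh(k)
        # clip tiny negatives, then lift the whole spectrum by the floor:
        # equivalent to whitening by (K + eps I)^(-1/2)
        lam = np.maximum(lam, 0.0) + floor * max(float(lam[-1]), 1.0)
        self.w = (u * (1.0 / np.sqrt(lam))) @ u.T
        one = self.w @ np.ones(kinship.shape[0])
        self._q1 = one / np.linalg.norm(one)

    def whiten_center(self, x: np.ndarray) -> np.ndarray:
        wx = self.w @ x
        return wx - self._q1 * (self._q1 @ wx)


def _impute(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float).copy()
    m = np.isnan(x)
    if m.any():
        x[m] = np.nanmean(x) if not m.all() else 0.0
    return x


def kinship_corrected_r2(
    a: np.ndarray,
    b: np.ndarray,
    kinship: Optional[np.ndarray] = None,
    whitener: Optional[KinshipWhitener] = None,
) -> float:
    """Squared dosage correlation corrected for relatedness (r2K), in [0, 1].

    With ``kinship=None`` (or the identity) this is the classical squared
    Pearson correlation. Returns NaN when either vector is constant after
    whitening.
    """
    a, b = _impute(a), _impute(b)
    if a.shape != b.shape:
        raise DesignError("r2K: dosage vectors must cover the same lines")
    if whitener is None and kinship is not None:
        whitener = KinshipWhitener(kinship)
    if whitener is None:
        ra, rb = a - a.mean(), b - b.mean()
    else:
        ra, rb = whitener.whiten_center(a), whitener.whiten_center(b)
    na, nb = np.linalg.norm(ra), np.linalg.norm(rb)
    if na <= 1e-12 or nb <= 1e-12:
        return float("nan")
    r = float(ra @ rb / (na * nb))
    return float(np.clip(r * r, 0.0, 1.0))


class WindowScanner:
    """Precomputed whitened dosages for fast per-SNP window scans."""

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        kinship: Optional[np.ndarray],
        params: LDParams = LDParams(),
    ):
        self.geno = genotypes
        self.params = params
        self.whitener = KinshipWhitener(kinship) if kinship is not None else None
        self._cache: dict = {}

    def _chrom_data(self, chrom):
        if chrom not in self._cache:
            cols = self.geno.markers_on(chrom)
            x = self.geno.imputed(cols)
            if self.whitener is not None:
                resid = np.column_stack([self.whitener.whiten_center(x[:, j]) for j in range(x.shape[1])])
            else:
                resid = x - x.mean(axis=0)
            norms = np.linalg.norm(resid, axis=0)
            self._cache[chrom] = (cols, self.geno.markers["pos"].to_numpy()[cols], resid, norms)
        return self._cache[chrom]

    def r2k_profile(self, focal_marker: str) -> tuple:
        """(positions, r2K against the focal marker, focal index) on its chromosome."""
        j = self.geno.marker_index(focal_marker)
        chrom = self.geno.markers["chrom"].iloc[j]
        cols, pos, resid, norms = self._chrom_data(chrom)
        local = int(np.searchsorted(cols, j))
        if norms[local] <= 1e-12:
            raise EstimationError(f"focal marker {focal_marker} is monomorphic")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (resid.T @ resid[:, local]) / (norms * norms[local])
        return pos, np.clip(r * r, 0.0, 1.0), local, chrom

    def window(self, focal_marker: str) -> LDWindow:
        pos, r2, local, chrom = self.r2k_profile(focal_marker)
        thr, radius, min_run = (
            self.params.r2k_threshold,
            self.params.scan_radius_bp,
            self.params.min_run,
        )

        def sweep(indices):
            last = local
            run = 0
            for j in indices:
                if abs(int(pos[j]) - int(pos[local])) > radius:
                    break
                if np.isfinite(r2[j]) and r2[j] >= thr:
                    last = j
                    run = 0
                else:
                    run += 1
                    if run >= min_run:
                        break
            return last

        right = sweep(range(local + 1, len(pos)))
        left = sweep(range(local - 1, -1, -1))
        return LDWindow(
            focal_marker=focal_marker,
            chrom=chrom,
            start=max(1, int(pos[left])),
            end=int(pos[right]),
        )


def ld_window(
    focal_marker: str,
    genotypes: GenotypeMatrix,
    kinship: Optional[np.ndarray],
    params: LDParams = LDParams(),
) -> LDWindow:
    """LD window of one marker (see :class:`WindowScanner` for batch use).

    Scanning outward within ``scan_radius_bp``, the window boundary on each
    side is the last marker with r2K >= threshold seen before ``min_run``
    consecutive markers fall below it; the window always contains the focal
    marker and never extends below position 1.
    """
    return WindowScanner(genotypes, kinship, params).window(focal_marker)


def group_eqtls(
    records: pd.DataFrame,
    windows: dict,
    gene: Optional[GeneModel],
    trait: str,
) -> list[EQTL]:
    """Merge significant SNPs with overlapping LD windows into eQTLs.

    ``records`` holds the significant association records (one per member
    SNP); ``windows`` maps marker id to its :class:`LDWindow`. Membership is
    the transitive closure of interval overlap on the same chromosome; the
    eQTL interval is the union of member windows; the lead SNP maximizes
    logp with ties broken by smallest position.
    """
    if records.empty:
        return []
    missing = [m for m in records["marker"] if m not in windows]
    if missing:
        raise ConfigurationError(f"no LD window supplied for markers {missing[:5]}")
    rows = records.assign(
        _start=[windows[m].start for m in records["marker"]],
        _end=[windows[m].end for m in records["marker"]],
    ).sort_values(["chrom", "_start", "_end"], kind="mergesort")

    eqtls: list[EQTL] = []
    cluster: list = []

    def flush(cluster_rows):
        block = pd.DataFrame(cluster_rows)
        lead = (
            block.sort_values(["logp", "pos"], ascending=[False, True], kind="mergesort")
            .iloc[0]
            .drop(labels=["_start", "_end"])
        )
        q = EQTL(
            eqtl_id=f"{trait}_Q{len(eqtls) + 1}",
            trait=trait,
            chrom=block["chrom"].iloc[0],
            start=int(block["_start"].min()),
            end=int(block["_end"].max()),
            members=list(block["marker"]),
            lead=lead,
        )
        if gene is not None:
            q.is_local = classify_local_distant(q, gene)
        eqtls.append(q)

    cur_chrom, cur_end = None, None
    for _, row in rows.iterrows():
        if cluster and row["chrom"] == cur_chrom and row["_start"] <= cur_end:
            cluster.append(row)
            cur_end = max(cur_end, row["_end"])
        else:
            if cluster:
                flush(cluster)
            cluster = [row]
            cur_chrom, cur_end = row["chrom"], row["_end"]
    if cluster:
        flush(cluster)
    return eqtls


def classify_local_distant(eqtl: EQTL, gene: GeneModel) -> bool:
    """True (local) iff the gene's transcribed interval is strictly contained
    within the eQTL interval on the same chromosome."""
    return (
        str(eqtl.chrom) == str(gene.chrom)
        and eqtl.start <= gene.start
        and gene.end <= eqtl.end
    )


def colocalize(eqtls_a: Sequence[EQTL], eqtls_b: Sequence[EQTL]) -> list[tuple]:
    """All pairs whose closed intervals share >= 1 bp on the same chromosome."""
    pairs = []
    for qa in eqtls_a:
        for qb in eqtls_b:
            if str(qa.chrom) == str(qb.chrom) and qa.start <= qb.end and qb.start <= qa.end:
                pairs.append((qa, qb))
    return pairs


@dataclass
class ConcordanceResult:
    """Agreement between a lead-SNP haplotype and a structural polymorphism."""

    n_considered: int
    n_concordant: int
    discordant: list
    excluded_het: list
    excluded_missing: list

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_considered if self.n_considered else float("nan")


def haplotype_concordance(
    alleles: pd.Series,
    presence: pd.Series,
    presence_allele: int,
) -> ConcordanceResult:
    """Tally concordance between homozygous lead-SNP classes and a presence/
    absence polymorphism.

    ``presence_allele`` (0 or 2) states which homozygous dosage class is
    expected to carry the polymorphism; heterozygous (dosage 1) and missing
    entries are excluded from the tally.
    """
    if presence_allele not in (0, 2):
        raise ConfigurationError("presence_allele: must be the dosage 0 or 2 homozygote class")
    pres = presence.map(
        lambda v: {True: True, False: False, "+": True, "-": False}.get(v, pd.NA)
        if not pd.isna(v)
        else pd.NA
    )
    common = alleles.index.intersection(pres.index)
    if len(common) == 0:
        raise DesignError("haplotype_concordance: line sets do not intersect")
    alleles = alleles.loc[common]
    pres = pres.loc[common]

    het = [l for l in common if alleles[l] == 1]
    missing = [l for l in common if pd.isna(alleles[l]) or pd.isna(pres[l])]
    usable = [l for l in common if l not in set(het) | set(missing)]
    discordant = []
    n_conc = 0
    for l in usable:
        expected = alleles[l] == presence_allele
        if bool(pres[l]) == expected:
            n_conc += 1
        else:
            discordant.append(l)
    return ConcordanceResult(
        n_considered=len(usable),
        n_concordant=n_conc,
        discordant=discordant,
        excluded_het=het,
        excluded_missing=missing,
    )
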