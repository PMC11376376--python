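"""Synthetic hybrid-panel generator with planted ground truth.

Emulates the data-generating process the analysis assumes: a diversity panel
of inbred lines crossed to a common tester (so between-hybrid variation
reduces to line-side alleles and dosages are mostly homozygous 0/2),
structured into admixture groups with Balding-Nichols differentiated allele
frequencies, local LD along chromosomes, expression traits with a planted
local causal variant plus distant effects and a polygenic background, and a
qPCR assay layer (Ct values with biological/technical replicate noise,
reference genes, and the two artifact mechanisms the QC stage targets: a
reference gene carrying its own genetic effect and a primer-site allele that
perturbs amplification in carrier lines).

LD model: each line carries a latent standard-normal AR(1) process along each
chromosome (correlation exp(-d/L) at distance d bp, L the LD length scale);
the allele at a marker is the indicator that the latent value falls below the
group-specific frequency quantile. This Gaussian-copula construction gives
exact per-group allele frequencies, monotone LD decay with distance, and
strong local LD, while staying far cheaper than a coalescent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneModel, GenotypeMatrix
from .exceptions import ConfigurationError, UnknownIdentifierError

logger = logging.getLogger(__name__)

#: admixture-group sizes of a 252-line dent panel crossed to a common flint
#: tester (stiff stalk, iodent, Lancaster, Lancaster early, stiff stalk
#: early, and the residual admixture group)
DEFAULT_GROUP_SIZES_252 = (32, 34, 32, 16, 36, 102)
DEFAULT_GROUP_NAMES_6 = ("B73", "PH207", "Mo17", "Oh43", "B14a", "W117")


@dataclass
class PanelConfig:
    """Shape and population-genetic parameters of the simulated panel."""

    n_lines: int = 252
    n_groups: int = 6
    group_sizes: Optional[Sequence[int]] = None
    n_chrom: int = 3
    markers_per_chrom: int = 500
    chrom_length_bp: int = 30_000_000
    ld_block_len_bp: int = 1_000_000
    differentiation: float = 0.10
    maf_range: tuple = (0.05, 0.5)
    het_rate: float = 0.01
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            if self.n_lines == 252 and self.n_groups == 6:
                self.group_sizes = DEFAULT_GROUP_SIZES_252
            else:
                base = self.n_lines // self.n_groups
                sizes = [base] * self.n_groups
                for i in range(self.n_lines - base * self.n_groups):
                    sizes[i] += 1
                self.group_sizes = tuple(sizes)
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if sum(self.group_sizes) != self.n_lines:
            raise ConfigurationError("group_sizes: must sum to n_lines")
        if len(self.group_sizes) != self.n_groups:
            raise ConfigurationError("group_sizes: must have n_groups entries")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range: must lie within (0, 0.5]")
        if not (0.0 <= self.differentiation < 1.0):
            raise ConfigurationError("differentiation: must lie in [0, 1)")
        for name in ("het_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}: must be a probability")
        for name in ("n_lines", "n_chrom", "markers_per_chrom", "chrom_length_bp", "ld_block_len_bp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be positive")
        if self.markers_per_chrom > self.chrom_length_bp:
            raise ConfigurationError("markers_per_chrom: cannot exceed chrom_length_bp")

    @property
    def group_names(self) -> tuple:
        if self.n_groups == 6:
            return DEFAULT_GROUP_NAMES_6
        return tuple(f"G{i + 1}" for i in range(self.n_groups))


def simulate_panel(config: PanelConfig) -> tuple[GenotypeMatrix, pd.Series]:
    """Simulate the panel's line-side dosage matrix and group labels.

    Returns dosages in {0, 1, 2} (NaN at ``missing_rate``), with groups
    differentiated per the Balding-Nichols model and within-chromosome LD
    decaying as exp(-d / ld_block_len_bp). Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    group_labels = np.repeat(np.arange(config.n_groups), config.group_sizes)
    lines = [f"L{i + 1:04d}" for i in range(n)]
    groups = pd.Series(
        [config.group_names[g] for g in group_labels], index=lines, name="group"
    )

    f = config.differentiation
    lo, hi = config.maf_range
    chrom_blocks = []
    dosage_blocks = []
    for c in range(config.n_chrom):
        m = config.markers_per_chrom
        # jittered grid, emulating the even genome coverage genotyping
        # arrays are designed for (bounds the largest inter-marker gap)
        spacing = config.chrom_length_bp / m
        pos = (np.arange(m) + 0.5) * spacing + rng.uniform(-0.3, 0.3, m) * spacing
        pos = np.maximum(np.round(pos).astype(np.int64), 1)
        pos = np.maximum.accumulate(pos + np.arange(m))  # strictly increasing
        ar = np.exp(-np.diff(pos) / config.ld_block_len_bp)
        # ancestral allele frequencies vary smoothly along the chromosome
        # (markers on one haplotype block share their frequency, as in real
        # LD blocks; frequency mismatch otherwise caps attainable r2)
        u = np.empty(m)
        u[0] = rng.standard_normal()
        for k in range(1, m):
            u[k] = ar[k - 1] * u[k - 1] + np.sqrt(1.0 - ar[k - 1] ** 2) * rng.standard_normal()
        v = stats.norm.cdf(u)
        if hi >= 0.5:
            # continuous map onto (lo, 1-lo); minor allele frequency >= lo
            p_anc = lo + (1.0 - 2.0 * lo) * v
        else:
            # capped MAF: keep the map continuous by fixing the alternate
            # allele's orientation for the whole chromosome
            minor = lo + (hi - lo) * v
            p_anc = minor if rng.random() < 0.5 else 1.0 - minor
        if f > 0:
            # Balding-Nichols group frequencies, drawn through a smoothly
            # varying latent field per group so neighbouring markers keep
            # matched frequencies within each group (haplotype-block realism)
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            wg = np.empty((config.n_groups, m))
            wg[:, 0] = rng.standard_normal(config.n_groups)
            for k in range(1, m):
                wg[:, k] = ar[k - 1] * wg[:, k - 1] + np.sqrt(
                    1.0 - ar[k - 1] ** 2
                ) * rng.standard_normal(config.n_groups)
            q = stats.beta.ppf(stats.norm.cdf(wg), a[None, :], b[None, :])
        else:
            q = np.tile(p_anc, (config.n_groups, 1))
        q = np.clip(q, 1e-4, 1.0 - 1e-4)

        # latent AR(1) field per line, thresholded at the group quantile
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, m - 1)) if m > 1 else None
        for k in range(1, m):
            z[:, k] = ar[k - 1] * z[:, k - 1] + np.sqrt(1.0 - ar[k - 1] ** 2) * innov[:, k - 1]
        thresh = stats.norm.ppf(q)[group_labels, :]
        dos = np.where(z < thresh, 2.0, 0.0)

        het = rng.random((n, m)) < config.het_rate
        dos[het] = 1.0
        miss = rng.random((n, m)) < config.missing_rate
        dos[miss] = np.nan

        chrom = str(c + 1)
        chrom_blocks.append(
            pd.DataFrame(
                {
                    "marker": [f"S{chrom}_{p}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "ref": "A",
                    "alt": "T",
                }
            )
        )
        dosage_blocks.append(dos)

    markers = pd.concat(chrom_blocks, ignore_index=True)
    geno = GenotypeMatrix(np.hstack(dosage_blocks), lines, markers)
    return geno, groups


def marker_near(geno: GenotypeMatrix, chrom, frac: float, min_maf: float = 0.2) -> str:
    """Id of a common marker closest to a relative position along a chromosome.

    Convenience for placing causal variants in scenarios without hard-coding
    marker names.
    """
    cols = geno.markers_on(chrom)
    if cols.size == 0:
        raise UnknownIdentifierError(f"no markers on chromosome {chrom!r}")
    sub = geno.markers.iloc[cols]
    maf = geno.maf()[cols]
    target = sub["pos"].min() + frac * (sub["pos"].max() - sub["pos"].min())
    order = np.argsort(np.abs(sub["pos"].to_numpy() - target))
    for k in order:
        if maf[k] >= min_maf:
            return sub["marker"].iloc[k]
    return sub["marker"].iloc[order[0]]


@dataclass
class TrueArchitecture:
    """Planted genetic architecture of one expression trait."""

    local_causal: Optional[tuple] = None  # (marker id, effect on log2 expression)
    distant_causals: Sequence[tuple] = ()
    polygenic_var: float = 0.0
    residual_var_line: float = 0.0
    group_shift: Optional[dict] = None
    gene_model: Optional[GeneModel] = None

    def __post_init__(self) -> None:
        if self.polygenic_var < 0 or self.residual_var_line < 0:
            raise ConfigurationError("polygenic_var/residual_var_line: variances must be >= 0")

    @property
    def causals(self) -> list[tuple]:
        out = []
        if self.local_causal is not None:
            out.append(tuple(self.local_causal))
        out.extend(tuple(c) for c in self.distant_causals)
        return out


def plant_architecture(
    genotypes: GenotypeMatrix,
    arch: TrueArchitecture,
    rng: np.random.Generator | int | None = None,
    groups: Optional[pd.Series] = None,
    kinship: Optional[np.ndarray] = None,
) -> tuple[pd.Series, dict]:
    """Per-line true line effects for one trait, plus a truth table.

    line effect = sum(effect * dosage) + polygenic draw from
    N(0, polygenic_var * K) + N(0, residual_var_line) + group shift.
    The polygenic term uses the panel's own realized kinship so the simulated
    background matches what the GWAS model assumes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = genotypes.n_lines
    value = np.zeros(n)
    truth: dict = {"causals": [], "polygenic_var": arch.polygenic_var}
    for marker_id, effect in arch.causals:
        x = genotypes.dosage(marker_id, imputed=True)
        value += effect * x
        j = genotypes.marker_index(marker_id)
        row = genotypes.markers.iloc[j]
        truth["causals"].append(
            {"marker": marker_id, "chrom": row["chrom"], "pos": int(row["pos"]), "effect": effect}
        )
    if arch.polygenic_var > 0:
        if kinship is None:
            from .mixed_model_gwas import compute_kinship

            kinship = compute_kinship(genotypes)
        # unit-diagonal scaling so polygenic_var is the per-line variance
        kinship = kinship / float(np.mean(np.diag(kinship)))
        cov = arch.polygenic_var * (kinship + 1e-8 * np.eye(n))
        value += np.linalg.cholesky(cov) @ rng.standard_normal(n)
    if arch.residual_var_line > 0:
        value += rng.normal(0.0, np.sqrt(arch.residual_var_line), n)
    if arch.group_shift:
        if groups is None:
            raise ConfigurationError("group_shift: group labels are required")
        value += groups.map(arch.group_shift).fillna(0.0).to_numpy(float)
    if arch.gene_model is not None:
        truth["gene"] = {
            "gene_id": arch.gene_model.gene_id,
            "chrom": arch.gene_model.chrom,
            "start": arch.gene_model.start,
            "end": arch.gene_model.end,
        }
    return pd.Series(value, index=genotypes.lines, name="line_effect"), truth


def effect_for_marker_r2(
    genotypes: GenotypeMatrix, marker_id: str, target_r2: float, other_var: float
) -> float:
    """Additive effect so the marker explains ``target_r2`` of trait variance.

    ``other_var`` is the total non-marker variance (polygenic + line residual
    + expression noise on genotype means) the trait will carry.
    """
    x = genotypes.dosage(marker_id, imputed=True)
    vx = float(np.var(x))
    if vx <= 0:
        raise ConfigurationError(f"marker {marker_id} is monomorphic")
    return float(np.sqrt(target_r2 / (1.0 - target_r2) * other_var / vx))


@dataclass
class PrimerDropout:
    """A polymorphism under a qPCR primer that perturbs amplification."""

    gene: str
    marker: str
    carrier_allele: int = 2  # homozygous dosage class whose amplification fails
    ct_shift: float = 0.0
    missing_prob: float = 0.0


@dataclass
class AssayArtifactConfig:
    """Noise magnitudes and planted artifacts of the simulated qPCR assay."""

    rep_noise_sd: float = 0.4   # biological replicate noise, Ct units
    tech_noise_sd: float = 0.15  # technical replicate noise, Ct units
    base_ct: dict = field(default_factory=dict)  # per-gene Ct baseline
    default_target_ct: float = 24.0
    default_reference_ct: float = 20.0
    ref_gene_genetic_effect: Optional[tuple] = None  # (ref gene, marker, Ct per alt allele)
    primer_dropout: Optional[PrimerDropout] = None

    def __post_init__(self) -> None:
        if self.rep_noise_sd < 0 or self.tech_noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")
        for gene, ct in self.base_ct.items():
            if not (15.0 <= ct <= 35.0):
                raise ConfigurationError(f"base_ct[{gene}]: {ct} outside plausible 15-35 range")
        for name in ("default_target_ct", "default_reference_ct"):
            if not (15.0 <= getattr(self, name) <= 35.0):
                raise ConfigurationError(f"{name}: outside plausible 15-35 range")

    def base_for(self, gene: str, is_reference: bool) -> float:
        if gene in self.base_ct:
            return self.base_ct[gene]
        return self.default_reference_ct if is_reference else self.default_target_ct


def expression_noise_variance(assay: AssayArtifactConfig, n_ref: int, n_tech: int = 2) -> float:
    """Variance of the log2 relative-expression noise per biological replicate.

    The delta-Ct trait inherits noise from the target gene and from the mean of
    the reference genes: (1 + 1/n_ref) * (rep_sd^2 + tech_sd^2 / n_tech).
    Useful to size planted heritabilities exactly.
    """
    per_gene = assay.rep_noise_sd**2 + assay.tech_noise_sd**2 / n_tech
    return (1.0 + 1.0 / n_ref) * per_gene


def simulate_ct(
    line_effects: pd.DataFrame | pd.Series,
    assay: AssayArtifactConfig,
    reference_genes: Sequence[str],
    genotypes: Optional[GenotypeMatrix] = None,
    n_bio: int = 3,
    n_tech: int = 2,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Replicate-level Ct table for target and reference genes.

    target Ct = base_ct - (line effect + bio-rep noise) + tech noise; the
    reference genes carry only noise unless ``ref_gene_genetic_effect`` plants
    a genetic Ct shift on one of them (the reference-gene artifact), and
    ``primer_dropout`` shifts or removes target Cts in carrier lines.
    Returns columns (line, bio_rep, tech_rep, gene, ct).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(line_effects, pd.Series):
        name = line_effects.name or "target"
        line_effects = line_effects.to_frame(name)
    reference_genes = list(reference_genes)
    if len(reference_genes) < 2:
        raise ConfigurationError("reference_genes: at least 2 reference genes are required")
    needs_geno = assay.ref_gene_genetic_effect is not None or assay.primer_dropout is not None
    if needs_geno and genotypes is None:
        raise ConfigurationError("genotypes: required when a genetic assay artifact is configured")

    lines = list(line_effects.index)
    n = len(lines)
    records = []

    def emit(gene: str, per_line_bio_ct: np.ndarray, drop_mask: np.ndarray | None = None):
        for b in range(n_bio):
            for t in range(n_tech):
                ct = per_line_bio_ct[:, b] + rng.normal(0.0, assay.tech_noise_sd, n)
                keep = np.ones(n, bool) if drop_mask is None else ~drop_mask[:, b]
                records.append(
                    pd.DataFrame(
                        {
                            "line": np.asarray(lines)[keep],
                            "bio_rep": b + 1,
                            "tech_rep": t + 1,
                            "gene": gene,
                            "ct": ct[keep],
                        }
                    )
                )

    for gene in line_effects.columns:
        eff = line_effects[gene].to_numpy(float)
        bio = rng.normal(0.0, assay.rep_noise_sd, (n, n_bio))
        ct_lb = assay.base_for(gene, is_reference=False) - (eff[:, None] + bio)
        drop = None
        pd_cfg = assay.primer_dropout
        if pd_cfg is not None and pd_cfg.gene == gene:
            dos = genotypes.dosage(pd_cfg.marker)
            dos = pd.Series(dos, index=genotypes.lines).reindex(lines).to_numpy(float)
            shift = np.zeros(n)
            carrier = dos == pd_cfg.carrier_allele
            shift[carrier] = pd_cfg.ct_shift
            shift[dos == 1] = pd_cfg.ct_shift / 2.0
            ct_lb = ct_lb + shift[:, None]
            if pd_cfg.missing_prob > 0:
                affected = carrier | (dos == 1)
                drop = (rng.random((n, n_bio)) < pd_cfg.missing_prob) & affected[:, None]
        emit(gene, ct_lb, drop)

    for gene in reference_genes:
        bio = rng.normal(0.0, assay.rep_noise_sd, (n, n_bio))
        ct_lb = assay.base_for(gene, is_reference=True) + bio
        if assay.ref_gene_genetic_effect is not None:
            ref_gene, marker, ct_per_allele = assay.ref_gene_genetic_effect
            if ref_gene == gene:
                dos = genotypes.dosage(marker, imputed=True)
                dos = pd.Series(dos, index=genotypes.lines).reindex(lines).to_numpy(float)
                ct_lb = ct_lb + ct_per_allele * dos[:, None]
        emit(gene, ct_lb)

    return pd.concat(records, ignore_index=True)


def structural_table_from_marker(
    genotypes: GenotypeMatrix,
    marker_id: str,
    carrier_allele: int = 0,
    discordant: Sequence[str] = (),
) -> pd.Series:
    """Per-line presence/absence of a structural polymorphism tagging a marker.

    Presence is assigned to the ``carrier_allele`` homozygote class;
    heterozygous and missing lines get NA. ``discordant`` names lines whose
    call is flipped, emulating an accession where the haplotype and the
    structural variant disagree.
    """
    dos = genotypes.dosage(marker_id)
    presence = pd.Series(pd.NA, index=genotypes.lines, dtype="boolean", name="presence")
    presence[dos == carrier_allele] = True
    presence[dos == (2 - carrier_allele)] = False
    for line in discordant:
        if line not in presence.index:
            raise UnknownIdentifierError(f"unknown line id {line!r}")
        if presence[line] is not pd.NA:
            presence[line] = not bool(presence[line])
    return presence
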