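"""File formats, configuration, and the end-to-end pipeline driver.

Formats: genotypes as VCF v4.2 (biallelic SNPs, GT-only) or a wide dosage
TSV carrying the marker map; Ct/expression/association/eQTL tables as TSV;
gene models as GFF3 (1-based inclusive); eQTL intervals exported to BED
(0-based half-open); configuration as YAML with one master seed; QC and
truth-recovery reports as JSON.

The driver chains the study's workflow: expression normalization ->
repeatability -> mixed-model GWAS with LOCO kinship -> LD-window eQTL
definition -> conditional (covariate) GWAS for strong local eQTLs ->
reference-gene / primer QC -> final eQTL tables, and, when planted truth is
available (simulated inputs), a recovery summary.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import artifact_qc, eqtl_windows, expression_quant, mixed_model_gwas, synthetic_panel
from .containers import GeneModel, GenotypeMatrix
from .eqtl_windows import EQTL, LDParams, WindowScanner
from .exceptions import ConfigurationError, PipeqtlError
from .mixed_model_gwas import ScanConfig

logger = logging.getLogger(__name__)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ------------------------------------------------------------- genotypes
def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as a minimal VCF v4.2 (GT field only)."""
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in genotypes.markers.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.lines) + "\n")
        for j, row in genotypes.markers.iterrows():
            calls = [
                gt.get(d, "./.") if np.isfinite(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['marker']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; other records are skipped and counted
    in ``result.markers.attrs['n_skipped']``."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    rows, cols, skipped = [], [], 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        dos = np.empty(len(lines))
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            dos[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(
            {
                "marker": v.ID if v.ID not in (None, ".") else f"S{v.CHROM}_{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": v.ALT[0],
            }
        )
        cols.append(dos)
    if not rows:
        raise ConfigurationError(f"no usable biallelic SNP records in {path}")
    markers = pd.DataFrame(rows)
    geno = GenotypeMatrix(np.column_stack(cols), lines, markers)
    geno.markers.attrs["n_skipped"] = skipped
    if skipped:
        logger.info("skipped %d non-biallelic/non-SNP records in %s", skipped, path)
    return geno


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Wide dosage TSV: marker map columns then one column per line."""
    dosage_cols = pd.DataFrame(
        genotypes.dosages.T, columns=genotypes.lines, index=genotypes.markers.index
    )
    wide = pd.concat([genotypes.markers, dosage_cols], axis=1)
    wide.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    wide = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ("marker", "chrom", "pos", "ref", "alt")
    missing = set(required) - set(wide.columns)
    if missing:
        raise ConfigurationError(f"dosage TSV lacks marker-map columns {sorted(missing)}")
    lines = [c for c in wide.columns if c not in required]
    dosages = wide[lines].to_numpy(float).T
    return GenotypeMatrix(dosages, lines, wide[["marker", "chrom", "pos", "ref", "alt"]])


def read_genotypes(path, fmt: Optional[str] = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the extension)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ConfigurationError(f"format: unknown genotype format {fmt!r}")


def write_genotypes(genotypes: GenotypeMatrix, path, fmt: Optional[str] = None) -> None:
    if fmt is None:
        fmt = "vcf" if str(path).endswith(".vcf") else "tsv"
    if fmt == "vcf":
        write_genotypes_vcf(genotypes, path)
    elif fmt == "tsv":
        write_genotypes_tsv(genotypes, path)
    else:
        raise ConfigurationError(f"format: unknown genotype format {fmt!r}")


# ------------------------------------------------------------ gene models
def read_gene_models_gff3(path) -> dict:
    """GFF3 gene features as {gene_id: GeneModel} (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        out[gid] = GeneModel(
            gene_id=gid, chrom=str(feat.seqid), start=feat.start, end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
        )
    return out


def write_gene_models_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpipeqtl\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ------------------------------------------------------------------ eQTLs
EQTL_TSV_COLUMNS = [
    "trait", "eqtl_id", "chrom", "start", "end", "n_snps", "lead_marker",
    "lead_logp", "lead_r2_lr", "lead_beta", "lead_pos", "lead_maf", "is_local",
]


def eqtls_to_frame(eqtls: Sequence[EQTL]) -> pd.DataFrame:
    rows = []
    for q in eqtls:
        rows.append(
            {
                "trait": q.trait,
                "eqtl_id": q.eqtl_id,
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "n_snps": q.n_snps,
                "lead_marker": q.lead["marker"],
                "lead_logp": q.lead["logp"],
                "lead_r2_lr": q.lead["r2_lr"],
                "lead_beta": q.lead["beta"],
                "lead_pos": q.lead["pos"],
                "lead_maf": q.lead["maf"],
                "is_local": q.is_local,
            }
        )
    return pd.DataFrame(rows, columns=EQTL_TSV_COLUMNS)


def export_eqtls(eqtls: Sequence[EQTL], tsv_path=None, bed_path=None) -> pd.DataFrame:
    """Write the eQTL table (TSV) and/or intervals (BED, 0-based half-open)."""
    frame = eqtls_to_frame(eqtls)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for q in eqtls:
                fh.write(f"{q.chrom}\t{q.start - 1}\t{q.end}\t{q.eqtl_id}\n")
    return frame


def read_eqtl_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ------------------------------------------------------------- Ct tables
def read_ct_table(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    missing = set(expression_quant.CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ConfigurationError(f"Ct table lacks columns {sorted(missing)}")
    return ct


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


# ------------------------------------------------------- pipeline config
@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (YAML round-trippable)."""

    seed: int = 0
    output_dir: str = "pipeline_out"
    # file inputs ...
    genotypes: Optional[str] = None
    ct_table: Optional[str] = None
    gene_models: Optional[str] = None
    groups: Optional[str] = None
    # ... or a simulated study
    simulate: Optional[dict] = None
    reference_genes: list = field(default_factory=lambda: ["Act1", "Ef1a", "Ubi2"])
    traits: Optional[list] = None
    trait_genes: Optional[dict] = None  # trait -> gene id in gene_models
    maf_min: float = 0.05
    logp_threshold: float = 5.0
    effect_allele: str = "alt"
    r2k_threshold: float = 0.1
    scan_radius_bp: int = 2_000_000
    min_run: int = 3
    covariate_trigger_logp: float = 12.0
    run_qc: bool = True
    primer_intervals: Optional[dict] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None and self.genotypes is None:
            raise ConfigurationError("genotypes: either file inputs or simulate must be given")
        if self.simulate is not None and self.seed is None:
            raise ConfigurationError("seed: required when simulation is requested")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ------------------------------------------------------- simulated inputs
@dataclass
class StudyInputs:
    genotypes: GenotypeMatrix
    groups: Optional[pd.Series]
    ct: pd.DataFrame
    reference_genes: list
    gene_models: dict  # gene id -> GeneModel (targets and references)
    truth: Optional[dict] = None


def simulate_demo_study(
    seed: int = 0,
    n_lines: int = 150,
    n_chrom: int = 3,
    markers_per_chrom: int = 500,
    chrom_length_bp: int = 12_000_000,
    local_r2: float = 0.5,
    distant_effect: float = 0.25,
    polygenic_var: float = 0.15,
    residual_var_line: float = 0.05,
    ref_artifact_ct: Optional[float] = None,
    primer_artifact: Optional[dict] = None,
) -> StudyInputs:
    """One-target demo study with a planted local eQTL and one distant eQTL.

    The target gene sits on chromosome 2 at the local causal marker; three
    reference genes are placed on other chromosomes. ``ref_artifact_ct``
    plants a genetic Ct shift on the Ubi2 reference (the reference-gene
    artifact); ``primer_artifact`` (keys: ct_shift, missing_prob) plants a
    primer-site dropout at a marker near the target gene.
    """
    master = np.random.SeedSequence(seed)
    s_panel, s_arch, s_ct = (np.random.default_rng(s) for s in master.spawn(3))
    panel = synthetic_panel.PanelConfig(
        n_lines=n_lines,
        n_chrom=n_chrom,
        markers_per_chrom=markers_per_chrom,
        chrom_length_bp=chrom_length_bp,
        seed=int(master.generate_state(1)[0] % (2**31)),
    )
    geno, groups = synthetic_panel.simulate_panel(panel)
    chroms = geno.chromosomes
    local_chrom = chroms[min(1, len(chroms) - 1)]
    distant_chrom = chroms[0]

    target = "PIP2_5"
    refs = ["Act1", "Ef1a", "Ubi2"]
    assay = synthetic_panel.AssayArtifactConfig()
    causal = synthetic_panel.marker_near(geno, local_chrom, 0.5)
    causal_pos = int(geno.markers["pos"].iloc[geno.marker_index(causal)])
    # promoter-variant geometry: the causal variant sits a few hundred bp
    # upstream of the transcribed region it regulates
    gene = GeneModel(target, local_chrom, causal_pos + 431, causal_pos + 431 + 2500)

    noise_var = synthetic_panel.expression_noise_variance(assay, n_ref=len(refs)) / 3.0
    other_var = polygenic_var + residual_var_line + noise_var
    local_eff = synthetic_panel.effect_for_marker_r2(geno, causal, local_r2, other_var)
    distant_marker = synthetic_panel.marker_near(geno, distant_chrom, 0.3)
    arch = synthetic_panel.TrueArchitecture(
        local_causal=(causal, local_eff),
        distant_causals=[(distant_marker, distant_effect)],
        polygenic_var=polygenic_var,
        residual_var_line=residual_var_line,
        gene_model=gene,
    )
    values, truth = synthetic_panel.plant_architecture(geno, arch, rng=s_arch, groups=groups)

    gene_models = {target: gene}
    # reference genes live away from the planted signals
    ref_positions = {
        "Act1": (chroms[0], 0.75),
        "Ef1a": (chroms[-1], 0.25),
        "Ubi2": (chroms[-1], 0.7),
    }
    artifact_marker = None
    if ref_artifact_ct is not None:
        artifact_marker = synthetic_panel.marker_near(geno, chroms[-1], 0.7)
        assay.ref_gene_genetic_effect = ("Ubi2", artifact_marker, ref_artifact_ct)
        truth["ref_artifact"] = {"gene": "Ubi2", "marker": artifact_marker, "ct_per_allele": ref_artifact_ct}
    for ref, (chrom, frac) in ref_positions.items():
        if ref == "Ubi2" and artifact_marker is not None:
            pos = int(geno.markers["pos"].iloc[geno.marker_index(artifact_marker)])
        else:
            mid = synthetic_panel.marker_near(geno, chrom, frac)
            pos = int(geno.markers["pos"].iloc[geno.marker_index(mid)])
        gene_models[ref] = GeneModel(ref, chrom, max(1, pos - 1000), pos + 1000)

    if primer_artifact is not None:
        # the perturbed primer site sits at the marker adjacent to the gene;
        # the unfavorable allele is the minor homozygote class, as in the
        # 29-carrier episode the subpanel correction was designed for
        primer_marker = causal
        p_alt = float(np.nanmean(geno.dosage(primer_marker))) / 2.0
        default_carrier = 2 if p_alt < 0.5 else 0
        carrier = int(primer_artifact.get("carrier_allele", default_carrier))
        assay.primer_dropout = synthetic_panel.PrimerDropout(
            gene=target,
            marker=primer_marker,
            carrier_allele=carrier,
            ct_shift=float(primer_artifact.get("ct_shift", 2.0)),
            missing_prob=float(primer_artifact.get("missing_prob", 0.0)),
        )
        truth["primer_artifact"] = {
            "gene": target, "marker": primer_marker, "carrier_allele": carrier,
        }

    ct = synthetic_panel.simulate_ct(
        values.rename(target), assay, refs, genotypes=geno, rng=s_ct
    )
    truth["trait"] = target
    return StudyInputs(
        genotypes=geno, groups=groups, ct=ct, reference_genes=refs,
        gene_models=gene_models, truth=truth,
    )


# --------------------------------------------------------------- pipeline
@dataclass
class PipelineResult:
    config: PipelineConfig
    heritability: pd.DataFrame
    associations: dict  # trait -> DataFrame
    eqtls_initial: dict  # trait -> list[EQTL]
    eqtls_final: dict  # trait -> list[EQTL] after covariate/QC stages
    qc_report: dict
    recovery: Optional[dict] = None


def _significant(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    return records[records["logp"] >= threshold].copy()


def _define_eqtls(records, sig, geno, kinship, ld_params, gene, trait):
    scanner = WindowScanner(geno, kinship, ld_params)
    windows = {m: scanner.window(m) for m in sig["marker"]}
    return eqtl_windows.group_eqtls(sig, windows, gene, trait)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full workflow; writes all outputs under ``config.output_dir``.

    Stage failures abort with the stage name; outputs written before the
    failure persist. Reruns with an identical config produce identical files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        config.to_yaml(out / "config.yaml")

        stage = "inputs"
        t0 = time.time()
        if config.simulate is not None:
            inputs = simulate_demo_study(seed=config.seed, **config.simulate)
        else:
            geno = read_genotypes(config.genotypes)
            ct = read_ct_table(config.ct_table)
            gene_models = read_gene_models_gff3(config.gene_models) if config.gene_models else {}
            groups = (
                pd.read_csv(config.groups, sep="\t", index_col=0).iloc[:, 0]
                if config.groups
                else None
            )
            inputs = StudyInputs(
                genotypes=geno, groups=groups, ct=ct,
                reference_genes=list(config.reference_genes),
                gene_models=gene_models, truth=None,
            )
        logger.info("stage inputs done in %.1fs", time.time() - t0)

        stage = "expression"
        expr = expression_quant.relative_expression(inputs.ct, inputs.reference_genes)
        write_table(expr, out / "expression.tsv")
        targets = config.traits or sorted(
            g for g in inputs.ct["gene"].unique() if g not in inputs.reference_genes
        )

        stage = "heritability"
        herit_rows = []
        for trait in targets:
            h = expression_quant.heritability(expr, trait)
            herit_rows.append({"trait": trait, "vg": h.vg, "ve": h.ve, "n": h.n, "h": h.h})
        herit = pd.DataFrame(herit_rows)
        write_table(herit, out / "heritability.tsv")

        stage = "kinship"
        kinships = mixed_model_gwas.build_kinship_set(inputs.genotypes)

        stage = "gwas"
        scan_cfg = ScanConfig(
            maf_min=config.maf_min,
            logp_threshold=config.logp_threshold,
            effect_allele=config.effect_allele,
        )
        ld_params = LDParams(
            r2k_threshold=config.r2k_threshold,
            scan_radius_bp=config.scan_radius_bp,
            min_run=config.min_run,
        )
        associations, eqtls_initial = {}, {}
        for trait in targets:
            y = expression_quant.trait_vector(expr, trait)
            rec = mixed_model_gwas.scan(y, inputs.genotypes, kinships, scan_cfg)
            associations[trait] = rec
            write_table(rec, out / f"associations_{trait}.tsv")
            gene = inputs.gene_models.get(config.trait_genes.get(trait) if config.trait_genes else trait)
            eqtls_initial[trait] = _define_eqtls(
                rec, _significant(rec, scan_cfg.logp_threshold), inputs.genotypes,
                kinships.global_k, ld_params, gene, trait,
            )
        export_eqtls(
            [q for qs in eqtls_initial.values() for q in qs],
            out / "eqtls_initial.tsv", out / "eqtls_initial.bed",
        )

        stage = "covariate_gwas"
        eqtls_final = dict(eqtls_initial)
        for trait in targets:
            locals_ = [q for q in eqtls_initial[trait] if q.is_local]
            strong = [q for q in locals_ if q.lead["logp"] > config.covariate_trigger_logp]
            if not strong:
                continue
            lead = str(max(strong, key=lambda q: q.lead["logp"]).lead["marker"])
            cov_cfg = dataclasses.replace(scan_cfg, covariate_markers=(lead,))
            y = expression_quant.trait_vector(expr, trait)
            rec = mixed_model_gwas.conditional_scan(y, inputs.genotypes, kinships, cov_cfg)
            write_table(rec, out / f"associations_{trait}_cov.tsv")
            gene = inputs.gene_models.get(config.trait_genes.get(trait) if config.trait_genes else trait)
            cov_eqtls = _define_eqtls(
                rec, _significant(rec, scan_cfg.logp_threshold), inputs.genotypes,
                kinships.global_k, ld_params, gene, trait,
            )
            # initial eQTLs are conserved; the covariate scan contributes the
            # ones independent of the conditioned local lead
            overlapping = {id(b) for _, b in eqtl_windows.colocalize(eqtls_initial[trait], cov_eqtls)}
            new = [q for q in cov_eqtls if id(q) not in overlapping]
            for i, q in enumerate(new, start=1):
                q.eqtl_id = f"{trait}_cov_Q{i}"
            eqtls_final[trait] = eqtls_initial[trait] + new

        stage = "qc"
        qc_report: dict = {"reference_gene_checks": [], "primer_checks": []}
        if config.run_qc:
            ref_models = [
                inputs.gene_models[g] for g in inputs.reference_genes if g in inputs.gene_models
            ]
            checks = artifact_qc.check_reference_gene_eqtl(eqtls_initial, ref_models)
            for c in checks:
                qc_report["reference_gene_checks"].append(
                    {
                        "reference_gene": c.reference_gene,
                        "trait": c.trait,
                        "flagged": c.flagged,
                        "flagged_lead": c.flagged_lead,
                        "action": c.recommended_action,
                        "eqtls": [q.eqtl_id for q in c.overlapping_eqtls],
                    }
                )
            for c in checks:
                if not c.flagged or c.recommended_action != "covariate_adjust":
                    continue
                y = expression_quant.trait_vector(expr, c.trait)
                adj_cfg = dataclasses.replace(scan_cfg, covariate_markers=(c.flagged_lead,))
                rec = mixed_model_gwas.conditional_scan(y, inputs.genotypes, kinships, adj_cfg)
                write_table(rec, out / f"associations_{c.trait}_adjusted.tsv")
                gene = inputs.gene_models.get(
                    config.trait_genes.get(c.trait) if config.trait_genes else c.trait
                )
                eqtls_final[c.trait] = _define_eqtls(
                    rec, _significant(rec, scan_cfg.logp_threshold), inputs.genotypes,
                    kinships.global_k, ld_params, gene, c.trait,
                )
            if config.primer_intervals:
                pchecks, mask = artifact_qc.primer_polymorphism_filter(
                    inputs.genotypes, config.primer_intervals
                )
                for c in pchecks:
                    qc_report["primer_checks"].append(
                        {
                            "target_gene": c.target_gene,
                            "markers": c.markers,
                            "n_carriers": len(c.carrier_lines),
                            "n_het": len(c.het_lines),
                            "n_retained": int(mask.sum()),
                        }
                    )
                for c in pchecks:
                    if not c.polymorphic or c.target_gene not in targets:
                        continue
                    y = expression_quant.trait_vector(expr, c.target_gene)
                    rec = mixed_model_gwas.subpanel_scan(
                        y, inputs.genotypes, mask.to_numpy(), scan_cfg
                    )
                    write_table(rec, out / f"associations_{c.target_gene}_subpanel.tsv")
                    sub = inputs.genotypes.subset_lines(mask.to_numpy())
                    gene = inputs.gene_models.get(
                        config.trait_genes.get(c.target_gene) if config.trait_genes else c.target_gene
                    )
                    eqtls_final[c.target_gene] = _define_eqtls(
                        rec, _significant(rec, scan_cfg.logp_threshold), sub,
                        mixed_model_gwas.compute_kinship(sub), ld_params, gene, c.target_gene,
                    )
        with open(out / "qc_report.json", "w") as fh:
            json.dump(qc_report, fh, indent=2, sort_keys=True)

        stage = "final_eqtls"
        export_eqtls(
            [q for qs in eqtls_final.values() for q in qs],
            out / "eqtls_final.tsv", out / "eqtls_final.bed",
        )

        stage = "recovery"
        recovery = None
        if inputs.truth is not None:
            recovery = summarize_recovery(inputs.truth, eqtls_final)
            with open(out / "recovery.json", "w") as fh:
                json.dump(recovery, fh, indent=2, sort_keys=True)
    except PipeqtlError as err:
        raise type(err)(f"stage '{stage}' failed: {err}") from err

    return PipelineResult(
        config=config,
        heritability=herit,
        associations=associations,
        eqtls_initial=eqtls_initial,
        eqtls_final=eqtls_final,
        qc_report=qc_report,
        recovery=recovery,
    )


def summarize_recovery(truth: dict, eqtls_by_trait: dict) -> dict:
    """Planted-vs-detected summary for simulated inputs."""
    trait = truth.get("trait")
    eqtls = eqtls_by_trait.get(trait, [])
    out: dict = {"trait": trait, "n_eqtls": len(eqtls), "causals": []}
    for causal in truth.get("causals", []):
        hits = [
            q.eqtl_id
            for q in eqtls
            if str(q.chrom) == str(causal["chrom"]) and q.start <= causal["pos"] <= q.end
        ]
        out["causals"].append(
            {
                "marker": causal["marker"],
                "pos": causal["pos"],
                "effect": causal["effect"],
                "detected_in": hits,
                "detected": bool(hits),
            }
        )
    locals_ = [q for q in eqtls if q.is_local]
    out["n_local"] = len(locals_)
    out["local_detected"] = bool(locals_)
    return out
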