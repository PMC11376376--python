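"""Ct tables to normalized expression traits, plus descriptive statistics.

Normalization follows the 2^dCt convention: per sample (line x biological
replicate), technical replicates are first averaged on the Ct scale, then
dCt = mean(reference Cts) - target Ct, and the log2 relative expression *is*
dCt (log2(2^dCt) = dCt). Traits entering the GWAS are genotype means of the
biological replicates. Repeatability across replicates ("heritability" in the
broad sense) is Vg / (Vg + Ve/n) from a one-way random-effects REML fit.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._reml import fit_random_intercept
from .exceptions import ConfigurationError, EstimationError, UnknownIdentifierError

logger = logging.getLogger(__name__)

CT_COLUMNS = ("line", "bio_rep", "tech_rep", "gene", "ct")


def relative_expression(ct: pd.DataFrame, reference_genes) -> pd.DataFrame:
    """Normalize a Ct table against reference genes.

    Returns one row per (line, bio_rep, target gene) with column
    ``log2_rel_expr`` = mean(reference technical-mean Cts) - target
    technical-mean Ct. Samples missing the target or any reference are kept
    as NaN rows; samples with no usable gene at all are dropped with a logged
    warning.
    """
    missing_cols = set(CT_COLUMNS) - set(ct.columns)
    if missing_cols:
        raise ConfigurationError(f"Ct table lacks columns {sorted(missing_cols)}")
    reference_genes = list(reference_genes)
    present = set(ct["gene"].unique())
    unknown = [g for g in reference_genes if g not in present]
    if unknown:
        raise ConfigurationError(f"reference_genes: {unknown} not present in the Ct table")
    if len(reference_genes) < 1:
        raise ConfigurationError("reference_genes: at least one reference gene is required")

    tech_mean = (
        ct.dropna(subset=["ct"])
        .groupby(["line", "bio_rep", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    all_missing = tech_mean.isna().all(axis=1)
    if all_missing.any():
        for line, rep in tech_mean.index[all_missing]:
            logger.warning("sample (%s, bio rep %s) has no usable Ct values; dropped", line, rep)
        tech_mean = tech_mean.loc[~all_missing]

    # require every requested reference for a sample; otherwise the sample is missing
    ref_block = tech_mean.reindex(columns=reference_genes)
    ref_mean = ref_block.mean(axis=1, skipna=False)
    targets = [g for g in tech_mean.columns if g not in reference_genes]

    out = []
    for gene in targets:
        vals = ref_mean - tech_mean[gene]
        block = vals.rename("log2_rel_expr").reset_index()
        block["gene"] = gene
        out.append(block)
    expr = pd.concat(out, ignore_index=True)[["line", "bio_rep", "gene", "log2_rel_expr"]]
    expr.attrs["reference_genes"] = reference_genes
    return expr


def genotype_means(expr: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-line mean of the biological replicates for one trait.

    Returns a DataFrame indexed by line with columns ``value`` (arithmetic
    mean over non-missing replicates) and ``n_reps``; lines with no usable
    replicate are absent, not zero.
    """
    sub = expr[expr["gene"] == trait]
    if sub.empty:
        raise UnknownIdentifierError(f"trait {trait!r} not present in the expression table")
    grouped = sub.dropna(subset=["log2_rel_expr"]).groupby("line")["log2_rel_expr"]
    out = pd.DataFrame({"value": grouped.mean(), "n_reps": grouped.size()})
    return out


def trait_vector(expr: pd.DataFrame, trait: str) -> pd.Series:
    """Genotype-mean trait as a Series indexed by line (GWAS input)."""
    return genotype_means(expr, trait)["value"].rename(trait)


@dataclass
class HeritabilityResult:
    """Repeatability of a trait across biological replicates."""

    vg: float
    ve: float
    n: float  # replicates per genotype entering the formula (median count)
    h: float  # Vg / (Vg + Ve/n), in [0, 1]


def heritability(expr: pd.DataFrame, trait: str) -> HeritabilityResult:
    """Broad-sense repeatability from Expression ~ Genotype (random) by REML.

    ``n`` in H = Vg/(Vg + Ve/n) is the median replicate count per genotype
    (3 in a balanced design with three biological replicates).
    """
    sub = expr[expr["gene"] == trait].dropna(subset=["log2_rel_expr"])
    if sub.empty:
        raise UnknownIdentifierError(f"trait {trait!r} not present in the expression table")
    lines = sub["line"].to_numpy()
    if len(np.unique(lines)) < 2:
        raise EstimationError("heritability needs at least 2 genotypes")
    y = sub["log2_rel_expr"].to_numpy(float)
    n_med = float(sub.groupby("line").size().median())
    if np.ptp(y) == 0.0:
        return HeritabilityResult(vg=0.0, ve=0.0, n=n_med, h=0.0)
    fit = fit_random_intercept(y, np.ones((len(y), 1)), lines, reml=True)
    vg, ve = max(fit.sigma_u2, 0.0), max(fit.sigma_e2, 0.0)
    denom = vg + ve / n_med
    h = 0.0 if denom <= 0 else float(np.clip(vg / denom, 0.0, 1.0))
    return HeritabilityResult(vg=vg, ve=ve, n=n_med, h=h)


@dataclass
class GroupTestResult:
    """Kruskal-Wallis omnibus test plus Holm-adjusted pairwise comparisons."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_raw, p_holm, stars


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def group_tests(trait: pd.Series, groups: pd.Series) -> GroupTestResult:
    """Nonparametric comparison of a trait across panel groups.

    Kruskal-Wallis omnibus with tie correction; all pairwise Wilcoxon
    rank-sum tests with Holm adjustment; star flags at 0.1/0.05/0.01.
    Groups with fewer than 2 members are skipped with a warning.
    """
    df = pd.DataFrame({"value": trait}).join(groups.rename("group"), how="inner").dropna()
    sizes = df.groupby("group").size()
    usable = sizes[sizes >= 2].index.tolist()
    for g in sizes[sizes < 2].index:
        logger.warning("group %s has fewer than 2 lines; skipped in group tests", g)
    if len(usable) < 2:
        raise EstimationError("group_tests needs at least 2 groups with >= 2 lines")
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in usable]
    stat, p = stats.kruskal(*samples)

    pairs = list(itertools.combinations(range(len(usable)), 2))
    raw = []
    for i, j in pairs:
        raw.append(stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided").pvalue)
    adj = multipletests(raw, method="holm")[1] if raw else np.array([])
    pairwise = pd.DataFrame(
        {
            "group1": [usable[i] for i, _ in pairs],
            "group2": [usable[j] for _, j in pairs],
            "p_raw": raw,
            "p_holm": adj,
        }
    )
    pairwise["stars"] = pairwise["p_holm"].map(_stars)
    return GroupTestResult(statistic=float(stat), pvalue=float(p), pairwise=pairwise)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame  # traits x components, orthonormal columns
    percent_variance: np.ndarray


def pca_summary(traits: pd.DataFrame) -> PCAResult:
    """PCA of standardized traits with case-wise deletion of missing lines.

    Constant traits are removed with a warning. Percent variance sums to 100
    and loadings are orthonormal.
    """
    data = traits.dropna(axis=0, how="any")
    if data.shape[0] < 3 or data.shape[1] < 2:
        raise EstimationError("pca_summary needs >= 3 complete lines and >= 2 traits")
    sd = data.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("constant traits removed from PCA: %s", constant)
        data = data.drop(columns=constant)
        sd = sd.drop(constant)
    if data.shape[1] < 2:
        raise EstimationError("fewer than 2 non-constant traits remain for PCA")
    z = (data - data.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s**2 / (len(data) - 1)
    pct = 100.0 * var / var.sum()
    comp = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=data.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=data.columns, columns=comp)
    return PCAResult(scores=scores, loadings=loadings, percent_variance=pct)
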