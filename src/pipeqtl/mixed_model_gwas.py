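"""Single-locus mixed-model association scan with LOCO kinship.

Model: y = mu + x beta + g + e with g ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I), K the genomic relationship matrix computed from all
markers except those on the chromosome of the tested marker (leave one
chromosome out, so the tested signal is not absorbed by the polygenic term).
Variance components are estimated once per (trait x chromosome) on the null
model by spectral REML and reused for every marker of that chromosome (the
P3D/EMMAX approximation); exact per-marker refitting is available behind a
flag. The marker effect is estimated by generalized least squares and tested
with a 1-df F statistic.

Writing V = sigma_g^2 K + sigma_e^2 I = sigma_g^2 (K + delta I) and
eigendecomposing K = U L U', GLS in the rotated basis U'y reduces to a
weighted regression with weights 1/(lambda_i + delta); the whole chromosome
scans as a handful of matrix products.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, KinshipSet, VarianceComponents
from .exceptions import (
    ConfigurationError,
    DesignError,
    EstimationError,
    UnknownIdentifierError,
)

logger = logging.getLogger(__name__)

LOG_DELTA_BOUNDS = (-12.0, 12.0)
_GRID_SIZE = 65
_LN10 = np.log(10.0)

ASSOCIATION_COLUMNS = [
    "marker", "chrom", "pos", "maf", "beta", "se", "fstat", "p", "logp", "r2_lr", "n",
]


# ----------------------------------------------------------------- kinship
def compute_kinship(
    genotypes: GenotypeMatrix, exclude_chromosome=None
) -> np.ndarray:
    """Centered cross-product (VanRaden method 1) kinship.

    K = Z Z' / (2 sum p(1-p)) with Z = dosages - 2p, missing dosages
    mean-imputed per marker; markers on ``exclude_chromosome`` are left out.
    """
    cols = np.arange(genotypes.n_markers)
    if exclude_chromosome is not None:
        keep = (genotypes.markers["chrom"] != exclude_chromosome).to_numpy()
        cols = cols[keep]
    x = genotypes.imputed(cols)
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    x = x[:, poly]
    p = p[poly]
    if x.shape[1] < 2:
        raise EstimationError("fewer than 2 polymorphic markers remain for kinship")
    z = x - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    k = (z @ z.T) / denom
    return (k + k.T) / 2.0


def build_kinship_set(genotypes: GenotypeMatrix) -> KinshipSet:
    """Global kinship plus one LOCO matrix per chromosome."""
    chroms = genotypes.chromosomes
    global_k = compute_kinship(genotypes)
    loco, used = {}, {}
    for c in chroms:
        if len(chroms) == 1:
            raise EstimationError("LOCO kinship needs at least 2 chromosomes")
        loco[c] = compute_kinship(genotypes, exclude_chromosome=c)
        used[c] = int((genotypes.markers["chrom"] != c).sum())
    return KinshipSet(lines=list(genotypes.lines), global_k=global_k, loco=loco, n_markers_used=used)


# ------------------------------------------------------------ spectral REML
def _spectral_profile(lam, yr, Xr, log_delta, reml, n):
    """(-2 loglik, aux) of the variance-ratio profile at one log(delta)."""
    d = np.exp(log_delta)
    w = 1.0 / (lam + d)
    Xw = Xr * w[:, None]
    A = Xw.T @ Xr
    b = Xw.T @ yr
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None
    r = yr - Xr @ beta
    rss = float(np.sum(w * r * r))
    rss = max(rss, 1e-300)
    p = Xr.shape[1]
    sum_log = float(np.sum(np.log(lam + d)))
    if reml:
        sg2 = rss / (n - p)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None
        crit = (n - p) * np.log(2 * np.pi * sg2) + (n - p) + sum_log + logdet_a
    else:
        sg2 = rss / n
        crit = n * np.log(2 * np.pi * sg2) + n + sum_log
    return crit, (beta, sg2, d)


def _fit_spectral(lam, yr, Xr, n, reml=True):
    grid = np.linspace(*LOG_DELTA_BOUNDS, _GRID_SIZE)
    vals = np.array([_spectral_profile(lam, yr, Xr, g, reml, n)[0] for g in grid])
    k = int(np.argmin(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: _spectral_profile(lam, yr, Xr, t, reml, n)[0],
        bounds=(a, b), method="bounded", options={"xatol": 1e-8},
    )
    best = res.x if res.fun <= vals[k] else grid[k]
    crit, payload = _spectral_profile(lam, yr, Xr, best, reml, n)
    if payload is None:
        raise EstimationError("spectral REML failed to evaluate at the optimum")
    beta, sg2, d = payload
    return {
        "beta": beta, "sigma_g2": sg2, "delta": d, "minus2ll": crit,
        "loglik": -0.5 * crit, "converged": bool(np.isfinite(crit)),
    }


def fit_null(
    trait,
    kinship: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    method: str = "reml",
) -> VarianceComponents:
    """REML (or ML) variance components of the polygenic null model.

    ``trait`` is a vector aligned with the kinship's line order; an intercept
    is always included, plus optional fixed covariates.
    """
    y = np.asarray(trait, float)
    n = len(y)
    if kinship.shape != (n, n):
        raise DesignError("kinship dimension does not match the trait")
    X = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("covariate design matrix is rank deficient")
    if np.ptp(y) == 0.0:
        return VarianceComponents(0.0, 0.0, float("nan"), False, n)
    lam, U = _eigh_checked(kinship)
    yr, Xr = U.T @ y, U.T @ X
    fit = _fit_spectral(lam, yr, Xr, n, reml=(method == "reml"))
    sg2 = fit["sigma_g2"]
    return VarianceComponents(
        sigma_g2=float(sg2),
        sigma_e2=float(fit["delta"] * sg2),
        loglik_reml=float(fit["loglik"]),
        converged=fit["converged"],
        n=n,
    )


def _eigh_checked(kinship: np.ndarray, tol: float = 1e-8) -> tuple:
    lam, U = np.linalg.eigh((kinship + kinship.T) / 2.0)
    scale = max(float(lam[-1]), 1.0)
    if lam[0] < -tol * scale:
        raise EstimationError(f"kinship is not PSD within tolerance (min eigenvalue {lam[0]:.3g})")
    return np.maximum(lam, 0.0), U


# ------------------------------------------------------------------- scan
@dataclass
class ScanConfig:
    """Marker filters, significance threshold, and model options of a scan."""

    maf_min: float = 0.05
    logp_threshold: float = 5.0
    covariate_markers: Sequence[str] = field(default_factory=tuple)
    effect_allele: str = "alt"  # report beta for the alternate ("alt") or reference ("ref") allele
    refit_per_marker: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ConfigurationError("maf_min: must lie in [0, 0.5)")
        if self.logp_threshold <= 0:
            raise ConfigurationError("logp_threshold: must be positive")
        if self.effect_allele not in ("alt", "ref"):
            raise ConfigurationError("effect_allele: must be 'alt' or 'ref'")


def scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    kinships: KinshipSet,
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Genome scan of one trait; returns one association record per marker.

    Markers with MAF <= maf_min are skipped (counted in
    ``result.attrs['n_skipped_maf']``); a tested marker collinear with the
    covariates is emitted with missing statistics, not dropped.
    """
    trait = pd.Series(trait).dropna()
    line_pos = {l: i for i, l in enumerate(kinships.lines)}
    unknown = [l for l in trait.index if l not in line_pos]
    if unknown:
        raise UnknownIdentifierError(f"trait lines not in the kinship set: {unknown[:5]}")
    used_lines = [l for l in kinships.lines if l in set(trait.index)]
    geno = genotypes if used_lines == genotypes.lines else genotypes.subset_lines(used_lines)
    y = trait.reindex(used_lines).to_numpy(float)
    krows = np.array([line_pos[l] for l in used_lines])
    n = len(y)

    for mid in config.covariate_markers:
        genotypes.marker_index(mid)  # raises on unknown ids
    cov = (
        np.column_stack([geno.dosage(m, imputed=True) for m in config.covariate_markers])
        if config.covariate_markers
        else None
    )
    X0 = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise DesignError("covariate design matrix is rank deficient")

    p_alt = geno.alt_freq()
    maf = np.minimum(p_alt, 1.0 - p_alt)
    frames = []
    n_skipped_maf = 0
    n_monomorphic = 0
    for chrom in geno.chromosomes:
        cols = geno.markers_on(chrom)
        mono = (p_alt[cols] <= 0.0) | (p_alt[cols] >= 1.0) | np.isnan(p_alt[cols])
        n_monomorphic += int(mono.sum())
        low = maf[cols] <= config.maf_min
        n_skipped_maf += int((low & ~mono).sum())
        cols = cols[~(mono | low)]
        if cols.size == 0:
            continue
        K = kinships.for_chrom(chrom)[np.ix_(krows, krows)]
        frames.append(
            _scan_chromosome(y, geno, cols, K, X0, config, n)
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    out.attrs["n_skipped_maf"] = n_skipped_maf
    out.attrs["n_monomorphic"] = n_monomorphic
    out.attrs["n_lines"] = n
    return out


def _scan_chromosome(y, geno, cols, K, X0, config, n) -> pd.DataFrame:
    lam, U = _eigh_checked(K)
    yr, X0r = U.T @ y, U.T @ X0
    null = _fit_spectral(lam, yr, X0r, n, reml=True)
    delta = null["delta"]
    w = 1.0 / (lam + delta)
    sw = np.sqrt(w)

    G = geno.imputed(cols)
    Gr = (U.T @ G) * sw[:, None]
    ys = yr * sw
    A0 = X0r * sw[:, None]
    Q, _ = np.linalg.qr(A0)
    ytil = ys - Q @ (Q.T @ ys)
    Gtil = Gr - Q @ (Q.T @ Gr)
    rss0 = float(ytil @ ytil)
    gs2 = np.sum(Gr * Gr, axis=0)
    xtx = np.sum(Gtil * Gtil, axis=0)
    xty = Gtil.T @ ytil
    collinear = xtx <= 1e-10 * np.maximum(gs2, 1e-300)

    p0 = X0.shape[1]
    dof = n - p0 - 1
    if dof <= 0:
        raise EstimationError("not enough lines for the marker test")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(collinear, np.nan, xty / xtx)
        rss1 = np.maximum(rss0 - xty * beta, 1e-300)
        fstat = np.where(collinear, np.nan, (rss0 - rss1) / (rss1 / dof))
        se = np.where(collinear, np.nan, np.sqrt(rss1 / dof / xtx))
        logsf = stats.f.logsf(fstat, 1, dof)
        logp = np.where(collinear, np.nan, -logsf / _LN10)
        pval = np.where(collinear, np.nan, np.exp(logsf))
        r2 = np.where(collinear, np.nan, np.clip(1.0 - rss1 / rss0, 0.0, 1.0))

    if config.refit_per_marker:
        beta, se, fstat, pval, logp, r2 = _refit_markers(
            lam, yr, X0r, (U.T @ G), n, null, collinear
        )

    if config.effect_allele == "ref":
        beta = -beta

    sub = geno.markers.iloc[cols]
    maf = np.minimum(geno.alt_freq()[cols], 1.0 - geno.alt_freq()[cols])
    return pd.DataFrame(
        {
            "marker": sub["marker"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "maf": maf,
            "beta": beta,
            "se": se,
            "fstat": fstat,
            "p": pval,
            "logp": logp,
            "r2_lr": r2,
            "n": n,
        }
    )


def _refit_markers(lam, yr, X0r, Gr_unw, n, null, collinear):
    """Exact per-marker REML refit (slow path behind ScanConfig.refit_per_marker)."""
    m = Gr_unw.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    fstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    logp = np.full(m, np.nan)
    r2 = np.full(m, np.nan)
    p0 = X0r.shape[1]
    dof = n - p0 - 1
    for j in range(m):
        if collinear[j]:
            continue
        Xr = np.column_stack([X0r, Gr_unw[:, j]])
        fit = _fit_spectral(lam, yr, Xr, n, reml=True)
        d = fit["delta"]
        w = 1.0 / (lam + d)
        A = (Xr * w[:, None]).T @ Xr
        b = (Xr * w[:, None]).T @ yr
        bb = np.linalg.solve(A, b)
        r = yr - Xr @ bb
        rss = float(np.sum(w * r * r))
        sg2 = rss / dof
        cov = sg2 * np.linalg.inv(A)
        beta[j] = bb[-1]
        se[j] = np.sqrt(cov[-1, -1])
        fstat[j] = (bb[-1] / se[j]) ** 2
        ls = stats.f.logsf(fstat[j], 1, dof)
        logp[j] = -ls / _LN10
        pval[j] = np.exp(ls)
        # ML likelihood ratio at this marker's delta against the null
        wn = 1.0 / (lam + d)
        An = (X0r * wn[:, None]).T @ X0r
        bn = (X0r * wn[:, None]).T @ yr
        b0 = np.linalg.solve(An, bn)
        rn = yr - X0r @ b0
        rss0 = float(np.sum(wn * rn * rn))
        r2[j] = np.clip(1.0 - rss / rss0, 0.0, 1.0)
    return beta, se, fstat, pval, logp, r2


def conditional_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    kinships: KinshipSet,
    config: ScanConfig,
) -> pd.DataFrame:
    """Scan with one or more marker dosages in the fixed-effect design.

    Testing a marker identical to (or collinear with) a covariate yields a
    record with missing statistics.
    """
    if not config.covariate_markers:
        raise ConfigurationError("covariate_markers: conditional_scan needs at least one covariate")
    return scan(trait, genotypes, kinships, config)


def subpanel_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    line_mask,
    config: ScanConfig = ScanConfig(),
    min_lines: int = 30,
) -> pd.DataFrame:
    """Scan restricted to a subset of lines.

    Kinship and variance components are re-derived on the retained lines;
    the scan contract is otherwise unchanged.
    """
    mask = np.asarray(line_mask)
    if mask.dtype == bool:
        retained = [l for l, keep in zip(genotypes.lines, mask) if keep]
    else:
        retained = [l for l in genotypes.lines if l in set(mask)]
    if len(retained) < min_lines:
        raise EstimationError(f"subpanel retains {len(retained)} lines; need >= {min_lines}")
    sub = genotypes.subset_lines(retained)
    kin = build_kinship_set(sub)
    return scan(trait.reindex(retained).dropna(), sub, kin, config)


def r2_lr(null_fit: VarianceComponents, marker_fit: VarianceComponents, n_lines: int) -> float:
    """Likelihood-ratio variance-explained estimate of a marker.

    r2_LR = 1 - exp(-(2/n)(LL_marker - LL_null)), clipped to [0, 1]; both
    fits must be on the same observations.
    """
    if null_fit.n != marker_fit.n or null_fit.n != n_lines:
        raise DesignError("r2_lr: the two fits must share the same observation set")
    return float(np.clip(1.0 - np.exp(-2.0 / n_lines * (marker_fit.loglik_reml - null_fit.loglik_reml)), 0.0, 1.0))


def genomic_control_lambda(pvalues) -> float:
    """Median-based genomic inflation factor of a set of p-values."""
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
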