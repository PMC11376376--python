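"""Ratiometric dual-fluorescence reporter assay and its 2x2 mixed model.

Each transiently transformed cell yields a reporter (promoter-driven) and a
normalizer (constitutive) total fluorescence intensity; the response is
log2(reporter/normalizer), which cancels transformation efficiency. The
experimental design crosses promoter background (B73 vs PH207) with the
presence/absence of the promoter indel, replicated over independent
bombardment experiments. The model is

    log2 ratio ~ background * indel  +  (1 | experiment)

fit by REML with a random intercept per experiment; fixed effects use
treatment coding with B73/absent as reference levels, so the indel effect
reads as the deviation caused by its presence. Wald t-tests with residual
degrees of freedom are the default; a likelihood-ratio alternative (ML fits)
is available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_random_intercept
from .exceptions import ConfigurationError, DesignError

logger = logging.getLogger(__name__)

CELL_COLUMNS = ("experiment", "background", "indel", "reporter", "normalizer")
BACKGROUNDS = ("B73", "PH207")
INDEL_LEVELS = ("absent", "present")


def cell_log_ratio(reporter, normalizer):
    """log2(reporter/normalizer) per cell.

    ``normalizer`` must be positive (records violating this are rejected);
    a zero reporter yields NaN with a warning rather than -inf.
    """
    reporter = np.asarray(reporter, float)
    normalizer = np.asarray(normalizer, float)
    if np.any(normalizer <= 0):
        raise ConfigurationError("normalizer: total intensity must be > 0")
    if np.any(reporter < 0):
        raise ConfigurationError("reporter: total intensity must be >= 0")
    zero = reporter == 0
    if np.any(zero):
        logger.warning("%d cells with zero reporter intensity set to missing", int(np.sum(zero)))
    with np.errstate(divide="ignore"):
        out = np.log2(reporter / normalizer)
    return np.where(zero, np.nan, out)


@dataclass
class AssayModelFit:
    """Fixed effects, random-intercept variance and tests of the 2x2 model."""

    effects: dict  # term -> {estimate, se, t, p}
    random_intercept_var: float
    residual_var: float
    n_cells: int
    n_experiments: int
    method: str

    def pvalue(self, term: str) -> float:
        return self.effects[term]["p"]

    def estimate(self, term: str) -> float:
        return self.effects[term]["estimate"]


_TERMS = ("intercept", "background", "indel", "interaction")


def _design(cells: pd.DataFrame) -> np.ndarray:
    bg = (cells["background"].astype(str) == BACKGROUNDS[1]).to_numpy(float)
    ind = (cells["indel"].astype(str) == INDEL_LEVELS[1]).to_numpy(float)
    return np.column_stack([np.ones(len(cells)), bg, ind, bg * ind])


def fit_assay_model(cells: pd.DataFrame, method: str = "wald") -> AssayModelFit:
    """Fit log2 ratio ~ background * indel + (1 | experiment) by REML.

    Requires >= 2 experiments and all four background x indel combinations;
    a missing combination raises a design error naming the empty cell.
    ``method='lrt'`` replaces the Wald p-values by likelihood-ratio tests of
    ML fits dropping one term at a time (the interaction first, then each
    main effect from the additive model).
    """
    missing_cols = set(CELL_COLUMNS) - set(cells.columns)
    if missing_cols and "log_ratio" not in cells.columns:
        raise ConfigurationError(f"cell table lacks columns {sorted(missing_cols)}")
    cells = cells.copy()
    if "log_ratio" not in cells.columns:
        cells["log_ratio"] = cell_log_ratio(cells["reporter"], cells["normalizer"])
    cells = cells.dropna(subset=["log_ratio"])
    for bg in BACKGROUNDS:
        for ind in INDEL_LEVELS:
            if not (
                (cells["background"].astype(str) == bg) & (cells["indel"].astype(str) == ind)
            ).any():
                raise DesignError(f"assay design is missing the {bg} x {ind} combination")
    if cells["experiment"].nunique() < 2:
        raise DesignError("assay model needs >= 2 independent experiments")

    y = cells["log_ratio"].to_numpy(float)
    X = _design(cells)
    groups = cells["experiment"].to_numpy()
    fit = fit_random_intercept(y, X, groups, reml=True)
    effects = fit.wald_table(_TERMS)

    if method == "lrt":
        full_ml = fit_random_intercept(y, X, groups, reml=False)
        # interaction: full vs additive; main effects: additive vs reduced
        additive = X[:, :3]
        add_ml = fit_random_intercept(y, additive, groups, reml=False)
        lrt = {"interaction": 2.0 * (full_ml.loglik - add_ml.loglik)}
        for term, col in (("background", 1), ("indel", 2)):
            reduced = additive[:, [c for c in range(3) if c != col]]
            red_ml = fit_random_intercept(y, reduced, groups, reml=False)
            lrt[term] = 2.0 * (add_ml.loglik - red_ml.loglik)
        for term, lr in lrt.items():
            effects[term]["p"] = float(stats.chi2.sf(max(lr, 0.0), df=1))
    elif method != "wald":
        raise ConfigurationError("method: must be 'wald' or 'lrt'")

    return AssayModelFit(
        effects=effects,
        random_intercept_var=fit.sigma_u2,
        residual_var=fit.sigma_e2,
        n_cells=fit.n_obs,
        n_experiments=fit.n_groups,
        method=method,
    )


def simulate_assay(
    background_effect: float = 0.0,
    indel_effect: float = -0.5,
    interaction: float = 0.0,
    n_experiments: int = 3,
    n_cells: int = 40,
    experiment_sd: float = 0.3,
    residual_sd: float = 0.6,
    baseline: float = -0.5,
    normalizer_mean: float = 1000.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate per-cell reporter/normalizer intensities from the 2x2 model.

    log2 ratios follow the fitted model's generative form (fixed effects +
    experiment random intercept + residual); intensities are back-computed
    around a log-normal normalizer so ``cell_log_ratio`` recovers the ratios
    exactly. Deterministic given the rng/seed.
    """
    if experiment_sd < 0 or residual_sd < 0:
        raise ConfigurationError("experiment_sd/residual_sd: must be >= 0")
    if n_experiments < 1 or n_cells < 1:
        raise ConfigurationError("n_experiments/n_cells: must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for e in range(1, n_experiments + 1):
        u = rng.normal(0.0, experiment_sd)
        for bg_i, bg in enumerate(BACKGROUNDS):
            for ind_i, ind in enumerate(INDEL_LEVELS):
                mu = (
                    baseline
                    + background_effect * bg_i
                    + indel_effect * ind_i
                    + interaction * bg_i * ind_i
                    + u
                )
                ratio = mu + rng.normal(0.0, residual_sd, n_cells)
                normalizer = np.exp(rng.normal(np.log(normalizer_mean), 0.3, n_cells))
                rows.append(
                    pd.DataFrame(
                        {
                            "experiment": f"exp{e}",
                            "background": bg,
                            "indel": ind,
                            "reporter": normalizer * np.exp2(ratio),
                            "normalizer": normalizer,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)
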