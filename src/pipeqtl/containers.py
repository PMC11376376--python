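"""Shared in-memory containers.

The pipeline's tabular data (Ct tables, expression tables, association
results) travel as pandas DataFrames with documented column contracts; the
containers here hold the objects that need invariants or indexed access
beyond what a flat table provides.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UnknownIdentifierError

#: required columns of the marker map carried by :class:`GenotypeMatrix`
MARKER_COLUMNS = ("marker", "chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with its marker map.

    Dosages count copies of the alternate allele (0, 1 or 2); missing calls
    are NaN. ``markers`` is a DataFrame with columns ``marker, chrom, pos,
    ref, alt``, sorted by (chrom, pos) with 1-based positions strictly
    increasing within each chromosome.
    """

    dosages: np.ndarray
    lines: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.lines = list(self.lines)
        self.markers = self.markers.reset_index(drop=True)
        missing_cols = set(MARKER_COLUMNS) - set(self.markers.columns)
        if missing_cols:
            raise ConfigurationError(f"marker map lacks columns {sorted(missing_cols)}")
        if self.dosages.shape != (len(self.lines), len(self.markers)):
            raise ConfigurationError(
                f"dosages shape {self.dosages.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        for _, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError("marker positions must be strictly increasing per chromosome")
        self._marker_index = {m: i for i, m in enumerate(self.markers["marker"])}
        self._line_index = {l: i for i, l in enumerate(self.lines)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.markers["chrom"]))

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise UnknownIdentifierError(f"unknown marker id {marker_id!r}") from None

    def markers_on(self, chrom) -> np.ndarray:
        """Column indices of markers on one chromosome, in position order."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    # -- dosage access --------------------------------------------------
    def dosage(self, marker_id: str, imputed: bool = False) -> np.ndarray:
        j = self.marker_index(marker_id)
        x = self.dosages[:, j].copy()
        if imputed:
            m = np.isnan(x)
            if m.any():
                fill = np.nanmean(x) if not np.all(m) else 0.0
                x[m] = fill
        return x

    def imputed(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Dosages with per-marker mean imputation of missing calls."""
        x = self.dosages if columns is None else self.dosages[:, columns]
        x = x.copy()
        col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(x))
        x[nan_r, nan_c] = col_mean[nan_c]
        return x

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker (missing calls ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting -----------------------------------------------------
    def subset_lines(self, keep: Sequence) -> "GenotypeMatrix":
        """Restrict to a subset of lines (bool mask or sequence of line ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = np.array([self._line_index[l] for l in keep])
        return GenotypeMatrix(self.dosages[idx], [self.lines[i] for i in idx], self.markers.copy())

    def subset_markers(self, columns: np.ndarray) -> "GenotypeMatrix":
        columns = np.asarray(columns)
        return GenotypeMatrix(
            self.dosages[:, columns], list(self.lines), self.markers.iloc[columns].copy()
        )


@dataclass(frozen=True)
class GeneModel:
    """Transcribed interval of a gene, 1-based inclusive."""

    gene_id: str
    chrom: object
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"gene {self.gene_id}: start > end")


@dataclass
class KinshipSet:
    """Global kinship plus leave-one-chromosome-out (LOCO) matrices.

    ``loco[c]`` excludes all markers on chromosome ``c`` and is the matrix to
    use when testing markers of that chromosome, so the tested signal is not
    absorbed by the polygenic term.
    """

    lines: list[str]
    global_k: np.ndarray
    loco: dict
    n_markers_used: dict = field(default_factory=dict)

    def for_chrom(self, chrom) -> np.ndarray:
        return self.loco.get(chrom, self.global_k)


@dataclass
class VarianceComponents:
    """REML variance components of the polygenic null model."""

    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    converged: bool
    n: int

    @property
    def delta(self) -> float:
        """Noise-to-genetic variance ratio sigma_e^2 / sigma_g^2."""
        if self.sigma_g2 <= 0:
            return np.inf
        return self.sigma_e2 / self.sigma_g2

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot <= 0 else self.sigma_g2 / tot
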