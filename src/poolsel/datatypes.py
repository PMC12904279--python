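"""Core data containers shared across the pipeline.

Conventions: strains are clonal haploids, so genotype dosages are 0
(reference allele), 1 (alternate allele) or NaN (missing call).
Coordinates are 1-based on the way in and out of VCF; all in-memory
indexing is 0-based. Frequencies live on the simplex over strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_REPLICONS = ("chromosome", "pSymA", "pSymB")

#: required columns of a per-variant metadata table
VARIANT_COLUMNS = ("replicon", "pos", "ld_group")


class ValidationError(ValueError):
    """An input table violates the data model."""


class UnidentifiableStrainsWarning(UserWarning):
    """Strains with identical genotype rows cannot be told apart."""


@dataclass
class StrainGenotypeMatrix:
    """Known reference panel of strain genotypes.

    Parameters
    ----------
    calls
        strains x variants DataFrame of dosages in {0.0, 1.0, NaN}.
    variants
        Per-variant metadata indexed by variant id with columns
        ``replicon``, ``pos`` (1-based) and ``ld_group``.
    replicon_set
        Allowed replicon labels; defaults to the three *S. meliloti*
        replicons (chromosome, pSymA, pSymB).
    """

    calls: pd.DataFrame
    variants: pd.DataFrame
    replicon_set: tuple = DEFAULT_REPLICONS

    def __post_init__(self) -> None:
        if self.calls.index.duplicated().any():
            raise ValidationError("duplicate strain ids")
        if self.calls.columns.duplicated().any():
            raise ValidationError("duplicate variant ids")
        if not self.calls.columns.equals(self.variants.index):
            self.variants = self.variants.reindex(self.calls.columns)
            if self.variants.isna().all(axis=1).any():
                raise ValidationError("variant metadata missing for some variants")
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValidationError(f"variant table lacks column {col!r}")
        bad = set(self.variants["replicon"]) - set(self.replicon_set)
        if bad:
            raise ValidationError(f"unknown replicon label(s): {sorted(bad)}")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValidationError("genotype dosages must be 0, 1 or missing")

    # -- basic accessors -------------------------------------------------
    @property
    def strain_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_strains(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def ld_map(self) -> pd.Series:
        """variant id -> LD group id."""
        return self.variants["ld_group"]

    # -- summaries -------------------------------------------------------
    def alt_freq(self) -> pd.Series:
        """Alternate-allele frequency among non-missing strains."""
        return self.calls.mean(axis=0, skipna=True)

    def maf(self) -> pd.Series:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missingness(self) -> pd.Series:
        return self.calls.isna().mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_variants(self, ids: Sequence) -> "StrainGenotypeMatrix":
        ids = pd.Index(ids)
        return StrainGenotypeMatrix(
            self.calls.loc[:, ids], self.variants.loc[ids], self.replicon_set
        )

    def subset_strains(self, ids: Sequence) -> "StrainGenotypeMatrix":
        ids = pd.Index(ids)
        return StrainGenotypeMatrix(
            self.calls.loc[ids], self.variants, self.replicon_set
        )

    def for_replicon(self, replicon: str) -> "StrainGenotypeMatrix":
        keep = self.variants.index[self.variants["replicon"] == replicon]
        return self.subset_variants(keep)

    def dosage(self, impute: bool = False) -> np.ndarray:
        """Dosage matrix; optionally mean-impute missing entries per variant."""
        g = self.calls.to_numpy(dtype=float)
        if impute and np.isnan(g).any():
            col_mean = np.nanmean(g, axis=0)
            idx = np.where(np.isnan(g))
            g = g.copy()
            g[idx] = np.take(col_mean, idx[1])
        return g


@dataclass
class PooledCounts:
    """Pooled allele counts for one sequenced sample."""

    sample_id: str
    counts: pd.DataFrame  # index variant id; columns ref_count, alt_count

    def __post_init__(self) -> None:
        for col in ("ref_count", "alt_count"):
            if col not in self.counts.columns:
                raise ValidationError(f"counts table lacks column {col!r}")
        vals = self.counts[["ref_count", "alt_count"]].to_numpy()
        if (vals < 0).any():
            raise ValidationError(f"negative counts in sample {self.sample_id}")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("read counts must be integers")
        self.counts = self.counts.astype({"ref_count": int, "alt_count": int})

    @property
    def variant_ids(self) -> pd.Index:
        return self.counts.index

    def depth(self) -> pd.Series:
        return self.counts["ref_count"] + self.counts["alt_count"]


@dataclass
class FrequencyEstimate:
    """Per-sample strain-frequency estimate with fit metadata."""

    sample_id: str
    freqs: pd.Series  # simplex over strains
    loglik: float
    n_iter: int
    converged: bool
    depth_summary: Mapping[str, float] = field(default_factory=dict)
    unidentifiable: tuple = ()  # groups of strains sharing a genotype row

    def __post_init__(self) -> None:
        f = self.freqs.to_numpy()
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
            raise ValidationError("frequency estimate is not on the simplex")


@dataclass
class FitnessTable:
    """Relative strain fitness w = log2(final/initial), strains x samples."""

    w: pd.DataFrame
    floored: pd.DataFrame  # True where final frequency was 0 and the floor applied
    host_genotype: pd.Series  # sample id -> host genotype
    floor: float = -8.0


@dataclass
class ShiftTable:
    """Fitness shifts Delta w (mutant minus wild type), strains x mutants."""

    shifts: pd.DataFrame
    aggregate: str  # "mean" or "median" across replicates
    any_floored: pd.DataFrame | None = None


@dataclass
class KinshipMatrix:
    """Strain x strain relatedness used as random-effect covariance."""

    matrix: pd.DataFrame
    replicon: str | None = None
    mode: str = "centered-standardized"

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("kinship matrix must be symmetric")


@dataclass
class LMMFit:
    """Single-variant mixed-model fit."""

    variant: str
    beta: float
    se: float
    wald_stat: float
    p_value: float
    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    converged: bool = True


@dataclass
class AssociationResult:
    """One GWAS table: a response (host shift or host fitness) on one replicon."""

    response: str
    replicon: str
    table: pd.DataFrame  # index variant or group id; beta, se, wald, p, rank
    level: str = "variant"  # or "group"

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values(["p", "sort_key"] if "sort_key" in self.table else "p")


@dataclass
class RDAResult:
    """Constrained-ordination summary with permutation test."""

    term: str
    constrained_inertia: float
    total_inertia: float
    r2: float
    adj_r2: float
    pseudo_f: float
    permutation_p: float
    n_perm: int
    axis_scores: pd.DataFrame | None = None


@dataclass
class ModelComparison:
    """Adjusted-R2 comparison of genotype+block vs stage+block models."""

    table: pd.DataFrame  # index trait; adj_r2_genotype, adj_r2_stage, winner


@dataclass
class PervasivenessReport:
    """Cross-GWAS candidate classification."""

    table: pd.DataFrame
    top: int = 10
    min_hosts: int = 6
    p_threshold: float = 1e-5
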