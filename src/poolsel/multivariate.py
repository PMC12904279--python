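"""Host-trait models, Tukey contrasts, constrained ordination and PCA.

Univariate traits get two additive least-squares models -- host
genotype + block, and symbiotic stage + block -- compared only via
adjusted R^2 (genotypes are nested within stage, so nesting the
predictors in one model would be collinear). The multivariate
strain-fitness matrix is analysed by redundancy analysis (RDA):
column-centered responses projected onto the factor's dummy space,
with significance from an unrestricted row-permutation ANOVA.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .datatypes import ModelComparison, RDAResult

__all__ = [
    "fit_trait_models",
    "tukey_pairwise",
    "rda_permanova",
    "pairwise_rda_contrasts",
    "trait_pca",
    "genotype_correlations",
]

#: traits log10-transformed before modelling (heteroscedasticity control)
LOG_TRAITS = ("avg_nodule_area", "total_nodule_area")


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _check_full_rank(fit, label: str) -> None:
    x = fit.model.exog
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(f"rank-deficient design for {label}: aliased terms present")


def fit_trait_models(
    traits: pd.DataFrame,
    stage_map: Mapping[str, str],
    trait_columns: Sequence[str] | None = None,
) -> ModelComparison:
    """Adjusted-R^2 comparison of genotype+block vs stage+block per trait.

    ``traits`` holds one row per pot with columns ``host_genotype``,
    ``block`` and the trait values; ``stage_map`` assigns each host
    genotype its symbiotic-stage category.
    """
    df = traits.copy()
    if df["host_genotype"].nunique() < 2 or df["block"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and >= 2 blocks")
    df["stage"] = df["host_genotype"].map(dict(stage_map))
    if df["stage"].isna().any():
        raise ValueError("stage_map does not cover all host genotypes")
    if trait_columns is None:
        trait_columns = [
            c for c in df.columns
            if c not in ("host_genotype", "block", "stage", "n_plants")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    rows = {}
    for trait in trait_columns:
        d = df[["host_genotype", "block", "stage", trait]].dropna().copy()
        d["y"] = np.log10(d[trait]) if trait in LOG_TRAITS else d[trait]
        fit_g = smf.ols("y ~ C(host_genotype) + C(block)", data=d).fit()
        fit_s = smf.ols("y ~ C(stage) + C(block)", data=d).fit()
        _check_full_rank(fit_g, f"{trait} ~ genotype + block")
        _check_full_rank(fit_s, f"{trait} ~ stage + block")
        ag, as_ = fit_g.rsquared_adj, fit_s.rsquared_adj
        rows[trait] = {
            "adj_r2_genotype": ag,
            "adj_r2_stage": as_,
            "winner": "genotype" if ag > as_ else "stage",
        }
    return ModelComparison(table=pd.DataFrame(rows).T)


def tukey_pairwise(
    traits: pd.DataFrame,
    trait: str,
    wildtype: str,
    log10: bool | None = None,
) -> pd.DataFrame:
    """Tukey-HSD-adjusted mutant-vs-wild-type contrasts from the
    genotype+block model.

    Adjusted p uses the studentized-range distribution with k = number
    of genotype levels and the model's residual df (for two groups this
    reduces to the two-sample t-test, since q = |t| sqrt(2)).
    Genotypes with fewer than two replicates are flagged, not tested.
    """
    d = traits[["host_genotype", "block", trait]].dropna().copy()
    if log10 is None:
        log10 = trait in LOG_TRAITS
    d["y"] = np.log10(d[trait]) if log10 else d[trait]
    fit = smf.ols(
        f"y ~ C(host_genotype, Treatment(reference={wildtype!r})) + C(block)", data=d
    ).fit()
    _check_full_rank(fit, f"{trait} ~ genotype + block")
    k = d["host_genotype"].nunique()
    df_resid = fit.df_resid
    counts = d["host_genotype"].value_counts()
    rows = []
    prefix = f"C(host_genotype, Treatment(reference={wildtype!r}))[T."
    for name, coef in fit.params.items():
        if not name.startswith(prefix):
            continue
        genotype = name[len(prefix):-1]
        if counts.get(genotype, 0) < 2 or counts.get(wildtype, 0) < 2:
            rows.append((genotype, np.nan, np.nan, np.nan, np.nan, True))
            continue
        se = fit.bse[name]
        t = coef / se
        q = abs(t) * np.sqrt(2.0)
        p_adj = float(np.clip(stats.studentized_range.sf(q, k, df_resid), 0.0, 1.0))
        rows.append((genotype, coef, se, t, p_adj, False))
    return pd.DataFrame(
        rows, columns=["genotype", "estimate", "se", "t", "p_adj", "flagged"]
    ).set_index("genotype").assign(significant=lambda x: x["p_adj"] < 0.05)


def _factor_projection(x: pd.Series):
    dummies = pd.get_dummies(x, dtype=float)
    xc = dummies.to_numpy() - dummies.to_numpy().mean(axis=0)
    q, r = np.linalg.qr(xc)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]  # orthonormal basis, rank = levels - 1


def rda_permanova(
    y: pd.DataFrame,
    x: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    term: str | None = None,
    blocks: pd.Series | None = None,
    return_scores: bool = True,
) -> RDAResult:
    """RDA of a samples x strains response matrix on one factor.

    Constrained inertia is the squared norm of the projection of the
    column-centered Y onto the factor's (centered) dummy space; the
    permutation ANOVA permutes sample rows of Y (unrestricted by
    default, within ``blocks`` when given) and counts pseudo-F values
    at least as large as observed: p = (1 + #exceed)/(n_perm + 1).
    """
    x = x.reindex(y.index)
    if x.isna().any():
        raise ValueError("factor missing for some samples")
    levels = pd.unique(x)
    if len(levels) < 2:
        raise ValueError("factor must have >= 2 levels")
    sizes = x.value_counts()
    if (sizes == 1).any():
        warnings.warn(
            f"factor level(s) with a single sample: {list(sizes.index[sizes == 1])}",
            stacklevel=2,
        )
    yc = y.to_numpy(dtype=float)
    yc = yc - yc.mean(axis=0)
    total = float((yc**2).sum())
    q = _factor_projection(x)
    df1 = q.shape[1]
    n = yc.shape[0]
    df2 = n - df1 - 1

    def constrained(ymat):
        proj = q.T @ ymat
        return float((proj**2).sum())

    con = constrained(yc)
    r2 = con / total if total > 0 else 0.0
    resid = max(total - con, 0.0)  # clamp float noise on exact fits
    f_obs = np.inf if resid <= 1e-12 * max(total, 1.0) or df2 <= 0 else (
        (con / df1) / (resid / df2)
    )
    # with total inertia permutation-invariant, pseudo-F >= F_obs is
    # equivalent to constrained inertia >= observed: compare inertias
    rng = np.random.default_rng(seed)
    exceed = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        if blocks is None:
            perm = rng.permutation(idx)
        else:
            perm = idx.copy()
            for _, members in pd.Series(idx, index=y.index).groupby(
                blocks.reindex(y.index)
            ):
                vals = members.to_numpy()
                perm[vals] = rng.permutation(vals)
        if constrained(yc[perm]) >= con - 1e-12 * max(total, 1.0):
            exceed += 1
    p_perm = (1 + exceed) / (n_perm + 1)
    scores = None
    if return_scores:
        fitted = q @ (q.T @ yc)
        u, s, _ = np.linalg.svd(fitted, full_matrices=False)
        n_axes = int((s > 1e-10).sum())
        scores = pd.DataFrame(
            u[:, :n_axes] * s[:n_axes],
            index=y.index,
            columns=[f"RDA{i+1}" for i in range(n_axes)],
        )
    return RDAResult(
        term=term or (x.name or "factor"),
        constrained_inertia=con,
        total_inertia=total,
        r2=r2,
        adj_r2=_adjusted_r2(r2, n, df1),
        pseudo_f=f_obs,
        permutation_p=p_perm,
        n_perm=n_perm,
        axis_scores=scores,
    )


def pairwise_rda_contrasts(
    y: pd.DataFrame,
    host_genotype: pd.Series,
    wildtype: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, RDAResult]:
    """Mutant-vs-wild-type RDA for every mutant with samples."""
    import logging

    logger = logging.getLogger(__name__)
    hosts = host_genotype.reindex(y.index)
    if (hosts == wildtype).sum() == 0:
        raise ValueError(f"no wild-type ({wildtype!r}) samples present")
    out = {}
    for i, mutant in enumerate(m for m in pd.unique(hosts) if m != wildtype):
        mask = hosts.isin([mutant, wildtype])
        if (hosts == mutant).sum() == 0:  # pragma: no cover - defensive
            logger.info("pairwise_rda_contrasts: %r has no samples; skipped", mutant)
            continue
        out[mutant] = rda_permanova(
            y.loc[mask], hosts.loc[mask], n_perm=n_perm,
            seed=seed + i + 1, term=f"{mutant} vs {wildtype}", return_scores=False,
        )
    return out


def trait_pca(
    table: pd.DataFrame,
    genotype_col: str = "host_genotype",
    average_genotypes: Sequence[str] | str = "incomplete",
) -> dict:
    """PCA of standardized pot-level traits.

    Genotypes listed in ``average_genotypes`` (or, with "incomplete",
    any genotype carrying missing trait values) are collapsed to their
    replicate means before the decomposition so partial data does not
    drop them entirely. Returns scores, loadings (orthonormal) and
    per-axis variance fractions.
    """
    num = table.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("block", "n_plants") if c in table.columns],
        errors="ignore",
    )
    geno = table[genotype_col]
    if average_genotypes == "incomplete":
        incomplete = [g for g, sub in num.groupby(geno) if sub.isna().any().any()]
    else:
        incomplete = list(average_genotypes)
    parts = [num.loc[~geno.isin(incomplete)]]
    labels = [geno.loc[~geno.isin(incomplete)]]
    for g in incomplete:
        parts.append(num.loc[geno == g].mean(skipna=True).to_frame(f"{g}_avg").T)
        labels.append(pd.Series([g], index=[f"{g}_avg"]))
    x = pd.concat(parts)
    geno_out = pd.concat(labels)
    x = x.dropna(axis=0)
    sd = x.std(ddof=1)
    zero = sd[sd == 0].index
    if len(zero):
        warnings.warn(f"trait_pca: dropped zero-variance column(s) {list(zero)}",
                      stacklevel=2)
        x = x.drop(columns=zero)
        sd = sd.drop(zero)
    z = (x - x.mean()) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var_frac = s**2 / (s**2).sum()
    axes = [f"PC{i+1}" for i in range(len(s))]
    return {
        "scores": pd.DataFrame(u * s, index=x.index, columns=axes).assign(
            **{genotype_col: geno_out.reindex(x.index)}
        ),
        "loadings": pd.DataFrame(vt.T, index=x.columns, columns=axes),
        "variance_fractions": pd.Series(var_frac, index=axes),
    }


def genotype_correlations(
    table: pd.DataFrame, genotype_col: str = "host_genotype"
) -> pd.DataFrame:
    """Pearson correlations between traits at genotype means."""
    num = table.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("block", "n_plants") if c in table.columns],
        errors="ignore",
    )
    means = num.groupby(table[genotype_col]).mean()
    if means.shape[0] < 3:
        raise ValueError("need >= 3 genotypes for genotype-mean correlations")
    return means.corr(method="pearson")
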