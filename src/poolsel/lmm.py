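"""Per-replicon linear mixed-model association.

Single-variant model: y = W alpha + x beta + u + eps with
u ~ N(0, sigma_g^2 K) and eps ~ N(0, sigma_e^2 I), fitted by REML on
the eigenbasis of the kinship matrix K (spectral decomposition done
once per response x replicon, so each variant costs a 1-D search over
delta = sigma_e^2 / sigma_g^2). Analyses run separately per replicon
because each replicon of the *S. meliloti* genome carries its own
population structure; K is the centered-standardized realised
relationship matrix of that replicon's variants.

Variance components are re-estimated for every variant (exact-LMM
behaviour); ``per_variant_reml=False`` reuses the null-model delta for
all variants as a faster approximation.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import (
    AssociationResult,
    KinshipMatrix,
    LMMFit,
    StrainGenotypeMatrix,
)

__all__ = [
    "filter_variants",
    "compute_kinship",
    "LMMScanner",
    "fit_lmm_single",
    "run_gwas",
    "collapse_to_ld_groups",
]

logger = logging.getLogger(__name__)

_LOG10_DELTA_RANGE = (-5.0, 5.0)
_N_GRID = 64
_P_FLOOR = 1e-300


def filter_variants(
    genotypes: StrainGenotypeMatrix, maf: float = 0.05, missingness: float = 0.2
) -> StrainGenotypeMatrix:
    """Drop variants with minor-allele frequency < maf or missing fraction > missingness."""
    m = genotypes.maf()
    miss = genotypes.missingness()
    keep = (m >= maf) & (miss <= missingness)
    removed = genotypes.variant_ids[~keep]
    if len(removed):
        logger.info(
            "filter_variants: removed %d of %d variants (maf<%g or missing>%g)",
            len(removed), genotypes.n_variants, maf, missingness,
        )
    if keep.sum() == 0:
        raise ValueError("no variants pass the MAF/missingness filters")
    return genotypes.subset_variants(genotypes.variant_ids[keep])


def compute_kinship(genotypes: StrainGenotypeMatrix) -> KinshipMatrix:
    """Centered-standardized kinship K = Z Z^T / m (missing mean-imputed)."""
    if genotypes.n_variants < 2:
        raise ValueError("need >= 2 variants to estimate kinship")
    z = genotypes.dosage(impute=True)
    z = z - z.mean(axis=0)
    sd = z.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"compute_kinship: dropped {int(zero.sum())} zero-variance column(s)",
            stacklevel=2,
        )
        z = z[:, ~zero]
        sd = sd[~zero]
        if z.shape[1] == 0:
            raise ValueError("all variants have zero variance")
    z = z / sd
    k = z @ z.T / z.shape[1]
    reps = pd.unique(genotypes.variants["replicon"])
    return KinshipMatrix(
        matrix=pd.DataFrame(k, index=genotypes.strain_ids, columns=genotypes.strain_ids),
        replicon=reps[0] if len(reps) == 1 else None,
    )


class LMMScanner:
    """REML machinery for one (response, kinship) pair.

    Eigendecomposes K once; each variant is then a cheap profiled-REML
    search over log10 delta (dense grid pre-scan + bounded Brent
    refinement, robust to the multimodal surfaces small panels can
    produce).
    """

    def __init__(
        self,
        y: pd.Series | np.ndarray,
        kinship: KinshipMatrix | np.ndarray,
        covariates: np.ndarray | None = None,
    ):
        if isinstance(kinship, KinshipMatrix):
            k = kinship.matrix.to_numpy()
        else:
            k = np.asarray(kinship, dtype=float)
        yv = np.asarray(y, dtype=float)
        n = yv.size
        if k.shape != (n, n):
            raise ValueError("kinship dimensions do not match the response")
        if not np.all(np.isfinite(yv)):
            raise ValueError("response contains non-finite values")
        if np.ptp(yv) == 0:
            raise ValueError("degenerate response (constant y)")
        lam, u = np.linalg.eigh(k)
        if lam.min() < -1e-8:
            raise ValueError("kinship matrix is not positive semi-definite")
        self.lam = np.clip(lam, 0.0, None)
        self.u = u
        self.n = n
        self.yt = u.T @ yv
        w = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), covariates]
        )
        self.wt = u.T @ w
        self.p0 = self.wt.shape[1]
        # dense delta grid shared by all variants
        grid = np.logspace(*_LOG10_DELTA_RANGE, _N_GRID)
        self._grid = grid
        self._winv = 1.0 / (self.lam[None, :] + grid[:, None])  # (G, n)
        self._logdet_h = np.log(self.lam[None, :] + grid[:, None]).sum(axis=1)

    # -- profiled REML at one delta -------------------------------------
    def _reml_at(self, delta: float, xt: np.ndarray | None):
        d = self.lam + delta
        w = 1.0 / d
        xmat = self.wt if xt is None else np.column_stack([self.wt, xt])
        p = xmat.shape[1]
        a = xmat.T @ (w[:, None] * xmat)
        b = xmat.T @ (w * self.yt)
        try:
            beta = np.linalg.solve(a, b)
            sign, logdet_a = np.linalg.slogdet(a)
        except np.linalg.LinAlgError:
            return None
        if sign <= 0:
            return None
        quad = float(w @ (self.yt**2) - b @ beta)
        if quad <= 0:
            return None
        npp = self.n - p
        ll = 0.5 * (
            npp * np.log(npp / (2 * np.pi))
            - npp
            - npp * np.log(quad)
            - np.log(d).sum()
            - logdet_a
        )
        return ll, beta, a, quad

    def _grid_scan(self, xt: np.ndarray | None) -> np.ndarray:
        """REML log-likelihood at every grid delta (vectorised)."""
        xmat = self.wt if xt is None else np.column_stack([self.wt, xt])
        p = xmat.shape[1]
        w = self._winv  # (G, n)
        a = np.einsum("gn,np,nq->gpq", w, xmat, xmat)
        b = np.einsum("gn,np,n->gp", w, xmat, self.yt)
        syy = w @ (self.yt**2)
        with np.errstate(all="ignore"):
            beta = np.linalg.solve(a, b[..., None])[..., 0]
            sign, logdet_a = np.linalg.slogdet(a)
            quad = syy - np.einsum("gp,gp->g", b, beta)
            npp = self.n - p
            ll = 0.5 * (
                npp * np.log(npp / (2 * np.pi))
                - npp
                - npp * np.log(quad)
                - self._logdet_h
                - logdet_a
            )
        ll[(sign <= 0) | ~np.isfinite(ll) | (quad <= 0)] = -np.inf
        return ll

    def _optimise_delta(self, xt: np.ndarray | None) -> float | None:
        ll = self._grid_scan(xt)
        if not np.isfinite(ll).any():
            return None
        i = int(np.argmax(ll))
        lo = np.log10(self._grid[max(i - 1, 0)])
        hi = np.log10(self._grid[min(i + 1, _N_GRID - 1)])

        def neg(log10d):
            out = self._reml_at(10.0**log10d, xt)
            return np.inf if out is None else -out[0]

        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded")
        cand = 10.0**res.x
        best = self._reml_at(cand, xt)
        if best is None or best[0] < ll[i]:
            cand = self._grid[i]
        return float(cand)

    def fit(self, x: np.ndarray, variant: str = "x", delta: float | None = None) -> LMMFit:
        """Fit one variant; ``delta`` fixes the variance ratio if given."""
        xv = np.asarray(x, dtype=float)
        if np.isnan(xv).any():
            raise ValueError("variant genotypes must be imputed before fitting")
        xt = self.u.T @ xv
        if delta is None:
            delta = self._optimise_delta(xt)
        if delta is not None:
            out = self._reml_at(delta, xt)
        else:
            out = None
        if out is None:
            return LMMFit(variant, np.nan, np.nan, np.nan, np.nan,
                          np.nan, np.nan, np.nan, -np.inf, converged=False)
        ll, beta, a, quad = out
        p = self.p0 + 1
        sigma_g2 = quad / (self.n - p)
        cov = np.linalg.inv(a) * sigma_g2
        b = float(beta[-1])
        se = float(np.sqrt(cov[-1, -1]))
        wald = (b / se) ** 2 if se > 0 else np.inf
        pval = max(float(stats.chi2.sf(wald, 1)), _P_FLOOR)
        return LMMFit(
            variant=variant, beta=b, se=se, wald_stat=wald, p_value=pval,
            sigma_g2=float(sigma_g2), sigma_e2=float(sigma_g2 * delta),
            delta=float(delta), reml_loglik=float(ll),
        )

    def null_delta(self) -> float | None:
        return self._optimise_delta(None)

    # -- vectorised multi-variant scan -----------------------------------
    def _eval_vec(self, log10d: np.ndarray, xt: np.ndarray):
        """Profiled REML at per-variant deltas (intercept-only model).

        ``log10d`` is (m,), ``xt`` is (n, m); returns (ll, beta, se2, quad)
        each (m,). Invalid fits (singular design, zero residual) get -inf.
        """
        wt0 = self.wt[:, 0]
        yt = self.yt
        d = self.lam[None, :] + (10.0 ** log10d)[:, None]  # (m, n)
        w = 1.0 / d
        xtT = xt.T  # (m, n)
        a11 = w @ (wt0 * wt0)
        a12 = (w * (wt0[None, :] * xtT)).sum(axis=1)
        a22 = (w * (xtT * xtT)).sum(axis=1)
        b1 = w @ (wt0 * yt)
        b2 = (w * (yt[None, :] * xtT)).sum(axis=1)
        syy = w @ (yt * yt)
        det = a11 * a22 - a12 * a12
        with np.errstate(all="ignore"):
            beta = (a11 * b2 - a12 * b1) / det
            beta0 = (a22 * b1 - a12 * b2) / det
            quad = syy - b1 * beta0 - b2 * beta
            npp = self.n - 2
            ll = 0.5 * (
                npp * (np.log(npp / (2 * np.pi)) - 1.0)
                - npp * np.log(quad)
                - np.log(d).sum(axis=1)
                - np.log(det)
            )
            se2 = (quad / npp) * a11 / det  # sigma_g2 * (A^-1)[x,x]
        bad = ~np.isfinite(ll) | (det <= 0) | (quad <= 0)
        ll = np.where(bad, -np.inf, ll)
        return ll, beta, se2, quad

    def fit_all(
        self,
        g: np.ndarray,
        variant_ids,
        delta: float | None = None,
        n_refine: int = 32,
    ) -> pd.DataFrame:
        """Exact per-variant REML scan, vectorised across variants.

        Same profiled REML in delta as ``fit``: the shared 64-point
        grid brackets the optimum, then a golden-section refinement
        runs for all variants at once. ``delta`` fixes the variance
        ratio instead (the fast null-model approximation).
        """
        if self.p0 != 1:  # covariates: fall back to the per-variant path
            fits = [self.fit(g[:, j], variant_ids[j], delta) for j in range(g.shape[1])]
            return pd.DataFrame(
                [(f.variant, f.beta, f.se, f.wald_stat, f.p_value, f.converged)
                 for f in fits],
                columns=["variant", "beta", "se", "wald", "p", "converged"],
            ).set_index("variant")
        xt = self.u.T @ g  # (n, m)
        m = xt.shape[1]
        if delta is not None:
            best_log = np.full(m, np.log10(delta))
        else:
            # grid scan, all variants at once
            logs = np.log10(self._grid)
            ll_grid = np.full((_N_GRID, m), -np.inf)
            for i, lg in enumerate(logs):
                ll_grid[i], _, _, _ = self._eval_vec(np.full(m, lg), xt)
            i_best = np.argmax(ll_grid, axis=0)
            lo = logs[np.clip(i_best - 1, 0, _N_GRID - 1)]
            hi = logs[np.clip(i_best + 1, 0, _N_GRID - 1)]
            # golden-section search on [lo, hi] per variant
            invphi = (np.sqrt(5.0) - 1.0) / 2.0
            x1 = hi - invphi * (hi - lo)
            x2 = lo + invphi * (hi - lo)
            f1 = self._eval_vec(x1, xt)[0]
            f2 = self._eval_vec(x2, xt)[0]
            for _ in range(n_refine):
                take1 = f1 >= f2  # optimum in [lo, x2] where x1 is better
                lo = np.where(take1, lo, x1)
                hi = np.where(take1, x2, hi)
                cand1 = hi - invphi * (hi - lo)
                cand2 = lo + invphi * (hi - lo)
                fresh = np.where(take1, cand1, cand2)
                f_fresh = self._eval_vec(fresh, xt)[0]
                x1, x2, f1, f2 = (
                    np.where(take1, cand1, x2),
                    np.where(take1, x1, cand2),
                    np.where(take1, f_fresh, f2),
                    np.where(take1, f1, f_fresh),
                )
            best_log = np.where(f1 >= f2, x1, x2)
            # never do worse than the grid
            ll_ref = self._eval_vec(best_log, xt)[0]
            grid_best = ll_grid[i_best, np.arange(m)]
            best_log = np.where(ll_ref >= grid_best, best_log,
                                logs[i_best])
        ll, beta, se2, _ = self._eval_vec(best_log, xt)
        ok = np.isfinite(ll) & (se2 > 0)
        se = np.sqrt(np.where(ok, se2, np.nan))
        wald = np.where(ok, (beta / se) ** 2, np.nan)
        p = np.where(ok, np.maximum(stats.chi2.sf(wald, 1), _P_FLOOR), np.nan)
        return pd.DataFrame(
            {
                "variant": list(variant_ids),
                "beta": np.where(ok, beta, np.nan),
                "se": se,
                "wald": wald,
                "p": p,
                "converged": ok,
            }
        ).set_index("variant")


def fit_lmm_single(
    y, x, kinship: KinshipMatrix | np.ndarray, covariates=None, variant: str = "x"
) -> LMMFit:
    """One-shot single-variant REML fit (see LMMScanner for the method)."""
    return LMMScanner(y, kinship, covariates).fit(np.asarray(x, dtype=float), variant)


def _scan_replicon(
    y: pd.Series,
    genotypes: StrainGenotypeMatrix,
    kinship: KinshipMatrix,
    per_variant_reml: bool = True,
) -> pd.DataFrame:
    scanner = LMMScanner(y.to_numpy(), kinship)
    fixed_delta = None if per_variant_reml else scanner.null_delta()
    g = genotypes.dosage(impute=True)
    tab = scanner.fit_all(g, genotypes.variant_ids, delta=fixed_delta)
    tab["ld_group"] = genotypes.ld_map()
    tab["rank"] = tab["p"].rank(method="min").astype(int)
    return tab


def run_gwas(
    responses: pd.DataFrame,
    genotypes: StrainGenotypeMatrix,
    mode: str = "shift",
    maf: float = 0.05,
    missingness: float = 0.2,
    per_variant_reml: bool = True,
    replicons: Sequence[str] | None = None,
) -> list[AssociationResult]:
    """Run the per-replicon LMM for every response column.

    ``responses`` is strains x labels (fitness shifts per mutant host,
    or per-host fitness). Labels whose column is entirely missing are
    skipped with a log entry (hosts that formed no nodules). Ranks are
    per (response, replicon), ties sharing the minimum rank.
    """
    if replicons is None:
        replicons = list(pd.unique(genotypes.variants["replicon"]))
    results: list[AssociationResult] = []
    prepared = []
    for rep in replicons:
        sub = genotypes.for_replicon(rep)
        sub = filter_variants(sub, maf=maf, missingness=missingness)
        prepared.append((rep, sub, compute_kinship(sub)))
    for label in responses.columns:
        y = responses[label]
        if y.isna().all():
            logger.info("run_gwas: response %r has no data; skipped", label)
            continue
        if y.isna().any():
            raise ValueError(f"response {label!r} has partial missingness")
        y = y.reindex(genotypes.strain_ids)
        if y.isna().any():
            raise ValueError(f"response {label!r} not aligned to panel strains")
        for rep, sub, kin in prepared:
            tab = _scan_replicon(y, sub, kin, per_variant_reml=per_variant_reml)
            results.append(
                AssociationResult(
                    response=f"{mode}:{label}", replicon=rep, table=tab, level="variant"
                )
            )
    return results


def collapse_to_ld_groups(
    result: AssociationResult, ld_map: pd.Series | None = None
) -> AssociationResult:
    """Collapse a variant-level table to LD groups (best member stands in).

    The member with minimum p (ties broken by variant id) represents
    the group; ranks are recomputed at group level with ties sharing
    the minimum rank.
    """
    tab = result.table
    if ld_map is None:
        if "ld_group" not in tab.columns:
            raise ValueError("no LD map available")
        groups = tab["ld_group"]
    else:
        groups = ld_map.reindex(tab.index)
        if groups.isna().any():
            missing = list(tab.index[groups.isna()][:5])
            raise ValueError(f"variants not mapped to an LD group: {missing}")
    ordered = tab.assign(_g=groups).reset_index(names="variant")
    ordered = ordered.sort_values(["p", "variant"], kind="mergesort")
    best = ordered.groupby("_g", sort=False).first()
    members = ordered.groupby("_g", sort=False)["variant"].agg(list)
    out = best[["variant", "beta", "se", "wald", "p"]].rename(
        columns={"variant": "representative"}
    )
    out["members"] = members
    out["n_members"] = members.str.len()
    out["rank"] = out["p"].rank(method="min").astype(int)
    out.index.name = "ld_group"
    return AssociationResult(
        response=result.response, replicon=result.replicon, table=out, level="group"
    )
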