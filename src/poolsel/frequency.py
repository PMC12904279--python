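"""Strain-frequency deconvolution from pooled allele counts.

Model: at variant v the pool's alternate-allele dosage is
q_v = sum_i f_i g_iv with f the strain frequencies (simplex) and g the
known 0/1 panel. A read reports the alternate allele with probability
m_v = q_v (1 - e) + (1 - q_v) e, where e is a sequencing-error rate,
and the alternate count a_v is Binomial(n_v, m_v).

The maximum-likelihood f is found by EM: a read at variant v is
attributed to strain i with posterior weight proportional to
f_i p_iv (alt reads) or f_i (1 - p_iv) (ref reads), where
p_iv = g_iv (1 - e) + (1 - g_iv) e. The M-step averages those weights
over all reads. Because m_v is linear in f, this is the exact EM for
the stated likelihood, so the log-likelihood is non-decreasing every
iteration. A squared-extrapolation (SQUAREM-style) step accelerates
convergence; it is only accepted when it does not decrease the
log-likelihood, preserving monotonicity.

Strains with identical genotype rows are not identifiable: they are
estimated as a merged class whose frequency is split equally, with a
warning naming the strain set.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    FrequencyEstimate,
    PooledCounts,
    StrainGenotypeMatrix,
    UnidentifiableStrainsWarning,
)

__all__ = [
    "pool_loglik",
    "estimate_frequencies",
    "estimate_many",
    "summarize_inoculum",
    "InoculumSummary",
]


def _aligned_arrays(counts: PooledCounts, genotypes: StrainGenotypeMatrix):
    """Return (g, a, r) for variants usable in the likelihood.

    Variants absent from the counts table, with zero depth, or with any
    missing panel call are dropped (missing calls are never imputed
    here: a strain's likelihood contribution would be undefined).
    """
    common = genotypes.variant_ids.intersection(counts.variant_ids)
    if len(common) == 0:
        raise ValueError("counts and panel share no variants")
    g = genotypes.calls[common].to_numpy(dtype=float)
    sub = counts.counts.loc[common]
    a = sub["alt_count"].to_numpy(dtype=float)
    r = sub["ref_count"].to_numpy(dtype=float)
    keep = (a + r) > 0
    keep &= ~np.isnan(g).any(axis=0)
    if not keep.any():
        raise ValueError("no variant with nonzero depth and complete panel calls")
    return g[:, keep], a[keep], r[keep]


def _loglik(f: np.ndarray, p: np.ndarray, a: np.ndarray, r: np.ndarray) -> float:
    m = f @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.where(a > 0, a * np.log(m), 0.0)
        lr = np.where(r > 0, r * np.log(1.0 - m), 0.0)
    ll = la.sum() + lr.sum()
    return float(ll) if np.isfinite(ll) else float("-inf")


def pool_loglik(
    freqs: Sequence[float] | pd.Series,
    counts: PooledCounts,
    genotypes: StrainGenotypeMatrix,
    seq_error: float = 1e-3,
) -> float:
    """Binomial log-likelihood of pooled counts under strain frequencies.

    Returns -inf (not an exception) when an observed allele has
    probability zero, e.g. seq_error = 0 with alternate reads at a
    variant no weighted strain carries.
    """
    if isinstance(freqs, pd.Series):
        f = freqs.reindex(genotypes.strain_ids).to_numpy(dtype=float)
    else:
        f = np.asarray(freqs, dtype=float)
    if f.shape != (genotypes.n_strains,):
        raise ValueError("freqs length does not match the panel's strains")
    if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("freqs must be on the simplex")
    g, a, r = _aligned_arrays(counts, genotypes)
    p = g * (1.0 - seq_error) + (1.0 - g) * seq_error
    return _loglik(np.clip(f, 0.0, None), p, a, r)


def _safe_ratio(num, den):
    # num/den with the convention 0/0 = 0 (no reads, no contribution)
    return np.where(num > 0, num / np.maximum(den, 1e-300), 0.0)


def _em_step(f, p, a, r, m=None):
    if m is None:
        m = f @ p
    # posterior read counts per strain, normalised by the total read count
    wa = p @ _safe_ratio(a, m)
    wr = (1.0 - p) @ _safe_ratio(r, 1.0 - m)
    return f * (wa + wr) / (a.sum() + r.sum())


def _run_em(f0, p, a, r, tol, max_iter):
    """Monotone EM with guarded squared extrapolation."""
    f = f0
    ll = _loglik(f, p, a, r)
    n_iter = 0
    converged = False
    while n_iter < max_iter:
        f1 = _em_step(f, p, a, r)
        f2 = _em_step(f1, p, a, r)
        n_iter += 2
        ll2 = _loglik(f2, p, a, r)
        # squared extrapolation along the EM path (SQUAREM S3 step length)
        dr = f1 - f
        dv = f2 - f1 - dr
        nv = np.sqrt((dv * dv).sum())
        accepted = False
        if nv > 0:
            alpha = -np.sqrt((dr * dr).sum()) / nv
            cand = f - 2.0 * alpha * dr + alpha * alpha * dv
            cand = np.clip(cand, 0.0, None)
            s = cand.sum()
            if s > 0:
                cand = cand / s
                cand = _em_step(cand, p, a, r)  # stabilising EM step
                n_iter += 1
                llc = _loglik(cand, p, a, r)
                if llc >= ll2:  # keep only if monotone
                    f_new, ll_new = cand, llc
                    accepted = True
        if not accepted:
            f_new, ll_new = f2, ll2
        gain = ll_new - ll
        f, ll = f_new, ll_new
        if abs(gain) < tol:  # tiny negative gains are float noise at the optimum
            converged = True
            break
    return f, ll, n_iter, converged


def estimate_frequencies(
    counts: PooledCounts,
    genotypes: StrainGenotypeMatrix,
    seq_error: float = 1e-3,
    tol: float = 1e-8,
    max_iter: int = 5000,
    n_restarts: int = 0,
    seed: int | None = None,
) -> FrequencyEstimate:
    """Maximum-likelihood strain frequencies for one pooled sample.

    Deterministic given its inputs: initialisation is uniform; ``seed``
    is only used for the optional random restarts (``n_restarts``
    Dirichlet(1) starts, best final likelihood reported).
    """
    if genotypes.n_strains < 1:
        raise ValueError("panel has no strains")
    g, a, r = _aligned_arrays(counts, genotypes)
    p = g * (1.0 - seq_error) + (1.0 - g) * seq_error

    # merge strains whose genotype rows are identical (unidentifiable)
    _, class_of, class_sizes = np.unique(
        g, axis=0, return_inverse=True, return_counts=True
    )
    n_classes = class_sizes.size
    unidentifiable = []
    if n_classes < genotypes.n_strains:
        for c in np.nonzero(class_sizes > 1)[0]:
            members = tuple(genotypes.strain_ids[class_of == c])
            unidentifiable.append(members)
        warnings.warn(
            "strains with identical genotypes estimated as merged classes: "
            + "; ".join(",".join(m) for m in unidentifiable),
            UnidentifiableStrainsWarning,
            stacklevel=2,
        )
    # class-level allele probabilities (rows within a class are identical)
    pc = np.empty((n_classes, p.shape[1]))
    for c in range(n_classes):
        pc[c] = p[np.argmax(class_of == c)]

    if n_classes == 1:
        fc, ll, n_iter, converged = np.ones(1), _loglik(np.ones(1), pc, a, r), 1, True
    else:
        starts = [np.full(n_classes, 1.0 / n_classes)]
        if n_restarts > 0:
            rng = np.random.default_rng(seed)
            starts += [rng.dirichlet(np.ones(n_classes)) for _ in range(n_restarts)]
        best = None
        total_iter = 0
        for f0 in starts:
            f, ll, it, conv = _run_em(f0, pc, a, r, tol, max_iter)
            total_iter += it
            if best is None or ll > best[1]:
                best = (f, ll, conv)
        fc, ll, converged = best
        n_iter = total_iter

    # split merged classes equally back onto strains
    f_strain = fc[class_of] / class_sizes[class_of]
    f_strain = np.where(f_strain < 1e-12, 0.0, f_strain)
    f_strain = f_strain / f_strain.sum()
    depth = a + r
    return FrequencyEstimate(
        sample_id=counts.sample_id,
        freqs=pd.Series(f_strain, index=genotypes.strain_ids, name=counts.sample_id),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        depth_summary={
            "mean": float(depth.mean()),
            "median": float(np.median(depth)),
            "n_variants": int(depth.size),
        },
        unidentifiable=tuple(unidentifiable),
    )


def _em_step_batch(f, p, a, r):
    m = f @ p
    wa = _safe_ratio(a, m) @ p.T
    wr = _safe_ratio(r, 1.0 - m) @ (1.0 - p).T
    tot = (a + r).sum(axis=1, keepdims=True)
    return f * (wa + wr) / tot


def _loglik_batch(f, p, a, r):
    m = f @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.where(a > 0, a * np.log(m), 0.0)
        lr = np.where(r > 0, r * np.log(1.0 - m), 0.0)
    ll = la.sum(axis=1) + lr.sum(axis=1)
    return np.where(np.isfinite(ll), ll, -np.inf)


def _run_em_batch(f0, p, a, r, tol, max_iter):
    """The guarded accelerated EM of ``_run_em``, over samples at once.

    Identical per-sample updates, but the matrix products run over all
    samples together; per-sample extrapolation steps are accepted only
    where they do not decrease that sample's log-likelihood.
    """
    n = f0.shape[0]
    f_out = f0.copy()
    ll_out = _loglik_batch(f0, p, a, r)
    n_iter = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    active = np.arange(n)
    f, ll = f_out.copy(), ll_out.copy()
    it = 0
    while it < max_iter and active.size:
        fa, aa, ra = f[active], a[active], r[active]
        f1 = _em_step_batch(fa, p, aa, ra)
        f2 = _em_step_batch(f1, p, aa, ra)
        it += 2
        ll_new = _loglik_batch(f2, p, aa, ra)
        f_new = f2
        dr = f1 - fa
        dv = f2 - f1 - dr
        nv = np.sqrt((dv * dv).sum(axis=1))
        ok = nv > 0
        if ok.any():
            alpha = np.zeros(active.size)
            alpha[ok] = -np.sqrt((dr[ok] ** 2).sum(axis=1)) / nv[ok]
            cand = fa - 2.0 * alpha[:, None] * dr + alpha[:, None] ** 2 * dv
            cand = np.clip(cand, 0.0, None)
            s = cand.sum(axis=1, keepdims=True)
            good = (s[:, 0] > 0) & ok
            cand = np.where(s > 0, cand / np.where(s > 0, s, 1.0), f2)
            cand = _em_step_batch(cand, p, aa, ra)
            it += 1
            llc = _loglik_batch(cand, p, aa, ra)
            accept = good & (llc >= ll_new)
            f_new = np.where(accept[:, None], cand, f2)
            ll_new = np.where(accept, llc, ll_new)
        gain = ll_new - ll[active]
        f[active] = f_new
        ll[active] = ll_new
        done = np.abs(gain) < tol  # tiny negative gain = float noise at optimum
        idx_done = active[done]
        n_iter[idx_done] = it
        converged[idx_done] = True
        active = active[~done]
    n_iter[~converged] = it
    return f, ll, n_iter, converged


def estimate_many(
    counts_list: Iterable[PooledCounts],
    genotypes: StrainGenotypeMatrix,
    seq_error: float = 1e-3,
    tol: float = 1e-8,
    max_iter: int = 5000,
    **kwargs,
) -> list[FrequencyEstimate]:
    """Estimate many samples against one panel.

    When every sample covers the same variant set the EM runs over all
    samples jointly (one batch of matrix products per iteration); the
    per-sample updates, and hence the optimum each sample converges to,
    are the same as ``estimate_frequencies``'s.
    """
    counts_list = list(counts_list)
    if kwargs or len(counts_list) < 2:
        return [
            estimate_frequencies(c, genotypes, seq_error=seq_error, tol=tol,
                                 max_iter=max_iter, **kwargs)
            for c in counts_list
        ]
    ids0 = counts_list[0].variant_ids
    if not all(c.variant_ids.equals(ids0) for c in counts_list[1:]):
        return [
            estimate_frequencies(c, genotypes, seq_error=seq_error, tol=tol,
                                 max_iter=max_iter)
            for c in counts_list
        ]

    common = genotypes.variant_ids.intersection(ids0)
    if len(common) == 0:
        raise ValueError("counts and panel share no variants")
    sub = np.stack(
        [c.counts.loc[common, ["alt_count", "ref_count"]].to_numpy(dtype=float)
         for c in counts_list]
    )  # (N, V, 2)
    gg = genotypes.calls[common].to_numpy(dtype=float)
    keep = ~np.isnan(gg).any(axis=0)  # depth masks can differ; keep complete panel
    gg = gg[:, keep]
    a = sub[:, keep, 0]
    r = sub[:, keep, 1]
    p = gg * (1.0 - seq_error) + (1.0 - gg) * seq_error

    _, class_of, class_sizes = np.unique(
        gg, axis=0, return_inverse=True, return_counts=True
    )
    n_classes = class_sizes.size
    unidentifiable = []
    if n_classes < genotypes.n_strains:
        for c in np.nonzero(class_sizes > 1)[0]:
            unidentifiable.append(tuple(genotypes.strain_ids[class_of == c]))
        warnings.warn(
            "strains with identical genotypes estimated as merged classes: "
            + "; ".join(",".join(m) for m in unidentifiable),
            UnidentifiableStrainsWarning,
            stacklevel=2,
        )
    pc = np.empty((n_classes, p.shape[1]))
    for c in range(n_classes):
        pc[c] = p[np.argmax(class_of == c)]

    n = len(counts_list)
    f0 = np.full((n, n_classes), 1.0 / n_classes)
    fc, ll, n_iter, conv = _run_em_batch(f0, pc, a, r, tol, max_iter)
    out = []
    depth = a + r
    for i, c in enumerate(counts_list):
        f_strain = fc[i][class_of] / class_sizes[class_of]
        f_strain = np.where(f_strain < 1e-12, 0.0, f_strain)
        f_strain = f_strain / f_strain.sum()
        out.append(
            FrequencyEstimate(
                sample_id=c.sample_id,
                freqs=pd.Series(f_strain, index=genotypes.strain_ids,
                                name=c.sample_id),
                loglik=float(ll[i]),
                n_iter=int(n_iter[i]),
                converged=bool(conv[i]),
                depth_summary={
                    "mean": float(depth[i].mean()),
                    "median": float(np.median(depth[i])),
                    "n_variants": int(depth[i].size),
                },
                unidentifiable=tuple(unidentifiable),
            )
        )
    return out


class InoculumSummary:
    """Initial-community summary: per-strain medians plus spread.

    ``per_strain_median`` is the median frequency of each strain over
    replicate aliquots; ``median``/``q05``/``q95`` summarise that
    distribution across strains (linear-interpolation quantiles).
    """

    def __init__(self, per_strain_median: pd.Series):
        self.per_strain_median = per_strain_median
        q = np.quantile(per_strain_median.to_numpy(), [0.05, 0.5, 0.95])
        self.q05, self.median, self.q95 = (float(x) for x in q)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"InoculumSummary(median={self.median:.4g}, "
            f"5%-95%: {self.q05:.4g}-{self.q95:.4g})"
        )


def summarize_inoculum(estimates: Sequence[FrequencyEstimate]) -> InoculumSummary:
    """Summarise replicate aliquot estimates of the initial community."""
    if len(estimates) == 0:
        raise ValueError("no initial-community estimates supplied")
    mat = pd.concat([e.freqs.rename(e.sample_id) for e in estimates], axis=1)
    return InoculumSummary(mat.median(axis=1).rename("inoculum_freq"))
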