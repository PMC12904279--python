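"""Cross-GWAS candidate selection and pervasive/limited classification.

From each host mutant's fitness-shift GWAS the top five variant
groups (by p-value rank) are pooled into a candidate union. Each
candidate is then cross-compared in every mutant's GWAS: a group
ranking in the top 10 within six or more host mutants is classified
"pervasive", five or fewer "limited". Classification is by rank, not
p-value, so hosts with different power contribute equally;
significance (minimum p below a Bonferroni-style threshold, default
1e-5) is annotated but never gates classification. Pervasive
candidates whose alternate allele helps in mutant hosts but
significantly hurts in the wild type (or vice versa) are flagged as
sign trade-offs.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import AssociationResult, PervasivenessReport

__all__ = [
    "select_top_k",
    "classify_pervasiveness",
    "detect_sign_tradeoff",
    "candidate_overlap",
]

HostResults = Mapping[str, Sequence[AssociationResult]]
"""host -> its group-level AssociationResult tables (one per replicon)."""


def _host_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Concatenate a host's per-replicon group tables (ranks stay per replicon)."""
    frames = []
    for res in results:
        if res.level != "group":
            raise ValueError("ranking expects group-level results; collapse first")
        t = res.table.copy()
        t["replicon"] = res.replicon
        frames.append(t)
    return pd.concat(frames)


def select_top_k(host_results: HostResults, k: int = 5) -> pd.DataFrame:
    """Union of each host's k best groups by p (deterministic tie-break).

    Returns one row per candidate group with the nominating hosts
    retained as provenance.
    """
    import warnings

    nominations: dict[str, list[str]] = {}
    for host, results in host_results.items():
        tab = _host_table(results).reset_index()
        tab = tab.sort_values(["p", "ld_group"], kind="mergesort")
        if len(tab) < k:
            warnings.warn(
                f"host {host!r} has only {len(tab)} groups (< k={k}); all returned",
                stacklevel=2,
            )
        for gid in tab["ld_group"].head(k):
            nominations.setdefault(gid, []).append(host)
    rows = [
        {"ld_group": g, "nominated_by": tuple(hs), "n_nominations": len(hs)}
        for g, hs in nominations.items()
    ]
    return pd.DataFrame(rows).set_index("ld_group")


def classify_pervasiveness(
    candidates: pd.DataFrame | Sequence[str],
    host_results: HostResults,
    top: int = 10,
    min_hosts: int = 6,
    p_threshold: float = 1e-5,
) -> PervasivenessReport:
    """Cross-compare candidate groups in every host's GWAS and classify.

    A candidate absent from some host's tables (filtered out there)
    counts as not-top-10 in that host and is flagged. Pervasive means
    rank <= ``top`` (within the group's replicon) in >= ``min_hosts``
    hosts; otherwise limited.
    """
    if isinstance(candidates, pd.DataFrame):
        cand_ids = list(candidates.index)
        nominated = candidates.get("nominated_by")
    else:
        cand_ids = list(candidates)
        nominated = None
    tables = {host: _host_table(res) for host, res in host_results.items()}
    rows = []
    for gid in cand_ids:
        hosts_hit, betas, missing_in = [], {}, []
        min_p = np.inf
        for host, tab in tables.items():
            if gid not in tab.index:
                missing_in.append(host)
                continue
            rec = tab.loc[gid]
            betas[host] = float(rec["beta"])
            min_p = min(min_p, float(rec["p"]))
            if int(rec["rank"]) <= top:
                hosts_hit.append(host)
        n_top = len(hosts_hit)
        rows.append(
            {
                "ld_group": gid,
                "n_top10": n_top,
                "hosts_top10": tuple(sorted(hosts_hit)),
                "classification": "pervasive" if n_top >= min_hosts else "limited",
                "hosts_selected_top5": tuple(nominated.loc[gid]) if nominated is not None else (),
                "significant": bool(min_p < p_threshold),
                "min_p": float(min_p) if np.isfinite(min_p) else np.nan,
                "beta_by_host": betas,
                "filtered_in_hosts": tuple(missing_in),
                "wildtype_beta_sign": "none",
                "tradeoff": False,
            }
        )
    table = pd.DataFrame(rows).set_index("ld_group")
    return PervasivenessReport(
        table=table, top=top, min_hosts=min_hosts, p_threshold=p_threshold
    )


def detect_sign_tradeoff(
    report: PervasivenessReport,
    wildtype_results: Sequence[AssociationResult],
    min_hosts: int | None = None,
    wt_p_threshold: float = 0.05,
) -> PervasivenessReport:
    """Flag candidates whose mutant-host and wild-type effect signs oppose.

    The wild-type sign is taken at the group representative in the
    wild-type fitness GWAS; a sign is only called when at least
    nominally supported (p < ``wt_p_threshold``), otherwise it is
    "none" and no trade-off is flagged. A trade-off requires a
    consistent allele sign (any magnitude) in >= ``min_hosts`` of the
    candidate's top-10 mutant hosts, opposite to the wild-type sign.
    """
    if min_hosts is None:
        min_hosts = report.min_hosts
    wt = _host_table(wildtype_results)
    table = report.table.copy()
    signs, tradeoffs = [], []
    for gid, rec in table.iterrows():
        wt_sign = "none"
        wt_beta = np.nan
        if gid in wt.index:
            w = wt.loc[gid]
            if float(w["p"]) < wt_p_threshold:
                wt_beta = float(w["beta"])
                wt_sign = "+" if wt_beta > 0 else "-" if wt_beta < 0 else "none"
        hit_betas = [
            b for h, b in rec["beta_by_host"].items() if h in rec["hosts_top10"]
        ]
        n_pos = sum(1 for b in hit_betas if b > 0)
        n_neg = sum(1 for b in hit_betas if b < 0)
        trade = (n_pos >= min_hosts and wt_sign == "-") or (
            n_neg >= min_hosts and wt_sign == "+"
        )
        signs.append(wt_sign)
        tradeoffs.append(bool(trade))
    table["wildtype_beta_sign"] = signs
    table["tradeoff"] = tradeoffs
    return PervasivenessReport(
        table=table,
        top=report.top,
        min_hosts=report.min_hosts,
        p_threshold=report.p_threshold,
    )


def candidate_overlap(
    result_a: AssociationResult, result_b: AssociationResult, top_frac: float = 0.001
) -> float:
    """Fraction of A's top-``top_frac`` variants shared with B's.

    Both results must cover the same variant universe; the top sets
    hold ceil(top_frac * m) smallest-p variants each.
    """
    ids_a, ids_b = set(result_a.table.index), set(result_b.table.index)
    if ids_a != ids_b:
        raise ValueError("results cover different variant universes")
    m = len(ids_a)
    if m * top_frac < 1:
        raise ValueError("list too small for the requested top fraction")
    k = math.ceil(m * top_frac)

    def top_set(res):
        t = res.table.reset_index(names="id").sort_values(["p", "id"], kind="mergesort")
        return set(t["id"].head(k))

    ta, tb = top_set(result_a), top_set(result_b)
    return len(ta & tb) / len(ta)
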