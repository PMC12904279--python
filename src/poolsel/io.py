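"""Readers and writers for the pipeline's on-disk formats.

Genotype panels travel as VCF 4.2 (haploid/homozygous GT calls only --
the strains are clonal -- with INFO tags REPLICON and LDGROUP) or as a
TSV matrix plus a variant-metadata sidecar. Pooled counts, sample
sheets and trait tables are plain TSV/CSV with a header line.
Coordinates are 1-based in files, 0-based in memory; the conversion
lives here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_REPLICONS,
    PooledCounts,
    StrainGenotypeMatrix,
    ValidationError,
)

__all__ = [
    "write_genotypes_vcf",
    "read_genotypes",
    "write_counts",
    "read_counts",
    "read_samplesheet",
    "write_table",
    "read_table",
]

STAGE_VALUES = ("early", "late", "AON", "wildtype")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes_vcf(genotypes: StrainGenotypeMatrix, path) -> None:
    """Write the panel as VCF 4.2 with GT 0/0, 1/1 or ./. per strain."""
    path = Path(path)
    strains = list(genotypes.strain_ids)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=REPLICON,Number=1,Type=String,Description="Replicon">',
        '##INFO=<ID=LDGROUP,Number=1,Type=String,Description="LD group id">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for rep in dict.fromkeys(genotypes.variants["replicon"]):
        lines.append(f"##contig=<ID={rep}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(strains)
    )
    calls = genotypes.calls.to_numpy()
    for j, vid in enumerate(genotypes.variant_ids):
        meta = genotypes.variants.loc[vid]
        gts = [
            "./." if np.isnan(calls[i, j]) else ("1/1" if calls[i, j] == 1 else "0/0")
            for i in range(len(strains))
        ]
        lines.append(
            "\t".join(
                [
                    str(meta["replicon"]),
                    str(int(meta["pos"])),
                    str(vid),
                    "A",
                    "T",
                    ".",
                    "PASS",
                    f"REPLICON={meta['replicon']};LDGROUP={meta['ld_group']}",
                    "GT",
                ]
                + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _read_genotypes_vcf(path, replicon_set) -> StrainGenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    meta = []
    for var in vcf:
        alts = var.ALT or []
        multi = len(alts) > 1
        replicon = var.INFO.get("REPLICON") or var.CHROM
        ldg = var.INFO.get("LDGROUP")
        if replicon not in replicon_set:
            raise ValidationError(
                f"unknown replicon label {replicon!r} at {var.CHROM}:{var.POS}"
            )
        gts = var.genotypes  # [a1, a2, phased] per sample
        for alt_idx, alt in enumerate(alts, start=1):
            vid = var.ID or f"{var.CHROM}:{var.POS}"
            if multi:
                vid = f"{vid}_alt{alt_idx}"  # split multiallelic, flagged by suffix
            col = np.empty(len(strains))
            for i, g in enumerate(gts):
                a = [x for x in g[:-1] if x is not None]
                if not a or a[0] < 0:
                    col[i] = np.nan
                    continue
                if len(a) == 2 and a[0] != a[1]:
                    raise ValidationError(
                        f"heterozygous call for strain {strains[i]} at variant "
                        f"{var.ID or f'{var.CHROM}:{var.POS}'} (strains are clonal)"
                    )
                col[i] = 1.0 if a[0] == alt_idx else 0.0
            cols[vid] = col
            meta.append((vid, replicon, var.POS, ldg if ldg is not None else vid))
    calls = pd.DataFrame(cols, index=strains)
    variants = pd.DataFrame(
        [(m[1], m[2], m[3]) for m in meta],
        index=pd.Index([m[0] for m in meta], name="variant_id"),
        columns=["replicon", "pos", "ld_group"],
    )
    return StrainGenotypeMatrix(calls, variants, tuple(replicon_set))


def _read_genotypes_tsv(path, variants_path, replicon_set) -> StrainGenotypeMatrix:
    calls = pd.read_csv(path, sep="\t", index_col=0)
    bad = calls.stack(future_stack=True).dropna()
    het = bad[(bad != 0) & (bad != 1)]
    if len(het):
        raise ValidationError(
            f"non-clonal/invalid dosage at variant {het.index[0][1]!r}"
        )
    variants = pd.read_csv(variants_path, sep="\t", index_col=0)
    return StrainGenotypeMatrix(calls, variants, tuple(replicon_set))


def read_genotypes(
    path,
    variants_path=None,
    replicon_set: Sequence[str] = DEFAULT_REPLICONS,
) -> StrainGenotypeMatrix:
    """Read a strain panel from VCF (.vcf) or TSV matrix + sidecar.

    Heterozygous calls are rejected with the offending variant named;
    multiallelic records are split into biallelic ones (ids suffixed
    ``_altN``). LD groups come from the LDGROUP INFO tag or the sidecar
    table; variants without one become singleton groups.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz"):
        return _read_genotypes_vcf(path, replicon_set)
    if variants_path is None:
        raise ValueError("TSV genotypes need a variant-metadata sidecar table")
    return _read_genotypes_tsv(path, variants_path, replicon_set)


# ---------------------------------------------------------------------------
# counts and generic tables
# ---------------------------------------------------------------------------

def write_counts(counts: PooledCounts | Iterable[PooledCounts], path) -> None:
    """Write pooled counts as TSV: sample_id, variant_id, ref_count, alt_count."""
    if isinstance(counts, PooledCounts):
        counts = [counts]
    frames = []
    for c in counts:
        t = c.counts.reset_index()
        t.insert(0, "sample_id", c.sample_id)
        frames.append(t)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_counts(path) -> list[PooledCounts]:
    """Read pooled counts TSV (one or more samples) into PooledCounts."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "ref_count", "alt_count"}
    if not required <= set(df.columns):
        raise ValidationError(f"counts table needs columns {sorted(required)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = Path(path).stem
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise ValidationError("negative read counts")
    out = []
    for sid, sub in df.groupby("sample_id", sort=False):
        out.append(PooledCounts(str(sid), sub.set_index("variant_id")[
            ["ref_count", "alt_count"]]))
    return out


def read_samplesheet(path, wildtype: str | None = None) -> pd.DataFrame:
    """Read and validate the sample sheet (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "host_genotype", "stage_category", "block"}
    if not required <= set(df.columns):
        raise ValidationError(f"sample sheet needs columns {sorted(required)}")
    bad = set(df["stage_category"]) - set(STAGE_VALUES)
    if bad:
        raise ValidationError(f"unknown stage categories: {sorted(bad)}")
    wt_genos = df.loc[df["stage_category"] == "wildtype", "host_genotype"].unique()
    if len(wt_genos) != 1:
        raise ValidationError(
            f"exactly one wild-type genotype required, found {list(wt_genos)}"
        )
    if wildtype is not None and wt_genos[0] != wildtype:
        raise ValidationError(
            f"wild type in sheet is {wt_genos[0]!r}, expected {wildtype!r}"
        )
    return df.set_index("sample_id")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a results table (TSV or CSV by extension), UTF-8, stable columns."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=index, encoding="utf-8")


def read_table(path, index_col=0) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col, encoding="utf-8")
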