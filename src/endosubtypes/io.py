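"""Readers and writers for the pipeline's on-disk formats.

Tabular artifacts are plain TSV; genotypes travel as VCF (GT counted to
dosage, DS read directly, ``./.`` becomes missing) or as a dosage TSV
with one row per variant. Every writer/reader pair round-trips exactly;
malformed input raises with the offending location. Positions are
1-based everywhere, per VCF convention.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import GenotypeMatrix
from .features import PhenotypeMatrix

__all__ = [
    "write_subjects", "read_subjects",
    "write_icd", "read_icd",
    "write_feature_matrix", "read_feature_matrix",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf",
    "write_locus_list", "read_locus_list",
    "write_summary_stats", "read_summary_stats",
    "write_truth_json", "write_manifest",
]

SUBJECT_COLUMNS = ["subject_id", "age", "sex", "ancestry", "dataset"]
ICD_COLUMNS = ["subject_id", "vocabulary", "code"]
LOCUS_COLUMNS = ["rsid", "chrom", "pos", "locus_label"]
SUMMARY_STAT_COLUMNS = [
    "variant", "chrom", "pos", "effect_allele", "phenotype", "stratum",
    "beta", "se", "p", "n_case", "n_control",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


# -- subjects ---------------------------------------------------------------

def write_subjects(subjects: pd.DataFrame, path) -> None:
    _require_columns(subjects, SUBJECT_COLUMNS, "subjects table")
    subjects[SUBJECT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    _require_columns(df, SUBJECT_COLUMNS, f"subjects file {path}")
    return df


# -- ICD long table ---------------------------------------------------------

def write_icd(icd: pd.DataFrame, path) -> None:
    _require_columns(icd, ICD_COLUMNS, "ICD table")
    icd[ICD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_icd(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ICD_COLUMNS, f"ICD file {path}")
    return df


# -- feature matrix ---------------------------------------------------------

def write_feature_matrix(matrix: PhenotypeMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_feature_matrix(path) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return PhenotypeMatrix(df.index.to_numpy(dtype=object),
                           list(df.columns), df.to_numpy())


# -- dosage TSV -------------------------------------------------------------

def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    """One row per variant: rsid, chrom, pos, ref, alt, locus_label, then
    one dosage column per subject (empty cell = missing)."""
    meta = G.variants[["rsid", "chrom", "pos", "ref", "alt", "locus_label"]].copy()
    dose = pd.DataFrame(G.dosages.T, columns=list(G.subject_ids))
    pd.concat([meta.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["rsid", "chrom", "pos", "ref", "alt", "locus_label"]
    _require_columns(df, meta_cols, f"dosage file {path}")
    subject_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[subject_ids].to_numpy(dtype=float).T
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    return GenotypeMatrix(np.asarray(subject_ids, dtype=object), variants, dosages)


# -- VCF --------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path, use_ds: bool = False) -> None:
    """Uncompressed VCFv4.2. Integer dosages are written as GT
    (0/0, 0/1, 1/1; missing -> ./.), non-integer dosages force DS."""
    dos = G.dosages
    integral = np.all(np.isnan(dos) | (np.mod(dos, 1) == 0))
    use_ds = use_ds or not integral
    chroms = list(dict.fromkeys(G.variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=endosubtypes\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        if use_ds:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        else:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in G.subject_ids) + "\n")
        order = np.lexsort((G.variants["pos"].to_numpy(),
                            G.variants["chrom"].astype(str).to_numpy()))
        for j in order:
            v = G.variants.iloc[j]
            fields = [str(v["chrom"]), str(int(v["pos"])), str(v["rsid"]),
                      str(v.get("ref", "A")), str(v.get("alt", "G")), ".", ".",
                      f"LOCUS={v.get('locus_label', v['rsid'])}",
                      "DS" if use_ds else "GT"]
            col = dos[:, j]
            if use_ds:
                cells = ["." if np.isnan(x) else f"{x:g}" for x in col]
            else:
                gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                cells = ["./." if np.isnan(x) else gt[float(x)] for x in col]
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT (allele count -> dosage) or DS genotypes via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = np.asarray(vcf.samples, dtype=object)
    rows, meta = [], []
    for var in vcf:
        fmts = var.FORMAT
        if "DS" in fmts:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            ds = np.empty(len(subject_ids))
            for i, g in enumerate(var.genotypes):
                alleles = [a for a in g[:-1] if a >= 0]
                ds[i] = sum(alleles) if len(alleles) == len(g) - 1 else np.nan
        info_locus = dict(var.INFO).get("LOCUS")
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                     int(var.POS), var.REF, var.ALT[0] if var.ALT else ".",
                     info_locus or (var.ID or f"{var.CHROM}:{var.POS}")))
        rows.append(ds)
    variants = pd.DataFrame(
        meta, columns=["rsid", "chrom", "pos", "ref", "alt", "locus_label"])
    dosages = np.vstack(rows).T if rows else np.zeros((len(subject_ids), 0))
    return GenotypeMatrix(subject_ids, variants, dosages)


# -- locus list -------------------------------------------------------------

def write_locus_list(loci: pd.DataFrame, path) -> None:
    _require_columns(loci, LOCUS_COLUMNS, "locus list")
    loci[LOCUS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_locus_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    _require_columns(df, LOCUS_COLUMNS, f"locus list {path}")
    return df


# -- summary statistics -----------------------------------------------------

def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Stable GWAS-SSF-compatible column order."""
    _require_columns(results, SUMMARY_STAT_COLUMNS, "summary statistics")
    extra = [c for c in results.columns if c not in SUMMARY_STAT_COLUMNS]
    results[SUMMARY_STAT_COLUMNS + extra].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "chrom": str})
    _require_columns(df, SUMMARY_STAT_COLUMNS, f"summary statistics {path}")
    return df


# -- truth + manifest -------------------------------------------------------

def write_truth_json(truth, path) -> None:
    payload = {
        "subtype": {str(k): int(v) for k, v in truth.subtype.items()},
        "variant_betas": {k: list(v) for k, v in truth.variant_betas.items()},
        "feature_prevalence": truth.feature_prevalence.to_dict(orient="index"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stage: str, seed: int | None, inputs: Sequence, outputs: Sequence) -> None:
    payload = {
        "stage": stage,
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(p) for p in outputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
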