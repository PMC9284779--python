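"""Standard-format I/O: VCF 4.2 (GT-only, unphased), phenotype and trait TSVs.

Positions are 1-based inclusive everywhere inside the package; the VCF
writer is a plain text emitter (genotypes only), reading goes through
cyvcf2.  Missing genotypes are coded ``./.`` on disk and -1 in memory;
phased separators on input are accepted with the phase discarded, and
multi-allelic or malformed records are skipped with a counted warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, variants: pd.DataFrame, genotypes: np.ndarray,
              sample_ids: list[str]) -> None:
    """Write a minimal VCF 4.2 with unphased GT calls, sorted by position."""
    order = np.argsort(variants["pos"].to_numpy(), kind="stable")
    v = variants.iloc[order]
    g = genotypes[:, order]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, (_, row) in enumerate(v.iterrows()):
            gts = "\t".join(_GT_STRINGS[int(x)] for x in g[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a VCF into (variant table, sample-by-variant 0/1/2/-1 matrix, ids).

    Multi-allelic records are rejected (count logged); phased "|" separators
    are accepted and the phase discarded.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        g = np.empty(len(samples), dtype=np.int8)
        bad = False
        for i, call in enumerate(rec.genotypes):
            a, b = call[0], call[1]
            if a < 0 or b < 0:
                g[i] = MISSING
            else:
                g[i] = a + b
        if bad:
            n_skipped += 1
            continue
        rows.append({"chrom": rec.CHROM, "pos": rec.POS,
                     "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                     "ref": rec.REF, "alt": rec.ALT[0]})
        cols.append(g)
    if n_skipped:
        logger.warning("read_vcf: skipped %d multi-allelic/malformed records",
                       n_skipped)
    variants = pd.DataFrame(rows)
    genotypes = (np.column_stack(cols) if cols
                 else np.empty((len(samples), 0), dtype=np.int8))
    return variants, genotypes, samples


def write_pheno_tsv(path, sample_ids, status, covariates: pd.DataFrame) -> None:
    df = pd.DataFrame({"sample_id": sample_ids, "status": np.asarray(status)})
    df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_pheno_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise ValueError("phenotype table needs sample_id and status columns")
    return df


def write_trait_tsv(path, sample_ids, traits: pd.DataFrame) -> None:
    df = pd.concat([pd.DataFrame({"sample_id": sample_ids}),
                    traits.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_trait_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genotype_tsv(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Transposed tabular genotypes: columns chrom,pos,id,ref,alt,<samples>."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "pos", "id", "ref", "alt"]
    variants = df[meta_cols].copy()
    samples = [c for c in df.columns if c not in meta_cols]
    g = df[samples].to_numpy()
    g = np.where(pd.isna(g), MISSING, g).astype(np.int8).T
    return variants, g, samples


def write_cohort(cohort, out_prefix) -> dict[str, Path]:
    """Emit a simulated cohort: VCF + phenotype/covariate + trait TSVs.

    Round-trips losslessly through :func:`read_vcf` (genotypes incl. missing
    codes) and the TSV readers.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "pheno": Path(f"{prefix}.pheno.tsv"),
        "traits": Path(f"{prefix}.traits.tsv"),
    }
    write_vcf(paths["vcf"], cohort.variants, cohort.genotypes,
              cohort.sample_ids)
    write_pheno_tsv(paths["pheno"], cohort.sample_ids, cohort.status,
                    cohort.covariates)
    write_trait_tsv(paths["traits"], cohort.sample_ids, cohort.traits)
    return paths
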