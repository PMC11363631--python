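"""Readers and writers for the pipeline's tab-separated artifacts and the
minimal VCF genotype export.

TSV with a header line is the lingua franca; every reader validates its
schema and reports the offending column.  Genomic coordinates are
1-based throughout, as in the pileup format and the locus names.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotyping import NO_CALL, PanelLocus
from .pedigree import Pedigree


class SchemaError(ValueError):
    pass


def _require(df: pd.DataFrame, cols: Sequence[str], what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table {path}: missing columns {missing}")


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pedigree(ped: Pedigree, path) -> Path:
    return write_tsv(ped.to_frame(), path)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["id", "sire", "dam"], "pedigree", path)
    return Pedigree.from_frame(df)


def write_panel(panel: Sequence[PanelLocus], path) -> Path:
    return write_tsv(
        pd.DataFrame(
            {
                "chrom": [l.chrom for l in panel],
                "pos": [l.pos for l in panel],
                "allele_A": [l.allele_A for l in panel],
                "allele_L": [l.allele_L for l in panel],
            }
        ),
        path,
    )


def read_panel(path) -> list[PanelLocus]:
    df = read_tsv(path)
    _require(df, ["chrom", "pos", "allele_A", "allele_L"], "panel", path)
    return [
        PanelLocus(str(r.chrom), int(r.pos), str(r.allele_A), str(r.allele_L))
        for r in df.itertuples()
    ]


def read_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    _require(df, ["sample_id", "chrom", "pos", "n_A", "n_L"], "counts", path)
    if "n_other" not in df.columns:
        df["n_other"] = 0
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table with binary status Y, or a 1-5 smolt score from
    which Y is derived (scores 3-5 count as smoltified)."""
    df = read_tsv(path)
    if "Y" not in df.columns and "smolt_score" in df.columns:
        df["Y"] = (df["smolt_score"] >= 3).astype(int)
    _require(df, ["id", "Y", "W", "S"], "phenotype", path)
    if "smolt_score" in df.columns and "Y" in df.columns:
        bad = (df["Y"] == 1) != (df["smolt_score"] >= 3)
        if bad.any():
            raise SchemaError(
                f"phenotype table {path}: Y disagrees with smolt_score >= 3 "
                f"at row {int(np.argmax(bad.values)) + 1}"
            )
    return df


def read_ct(path) -> pd.DataFrame:
    df = read_tsv(path)
    _require(df, ["sample_id", "tissue", "gene", "replicate", "Ct"], "Ct", path)
    return df


_GT = {"AA": "0/0", "AL": "0/1", "LL": "1/1", NO_CALL: "./."}
_GT_BACK = {v: k for k, v in _GT.items()}


def write_vcf(calls: pd.DataFrame, panel: Sequence[PanelLocus], path) -> Path:
    """Minimal VCF 4.2: one record per panel locus, GT per sample.

    REF is the anadromous allele and ALT the landlocked allele, so the
    alternate-allele dosage counts L alleles.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = sorted(calls["sample_id"].unique())
    wide = calls.pivot_table(
        index=["chrom", "pos"], columns="sample_id", values="call", aggfunc="first"
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=smoltpipe\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({l.chrom for l in panel}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for loc in sorted(panel, key=lambda l: (l.chrom, l.pos)):
            gts = []
            for s in samples:
                try:
                    call = wide.loc[(loc.chrom, loc.pos), s]
                except KeyError:
                    call = NO_CALL
                if not isinstance(call, str):
                    call = NO_CALL
                gts.append(_GT.get(call, "./."))
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.chrom}:{loc.pos}\t{loc.allele_A}\t"
                f"{loc.allele_L}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def read_vcf(path) -> pd.DataFrame:
    """Re-parse the minimal VCF back into a calls table."""
    rows = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos = fields[0], int(fields[1])
            for s, gt in zip(samples, fields[9:]):
                rows.append((s, chrom, pos, _GT_BACK.get(gt, NO_CALL)))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "call"])
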