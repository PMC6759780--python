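"""Plain-text input/output: genotype TSV/VCF, marker maps, phenotypes, truth JSON.

Genotype TSV layout: rows = individuals, columns = markers, codes 0/1/2,
``NA`` for missing.  VCF output is unphased diploid GT with the marker
codes mapped to 0/0, 0/1, 1/1 and ``./.``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import MISSING, ChromSpec, GenotypeMatrix

__all__ = [
    "write_genotype_tsv", "read_genotype_tsv",
    "write_marker_map", "read_marker_map",
    "write_vcf", "read_vcf",
    "write_phenotypes", "read_phenotypes",
    "write_truth_json",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_FROM_GT = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING,
            "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": MISSING}


def write_genotype_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        geno.values.astype(object), index=geno.ids, columns=geno.markers["marker"]
    )
    df[df == MISSING] = "NA"
    df.to_csv(path, sep="\t", index_label="individual")


def read_genotype_tsv(path, markers: pd.DataFrame, population: str = "natural") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual", na_values="NA")
    values = df.to_numpy(dtype=float)
    values = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    return GenotypeMatrix(values, markers, [str(i) for i in df.index], population)


def write_marker_map(markers: pd.DataFrame, path) -> None:
    markers[["marker", "chrom", "pos", "cm"]].to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["ref"] = df.get("ref", "A")
    df["alt"] = df.get("alt", "B")
    return df


def write_vcf(geno: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=trmgs\n")
        for chrom, sub in geno.markers.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.ids) + "\n")
        mk = geno.markers
        for j in range(geno.n_markers):
            gts = "\t".join(_GT[int(v)] for v in geno.values[:, j])
            fh.write(
                f"{mk['chrom'].iat[j]}\t{mk['pos'].iat[j]}\t{mk['marker'].iat[j]}\t"
                f"{mk['ref'].iat[j]}\t{mk['alt'].iat[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path, population: str = "natural") -> GenotypeMatrix:
    ids: list[str] = []
    rows = []
    codes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ids = parts[9:]
                continue
            chrom, pos, mid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            rows.append((mid, chrom, pos, np.nan, ref, alt))
            codes.append([_FROM_GT.get(g.split(":")[0], MISSING) for g in parts[9:]])
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "cm", "ref", "alt"])
    values = np.asarray(codes, dtype=np.int8).T
    return GenotypeMatrix(values, markers, ids, population)


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth: dict, path) -> None:
    """Serialize a simulation truth dict (arrays to lists, architecture to fields)."""
    def enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, default=enc, indent=1))
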