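"""Readers and writers for the plain-text formats used by the pipeline.

All tables are TSV with a header row; GWAS summary statistics are
whitespace-delimited (the common distribution format); gene sets use the
standard GMT layout (name, description, tab-separated members).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import CountMatrix


def read_counts(counts_path, design_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return CountMatrix(counts, design)


def write_counts(cm: CountMatrix, counts_path, design_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.design.to_csv(design_path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """BED-like TSV: gene id, chromosome, 0-based TSS position, strand."""
    ann = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss", "strand"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    return ann


def read_gwas(path) -> pd.DataFrame:
    """Whitespace-delimited summary statistics: snp, chrom, pos, pval."""
    tab = pd.read_csv(path, sep=r"\s+")
    required = {"snp", "chrom", "pos", "pval"}
    if not required.issubset(tab.columns):
        raise ValueError(f"GWAS table needs columns {sorted(required)}")
    return tab


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "octempo") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
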