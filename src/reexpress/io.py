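"""Plain-text readers/writers for the pipeline's fixture formats.

Matrices are tab-separated with a header row of sample IDs and a first
column of probe/gene IDs; probe annotation is a BED-like TSV; gene sets
use GMT; promoters use FASTA with ``gene|window:-450..+50`` headers;
PWMs are 4-row (A, C, G, T) tab-separated count matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_matrix", "write_matrix",
    "read_annotation", "write_annotation",
    "read_gmt", "write_gmt",
    "read_fasta", "write_fasta",
    "read_pwm", "write_pwm",
    "read_gene_list", "write_gene_list",
    "read_ground_truth", "write_ground_truth",
]

ANNOTATION_COLUMNS = ["chrom", "pos", "probe_id", "gene_id",
                      "tss_distance", "island_flag", "snp_flag"]


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_annotation(path) -> pd.DataFrame:
    """Probe annotation TSV (BED-like column order), indexed by probe."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation lacks columns {sorted(missing)}")
    df["island_flag"] = df["island_flag"].astype(bool)
    df["snp_flag"] = df["snp_flag"].astype(bool)
    return df.set_index("probe_id")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.reset_index()[ANNOTATION_COLUMNS].copy()
    out["island_flag"] = out["island_flag"].astype(int)
    out["snp_flag"] = out["snp_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = []
    for name, members in sets.items():
        desc = descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def promoter_header(gene_id: str, start: int = -450, end: int = 50) -> str:
    return f"{gene_id}|window:{start}..{end}"


def parse_promoter_header(header: str) -> tuple[str, int, int]:
    gene, _, window = header.partition("|window:")
    lo, _, hi = window.partition("..")
    return gene, int(lo), int(hi)


def read_pwm(path, name: str | None = None) -> np.ndarray:
    """4-row (A, C, G, T) tab-separated count matrix."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        base, values = parts[0], parts[1:]
        if base.upper() not in "ACGT":
            raise ValueError(f"unexpected PWM row label {base!r}")
        rows.append((base.upper(), [float(v) for v in values]))
    order = {b: i for i, (b, _) in enumerate(rows)}
    if sorted(order) != ["A", "C", "G", "T"]:
        raise ValueError("PWM file must contain exactly rows A, C, G, T")
    return np.array([dict(rows)[b] for b in "ACGT"])


def write_pwm(counts: np.ndarray, path) -> None:
    counts = np.asarray(counts)
    lines = ["\t".join([b, *(f"{v:g}" for v in counts[i])])
             for i, b in enumerate("ACGT")]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_ground_truth(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def write_ground_truth(truth: dict, path) -> None:
    if str(path).endswith((".yaml", ".yml")):
        Path(path).write_text(yaml.safe_dump(truth, sort_keys=True))
    else:
        Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
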