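"""Plain-text I/O: edge lists, gene lists, GMT module sets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from survmod.modules import CandidateModule


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Edge TSV with >= 3 columns (gene_a, gene_b, confidence)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least gene_a/gene_b columns")
    if df.shape[1] == 2:
        df["confidence"] = 1.0
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "confidence"]
    df["gene_a"] = df["gene_a"].astype(str)
    df["gene_b"] = df["gene_b"].astype(str)
    return df


def read_rna_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need rna_id/protein_gene columns")
    df = df.iloc[:, :2]
    df.columns = ["rna_id", "protein_gene"]
    return df.astype(str)


def read_gene_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gmt(modules: list[CandidateModule], path: str | Path) -> None:
    """One module per line: id, score description, tab-separated genes."""
    with open(path, "w") as fh:
        for i, mod in enumerate(modules, start=1):
            desc = (
                f"raw={mod.raw_score:.4f}"
                + (f";adj={mod.adjusted_score:.4f}" if mod.adjusted_score is not None else "")
                + (f";p={mod.empirical_p:.6f}" if mod.empirical_p is not None else "")
            )
            fh.write("\t".join([f"module_{i:03d}", desc, *mod.genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line: {line[:60]!r}")
        out[parts[0]] = parts[2:]
    return out
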