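"""Tabular input/output: gene/value tables, mutation matrices, rankings."""

from __future__ import annotations

import pandas as pd

__all__ = ["read_scores", "read_mutation_matrix", "write_rnk", "write_sif"]


def read_scores(path) -> dict:
    """Read a two-column gene/value TSV (header optional) into a dict."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            try:
                value = float(fields[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"line {lineno}: non-numeric value {fields[1]!r}")
            if fields[0] in scores:
                raise ValueError(f"line {lineno}: duplicate gene {fields[0]!r}")
            scores[fields[0]] = value
    if not scores:
        raise ValueError(f"no scores read from {path}")
    return scores


def read_mutation_matrix(path) -> pd.DataFrame:
    """Read a binary genes-by-samples TSV (gene IDs in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_rnk(path, genes, scores) -> None:
    """Write a GSEA-style .rnk file (gene<TAB>score, ranked descending)."""
    pairs = sorted(zip(genes, scores), key=lambda t: (-t[1], t[0]))
    with open(path, "w") as fh:
        for g, s in pairs:
            fh.write(f"{g}\t{s:.10g}\n")


def write_sif(path, edges, relation: str = "pp") -> None:
    """Write an edge list as SIF (node<TAB>relation<TAB>node)."""
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{relation}\t{v}\n")
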