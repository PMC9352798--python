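"""Readers and writers for the interchange formats.

Canonical table dialect: TSV, UTF-8, LF line endings, ``#`` comment
lines. Formats: expression matrix (first column ``gene``, remaining
columns sample ids), sample metadata (``sample``/``group``), edge lists
(two gene columns, pair stored in lexicographic order), LRI score tables,
DEG tables, GMT gene sets, plain gene lists, and JSON for the simulation
truth and the run manifest. Every writer's output is readable by its
reader.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .game import LRIScoreTable
from .network import CoexpressionNetwork, canonical_edge
from .saliency import GeneSetCollection
from .simulate import SyntheticTruth

_READ_KW = dict(sep="\t", comment="#", encoding="utf-8")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples matrix; unique gene ids in column 1, unique sample
    ids in the header; all cells finite numbers."""
    path = Path(path)
    try:
        # round_trip parsing: exact float64 recovery of our own %.17g output
        df = pd.read_csv(
            path, **_READ_KW, index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    if df.index.isna().any() or (df.index.astype(str).str.strip() == "").any():
        raise ParseError(f"{path}: missing gene id")
    num = df.apply(
        lambda col: pd.to_numeric(col, errors="coerce")
        if col.dtype == object
        else col
    )
    arr = num.to_numpy(dtype=float) if num.size else np.empty(df.shape)
    bad = ~np.isfinite(arr)
    if bad.any():
        gene = num.index[bad.any(axis=1)][0]
        # +2: header line plus 1-based numbering (comments shift this)
        line = df.index.get_loc(gene) + 2
        raise ParseError(
            f"{path}: non-numeric or non-finite value for gene {gene!r} (line ~{line})"
        )
    out = df.astype(float)
    out.index = out.index.astype(str)
    out.index.name = "gene"
    return out


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata with columns ``sample`` and ``group``."""
    path = Path(path)
    df = pd.read_csv(path, **_READ_KW, dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return df[["sample", "group"]]


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df[["sample", "group"]].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edge_list(path: str | Path, nodes: Iterable[str] | None = None) -> CoexpressionNetwork:
    """Two-column edge list; header line ``gene_a<TAB>gene_b`` optional.

    ``nodes`` extends the node set beyond edge endpoints (isolated genes).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            a, b = parts[0].strip(), parts[1].strip()
            if ln == 1 and (a, b) == ("gene_a", "gene_b"):
                continue
            edges.append((a, b))
    node_list: list[str] = list(nodes) if nodes is not None else []
    seen = set(node_list)
    for a, b in edges:
        for g in (a, b):
            if g not in seen:
                seen.add(g)
                node_list.append(g)
    return CoexpressionNetwork(node_list, edges)


def write_edge_list(network: CoexpressionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in network.edges:
            fh.write(f"{a}\t{b}\n")


def write_scores(table: LRIScoreTable, path: str | Path, precision: int = 6) -> None:
    table.to_dataframe(precision).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_scores(path: str | Path) -> LRIScoreTable:
    df = pd.read_csv(path, **_READ_KW, dtype={"gene": str})
    for col in ("gene", "lri_exact", "degree"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    genes = tuple(df["gene"])
    scores = tuple(Fraction(s) for s in df["lri_exact"])
    degrees = tuple(int(d) for d in df["degree"])
    return LRIScoreTable(genes, scores, degrees)


def write_deg(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.17g")


def read_deg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW, index_col=0)
    df["is_deg"] = df["is_deg"].astype(bool)
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; ``#`` comments and blank lines ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Standard GMT: name, description, then member genes, tab-separated."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{ln}: GMT rows need name, description and ≥1 gene"
                )
            name = parts[0].strip()
            if name in sets:
                raise ParseError(f"{path}:{ln}: duplicate set name {name!r}")
            members = [g.strip() for g in parts[2:] if g.strip()]
            if not members:
                raise ParseError(f"{path}:{ln}: set {name!r} has no genes")
            sets[name] = members
            descriptions[name] = parts[1].strip()
    return GeneSetCollection.from_sets(sets, universe, descriptions)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "module_members": [list(m) for m in truth.module_members],
        "hub_genes": list(truth.hub_genes),
        "deg_genes": list(truth.deg_genes),
        "module_correlations": list(truth.module_correlations),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_truth(path: str | Path) -> SyntheticTruth:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return SyntheticTruth(
        module_members=tuple(tuple(m) for m in data["module_members"]),
        hub_genes=tuple(data["hub_genes"]),
        deg_genes=tuple(data["deg_genes"]),
        module_correlations=tuple(data["module_correlations"]),
    )


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
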