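"""Readers and writers for every external format the pipeline touches.

All tabular files are tab-separated with a header row; sequence data is
FASTA (uppercased, DNA transcribed to RNA on read); gene sets are GMT;
networks go out as GraphML or SIF-plus-attribute-tables for Cytoscape-style
consumers. Errors carry file and line context.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx
import pandas as pd

BIOTYPES = ("mRNA", "miRNA", "snRNA", "snoRNA", "misc")
SMALL_RNA_BIOTYPES = ("miRNA", "snRNA", "snoRNA")

_RNA_ALPHABET = set("ACGUN")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# tabular: counts, sample sheet, annotation
# ---------------------------------------------------------------------------


def read_counts(path) -> pd.DataFrame:
    """Read a transcripts x samples counts TSV into an integer DataFrame.

    Counts must be non-negative integers; duplicate transcript ids are
    rejected with the offending ids named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated transcript ids {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample ids {dups}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: negative or non-integer count at row {row!r}, column {col!r}"
            )
    return df.astype(int)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_matrix(path) -> pd.DataFrame:
    """Read a real-valued transcripts x samples TSV (any processing stage)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet (sample_id, animal, tissue, library)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "animal", "tissue", "library"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicated sample ids {dups}")
    if "mapped_reads" in df.columns:
        df["mapped_reads"] = pd.to_numeric(df["mapped_reads"])
    return df.set_index("sample_id", drop=False)


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read transcript annotation (transcript_id, biotype, length_bp[, is_tf])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "biotype", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise FormatError(f"{path}: duplicated transcript ids {dups}")
    bad = ~df["biotype"].isin(BIOTYPES)
    if bad.any():
        raise FormatError(
            f"{path}: unknown biotype {df.loc[bad, 'biotype'].unique().tolist()}"
            f" (allowed: {list(BIOTYPES)})"
        )
    if (df["length_bp"] <= 0).any():
        row = df.loc[df["length_bp"] <= 0, "transcript_id"].iloc[0]
        raise FormatError(f"{path}: non-positive length for {row!r}")
    if "is_tf" not in df.columns:
        df["is_tf"] = False
    df["is_tf"] = df["is_tf"].astype(bool)
    return df.set_index("transcript_id", drop=False)


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into an ordered id -> RNA sequence map.

    Sequences are uppercased and transcribed (T -> U); ids are the first
    whitespace token of the header; duplicate ids and non-ACGUN characters
    are rejected.
    """
    path = Path(path)
    records: Dict[str, str] = {}
    current: Optional[str] = None
    chunks: List[str] = []

    def _commit(lineno):
        if current is None:
            return
        seq = "".join(chunks).upper().replace("T", "U")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {current!r}")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: invalid characters {sorted(bad)} in record {current!r}"
            )
        records[current] = seq

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _commit(lineno)
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if current in records:
                    raise FormatError(f"{path}:{lineno}: duplicate id {current!r}")
                chunks = []
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line)
        _commit(None)
    return records


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> Dict[str, Dict]:
    """Read a GMT gene-set file into {name: {description, members}}.

    Member lists are deduplicated preserving order; sets with no members
    are dropped with a warning.
    """
    path = Path(path)
    sets: Dict[str, Dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            name, desc, *members = fields
            members = list(dict.fromkeys(m for m in members if m))
            if not members:
                warnings.warn(f"{path}:{lineno}: gene set {name!r} has no members; dropped")
                continue
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = {"description": desc, "members": members}
    return sets


def write_gmt(sets: Dict[str, Dict], path) -> None:
    with open(path, "w") as fh:
        for name, rec in sets.items():
            fh.write("\t".join([name, rec.get("description", "")] + list(rec["members"])) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

_NODE_ATTRS = ("biotype", "de_comparisons", "is_tf", "rif_significant", "hub", "hub_centrality")


def write_network(graph: nx.Graph, path, dialect: str = "graphml") -> List[Path]:
    """Write a co-expression network for downstream visualization.

    ``graphml`` emits one file with node attributes and the signed edge
    correlation ``r``; ``sif`` emits the edge list plus two attribute TSVs
    (``<stem>.nodes.tsv``, ``<stem>.edges.tsv``).
    """
    path = Path(path)
    if dialect == "graphml":
        g = graph.copy()
        for _, data in g.nodes(data=True):
            if isinstance(data.get("de_comparisons"), (list, tuple, set)):
                data["de_comparisons"] = ",".join(sorted(data["de_comparisons"]))
        nx.write_graphml(g, path)
        return [path]
    if dialect == "sif":
        stem = path.with_suffix("")
        sif_path = stem.with_suffix(".sif")
        with open(sif_path, "w") as fh:
            for a, b, data in graph.edges(data=True):
                rel = "neg" if data.get("r", 0.0) < 0 else "pos"
                fh.write(f"{a}\t{rel}\t{b}\n")
            for node in graph.nodes:
                if graph.degree(node) == 0:
                    fh.write(f"{node}\n")
        node_rows = []
        for node, data in graph.nodes(data=True):
            row = {"id": node}
            for attr in _NODE_ATTRS:
                val = data.get(attr)
                if isinstance(val, (list, tuple, set)):
                    val = ",".join(sorted(val))
                row[attr] = val
            node_rows.append(row)
        nodes_path = stem.parent / (stem.name + ".nodes.tsv")
        edges_path = stem.parent / (stem.name + ".edges.tsv")
        pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
        edge_rows = [
            {"node_a": a, "node_b": b, "r": data.get("r")}
            for a, b, data in graph.edges(data=True)
        ]
        pd.DataFrame(edge_rows, columns=["node_a", "node_b", "r"]).to_csv(
            edges_path, sep="\t", index=False
        )
        return [sif_path, nodes_path, edges_path]
    raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path) -> nx.Graph:
    g = nx.read_graphml(Path(path))
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        if "de_comparisons" in data and isinstance(data["de_comparisons"], str):
            data["de_comparisons"] = (
                sorted(data["de_comparisons"].split(",")) if data["de_comparisons"] else []
            )
        out.add_node(node, **data)
    for a, b, data in g.edges(data=True):
        out.add_edge(a, b, **data)
    return out


# ---------------------------------------------------------------------------
# JSON helpers (simulation truth, run reports)
# ---------------------------------------------------------------------------


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
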