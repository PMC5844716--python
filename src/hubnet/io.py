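"""Readers and writers for the plain-text interchange formats.

All tabular files are TSV (expression matrix, group assignments, edge lists,
pathway adjacency, GO parent-child edges) or CSV (qPCR Ct tables); gene sets
use the standard GMT layout (term, description, then member genes, tab
separated). Every writer has a matching reader and the pair round-trips
losslessly, which the test suite asserts.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

# --------------------------------------------------------------------------
# expression matrix + group factor


def write_expression_tsv(data: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample intensity matrix (first column ``gene``)."""
    out = data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    return data


def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    """Write the sample -> group assignment (columns ``sample``, ``group``)."""
    df = pd.DataFrame({"sample": groups.index.astype(str), "group": groups.values})
    df.to_csv(path, sep="\t", index=False)


def read_groups_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


# --------------------------------------------------------------------------
# gene sets (GMT)


def write_gmt(terms: list[tuple[str, str, list[str]]], path: str | Path) -> None:
    """Write gene sets as GMT: ``term_id<TAB>description<TAB>gene...``."""
    with open(path, "w") as fh:
        for term_id, description, members in terms:
            fh.write("\t".join([term_id, description, *members]) + "\n")


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    terms = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            terms.append((fields[0], fields[1], fields[2:]))
    return terms


# --------------------------------------------------------------------------
# edge lists


def write_edges_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a signed directed edge list (columns ``source target sign``)."""
    edges.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"source", "target", "sign"}
    if not expected.issubset(df.columns):
        raise ValueError(f"edge TSV must have columns {sorted(expected)}")
    return df


def write_adjacency_tsv(pairs: list[tuple[str, str]], path: str | Path) -> None:
    """Write undirected pathway-pathway adjacency (columns ``a b``)."""
    pd.DataFrame(pairs, columns=["a", "b"]).to_csv(path, sep="\t", index=False)


def read_adjacency_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.itertuples(index=False, name=None))


def write_parent_edges_tsv(pairs: list[tuple[str, str]], path: str | Path) -> None:
    """Write term hierarchy edges (columns ``child parent``)."""
    pd.DataFrame(pairs, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def read_parent_edges_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.itertuples(index=False, name=None))


# --------------------------------------------------------------------------
# qPCR Ct tables


def write_ct_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a Ct table (columns ``gene sample group ct``)."""
    table.to_csv(path, index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene": str, "sample": str, "group": str})
    expected = {"gene", "sample", "group", "ct"}
    if not expected.issubset(df.columns):
        raise ValueError(f"Ct CSV must have columns {sorted(expected)}")
    return df


# --------------------------------------------------------------------------
# ground truth


def write_ground_truth_json(truth_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_ground_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
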