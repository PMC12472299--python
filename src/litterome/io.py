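"""Plain-text readers and writers for all pipeline formats.

Community tables use the classic tab-delimited layout: one row per taxon,
first column the taxon id, one column per sample, and an optional trailing
``taxonomy`` column with a semicolon-delimited lineage.  Trees are Newick,
everything else is CSV.  Output tables begin with a ``#`` header comment
recording the package version, the writing stage and the seed so that every
artifact is auditable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import dendropy
import networkx as nx
import pandas as pd

from . import __version__
from .containers import CommunityTable

__all__ = [
    "read_community",
    "write_community",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_csv_table",
    "write_csv_table",
    "write_distance_matrix",
    "write_network",
    "write_json",
]


def _audit_header(stage: str, seed: int | None = None, **params) -> str:
    bits = [f"litterome v{__version__}", f"stage={stage}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    bits += [f"{k}={v}" for k, v in params.items()]
    return "# " + " ".join(bits) + "\n"


def read_community(path: str | Path, metadata: pd.Series | None = None) -> CommunityTable:
    """Parse a tab-delimited taxa-by-samples count table.

    Raises a parse error naming the offending row/column on negative or
    non-numeric counts; an absent taxonomy column yields blank lineages.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    taxonomy = None
    if raw.columns[-1].lower() == "taxonomy":
        taxonomy = raw.iloc[:, -1].fillna("")
        raw = raw.iloc[:, :-1]
    counts = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for taxon, value in raw[col].items():
            try:
                num = float(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name}: non-numeric count {value!r} at taxon {taxon!r}, sample {col!r}"
                ) from None
            if num < 0:
                raise ValueError(
                    f"{path.name}: negative count {num} at taxon {taxon!r}, sample {col!r}"
                )
            counts.at[taxon, col] = num
    counts = counts.T.astype(int)  # samples x taxa
    counts.index.name = None
    counts.columns.name = None
    return CommunityTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


def write_community(
    table: CommunityTable, path: str | Path, stage: str = "io", seed: int | None = None
) -> None:
    path = Path(path)
    out = table.counts.T.copy()  # taxa x samples
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    with open(path, "w") as fh:
        fh.write(_audit_header(stage, seed))
        out.to_csv(fh, sep="\t", index_label="OTU_ID")


def read_metadata(path: str | Path) -> pd.Series:
    """Sample metadata CSV with columns ``sample_id,group``."""
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{Path(path).name}: metadata needs sample_id and group columns")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_metadata(metadata: pd.Series, path: str | Path, stage: str = "io") -> None:
    with open(path, "w") as fh:
        fh.write(_audit_header(stage))
        metadata.rename("group").to_csv(fh, index_label="sample_id")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    Duplicate tip labels raise; zero-length branches only warn.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific parse errors
        if "Multiple occurrences" in str(exc) or "duplicate" in str(exc).lower():
            raise ValueError(f"duplicate tip labels in tree {Path(path).name}") from exc
        raise ValueError(f"unparsable Newick in {Path(path).name}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {sorted(dupes)}")
    zero = [
        e for e in tree.preorder_edge_iter()
        if e.length is not None and e.length == 0
    ]
    if zero:
        warnings.warn(f"tree contains {len(zero)} zero-length branches")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def read_csv_table(path: str | Path) -> pd.DataFrame:
    """Generic per-sample CSV (enzymes, bands, ...) indexed by sample id."""
    return pd.read_csv(path, index_col=0, comment="#")


def write_csv_table(
    df: pd.DataFrame, path: str | Path, stage: str = "io", seed: int | None = None,
    index_label: str = "sample_id",
) -> None:
    with open(path, "w") as fh:
        fh.write(_audit_header(stage, seed))
        df.to_csv(fh, index_label=index_label)


def write_distance_matrix(dm: pd.DataFrame, path: str | Path, stage: str = "io") -> None:
    with open(path, "w") as fh:
        fh.write(_audit_header(stage))
        dm.to_csv(fh, sep="\t", index_label="sample_id")


def write_network(graph: nx.Graph, out_prefix: str | Path, roles: pd.DataFrame | None = None) -> None:
    """Export a co-occurrence graph as GraphML plus edge/node TSV tables."""
    out_prefix = Path(out_prefix)
    nx.write_graphml(graph, f"{out_prefix}.graphml")
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "rho": d.get("rho"), "q": d.get("q")}
            for u, v, d in graph.edges(data=True)
        ]
    )
    edges.to_csv(f"{out_prefix}_edges.tsv", sep="\t", index=False)
    nodes = pd.DataFrame(
        [
            {"node": n, "taxonomy": d.get("taxonomy", ""), "abundance": d.get("abundance")}
            for n, d in graph.nodes(data=True)
        ]
    ).set_index("node")
    if roles is not None:
        nodes = nodes.join(roles[["module", "zi", "pi", "role", "keystone"]], how="left")
    nodes.to_csv(f"{out_prefix}_nodes.tsv", sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(value):
    if hasattr(value, "item"):
        return value.item()
    if isinstance(value, pd.Series):
        return value.to_dict()
    if isinstance(value, pd.DataFrame):
        return value.to_dict(orient="index")
    return str(value)
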