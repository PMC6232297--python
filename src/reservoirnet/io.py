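"""Readers and writers for every on-disk format the pipeline touches.

Tabular data travels as UTF-8 tab-delimited text (one header row); the mothur
``.shared`` dialect of the OTU table is also understood.  Networks are written
as GraphML, GEXF or a flat edge-list TSV.  Readers validate and reject rather
than silently repairing malformed input.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import EnvTable, OTUTable, TaxonomyMap

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_env_table",
    "write_env_table",
    "read_metadata",
    "read_taxonomy",
    "write_network",
    "read_network",
]

_FLOAT_FMT = "%.8g"  # >= 6 significant digits on all numeric output


def _read_delimited(path, sep="\t"):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=sep, index_col=0)


def read_otu_table(path, dialect: str = "wide-tsv", metadata=None,
                   samples_as_rows: bool = True) -> OTUTable:
    """Read an OTU count table.

    Parameters
    ----------
    dialect:
        ``"wide-tsv"`` — header row of OTU ids, first column sample ids (or the
        transpose with ``samples_as_rows=False``); ``"mothur-shared"`` — mothur
        ``.shared`` layout with ``label``/``Group``/``numOtus`` columns, the
        ``Group`` column holding sample ids.
    metadata:
        Optional DataFrame of per-sample design metadata.
    """
    if dialect == "wide-tsv":
        df = _read_delimited(path)
        if not samples_as_rows:
            df = df.T
    elif dialect == "mothur-shared":
        raw = pd.read_csv(path, sep="\t")
        required = {"label", "Group", "numOtus"}
        if not required.issubset(raw.columns):
            missing = sorted(required - set(raw.columns))
            raise ValueError(f"mothur shared file missing columns: {missing}")
        df = raw.drop(columns=["label", "numOtus"]).set_index("Group")
        df.index.name = "sample"
    else:
        raise ValueError(f"unknown OTU table dialect {dialect!r}")
    _validate_integer_counts(df)
    return OTUTable(df, metadata=metadata)


def _validate_integer_counts(df: pd.DataFrame) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric count at sample {row!r}, OTU {col!r}")
        df[col] = coerced
    # negativity / integrality errors are raised (with cell names) by OTUTable


def write_otu_table(table: OTUTable, path) -> None:
    df = table.counts.copy()
    df.index.name = df.index.name or "sample"
    df.to_csv(path, sep="\t")


def read_env_table(path) -> EnvTable:
    """Read an environmental table (TSV or CSV by extension); blanks -> NaN."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = _read_delimited(path, sep=sep)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value {df.loc[row, col]!r} at sample {row!r}, "
                f"variable {col!r}"
            )
        df[col] = coerced
    return EnvTable(df)


def write_env_table(env: EnvTable, path) -> None:
    df = env.values.copy()
    df.index.name = df.index.name or "sample"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    """Per-sample design metadata (reservoir / site / month columns)."""
    return _read_delimited(path)


def read_taxonomy(path) -> TaxonomyMap:
    """TSV with columns otu, phylum, class, genus (blank = unassigned)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "otu" not in df.columns:
        raise ValueError("taxonomy file must have an 'otu' column")
    if df["otu"].duplicated().any():
        dups = df.loc[df["otu"].duplicated(), "otu"].tolist()
        raise ValueError(f"duplicate OTU ids in taxonomy: {dups}")
    out = {}
    for _, row in df.iterrows():
        out[row["otu"]] = tuple(
            None if pd.isna(row.get(rank)) or row.get(rank) == "" else row.get(rank)
            for rank in TaxonomyMap.RANKS
        )
    return TaxonomyMap(out)


# ---------------------------------------------------------------------------
# networks


def _edge_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"source": a, "target": b, **{k: d.get(k) for k in ("r", "p", "q", "sign", "weight")}}
        for a, b, d in g.edges(data=True)
    ]
    cols = ["source", "target", "r", "p", "q", "sign", "weight"]
    return pd.DataFrame(rows, columns=cols)


def write_network(pos: nx.Graph, neg: nx.Graph, path, fmt: str = "graphml") -> list:
    """Write the co-occurrence (positive) and co-exclusion (negative) graphs.

    ``path`` is a stem; the sign tag and extension are appended.  Returns the
    list of files written.  GraphML round-trips all node attributes (kind,
    module, betweenness, x, y) and edge attributes (r, p, q, sign, weight).
    """
    path = Path(path)
    written = []
    for tag, g in (("cooccurrence", pos), ("coexclusion", neg)):
        if fmt == "graphml":
            target = path.parent / f"{path.name}.{tag}.graphml"
            nx.write_graphml(g, target)
        elif fmt == "gexf":
            target = path.parent / f"{path.name}.{tag}.gexf"
            nx.write_gexf(g, target)
        elif fmt == "edge-tsv":
            target = path.parent / f"{path.name}.{tag}.edges.tsv"
            _edge_frame(g).to_csv(target, sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
        else:
            raise ValueError(f"unknown network format {fmt!r}")
        written.append(target)
    return written


def read_network(path) -> nx.Graph:
    """Re-read a GraphML/GEXF file written by :func:`write_network`."""
    path = str(path)
    if path.endswith(".graphml"):
        return nx.read_graphml(path)
    if path.endswith(".gexf"):
        return nx.read_gexf(path)
    raise ValueError(f"cannot infer network format from {path!r}")
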