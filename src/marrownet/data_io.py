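"""Reading, validation and serialization of pipeline inputs and outputs.

The universal input is a samples-by-metabolites concentration matrix (μM)
keyed by ``(patient_id, compartment, day)`` where the compartment is bone
marrow extracellular fluid (``BM``) or peripheral blood plasma (``PB``) and
the day is 0, 8 or 29 of induction therapy. Missing measurements are stored
as explicit NaN markers and are never conflated with true zeros: the
relevance-network stage counts nonzero observations, so the distinction is
load-bearing.

Formats are plain delimited text (TSV by default, CSV accepted), GraphML for
networks, and an edge TSV with one row per edge in lexicographic node order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .panels import AMINO, CLASSES, LIPID, OTHER  # noqa: F401  (re-exported)

log = logging.getLogger(__name__)

COMPARTMENTS = ("BM", "PB")
DAYS = (0, 8, 29)
META_COLUMNS = ("patient_id", "compartment", "day")

EDGE_TSV_COLUMNS = ("node_a", "node_b", "r", "mi", "p", "q", "sign", "edge_class")


class DataError(ValueError):
    """Invalid input table, annotation or network."""


def normalize_name(name: str) -> str:
    """Whitespace-normalized, case-insensitive canonical metabolite name."""
    return " ".join(str(name).split()).lower()


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ConcentrationTable:
    """Samples × metabolites concentration matrix (μM).

    ``data`` is indexed by a ``(patient_id, compartment, day)`` MultiIndex;
    columns are canonical metabolite names; missing values are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_flat(cls, flat: pd.DataFrame) -> "ConcentrationTable":
        """Build from a flat frame whose first columns are the sample key."""
        missing_meta = [c for c in META_COLUMNS if c not in flat.columns]
        if missing_meta:
            raise DataError(f"missing metadata columns: {missing_meta}")
        flat = flat.copy()
        flat["patient_id"] = flat["patient_id"].astype(str)
        flat["compartment"] = flat["compartment"].astype(str).str.strip().str.upper()
        try:
            flat["day"] = flat["day"].astype(int)
        except (TypeError, ValueError) as exc:
            raise DataError(f"non-integer day values: {exc}") from None
        data = flat.set_index(list(META_COLUMNS))
        mapped = {}
        for col in data.columns:
            canon = normalize_name(col)
            if canon in mapped:
                raise DataError(f"duplicate metabolite after name normalization: {canon!r}")
            mapped[canon] = _check_numeric(data[col], col)
        out = pd.DataFrame(mapped, index=data.index)
        return cls(out)

    def validate(self) -> None:
        idx = self.data.index
        if list(idx.names) != list(META_COLUMNS):
            raise DataError(f"index must be {META_COLUMNS}, got {idx.names}")
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].tolist()
            raise DataError(f"duplicate sample keys: {dup}")
        bad_comp = set(idx.get_level_values("compartment")) - set(COMPARTMENTS)
        if bad_comp:
            raise DataError(f"unknown compartments: {sorted(bad_comp)}")
        bad_day = set(idx.get_level_values("day")) - set(DAYS)
        if bad_day:
            raise DataError(f"unknown days: {sorted(bad_day)} (allowed {DAYS})")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise DataError("negative concentrations present")

    # -- accessors --------------------------------------------------------
    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.data.index.get_level_values("patient_id")))

    def values_at(self, compartment: str, day: int) -> pd.DataFrame:
        """Metabolite values for one compartment/day, indexed by patient."""
        mask = (
            (self.data.index.get_level_values("compartment") == compartment)
            & (self.data.index.get_level_values("day") == int(day))
        )
        sub = self.data[mask]
        sub.index = sub.index.get_level_values("patient_id")
        return sub.sort_index()

    def to_flat(self) -> pd.DataFrame:
        return self.data.reset_index()


def _check_numeric(col: pd.Series, name) -> pd.Series:
    coerced = pd.to_numeric(col, errors="coerce")
    bad = coerced.isna() & col.notna() & (col.astype(str).str.strip() != "") \
        & (col.astype(str).str.strip().str.upper() != "NA")
    if bad.any():
        raise DataError(f"non-numeric value(s) in column {name!r}: {col[bad].tolist()}")
    return coerced


def read_concentration_table(path, sep: str | None = None) -> ConcentrationTable:
    """Read a TSV/CSV concentration table.

    The header names the metadata columns ``patient_id, compartment, day``
    followed by one column per metabolite. Empty cells and ``NA`` become
    missing markers, never zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _sep_for(path)
    flat = pd.read_csv(path, sep=sep, na_values=["", "NA"], keep_default_na=False)
    return ConcentrationTable.from_flat(flat)


def write_concentration_table(table: ConcentrationTable, path, sep: str | None = None) -> None:
    path = Path(path)
    sep = sep or _sep_for(path)
    table.to_flat().to_csv(path, sep=sep, index=False, na_rep="")


@dataclass
class AnnotationMap:
    """Total map metabolite -> class (lipid_metabolism / amino_acid / other)."""

    classes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = {}
        for name, klass in dict(self.classes).items():
            key = normalize_name(name)
            if klass not in CLASSES:
                raise DataError(f"unknown class token {klass!r} for {name!r} (allowed {CLASSES})")
            if key in canon and canon[key] != klass:
                raise DataError(f"conflicting classes for {key!r}")
            canon[key] = klass
        self.classes = canon

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.classes

    def __getitem__(self, name: str) -> str:
        key = normalize_name(name)
        if key not in self.classes:
            raise KeyError(name)
        return self.classes[key]

    def require_cover(self, metabolites: Iterable[str]) -> None:
        """Raise, naming the culprits, if any metabolite lacks a class."""
        missing = sorted(m for m in metabolites if m not in self)
        if missing:
            raise DataError(f"metabolites missing from annotation: {missing}")


def read_annotation(path, sep: str | None = None) -> AnnotationMap:
    """Read a two-column (metabolite, class) delimited file.

    A header row ``metabolite<sep>class`` is accepted and skipped.
    """
    path = Path(path)
    sep = sep or _sep_for(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str).dropna(how="all")
    if raw.shape[1] != 2:
        raise DataError(f"annotation must have exactly 2 columns, got {raw.shape[1]}")
    rows = raw.itertuples(index=False)
    first = next(rows, None)
    pairs = []
    if first is not None and normalize_name(first[0]) != "metabolite":
        pairs.append(first)
    pairs.extend(rows)
    return AnnotationMap({m: str(k).strip() for m, k in pairs})


def write_annotation(ann: AnnotationMap, path, sep: str | None = None) -> None:
    path = Path(path)
    sep = sep or _sep_for(path)
    frame = pd.DataFrame(sorted(ann.classes.items()), columns=["metabolite", "class"])
    frame.to_csv(path, sep=sep, index=False)


# -- network serialization -----------------------------------------------

def _edge_rows(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, attrs in graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append(
            {
                "node_a": a,
                "node_b": b,
                "r": attrs["r"],
                "mi": attrs["mi"],
                "p": attrs["p"],
                "q": attrs["q"],
                "sign": attrs["sign"],
                "edge_class": attrs["edge_class"],
            }
        )
    frame = pd.DataFrame(rows, columns=list(EDGE_TSV_COLUMNS))
    return frame.sort_values(["node_a", "node_b"]).reset_index(drop=True)


def write_network(net, path, format: str = "edge_tsv") -> None:
    """Serialize a relevance network.

    GraphML carries node class and the full edge attribute set; the edge TSV
    has one row per edge with columns ``node_a node_b r mi p q sign
    edge_class`` in lexicographic node order.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        g.graph.update({k: str(v) for k, v in net.provenance.items()})
        for n, attrs in net.graph.nodes(data=True):
            g.add_node(n, metabolite_class=attrs.get("metabolite_class", OTHER))
        for u, v, attrs in net.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                r=float(attrs["r"]),
                mi=float(attrs["mi"]),
                p=float(attrs["p"]),
                q=float(attrs["q"]),
                sign=str(attrs["sign"]),
                edge_class=str(attrs["edge_class"]),
            )
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        _edge_rows(net.graph).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv"):
    """Deserialize a network written by :func:`write_network`."""
    from .network import RelevanceNetwork  # local import: avoid cycle

    path = Path(path)
    g = nx.Graph()
    provenance: dict = {}
    if format == "graphml":
        raw = nx.read_graphml(path)
        provenance = dict(raw.graph)
        for n, attrs in raw.nodes(data=True):
            g.add_node(n, metabolite_class=attrs.get("metabolite_class", OTHER))
        for u, v, attrs in raw.edges(data=True):
            g.add_edge(
                u,
                v,
                r=float(attrs["r"]),
                mi=float(attrs["mi"]),
                p=float(attrs["p"]),
                q=float(attrs["q"]),
                sign=str(attrs["sign"]),
                edge_class=str(attrs["edge_class"]),
            )
    elif format == "edge_tsv":
        frame = pd.read_csv(path, sep="\t")
        for row in frame.itertuples(index=False):
            g.add_edge(
                row.node_a,
                row.node_b,
                r=float(row.r),
                mi=float(row.mi),
                p=float(row.p),
                q=float(row.q),
                sign=str(row.sign),
                edge_class=str(row.edge_class),
            )
    else:
        raise ValueError(f"unknown network format {format!r}")
    return RelevanceNetwork(graph=g, provenance=provenance)
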