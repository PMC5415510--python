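"""Reading and writing the tabular and geometric inputs of a regionalization run.

The substrate of every analysis is a table of spatial units (e.g. small
watershed polygons) carrying numeric geospatial variables grouped into
themes (terrestrial / climate / freshwater), plus an undirected contiguity
graph over those units.  Point-level ecosystem responses (e.g. lake total
phosphorus in μg/L, Secchi depth in m) attach to units for downstream
variance partitioning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

VALID_THEMES = ("terrestrial", "climate", "freshwater", "other")


@dataclass
class SpatialUnitTable:
    """Spatial units x raw geospatial variables, possibly with missing entries.

    ``values`` is an (n, p) float array where NaN marks a missing
    observation.  ``themes`` maps every variable name to one of
    ``terrestrial``, ``climate``, ``freshwater`` or ``other``.
    """

    unit_id: list[str]
    values: np.ndarray
    variable_names: list[str]
    themes: dict[str, str] = field(default_factory=dict)
    area: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (units x variables)")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need at least 2 units and 1 variable, got {n} x {p}")
        if len(self.unit_id) != n:
            raise ValueError("unit_id length does not match values rows")
        if len(self.variable_names) != p:
            raise ValueError("variable_names length does not match values columns")
        dupes = _duplicates(self.unit_id)
        if dupes:
            raise ValueError(f"duplicate unit ids: {sorted(dupes)}")
        if any(not u for u in self.unit_id):
            raise ValueError("empty unit id")
        vdupes = _duplicates(self.variable_names)
        if vdupes:
            raise ValueError(f"duplicate variable names: {sorted(vdupes)}")
        for v in self.variable_names:
            self.themes.setdefault(v, "other")
        bad = {v: t for v, t in self.themes.items() if t not in VALID_THEMES}
        if bad:
            raise ValueError(f"invalid themes {bad}; valid: {VALID_THEMES}")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "unit_id", self.unit_id)
        return df

    def index_of(self, unit_ids: Iterable[str]) -> np.ndarray:
        lookup = {u: i for i, u in enumerate(self.unit_id)}
        try:
            return np.array([lookup[u] for u in unit_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown unit id {exc.args[0]!r}") from None


@dataclass
class AdjacencyGraph:
    """Undirected contiguity graph over spatial units (no self-loops)."""

    unit_ids: list[str]
    edges: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        known = set(self.unit_ids)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            unknown = set(e) - known
            if unknown:
                raise ValueError(f"edge endpoint(s) not in unit list: {sorted(unknown)}")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on unit {a!r}")
        self.edges.add(frozenset((a, b)))

    def neighbors(self, unit: str) -> set[str]:
        return {next(iter(e - {unit})) for e in self.edges if unit in e}

    def to_sparse(self, order: list[str] | None = None) -> sparse.csr_matrix:
        """Binary symmetric adjacency matrix in the given unit order."""
        order = order if order is not None else self.unit_ids
        idx = {u: i for i, u in enumerate(order)}
        rows, cols = [], []
        for e in self.edges:
            a, b = tuple(e)
            if a not in idx or b not in idx:  # endpoints outside the ordering
                continue
            i, j = idx[a], idx[b]
            rows += [i, j]
            cols += [j, i]
        n = len(order)
        data = np.ones(len(rows), dtype=float)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def degree_zero_units(self) -> list[str]:
        touched = set().union(*self.edges) if self.edges else set()
        return [u for u in self.unit_ids if u not in touched]


@dataclass
class ResponseTable:
    """Point-level ecosystem responses located inside spatial units.

    ``data`` holds one row per point: ``point_id``, ``unit_id`` and one
    column per response (NaN = missing for that response).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"point_id", "unit_id"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"response table missing columns: {sorted(missing)}")
        dupes = _duplicates(list(self.data["point_id"]))
        if dupes:
            raise ValueError(f"duplicate point ids: {sorted(dupes)}")

    @property
    def response_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("point_id", "unit_id")]


def _duplicates(items: list) -> set:
    seen: set = set()
    dupes: set = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# readers


def read_unit_table(path: str | Path, theme_map: str | Path | None = None) -> SpatialUnitTable:
    """Read a unit feature CSV: first column = unit id, rest numeric variables.

    Empty cells become missing values (NaN), never zero.  ``theme_map`` is an
    optional two-column CSV ``variable,theme``; variables absent from it
    default to theme ``other``.
    """
    df = pd.read_csv(path, dtype={0: str}, keep_default_na=True)
    if df.shape[1] < 2:
        raise ValueError("unit table needs an id column plus at least one variable")
    id_col = df.columns[0]
    unit_id = df[id_col].astype(str).tolist()
    var_names = list(df.columns[1:])
    values = np.empty((len(df), len(var_names)), dtype=float)
    for j, col in enumerate(var_names):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise ValueError(
                f"non-numeric cell in column {col!r} at file row {row}"
            ) from None
    themes: dict[str, str] = {}
    if theme_map is not None:
        tm = pd.read_csv(theme_map, dtype=str)
        themes = dict(zip(tm.iloc[:, 0], tm.iloc[:, 1]))
    return SpatialUnitTable(unit_id=unit_id, values=values, variable_names=var_names, themes=themes)


def read_adjacency(path: str | Path, unit_table: SpatialUnitTable) -> AdjacencyGraph:
    """Read a two-column edge-list CSV into an undirected contiguity graph.

    Duplicate and reversed pairs collapse; units with no neighbor trigger a
    warning (islands degrade constrained clustering but are legal input).
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("adjacency CSV needs two columns of unit-id pairs")
    known = set(unit_table.unit_id)
    graph = AdjacencyGraph(unit_ids=list(unit_table.unit_id))
    for a, b in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        if a == b:
            raise ValueError(f"self-loop on unit {a!r}")
        for u in (a, b):
            if u not in known:
                raise ValueError(f"edge references unknown unit id {u!r}")
        graph.add_edge(a, b)
    isolated = graph.degree_zero_units()
    if isolated:
        warnings.warn(
            f"{len(isolated)} unit(s) have no neighbors (e.g. {isolated[:5]}); "
            "spatially isolated units should be removed before constrained clustering",
            stacklevel=2,
        )
    return graph


def adjacency_from_polygons(path: str | Path, rule: str = "rook",
                            id_property: str = "unit_id") -> AdjacencyGraph:
    """Derive contiguity from a GeoJSON FeatureCollection of polygons.

    rook (default): adjacent iff the shared boundary has positive length —
    the usual "share a border" reading for watershed polygons.  queen:
    adjacent iff boundaries touch at all (corner contact counts).
    """
    from shapely.geometry import shape

    if rule not in ("rook", "queen"):
        raise ValueError(f"rule must be 'rook' or 'queen', got {rule!r}")
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    ids: list[str] = []
    geoms = []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"feature {i} lacks the {id_property!r} property")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for feature {props[id_property]!r}")
        ids.append(str(props[id_property]))
        geoms.append(geom)
    graph = AdjacencyGraph(unit_ids=ids)
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0:
                graph.add_edge(ids[i], ids[j])
    return graph


def read_responses(path: str | Path) -> ResponseTable:
    """Read a point-response CSV: point_id, unit_id, then response columns."""
    df = pd.read_csv(path, dtype={0: str, 1: str})
    df = df.rename(columns={df.columns[0]: "point_id", df.columns[1]: "unit_id"})
    return ResponseTable(data=df)


# ---------------------------------------------------------------------------
# writers


def write_unit_table(table: SpatialUnitTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_adjacency(graph: AdjacencyGraph, path: str | Path) -> None:
    rows = sorted(tuple(sorted(e)) for e in graph.edges)
    pd.DataFrame(rows, columns=["unit_a", "unit_b"]).to_csv(path, index=False)


def write_assignment(regionalization, path: str | Path) -> None:
    pd.DataFrame(
        {"unit_id": regionalization.unit_id, "region": regionalization.label}
    ).to_csv(path, index=False)


def read_assignment(path: str | Path):
    from .cluster import Regionalization

    df = pd.read_csv(path, dtype={"unit_id": str})
    return Regionalization(
        unit_id=df["unit_id"].astype(str).tolist(),
        label=df["region"].to_numpy(dtype=int),
        k=int(df["region"].max()),
    )


def export_results(regionalization, reports: Mapping[str, object] | None,
                   out_dir: str | Path) -> list[Path]:
    """Write assignment CSV plus any quality / selection / importance reports.

    Returns the paths written.  Reading the assignment CSV back reproduces
    the unit -> label map exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []

    p = out / "assignment.csv"
    write_assignment(regionalization, p)
    written.append(p)

    reports = reports or {}
    for name, rep in reports.items():
        if hasattr(rep, "to_frame"):
            p = out / f"{name}.csv"
            rep.to_frame().to_csv(p, index=False)
        elif hasattr(rep, "to_dict"):
            p = out / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(rep.to_dict(), fh, indent=2)
        else:
            p = out / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(rep, fh, indent=2)
        written.append(p)
    return written
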