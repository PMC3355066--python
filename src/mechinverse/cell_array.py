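"""Polygonal cell arrays: data model, validation, geometry and file I/O.

A two-dimensional epithelial sheet is represented as a polygonal tiling:
vertices (tricellular junctions, or higher-order "rosettes"), edges
(cell-cell interfaces approximated by their chords) and cells (counter-
clockwise vertex loops).  Three topologies are supported:

``closed``
    a finite island of cells surrounded by an exterior region; force
    balance holds at every vertex and the exterior pressure is the
    reference zero.
``open``
    a field-of-view patch cut from a larger tissue; vertices touching the
    exterior/out-of-view region are not balanced.
``toroidal``
    a periodic box (used by the simulator); all geometry uses the
    minimum-image convention.

Edges carry an orientation convention: for the directed chord from
``vertex_pair[0]`` to ``vertex_pair[1]``, ``cell_pair[0]`` lies on the
LEFT.  The exterior region is denoted by the cell id ``EXTERIOR == -1``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateEdgeError,
    GeometryError,
    TopologyError,
    ValidationError,
)

EXTERIOR = -1

#: edges shorter than this fraction of the mean edge length are rejected
DEGENERACY_FRACTION = 1e-9


@dataclass
class Vertex:
    """A junction point of three or more cell interfaces."""

    id: int
    position: np.ndarray
    is_interior: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(2)


@dataclass
class Edge:
    """A cell-cell interface chord.

    ``cell_pair[0]`` is the cell to the left of the directed segment
    ``vertex_pair[0] -> vertex_pair[1]``.  ``curvature`` is an optional
    signed curvature (1/length), positive when the interface bows away
    from the left cell (towards the right cell).
    """

    id: int
    vertex_pair: tuple[int, int]
    cell_pair: tuple[int, int]
    curvature: float | None = None


@dataclass
class Cell:
    """A cell: counter-clockwise loop of vertex ids."""

    id: int
    vertex_loop: list[int]
    is_boundary: bool = False
    label: str | None = None


def minimum_image(delta: np.ndarray, box) -> np.ndarray:
    """Wrap displacement(s) ``delta`` into the centred periodic box."""
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


class CellArray:
    """A validated polygonal tiling of a cell sheet.

    Parameters
    ----------
    vertices, edges, cells : iterables of :class:`Vertex`, :class:`Edge`,
        :class:`Cell`.
    topology_kind : {"closed", "open", "toroidal"}
    box : (Lx, Ly), required iff toroidal.
    validate : bool
        Run full invariant validation (default).  Internal callers that
        construct arrays from already-validated ones may skip it.
    """

    def __init__(self, vertices, edges, cells, topology_kind, box=None,
                 validate=True):
        self.vertices: dict[int, Vertex] = {v.id: v for v in vertices}
        self.edges: dict[int, Edge] = {e.id: e for e in edges}
        self.cells: dict[int, Cell] = {c.id: c for c in cells}
        self.topology_kind = topology_kind
        self.box = tuple(float(b) for b in box) if box is not None else None
        self._build_index()
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    # index construction
    # ------------------------------------------------------------------
    def _build_index(self):
        if len(self.vertices) != len(set(self.vertices)):
            raise ValidationError("duplicate vertex ids")
        self.vertex_ids = sorted(self.vertices)
        self.edge_ids = sorted(self.edges)
        self.cell_ids = sorted(self.cells)
        self._vrow = {vid: k for k, vid in enumerate(self.vertex_ids)}
        self.positions = np.array(
            [self.vertices[vid].position for vid in self.vertex_ids],
            dtype=float,
        ).reshape(len(self.vertex_ids), 2)
        # per-vertex incident edges
        self.vertex_edges: dict[int, list[int]] = {v: [] for v in self.vertex_ids}
        for eid in self.edge_ids:
            e = self.edges[eid]
            for vid in e.vertex_pair:
                if vid not in self.vertices:
                    raise ValidationError(
                        f"dangling id: edge {eid} references vertex {vid}"
                    )
                self.vertex_edges[vid].append(eid)

    def vertex_row(self, vid: int) -> int:
        """Row of vertex ``vid`` in the ``positions`` array."""
        return self._vrow[vid]

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def _validate(self):
        if self.topology_kind not in ("closed", "open", "toroidal"):
            raise ValidationError(f"unknown topology_kind {self.topology_kind!r}")
        if self.topology_kind == "toroidal":
            if self.box is None:
                raise ValidationError("toroidal arrays require a box")
            if self.box[0] <= 0 or self.box[1] <= 0:
                raise ValidationError("box lengths must be positive")
        for vid, v in self.vertices.items():
            if not np.all(np.isfinite(v.position)):
                raise ValidationError(f"vertex {vid} has non-finite coordinates")
        # cross references + edge uniqueness + manifoldness
        seen: dict[frozenset, int] = {}
        claims: dict[tuple, int] = {}
        for eid, e in self.edges.items():
            i, j = e.vertex_pair
            a, b = e.cell_pair
            if i == j:
                raise ValidationError(f"edge {eid} repeats vertex {i}")
            if a == b:
                raise ValidationError(f"edge {eid} repeats cell {a}")
            for c in (a, b):
                if c != EXTERIOR and c not in self.cells:
                    raise ValidationError(
                        f"dangling id: edge {eid} references cell {c}"
                    )
            key = frozenset({(i, j), (j, i)})
            if key in seen:
                raise ValidationError(
                    f"edges {seen[key]} and {eid} duplicate vertex pair {i},{j}"
                )
            seen[key] = eid
        for cid, c in self.cells.items():
            loop = c.vertex_loop
            if len(loop) < 3:
                raise ValidationError(f"cell {cid} loop has fewer than 3 vertices")
            if len(set(loop)) != len(loop):
                raise ValidationError(f"cell {cid} loop repeats a vertex")
            for vid in loop:
                if vid not in self.vertices:
                    raise ValidationError(
                        f"dangling id: cell {cid} references vertex {vid}"
                    )
            for i, j in zip(loop, loop[1:] + loop[:1]):
                key = (min(i, j), max(i, j))
                claims[key] = claims.get(key, 0) + 1
                if claims[key] > 2:
                    raise TopologyError(
                        f"non-manifold edge: vertex pair {key} claimed by "
                        f">2 cells"
                    )
        # every cell-loop side must exist as an Edge and vice versa
        loop_keys = set(claims)
        edge_keys = {
            (min(e.vertex_pair), max(e.vertex_pair)) for e in self.edges.values()
        }
        if loop_keys != edge_keys:
            missing = loop_keys ^ edge_keys
            raise ValidationError(
                f"edge table and cell loops disagree on vertex pairs {missing}"
            )
        # derive interior flags: a vertex touching the exterior region is
        # never interior (a stored False is kept, e.g. for vertices cut
        # by the field of view without explicit exterior edges)
        for e in self.edges.values():
            if EXTERIOR in e.cell_pair:
                for vid in e.vertex_pair:
                    self.vertices[vid].is_interior = False
        # interior vertex degree
        for vid in self.vertex_ids:
            deg = len(self.vertex_edges[vid])
            if self.vertices[vid].is_interior and deg < 3:
                raise ValidationError(
                    f"interior vertex {vid} has degree {deg} < 3"
                )
            if deg < 2:
                raise ValidationError(f"vertex {vid} has degree {deg} < 2")
        if self.topology_kind == "toroidal":
            for e in self.edges.values():
                if EXTERIOR in e.cell_pair:
                    raise ValidationError("toroidal arrays cannot touch an exterior")
        # degenerate edges
        lengths = self.edge_lengths()
        mean_len = float(lengths.mean())
        short = lengths < DEGENERACY_FRACTION * mean_len
        if np.any(short):
            bad = [self.edge_ids[k] for k in np.nonzero(short)[0]]
            raise DegenerateEdgeError(f"degenerate (near zero length) edges: {bad}")
        if self.topology_kind == "toroidal" and min(self.box) < 3.0 * mean_len:
            raise ValidationError(
                "toroidal box must be at least 3x the mean edge length"
            )
        # orientation (planar arrays only; toroidal cells may wrap)
        if self.topology_kind != "toroidal":
            for cid in self.cell_ids:
                if self._signed_area(cid) <= 0:
                    raise ValidationError(
                        f"cell {cid} loop is not counter-clockwise"
                    )
        self._check_euler()

    def _check_euler(self):
        V, E, C = len(self.vertices), len(self.edges), len(self.cells)
        if self.topology_kind == "closed":
            # exterior counts as one extra face: V - E + (C + 1) = 2
            if V - E + C != 1:
                raise TopologyError(
                    f"closed array violates Euler's formula: V-E+C = {V - E + C} != 1"
                )
        elif self.topology_kind == "toroidal":
            if V - E + C != 0:
                raise TopologyError(
                    f"toroidal array violates Euler's formula: V-E+C = {V - E + C} != 0"
                )
        # open patches may have 2-valent perimeter vertices and cut faces;
        # a disk-topology check only applies when the patch is simply
        # connected, which we do not require.

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    def unwrapped_loop(self, cell_id: int) -> np.ndarray:
        """Loop coordinates of a cell, unwrapped by minimum image on a torus."""
        loop = self.cells[cell_id].vertex_loop
        pts = np.empty((len(loop), 2))
        pts[0] = self.vertices[loop[0]].position
        for k in range(1, len(loop)):
            step = self.vertices[loop[k]].position - self.vertices[loop[k - 1]].position
            pts[k] = pts[k - 1] + minimum_image(step, self.box)
        return pts

    def _signed_area(self, cell_id: int) -> float:
        pts = self.unwrapped_loop(cell_id)
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def cell_area(self, cell_id: int) -> float:
        """Polygon (shoelace) area of a cell; positive for CCW planar loops.

        Raises
        ------
        GeometryError
            If the loop self-intersects.
        """
        if cell_id not in self.cells:
            raise ValidationError(f"no cell with id {cell_id}")
        pts = self.unwrapped_loop(cell_id)
        import shapely.geometry as sgeom

        ring = sgeom.LinearRing(pts)
        if not ring.is_simple:
            raise GeometryError(f"cell {cell_id} loop self-intersects")
        return self._signed_area(cell_id)

    def cell_areas(self) -> np.ndarray:
        """Signed areas of all cells, in ``cell_ids`` order (no simplicity check)."""
        return np.array([self._signed_area(c) for c in self.cell_ids])

    def edge_vector(self, edge_id: int, from_vertex: int | None = None) -> np.ndarray:
        """Chord vector of an edge (minimum image on a torus).

        By default the vector runs from ``vertex_pair[0]`` to
        ``vertex_pair[1]``; pass ``from_vertex`` to orient it away from a
        chosen endpoint.
        """
        e = self.edges[edge_id]
        i, j = e.vertex_pair
        if from_vertex is not None:
            if from_vertex == j:
                i, j = j, i
            elif from_vertex != i:
                raise ValidationError(
                    f"vertex {from_vertex} is not an endpoint of edge {edge_id}"
                )
        d = self.vertices[j].position - self.vertices[i].position
        d = minimum_image(d, self.box)
        if float(np.hypot(d[0], d[1])) == 0.0:
            raise DegenerateEdgeError(f"edge {edge_id} has coincident endpoints")
        return d

    def edge_length(self, edge_id: int) -> float:
        d = self.edge_vector(edge_id)
        return float(np.hypot(d[0], d[1]))

    def edge_lengths(self) -> np.ndarray:
        """Lengths of all edges in ``edge_ids`` order."""
        rows_i = np.array([self._vrow[self.edges[e].vertex_pair[0]] for e in self.edge_ids])
        rows_j = np.array([self._vrow[self.edges[e].vertex_pair[1]] for e in self.edge_ids])
        d = minimum_image(self.positions[rows_j] - self.positions[rows_i], self.box)
        return np.hypot(d[:, 0], d[:, 1])

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    # ------------------------------------------------------------------
    # counting
    # ------------------------------------------------------------------
    def balanced_vertex_ids(self) -> list[int]:
        """Vertices at which force balance is imposed.

        All vertices for closed and toroidal arrays; only interior
        vertices (every incident cell in the field of view) for open
        arrays.
        """
        if self.topology_kind == "open":
            return [v for v in self.vertex_ids if self.vertices[v].is_interior]
        return list(self.vertex_ids)

    def count_expected_zero_modes(self) -> int:
        """Number of free constants left undetermined by force balance.

        The count follows from comparing parameters (E tensions + C
        pressures, the exterior pinned at zero) with balance constraints
        (two per balanced vertex), corrected for identically-redundant
        rows: a closed array satisfies global force and torque balance
        identically (3 redundancies), a periodic array global force
        balance only (2); open-array rows are generically independent.
        For closed arrays of threefold vertices this yields 4; rosettes
        (higher-order vertices) each add one.
        """
        E, C = len(self.edges), len(self.cells)
        V_bal = len(self.balanced_vertex_ids())
        if self.topology_kind == "closed":
            return E + C - 2 * V_bal + 3
        if self.topology_kind == "toroidal":
            return E + C - 2 * V_bal + 2
        return E + C - 2 * V_bal

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_cell_loops(cls, positions, loops, topology_kind, box=None,
                        labels=None, validate=True):
        """Build an array from vertex positions and CCW cell loops.

        Edges are derived by pairing half-edges: each consecutive vertex
        pair (i, j) of a CCW loop is a half-edge whose left cell is that
        loop's cell; the opposite half-edge (j, i) supplies the right
        cell.  Unpaired half-edges border the exterior (``-1``), which is
        an error for toroidal arrays.

        Parameters
        ----------
        positions : mapping vertex id -> (x, y)
        loops : mapping cell id -> list of vertex ids (CCW)
        """
        half: dict[tuple[int, int], int] = {}
        for cid, loop in loops.items():
            for i, j in zip(loop, loop[1:] + loop[:1]):
                if (i, j) in half:
                    raise TopologyError(f"half-edge ({i},{j}) claimed twice")
                half[(i, j)] = cid
        edges = []
        eid = 0
        done = set()
        for (i, j), a in half.items():
            if (i, j) in done:
                continue
            done.add((i, j))
            if (j, i) in half:
                b = half[(j, i)]
                done.add((j, i))
            else:
                if topology_kind == "toroidal":
                    raise TopologyError(
                        f"toroidal array has an unpaired half-edge ({i},{j})"
                    )
                b = EXTERIOR
            edges.append(Edge(eid, (i, j), (a, b)))
            eid += 1
        ext_vertices = {
            v for e in edges if EXTERIOR in e.cell_pair for v in e.vertex_pair
        }
        vertices = [
            Vertex(vid, pos, is_interior=vid not in ext_vertices)
            for vid, pos in positions.items()
        ]
        ext_cells = {
            c for e in edges if EXTERIOR in e.cell_pair for c in e.cell_pair
        } - {EXTERIOR}
        labels = labels or {}
        cells = [
            Cell(cid, list(loop), is_boundary=cid in ext_cells,
                 label=labels.get(cid))
            for cid, loop in loops.items()
        ]
        return cls(vertices, edges, cells, topology_kind, box=box,
                   validate=validate)

    def with_positions(self, positions: np.ndarray,
                       check: bool = True) -> "CellArray":
        """Copy of this array with new vertex coordinates (same topology).

        ``positions`` is indexed like ``self.positions``.  Validation is
        limited to a degeneracy check (skipped with ``check=False`` for
        intermediate states of iterative procedures); topology is
        unchanged by design.
        """
        positions = np.asarray(positions, dtype=float)
        vertices = [
            Vertex(vid, positions[k].copy(), self.vertices[vid].is_interior)
            for k, vid in enumerate(self.vertex_ids)
        ]
        edges = [
            Edge(e.id, e.vertex_pair, e.cell_pair, e.curvature)
            for e in (self.edges[i] for i in self.edge_ids)
        ]
        cells = [
            Cell(c.id, list(c.vertex_loop), c.is_boundary, c.label)
            for c in (self.cells[i] for i in self.cell_ids)
        ]
        out = CellArray(vertices, edges, cells, self.topology_kind,
                        box=self.box, validate=False)
        if check:
            lengths = out.edge_lengths()
            if np.any(lengths < DEGENERACY_FRACTION * lengths.mean()):
                raise DegenerateEdgeError("edge collapsed to zero length")
        return out


def hexagonal_lattice(nx: int, ny: int, edge_length: float = 1.0) -> CellArray:
    """Regular hexagonal lattice of ``nx * ny`` cells on a torus.

    ``ny`` must be even so the lattice closes periodically.  For the
    default edge length 1 the box is ``(nx*sqrt(3), ny*1.5)``.
    """
    if ny % 2:
        raise ValueError("ny must be even for a periodic hexagonal lattice")
    if nx < 3 or ny < 4:
        raise ValueError("need nx >= 3 and ny >= 4 to avoid self-adjacency")
    s = float(edge_length)
    w = math.sqrt(3.0) * s
    Lx, Ly = nx * w, ny * 1.5 * s
    centers = {}
    cid = 0
    for row in range(ny):
        for col in range(nx):
            cx = (col + 0.5 * (row % 2)) * w
            cy = row * 1.5 * s
            centers[cid] = (cx, cy)
            cid += 1
    # pointy-top hexagon corners
    angles = [math.radians(30 + 60 * k) for k in range(6)]
    pos_key_to_id: dict[tuple[int, int], int] = {}
    positions: dict[int, np.ndarray] = {}
    loops: dict[int, list[int]] = {}
    scale = 1e6 / s
    kx, ky = round(Lx * scale), round(Ly * scale)
    for cid, (cx, cy) in centers.items():
        loop = []
        for ang in angles:
            x = (cx + s * math.cos(ang)) % Lx
            y = (cy + s * math.sin(ang)) % Ly
            key = (round(x * scale) % kx, round(y * scale) % ky)
            if key not in pos_key_to_id:
                vid = len(pos_key_to_id)
                pos_key_to_id[key] = vid
                positions[vid] = np.array([x, y])
            loop.append(pos_key_to_id[key])
        loops[cid] = loop
    return CellArray.from_cell_loops(positions, loops, "toroidal", box=(Lx, Ly))


# ----------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------

def _array_to_dict(array: CellArray) -> dict:
    return {
        "topology": array.topology_kind,
        "box": list(array.box) if array.box is not None else None,
        "vertices": [
            {"id": v.id, "x": float(v.position[0]), "y": float(v.position[1]),
             "is_interior": bool(v.is_interior)}
            for v in (array.vertices[i] for i in array.vertex_ids)
        ],
        "edges": [
            {"id": e.id, "v1": e.vertex_pair[0], "v2": e.vertex_pair[1],
             "cell_left": e.cell_pair[0], "cell_right": e.cell_pair[1],
             "curvature": e.curvature}
            for e in (array.edges[i] for i in array.edge_ids)
        ],
        "cells": [
            {"id": c.id, "vertices": list(c.vertex_loop),
             "boundary": bool(c.is_boundary), "label": c.label}
            for c in (array.cells[i] for i in array.cell_ids)
        ],
    }


def _array_from_dict(data: dict) -> CellArray:
    ext_adjacent = {
        v for e in data["edges"] if EXTERIOR in (e["cell_left"], e["cell_right"])
        for v in (e["v1"], e["v2"])
    }
    vertices = [
        Vertex(v["id"], (v["x"], v["y"]),
               is_interior=v.get("is_interior", v["id"] not in ext_adjacent))
        for v in data["vertices"]
    ]
    edges = [
        Edge(e["id"], (e["v1"], e["v2"]), (e["cell_left"], e["cell_right"]),
             curvature=e.get("curvature"))
        for e in data["edges"]
    ]
    cells = [
        Cell(c["id"], list(c["vertices"]), is_boundary=bool(c.get("boundary", False)),
             label=c.get("label"))
        for c in data["cells"]
    ]
    return CellArray(vertices, edges, cells, data["topology"],
                     box=data.get("box"))


def save_array(array: CellArray, path, format: str = "json") -> None:
    """Write an array to ``path`` in JSON or CSV-tables format.

    For ``csv-tables``, ``path`` is a directory receiving
    ``vertices.csv``, ``edges.csv``, ``cells.csv`` and ``meta.json``
    (topology kind and periodic box).
    """
    path = Path(path)
    data = _array_to_dict(array)
    if format == "json":
        path.write_text(json.dumps(data, indent=1))
        return
    if format != "csv-tables":
        raise ValueError(f"unknown format {format!r}")
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "vertices.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "is_interior"])
        for v in data["vertices"]:
            w.writerow([v["id"], repr(v["x"]), repr(v["y"]), int(v["is_interior"])])
    with open(path / "edges.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "v1", "v2", "cell_left", "cell_right", "curvature"])
        for e in data["edges"]:
            curv = "" if e["curvature"] is None else repr(e["curvature"])
            w.writerow([e["id"], e["v1"], e["v2"], e["cell_left"],
                        e["cell_right"], curv])
    with open(path / "cells.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "vertices", "boundary", "label"])
        for c in data["cells"]:
            w.writerow([c["id"], "|".join(str(v) for v in c["vertices"]),
                        int(c["boundary"]), c["label"] or ""])
    (path / "meta.json").write_text(
        json.dumps({"topology": data["topology"], "box": data["box"]})
    )


def load_array(path, format: str | None = None) -> CellArray:
    """Load and fully validate a cell array from disk.

    ``format`` is inferred when omitted: a directory is read as
    CSV tables, a file as JSON.
    """
    path = Path(path)
    if format is None:
        format = "csv-tables" if path.is_dir() else "json"
    if format == "json":
        return _array_from_dict(json.loads(path.read_text()))
    if format != "csv-tables":
        raise ValueError(f"unknown format {format!r}")
    meta = json.loads((path / "meta.json").read_text())
    data = {"topology": meta["topology"], "box": meta["box"],
            "vertices": [], "edges": [], "cells": []}
    with open(path / "vertices.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            data["vertices"].append(
                {"id": int(row["id"]), "x": float(row["x"]), "y": float(row["y"]),
                 "is_interior": bool(int(row.get("is_interior", 1)))}
            )
    with open(path / "edges.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            curv = row.get("curvature", "")
            data["edges"].append(
                {"id": int(row["id"]), "v1": int(row["v1"]), "v2": int(row["v2"]),
                 "cell_left": int(row["cell_left"]),
                 "cell_right": int(row["cell_right"]),
                 "curvature": float(curv) if curv not in ("", None) else None}
            )
    with open(path / "cells.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            data["cells"].append(
                {"id": int(row["id"]),
                 "vertices": [int(v) for v in row["vertices"].split("|")],
                 "boundary": bool(int(row["boundary"])),
                 "label": row["label"] or None}
            )
    return _array_from_dict(data)
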