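"""Connectivity-derived internal coordinates.

A connected bonding graph on N atoms yields a Z-matrix-like scheme with
exactly N-1 bonds, N-2 angles and N-3 torsions (3N-6 coordinates in
total), which eliminates the external rototranslational degrees of
freedom.  Ring-closing bonds are dropped from the spanning tree; their
distances can be appended as redundant extra columns for generative-model
training, while entropy estimation uses exactly the 3N-6 tree set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import networkx as nx
import numpy as np

__all__ = [
    "CoordinateScheme",
    "Normalizer",
    "build_scheme",
    "evaluate",
    "fit_normalizer",
]


@dataclass(frozen=True)
class CoordinateScheme:
    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...]
    torsions: tuple[tuple[int, int, int, int], ...]
    ring_closures: tuple[tuple[int, int], ...] = ()
    root: int = 0

    def __post_init__(self) -> None:
        n = self.n_atoms
        if len(self.bonds) != n - 1 or len(self.angles) != max(n - 2, 0) \
                or len(self.torsions) != max(n - 3, 0):
            raise ValueError(
                f"scheme must have N-1/N-2/N-3 entries, got "
                f"{len(self.bonds)}/{len(self.angles)}/{len(self.torsions)} "
                f"for N={n}"
            )

    @property
    def n_atoms(self) -> int:
        atoms = {a for tup in self.bonds for a in tup}
        atoms |= {a for tup in self.angles for a in tup}
        atoms |= {a for tup in self.torsions for a in tup}
        atoms |= {a for tup in self.ring_closures for a in tup}
        return len(atoms)

    @property
    def n_coordinates(self) -> int:
        """3N-6 (tree coordinates only, ring closures excluded)."""
        return len(self.bonds) + len(self.angles) + len(self.torsions)

    def column_labels(self, redundant: bool = False) -> list[str]:
        labels = [f"bond_{i}_{j}" for i, j in self.bonds]
        labels += [f"angle_{i}_{j}_{k}" for i, j, k in self.angles]
        labels += [f"torsion_{i}_{j}_{k}_{l}" for i, j, k, l in self.torsions]
        if redundant:
            labels += [f"ringbond_{i}_{j}" for i, j in self.ring_closures]
        return labels

    def torsion_columns(self, redundant: bool = False) -> np.ndarray:
        """Boolean mask of columns holding circular (torsion) values."""
        n_cols = self.n_coordinates + (len(self.ring_closures) if redundant else 0)
        mask = np.zeros(n_cols, dtype=bool)
        start = len(self.bonds) + len(self.angles)
        mask[start: start + len(self.torsions)] = True
        return mask

    def bond_column(self, pair: Sequence[int]) -> int:
        """Column index of a given bonded atom pair (tree or ring bond)."""
        want = frozenset(pair)
        for idx, b in enumerate(self.bonds):
            if frozenset(b) == want:
                return idx
        for idx, b in enumerate(self.ring_closures):
            if frozenset(b) == want:
                return self.n_coordinates + idx
        raise KeyError(f"bond {tuple(pair)} not in scheme")

    def to_json(self) -> str:
        return json.dumps({
            "bonds": [list(b) for b in self.bonds],
            "angles": [list(a) for a in self.angles],
            "torsions": [list(t) for t in self.torsions],
            "ring_closures": [list(r) for r in self.ring_closures],
            "root": self.root,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CoordinateScheme":
        d = json.loads(text)
        return cls(
            bonds=tuple(tuple(b) for b in d["bonds"]),
            angles=tuple(tuple(a) for a in d["angles"]),
            torsions=tuple(tuple(t) for t in d["torsions"]),
            ring_closures=tuple(tuple(r) for r in d.get("ring_closures", [])),
            root=d.get("root", 0),
        )


def build_scheme(connectivity: Iterable[tuple[int, int]] | nx.Graph,
                 root: int | None = None) -> CoordinateScheme:
    """Z-matrix-like coordinate scheme from a bonding graph.

    A breadth-first spanning tree from ``root`` (ties broken by lowest
    atom index) places each atom relative to already-placed references:
    atom k defines a bond to its parent, an angle through the parent's
    reference and, from the fourth placed atom on, a torsion.  Bonds that
    close rings are recorded separately in ``ring_closures``.
    """
    graph = connectivity if isinstance(connectivity, nx.Graph) else nx.Graph(list(connectivity))
    n = graph.number_of_nodes()
    if n < 4:
        raise ValueError("need at least 4 atoms for a 3N-6 >= 6 scheme")
    if sorted(graph.nodes) != list(range(n)):
        raise ValueError("atoms must be labeled 0..N-1")
    if not nx.is_connected(graph):
        raise ValueError("connectivity graph is disconnected")
    if root is None:
        root = 0

    order: list[int] = [root]
    parent: dict[int, int] = {root: -1}
    queue = [root]
    while queue:
        u = queue.pop(0)
        for v in sorted(graph.neighbors(u)):
            if v not in parent:
                parent[v] = u
                order.append(v)
                queue.append(v)

    placed_rank = {a: i for i, a in enumerate(order)}
    tree_edges = {frozenset((a, parent[a])) for a in order if parent[a] != -1}
    ring_closures = tuple(
        (min(u, v), max(u, v)) for u, v in sorted(graph.edges)
        if frozenset((u, v)) not in tree_edges
    )

    def reference(atom: int, exclude: set[int]) -> int:
        """Earliest-placed atom outside ``exclude`` (prefers the parent's
        parent for a chemically natural chain)."""
        par = parent[atom]
        if par != -1 and parent[par] != -1 and parent[par] not in exclude:
            return parent[par]
        for a in order:
            if a not in exclude:
                return a
        raise RuntimeError("no reference atom available")

    bonds: list[tuple[int, int]] = []
    angles: list[tuple[int, int, int]] = []
    torsions: list[tuple[int, int, int, int]] = []
    for k, atom in enumerate(order):
        if k == 0:
            continue
        par = parent[atom]
        bonds.append((atom, par))
        if k >= 2:
            ref2 = reference(par, {atom, par})
            angles.append((atom, par, ref2))
            if k >= 3:
                ref3 = reference(ref2, {atom, par, ref2})
                torsions.append((atom, par, ref2, ref3))

    return CoordinateScheme(tuple(bonds), tuple(angles), tuple(torsions),
                            ring_closures, root)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _distances(coords: np.ndarray, pairs) -> np.ndarray:
    i = [p[0] for p in pairs]
    j = [p[1] for p in pairs]
    return np.linalg.norm(coords[..., i, :] - coords[..., j, :], axis=-1)


def _angles(coords: np.ndarray, triplets) -> np.ndarray:
    i = [t[0] for t in triplets]
    j = [t[1] for t in triplets]
    k = [t[2] for t in triplets]
    u = coords[..., i, :] - coords[..., j, :]
    v = coords[..., k, :] - coords[..., j, :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    bad = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(u * v, axis=-1) / denom
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    if np.any(bad):
        warnings.warn("degenerate (zero-length) angle arm; NaN emitted")
        ang = np.where(bad, np.nan, ang)
    return ang


def _torsions(coords: np.ndarray, quads) -> np.ndarray:
    """Signed dihedral in (-pi, pi] for (..., Q) quadruplets."""
    i = [q[0] for q in quads]
    j = [q[1] for q in quads]
    k = [q[2] for q in quads]
    l = [q[3] for q in quads]
    b1 = coords[..., j, :] - coords[..., i, :]
    b2 = coords[..., k, :] - coords[..., j, :]
    b3 = coords[..., l, :] - coords[..., k, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / np.where(b2n == 0, np.nan, b2n)
    degenerate = (np.linalg.norm(n1, axis=-1) == 0) | (np.linalg.norm(n2, axis=-1) == 0)
    with np.errstate(invalid="ignore"):
        tor = np.arctan2(y, x)
    if np.any(degenerate):
        warnings.warn("colinear atoms in torsion; NaN emitted")
        tor = np.where(degenerate, np.nan, tor)
    # arctan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] contract
    tor = np.where(tor == -np.pi, np.pi, tor)
    return tor


def evaluate(coords: np.ndarray, scheme: CoordinateScheme,
             redundant: bool = False) -> np.ndarray:
    """Internal-coordinate table for coordinates of shape (..., N, 3).

    Bond lengths in A, angles in [0, pi], torsions in (-pi, pi] radians.
    With ``redundant=True`` the ring-closure distances are appended as
    extra columns.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    parts = [_distances(coords, scheme.bonds)]
    if scheme.angles:
        parts.append(_angles(coords, scheme.angles))
    if scheme.torsions:
        parts.append(_torsions(coords, scheme.torsions))
    if redundant and scheme.ring_closures:
        parts.append(_distances(coords, scheme.ring_closures))
    return np.concatenate(parts, axis=-1)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    """Affine per-column map onto [-1, 1] fitted on training data.

    Columns that are constant in the training data map to 0 and are
    listed in ``constant_columns``.  Values outside the fitted bounds map
    outside [-1, 1] (no clipping): held-out frames may exceed the range.
    """

    lo: np.ndarray
    hi: np.ndarray
    constant_columns: np.ndarray

    def apply(self, table: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (table - self.lo) / safe - 1.0
        if self.constant_columns.any():
            out[..., self.constant_columns] = 0.0
        return out

    def invert(self, normalized: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        out = (normalized + 1.0) * span / 2.0 + self.lo
        if self.constant_columns.any():
            out[..., self.constant_columns] = self.lo[self.constant_columns]
        return out

    def to_json(self) -> str:
        return json.dumps({"lo": self.lo.tolist(), "hi": self.hi.tolist(),
                           "constant": self.constant_columns.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        d = json.loads(text)
        return cls(np.array(d["lo"]), np.array(d["hi"]),
                   np.array(d["constant"], dtype=bool))


def fit_normalizer(table: np.ndarray) -> Normalizer:
    """Fit per-column min/max bounds on a (rows, columns) training table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    lo = table.min(axis=0)
    hi = table.max(axis=0)
    constant = hi == lo
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant column(s) map to 0")
    return Normalizer(lo, hi, constant)
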