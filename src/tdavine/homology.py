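"""Vietoris-Rips persistent homology with representative cycles.

The per-timepoint pipeline stage: embed each voxel as the 4-D hyperspace
point (x, y, z, f_norm), build the Vietoris-Rips filtration truncated at a
maximum radius, and reduce the boundary matrix over GF(2) to obtain the
persistence diagram together with a representative cycle for every H1/H2
class.

Conventions
-----------
* Radius (not diameter) filtration: a simplex enters at half its diameter,
  so balls of radius r centred at the vertices pairwise intersect exactly
  when the simplex is present.  On a unit lattice the square-hole classes
  are literally born at radius 0.5.
* Coefficients are GF(2); representatives are orientation-free vertex sets.
* Classes still alive at ``r_max`` are reported with ``death = r_max`` and
  ``truncated=True`` -- never assigned a fake finite death.  Raising
  ``r_max`` can only complete the diagram; finite pairs never move.
* Zero-persistence pairs (birth == death) are dropped: they are invisible
  in any diagram and meaningless downstream.
* Determinism: simplices are totally ordered by (radius, dimension,
  lexicographic vertex tuple), ubiquitous lattice ties included, so the
  reduction -- and hence every representative -- is reproducible.

Representatives: a finite class's cycle is the one recorded in the reduced
boundary column of the simplex that kills it; a truncated class's cycle is
the chain accumulated for its birth column (R = dV bookkeeping).  Neither
is canonical -- no representative is -- but both are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import ResourceError, Series, TimePointCloud, ValidationError

DEFAULT_R_MAX = 12.0
DEFAULT_POINT_CAPS = {1: 2500, 2: 400}


def embed_hyperspace(cloud: TimePointCloud) -> np.ndarray:
    """``(n, 4)`` hyperspace points (x, y, z, amplitude), row order preserved."""
    return np.column_stack([cloud.coords, cloud.amplitudes])


@dataclass(frozen=True)
class Filtration:
    """Truncated Vietoris-Rips filtration of a point cloud.

    ``simplices[k]`` is an ``(m_k, k+1)`` int array of vertex tuples sorted
    by (radius, lexicographic vertex tuple); ``fvals[k]`` the matching entry
    radii (half the simplex diameter).
    """

    points: np.ndarray
    r_max: float
    max_dim: int
    simplices: dict[int, np.ndarray]
    fvals: dict[int, np.ndarray]


def _sorted_by_filtration(simplices: np.ndarray, fvals: np.ndarray):
    keys = tuple(simplices[:, k] for k in reversed(range(simplices.shape[1])))
    order = np.lexsort(keys + (fvals,))
    return simplices[order], fvals[order]


def build_rips(
    points: np.ndarray,
    r_max: float = DEFAULT_R_MAX,
    max_dim: int = 1,
    point_cap: int | None = None,
) -> Filtration:
    """All simplices of dimension <= max_dim + 1 entering at radius <= r_max.

    ``max_dim`` is the highest homology dimension requested (1 or 2); the
    filtration therefore contains simplices one dimension higher, which is
    combinatorially explosive -- hence the hard point caps (2500 points for
    H1, 400 for H2 by default).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 1:
        raise ValidationError("points must be a non-empty (n, d) array")
    if not r_max > 0:
        raise ValidationError("r_max must be positive")
    if max_dim not in (1, 2):
        raise ValidationError("max_dim must be 1 or 2")
    n = points.shape[0]
    cap = DEFAULT_POINT_CAPS[max_dim] if point_cap is None else point_cap
    if n > cap:
        raise ResourceError(
            f"{n} points exceeds the cap of {cap} for max_dim={max_dim}; "
            "use a tighter mask or a smaller r_max/grid"
        )

    half = squareform(pdist(points)) / 2.0 if n > 1 else np.zeros((1, 1))
    adj = (half <= r_max) & ~np.eye(n, dtype=bool)

    simplices = {0: np.arange(n, dtype=np.int64)[:, None]}
    fvals = {0: np.zeros(n)}

    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    efv = half[iu, ju]
    edges, efv = _sorted_by_filtration(edges, efv)
    simplices[1], fvals[1] = edges, efv

    tri_list, tri_f = [], []
    for (i, j), f_ij in zip(edges, efv):
        ks = np.nonzero(adj[i] & adj[j])[0]
        ks = ks[ks > j]
        if ks.size:
            f = np.maximum(f_ij, np.maximum(half[i, ks], half[j, ks]))
            keep = f <= r_max
            ks, f = ks[keep], f[keep]
            for k, fk in zip(ks, f):
                tri_list.append((i, j, k))
                tri_f.append(fk)
    tris = np.array(tri_list, dtype=np.int64).reshape(-1, 3)
    trif = np.array(tri_f, dtype=float)
    simplices[2], fvals[2] = _sorted_by_filtration(tris, trif)

    if max_dim == 2:
        tet_list, tet_f = [], []
        for (i, j, k), f_ijk in zip(simplices[2], fvals[2]):
            ls = np.nonzero(adj[i] & adj[j] & adj[k])[0]
            ls = ls[ls > k]
            if ls.size:
                f = np.maximum(
                    f_ijk,
                    np.maximum(half[i, ls], np.maximum(half[j, ls], half[k, ls])),
                )
                keep = f <= r_max
                ls, f = ls[keep], f[keep]
                for l, fl in zip(ls, f):
                    tet_list.append((i, j, k, l))
                    tet_f.append(fl)
        tets = np.array(tet_list, dtype=np.int64).reshape(-1, 4)
        tetf = np.array(tet_f, dtype=float)
        simplices[3], fvals[3] = _sorted_by_filtration(tets, tetf)

    return Filtration(points, float(r_max), max_dim, simplices, fvals)


@dataclass(frozen=True)
class Feature:
    """One persistent homology class.

    ``cycle`` is the representative as a tuple of simplices (vertex-index
    tuples into the filtration's point array); ``representative`` the
    corresponding unique voxel coordinates in 3-D stereotactic space.
    """

    dim: int
    birth: float
    death: float
    truncated: bool
    t: int
    id: str
    cycle: tuple[tuple[int, ...], ...]
    representative: np.ndarray

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    @property
    def centroid(self) -> np.ndarray:
        return self.representative.mean(axis=0)


@dataclass(frozen=True)
class Diagram:
    """Persistence diagram at one time index, truncated at ``r_max``."""

    t: int
    features: tuple[Feature, ...]
    r_max: float

    def select(self, dim: int) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.dim == dim)

    def points(self, dim: int) -> np.ndarray:
        """``(m, 2)`` birth/death pairs for one homology dimension."""
        sel = self.select(dim)
        if not sel:
            return np.empty((0, 2))
        return np.array([[f.birth, f.death] for f in sel])


def _reduce(columns: list[int], need_v: bool):
    """Standard left-to-right GF(2) column reduction.

    Columns are bitsets of row indices; the pivot of a column is its
    highest set bit.  Returns (reduced columns, V columns or None,
    pivot-row -> column map).
    """
    m = len(columns)
    reduced = [0] * m
    V = [0] * m if need_v else None
    pivot: dict[int, int] = {}
    for j in range(m):
        col = columns[j]
        v = 1 << j
        while col:
            low = col.bit_length() - 1
            k = pivot.get(low)
            if k is None:
                break
            col ^= reduced[k]
            if need_v:
                v ^= V[k]
        reduced[j] = col
        if need_v:
            V[j] = v
        if col:
            pivot[col.bit_length() - 1] = j
    return reduced, V, pivot


def _bits_to_indices(bits: int) -> list[int]:
    out = []
    while bits:
        low = bits.bit_length() - 1
        out.append(low)
        bits ^= 1 << low
    out.reverse()
    return out


def _boundary_columns(simplices: np.ndarray, face_index: dict) -> list[int]:
    cols = []
    k1 = simplices.shape[1]
    for s in simplices:
        bits = 0
        for drop in range(k1):
            face = tuple(int(v) for d, v in enumerate(s) if d != drop)
            bits |= 1 << face_index[face]
        cols.append(bits)
    return cols


def compute_persistence(filtration: Filtration, t: int = 0) -> Diagram:
    """Persistence pairs + representatives by GF(2) boundary reduction.

    Columns are processed in filtration order.  For each homology dimension
    k, births are the k-simplices whose own boundary column reduces to
    zero; a birth paired by a (k+1)-column dies at that column's radius,
    with the reduced killing column as its representative k-cycle; unpaired
    births are truncated at ``r_max`` with their accumulated birth chain as
    representative.
    """
    pts3 = filtration.points[:, :3]
    n = filtration.points.shape[0]
    simp, fv = filtration.simplices, filtration.fvals
    r_max = filtration.r_max

    edge_index = {tuple(int(v) for v in e): i for i, e in enumerate(simp[1])}
    cols1 = [(1 << int(i)) | (1 << int(j)) for i, j in simp[1]]
    red1, V1, piv1 = _reduce(cols1, need_v=True)

    need_v2 = filtration.max_dim >= 2
    cols2 = _boundary_columns(simp[2], edge_index) if len(simp[2]) else []
    red2, V2, piv2 = _reduce(cols2, need_v=need_v2)

    features: list[Feature] = []

    def add(dim, birth, death, truncated, cycle_simplices):
        verts = sorted({v for s in cycle_simplices for v in s})
        rep = pts3[verts]
        features.append(
            Feature(dim, float(birth), float(death), truncated, t, "",
                    tuple(cycle_simplices), rep)
        )

    # --- H0: every vertex is born at 0; negative edges kill components.
    killed = set()
    for vrow, ecol in piv1.items():
        killed.add(vrow)
        death = fv[1][ecol]
        if death > 0.0:
            add(0, 0.0, death, False, [(vrow,)])
    for v in range(n):
        if v not in killed:
            add(0, 0.0, r_max, True, [(v,)])

    # --- H1: positive edges, killed by triangles or truncated.
    tri_rows = {tuple(int(v) for v in s): i for i, s in enumerate(simp[2])}
    for j in range(len(simp[1])):
        if red1[j] != 0:
            continue  # negative edge (killed a component)
        birth = fv[1][j]
        col = piv2.get(j)
        if col is not None:
            death = fv[2][col]
            if death == birth:
                continue
            cycle = [tuple(int(v) for v in simp[1][e])
                     for e in _bits_to_indices(red2[col])]
            add(1, birth, death, False, cycle)
        else:
            cycle = [tuple(int(v) for v in simp[1][e])
                     for e in _bits_to_indices(V1[j])]
            add(1, birth, r_max, True, cycle)

    # --- H2 (opt-in): positive triangles, killed by tetrahedra.
    if filtration.max_dim >= 2:
        cols3 = _boundary_columns(simp[3], tri_rows) if len(simp[3]) else []
        red3, _, piv3 = _reduce(cols3, need_v=False)
        for j in range(len(simp[2])):
            if red2[j] != 0:
                continue
            birth = fv[2][j]
            col = piv3.get(j)
            if col is not None:
                death = fv[3][col]
                if death == birth:
                    continue
                cycle = [tuple(int(v) for v in simp[2][s])
                         for s in _bits_to_indices(red3[col])]
                add(2, birth, death, False, cycle)
            else:
                cycle = [tuple(int(v) for v in simp[2][s])
                         for s in _bits_to_indices(V2[j])]
                add(2, birth, r_max, True, cycle)

    features.sort(key=lambda f: (f.dim, f.birth, f.death))
    final = tuple(
        Feature(f.dim, f.birth, f.death, f.truncated, t, f"t{t}f{k}",
                f.cycle, f.representative)
        for k, f in enumerate(features)
    )
    return Diagram(t=t, features=final, r_max=r_max)


def diagrams_over_time(
    series: Series,
    r_max: float = DEFAULT_R_MAX,
    max_dim: int = 1,
    persistence_floor: float = 0.0,
    point_cap: int | None = None,
) -> list[Diagram]:
    """One truncated diagram per time index of a normalized series.

    Features with persistence below ``persistence_floor`` (truncated
    features count ``r_max - birth``) are omitted, mirroring the usual
    practice of hiding low-persistence clutter when stacking diagrams.
    """
    out = []
    for cloud in series.clouds:
        filt = build_rips(embed_hyperspace(cloud), r_max, max_dim, point_cap)
        diag = compute_persistence(filt, t=cloud.t)
        if persistence_floor > 0.0:
            kept = tuple(
                f for f in diag.features if f.persistence >= persistence_floor
            )
            diag = Diagram(t=diag.t, features=kept, r_max=diag.r_max)
        out.append(diag)
    return out
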