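"""Triangle-mesh primitives for cortical surface models.

Meshes are plain vertex/face arrays in millimetres.  The module provides
normals, adjacency, graph geodesics and a correspondence-preserving
decimation of paired pial/white surfaces: vertices are *removed*, never
moved, so decimated coordinates are a bit-exact subset of the originals and
the pial/white one-to-one vertex correspondence survives downsampling.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import sparse
from scipy.sparse.csgraph import dijkstra


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh input."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    faces : (M, 3) int array of vertex indices, consistently wound so that
        face normals point outward for closed meshes.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (M, 3)")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate(self) -> None:
        """Check index bounds, non-degenerate faces and edge-manifoldness."""
        n = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshError("face index out of range")
        a, b, c = self.faces.T
        if np.any((a == b) | (b == c) | (a == c)):
            bad = int(np.nonzero((a == b) | (b == c) | (a == c))[0][0])
            raise MeshError(f"face {bad} repeats a vertex")
        edges = np.sort(np.concatenate([self.faces[:, [0, 1]],
                                        self.faces[:, [1, 2]],
                                        self.faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshError("mesh is not edge-manifold")

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        e = np.sort(np.concatenate([self.faces[:, [0, 1]],
                                    self.faces[:, [1, 2]],
                                    self.faces[:, [2, 0]]]), axis=1)
        return np.unique(e, axis=0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class CorticalSurfacePair:
    """Pial + white surfaces with one-to-one vertex correspondence.

    Both meshes share an identical face list; corresponding vertices p_i
    (pial) and w_i (white) are joined by the cortical thickness vector.
    """

    pial: TriangleMesh
    white: TriangleMesh

    def __post_init__(self):
        if self.pial.n_vertices != self.white.n_vertices:
            raise MeshError("pial/white vertex counts differ")
        if not np.array_equal(self.pial.faces, self.white.faces):
            raise MeshError("pial/white face lists differ")

    @property
    def n_vertices(self) -> int:
        return self.pial.n_vertices

    def thickness(self) -> np.ndarray:
        """Per-vertex thickness ||w_i - p_i|| in mm."""
        return np.linalg.norm(self.white.vertices - self.pial.vertices, axis=1)

    def validate(self) -> None:
        self.pial.validate()
        self.white.validate()
        if np.any(self.thickness() <= 0):
            bad = int(np.nonzero(self.thickness() <= 0)[0][0])
            raise MeshError(f"zero thickness at vertex {bad}")


@dataclass
class DecimationMap:
    """Mapping from a decimated mesh back to the original.

    ``retained[k]`` is the original-vertex index of decimated vertex k;
    vertices are removed, never moved, so decimated coordinates equal the
    original coordinates at the retained indices.
    """

    retained: np.ndarray
    decimated_faces: np.ndarray

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=np.int64)
        self.decimated_faces = np.asarray(self.decimated_faces, dtype=np.int64)
        if len(np.unique(self.retained)) != len(self.retained):
            raise MeshError("retained indices are not unique")

    @property
    def n_vertices(self) -> int:
        return len(self.retained)


def face_normals(mesh: TriangleMesh) -> np.ndarray:
    """Per-face unit normals following the face winding (right-hand rule)."""
    v = mesh.vertices
    f = mesh.faces
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norms = np.linalg.norm(n, axis=1)
    if np.any(norms == 0):
        bad = int(np.nonzero(norms == 0)[0][0])
        raise MeshError(f"degenerate (zero-area) face {bad}")
    return n / norms[:, None]


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex unit normals: mean of adjacent unit face normals, renormalized."""
    fn = face_normals(mesh)
    acc = np.zeros_like(mesh.vertices)
    cnt = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], fn)
        np.add.at(cnt, mesh.faces[:, k], 1.0)
    if np.any(cnt == 0):
        bad = int(np.nonzero(cnt == 0)[0][0])
        raise MeshError(f"isolated vertex {bad} belongs to no face")
    mean = acc / cnt[:, None]
    norms = np.linalg.norm(mean, axis=1)
    if np.any(norms == 0):
        bad = int(np.nonzero(norms == 0)[0][0])
        raise MeshError(f"cancelling face normals at vertex {bad}")
    return mean / norms[:, None]


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Neighbor-index array per vertex (vertices sharing an edge)."""
    nbrs = [set() for _ in range(mesh.n_vertices)]
    for a, b in mesh.edges():
        nbrs[a].add(int(b))
        nbrs[b].add(int(a))
    return [np.array(sorted(s), dtype=np.int64) for s in nbrs]


def edge_graph(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Sparse symmetric graph with Euclidean edge lengths as weights."""
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sparse.coo_matrix((np.concatenate([w, w]),
                           (np.concatenate([e[:, 0], e[:, 1]]),
                            np.concatenate([e[:, 1], e[:, 0]]))),
                          shape=(n, n))
    return g.tocsr()


def geodesic_distances(mesh: TriangleMesh, seed_vertex: int,
                       radius: float) -> dict[int, float]:
    """Graph-geodesic distances from ``seed_vertex`` to vertices within ``radius``.

    Distances are shortest paths along mesh edges (edge weight = Euclidean
    length); vertices farther than ``radius`` (or disconnected) are absent.
    """
    if not 0 <= seed_vertex < mesh.n_vertices:
        raise MeshError(f"seed vertex {seed_vertex} out of range")
    if radius < 0:
        raise MeshError("radius must be non-negative")
    if radius == 0:
        return {int(seed_vertex): 0.0}
    g = edge_graph(mesh)
    d = dijkstra(g, directed=False, indices=seed_vertex, limit=radius)
    idx = np.nonzero(np.isfinite(d) & (d <= radius))[0]
    return {int(i): float(d[i]) for i in idx}


def geodesic_kernel(mesh: TriangleMesh, fwhm_mm: float,
                    truncate_sigmas: float = 3.0) -> sparse.csr_matrix:
    """Row-normalized geodesic Gaussian smoothing kernel on the mesh graph.

    FWHM -> 0 returns the identity.  The kernel is truncated at
    ``truncate_sigmas`` standard deviations.
    """
    n = mesh.n_vertices
    if fwhm_mm <= 0:
        return sparse.identity(n, format="csr")
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    limit = truncate_sigmas * sigma
    g = edge_graph(mesh)
    d = dijkstra(g, directed=False, limit=limit)  # (n, n), inf beyond limit
    rows, cols = np.nonzero(np.isfinite(d) & (d <= limit))
    vals = np.exp(-d[rows, cols] ** 2 / (2.0 * sigma ** 2))
    k = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    rowsum = np.asarray(k.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1.0
    return sparse.diags(1.0 / rowsum) @ k


# ---------------------------------------------------------------------------
# correspondence-preserving decimation

def decimate_pair(pair: CorticalSurfacePair, factor: float = 10.0
                  ) -> tuple[CorticalSurfacePair, DecimationMap]:
    """Downsample a pial/white pair by ``factor`` keeping vertex correspondence.

    Greedy edge collapse on the pial mesh, shortest edge first; every
    collapse snaps onto an existing original vertex so decimated coordinates
    are a bit-exact subset of the originals.  The decimated face list is
    computed on the pial mesh and copied to the white mesh, so both surfaces
    share one topology.  Tie-breaks (equal edge lengths) go to the lowest
    vertex indices; the procedure is fully deterministic.
    """
    if factor < 1:
        raise MeshError("decimation factor must be >= 1")
    n = pair.n_vertices
    target = int(round(n / factor))
    if target < 4:
        raise MeshError(f"target vertex count {target} < 4")
    if target >= n:
        dmap = DecimationMap(np.arange(n), pair.pial.faces.copy())
        return CorticalSurfacePair(pair.pial.copy(), pair.white.copy()), dmap

    retained, faces = _greedy_collapse(pair.pial, target)
    dec_pial = TriangleMesh(pair.pial.vertices[retained], faces)
    dec_white = TriangleMesh(pair.white.vertices[retained], faces.copy())
    return (CorticalSurfacePair(dec_pial, dec_white),
            DecimationMap(retained, faces))


def _face_normal(v, tri):
    a, b, c = tri
    return np.cross(v[b] - v[a], v[c] - v[a])


def _tri_quality(v, tri):
    """Shape quality in (0, 1]: 4*sqrt(3)*area / sum of squared edge lengths
    (1 for equilateral, -> 0 for degenerate slivers)."""
    a, b, c = tri
    e = ((v[b] - v[a]) ** 2).sum() + ((v[c] - v[b]) ** 2).sum() \
        + ((v[a] - v[c]) ** 2).sum()
    area = 0.5 * np.linalg.norm(np.cross(v[b] - v[a], v[c] - v[a]))
    return 4.0 * np.sqrt(3.0) * area / e if e > 0 else 0.0


def _greedy_collapse(mesh: TriangleMesh, target: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    v = mesh.vertices
    faces: dict[int, tuple[int, int, int]] = {
        i: tuple(int(x) for x in f) for i, f in enumerate(mesh.faces)}
    vfaces: list[set] = [set() for _ in range(mesh.n_vertices)]
    for fid, f in faces.items():
        for x in f:
            vfaces[x].add(fid)
    nbrs: list[set] = [set() for _ in range(mesh.n_vertices)]
    for a, b in mesh.edges():
        nbrs[a].add(int(b))
        nbrs[b].add(int(a))
    alive = np.ones(mesh.n_vertices, dtype=bool)
    count = mesh.n_vertices

    def edge_key(a, b):
        a, b = (a, b) if a < b else (b, a)
        return (float(np.linalg.norm(v[a] - v[b])), a, b)

    heap = [edge_key(a, b) for a, b in mesh.edges()]
    heapq.heapify(heap)
    progressed = True  # collapses since last heap rebuild
    quality_floor = 0.5  # lowered when no collapse clears it

    while count > target:
        if not heap:
            if not progressed:
                quality_floor /= 2.0
                if quality_floor < 0.02:
                    raise MeshError(
                        "decimation stuck: no valid edge collapse left")
            heap = [edge_key(a, b) for a in range(len(nbrs)) if alive[a]
                    for b in nbrs[a] if b > a]
            heapq.heapify(heap)
            progressed = False
            continue
        _, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or b not in nbrs[a]:
            continue
        lo, hi = (a, b) if a < b else (b, a)
        shared = vfaces[lo] & vfaces[hi]
        third = {x for fid in shared for x in faces[fid] if x not in (lo, hi)}
        if (nbrs[lo] & nbrs[hi]) != third or not 1 <= len(shared) <= 2:
            continue  # link condition: collapse would break topology
        # valence guards keep the tessellation regular: the vertices opposite
        # the collapsed edge each lose one neighbor, and the merged vertex
        # acquires the union ring
        if any(len(nbrs[t]) <= 4 for t in third):
            continue
        if len(nbrs[lo] | nbrs[hi]) - 2 > 8:
            continue

        def evaluate(s, d):
            """Remapped faces for merging d into s, or (None, q) if invalid;
            q is the worst resulting triangle quality."""
            new_tris = {}
            worst = 1.0
            existing = {frozenset(faces[g]) for g in vfaces[s]}
            for fid in vfaces[d] - shared:
                tri = faces[fid]
                new_tri = tuple(s if x == d else x for x in tri)
                key = frozenset(new_tri)
                if key in existing or \
                        key in {frozenset(t) for t in new_tris.values()}:
                    return None, 0.0  # duplicate face
                if np.dot(_face_normal(v, tri),
                          _face_normal(v, new_tri)) <= 0:
                    return None, 0.0  # normal flip
                new_tris[fid] = new_tri
                worst = min(worst, _tri_quality(v, new_tri))
            for fid in vfaces[s] - shared:
                worst = min(worst, _tri_quality(v, faces[fid]))
            return new_tris, worst

        # try both endpoints as survivor; prefer the better-shaped result,
        # ties to the lowest surviving index
        cand = []
        for s, d in ((lo, hi), (hi, lo)):
            tris, q = evaluate(s, d)
            if tris is not None:
                cand.append((-q, s, d, tris))
        if not cand:
            continue
        cand.sort(key=lambda t: (t[0], t[1]))
        if -cand[0][0] < quality_floor:
            continue  # too sliver-prone for now; retry after floor lowering
        _, s, d, new_tris = cand[0]
        # execute collapse: merge d into s
        for fid in shared:
            for x in faces[fid]:
                vfaces[x].discard(fid)
            del faces[fid]
        for fid, tri in new_tris.items():
            faces[fid] = tri
            vfaces[s].add(fid)
        vfaces[d] = set()
        for x in list(nbrs[d]):
            nbrs[x].discard(d)
            if x != s:
                nbrs[x].add(s)
                nbrs[s].add(x)
        nbrs[d] = set()
        alive[d] = False
        count -= 1
        progressed = True
        for x in nbrs[s]:
            heapq.heappush(heap, edge_key(s, x))

    retained = np.nonzero(alive)[0]
    old2new = np.full(mesh.n_vertices, -1, dtype=np.int64)
    old2new[retained] = np.arange(len(retained))
    out_faces = np.array([[old2new[x] for x in faces[fid]]
                          for fid in sorted(faces)], dtype=np.int64)
    out_faces = _edge_flip_pass(v[retained], out_faces)
    return retained, out_faces


def _edge_flip_pass(v: np.ndarray, faces: np.ndarray,
                    max_passes: int = 20) -> np.ndarray:
    """Greedy edge flipping to even out the tessellation after collapse.

    An interior edge (a, b) with opposite vertices (c, d) is flipped to
    (c, d) when that strictly improves the worse of the two triangle shape
    qualities, keeps face normals consistent, and (c, d) is not already an
    edge.  Vertices are untouched.
    """
    faces = {i: tuple(int(x) for x in f) for i, f in enumerate(faces)}
    for _ in range(max_passes):
        edge_faces: dict[tuple, list] = {}
        edges_all = set()
        for fid, f in faces.items():
            for i in range(3):
                e = tuple(sorted((f[i], f[(i + 1) % 3])))
                edge_faces.setdefault(e, []).append(fid)
                edges_all.add(e)
        flipped = 0
        for e, fids in sorted(edge_faces.items()):
            if len(fids) != 2:
                continue
            f1, f2 = faces.get(fids[0]), faces.get(fids[1])
            if f1 is None or f2 is None:
                continue
            if not (set(e) <= set(f1) and set(e) <= set(f2)):
                continue  # stale after an earlier flip this pass
            a, b = e
            c = next(x for x in f1 if x not in e)
            d = next(x for x in f2 if x not in e)
            if c == d or tuple(sorted((c, d))) in edges_all:
                continue
            old_q = min(_tri_quality(v, f1), _tri_quality(v, f2))
            # preserve winding: rotate f1 so the shared edge is (a, b) in
            # the order it appears, then the flipped pair is (c,d,b),(d,c,a)
            i = f1.index(a)
            ordered = f1[i:] + f1[:i]
            if ordered[1] == b:
                new1 = (a, d, c)
                new2 = (b, c, d)
            else:
                new1 = (a, c, d)
                new2 = (b, d, c)
            new_q = min(_tri_quality(v, new1), _tri_quality(v, new2))
            if new_q <= old_q + 1e-12:
                continue
            n_old = _face_normal(v, f1) + _face_normal(v, f2)
            if np.dot(_face_normal(v, new1), n_old) <= 0 or \
                    np.dot(_face_normal(v, new2), n_old) <= 0:
                continue
            faces[fids[0]], faces[fids[1]] = new1, new2
            edges_all.discard(e)
            edges_all.add(tuple(sorted((c, d))))
            flipped += 1
        if flipped == 0:
            break
    return np.array([faces[fid] for fid in sorted(faces)], dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O: FreeSurfer binary surfaces, GIFTI, TSV decimation maps

def read_surface(path: str | Path) -> TriangleMesh:
    """Read a FreeSurfer binary surface or GIFTI (.gii) surface."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        verts = img.agg_data("NIFTI_INTENT_POINTSET")
        faces = img.agg_data("NIFTI_INTENT_TRIANGLE")
        return TriangleMesh(np.asarray(verts), np.asarray(faces))
    verts, faces = nib.freesurfer.io.read_geometry(str(path))
    return TriangleMesh(verts, faces)


def write_surface(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as FreeSurfer binary surface or GIFTI (by extension)."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(path))
    else:
        nib.freesurfer.io.write_geometry(str(path), mesh.vertices, mesh.faces)


def write_decimation_map(dmap: DecimationMap, prefix: str | Path) -> None:
    """Serialize as two TSVs: ``<prefix>.map.tsv`` and ``<prefix>.faces.tsv``."""
    prefix = Path(prefix)
    rows = np.column_stack([np.arange(dmap.n_vertices), dmap.retained])
    np.savetxt(f"{prefix}.map.tsv", rows, fmt="%d", delimiter="\t",
               header="decimated_index\toriginal_index", comments="")
    np.savetxt(f"{prefix}.faces.tsv", dmap.decimated_faces, fmt="%d",
               delimiter="\t", header="v0\tv1\tv2", comments="")


def read_decimation_map(prefix: str | Path) -> DecimationMap:
    prefix = Path(prefix)
    rows = np.loadtxt(f"{prefix}.map.tsv", dtype=np.int64,
                      delimiter="\t", skiprows=1, ndmin=2)
    faces = np.loadtxt(f"{prefix}.faces.tsv", dtype=np.int64,
                       delimiter="\t", skiprows=1, ndmin=2)
    return DecimationMap(rows[:, 1], faces)
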