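"""Dipole-orientation estimators for cortical surface source models.

Five estimators of the per-vertex current-dipole orientation, approximating
the axis of the local cortical column:

* ``downsampled_normals`` — vertex normals of the decimated mesh (the common
  default in MEG pipelines, biased by the face distortion decimation causes).
* ``cortical_patch_statistics`` — average of original-mesh vertex normals over
  the 1-ring of the corresponding original vertex.
* ``original_normals`` — vertex normals of the original mesh sampled at the
  retained vertices.
* ``link_vectors`` — the vector joining corresponding pial and white vertices,
  v_i = w_i − p_i, i.e. a direct two-surface estimate of the column axis.
* ``variational`` — a vector field between the two surfaces minimizing an
  energy that rewards normality to both surfaces and mutual parallelism.

All fields are unit length.  Orientation sign carries no physical meaning in
covariance-based inversion; no global sign harmonization is applied, and the
0/180° ambiguity can be folded away in reporting only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .mesh_core import (CorticalSurfacePair, DecimationMap, MeshError,
                        TriangleMesh, vertex_adjacency, vertex_normals)

METHODS = ("downsampled_normals", "cortical_patch_statistics",
           "original_normals", "link_vectors", "variational")


@dataclass
class OrientationField:
    """Per-vertex unit dipole-orientation vectors with provenance."""

    vectors: np.ndarray
    method: str
    surface: str  # pial | white | combined
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientation vectors must be unit length")

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    def negated(self) -> "OrientationField":
        prov = dict(self.provenance, negated=True)
        return OrientationField(-self.vectors, self.method, self.surface, prov)


def _normalize(v: np.ndarray, what: str = "vector") -> np.ndarray:
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norms == 0):
        bad = int(np.nonzero(norms.ravel() == 0)[0][0])
        raise ValueError(f"zero {what} at index {bad}")
    return v / norms


def downsampled_normals(decimated: TriangleMesh,
                        surface: str = "pial") -> OrientationField:
    """Vertex normals of the decimated mesh."""
    return OrientationField(vertex_normals(decimated),
                            "downsampled_normals", surface)


def original_normals(original: TriangleMesh, dmap: DecimationMap,
                     surface: str = "pial") -> OrientationField:
    """Vertex normals of the original mesh, sampled at the retained vertices."""
    vn = vertex_normals(original)
    return OrientationField(vn[dmap.retained], "original_normals", surface)


def cortical_patch_statistics(original: TriangleMesh, dmap: DecimationMap,
                              surface: str = "pial") -> OrientationField:
    """Mean original-mesh vertex normal over the 1-ring of each retained vertex.

    The neighbor set excludes the center vertex itself.
    """
    vn = vertex_normals(original)
    adj = vertex_adjacency(original)
    out = np.empty((dmap.n_vertices, 3))
    for k, orig in enumerate(dmap.retained):
        nb = adj[orig]
        if len(nb) == 0:
            raise MeshError(f"original vertex {orig} has no neighbors")
        out[k] = vn[nb].mean(axis=0)
    return OrientationField(_normalize(out, "mean neighbor normal"),
                            "cortical_patch_statistics", surface)


def link_vectors(pair: CorticalSurfacePair,
                 surface: str = "pial") -> OrientationField:
    """Unit vectors from each pial vertex to its corresponding white vertex.

    The direction convention is pial→white; the white-surface field is the
    exact negation (180° at every vertex), and sign is immaterial for
    covariance-based inversion.
    """
    v = pair.white.vertices - pair.pial.vertices
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        bad = int(np.nonzero(norms == 0)[0][0])
        raise MeshError(f"coincident pial/white vertices at {bad}")
    return OrientationField(v / norms[:, None], "link_vectors", surface,
                            provenance={"direction": "pial_to_white"})


def variational_field(original_pair: CorticalSurfacePair,
                      dmap: DecimationMap | None = None,
                      weights: tuple[float, float] = (1.0, 0.5),
                      max_iter: int = 1000, tol: float = 1e-8,
                      surface: str = "pial") -> OrientationField:
    """Energy-minimizing vector field between white and pial surfaces.

    Minimizes, over unit vectors v_i on the original mesh,

        E(v) = Σ_i [ α (1 − v_i·n_i^pial) + α (1 − v_i·n_i^white)
                     + β Σ_{j∈N(i)} (1 − v_i·v_j) ]

    by projected gradient descent with backtracking line search (initial step
    0.1, halved on energy increase), initialized from the link vectors with
    per-vertex sign aligned to the mean surface normal (link vectors point
    inward, normals outward; sign is arbitrary and an antipodal start is a
    stationary point of the projected descent).  If ``dmap`` is given the
    converged field is sampled at the retained vertices.
    """
    alpha, beta = weights
    if alpha <= 0 or beta < 0:
        raise ValueError("alpha must be > 0 and beta >= 0")
    n_p = vertex_normals(original_pair.pial)
    n_w = vertex_normals(original_pair.white)
    v = link_vectors(original_pair).vectors.copy()
    mean_n = n_p + n_w
    flip = np.einsum("ij,ij->i", v, mean_n) < 0
    v[flip] *= -1.0

    edges = original_pair.pial.edges()
    n = original_pair.n_vertices
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                            shape=(n, n)).tocsr()
    total_deg = adj.sum()

    def energy(vv):
        e_norm = alpha * (2 * n - np.einsum("ij,ij->i", vv, mean_n).sum())
        e_par = beta * (total_deg - np.einsum("ij,ij->i", vv, adj @ vv).sum())
        return e_norm + e_par

    e = energy(v)
    history = [float(e)]
    step = 0.1
    converged = False
    for _ in range(max_iter):
        grad = -alpha * mean_n - 2.0 * beta * (adj @ v)
        while True:
            v_try = _normalize(v - step * grad)
            e_try = energy(v_try)
            if e_try <= e or step < 1e-12:
                break
            step *= 0.5
        if e_try > e:
            converged = True  # cannot descend further
            break
        if e - e_try < tol:
            v, e = v_try, e_try
            history.append(float(e))
            converged = True
            break
        v, e = v_try, e_try
        history.append(float(e))
    prov = {"alpha": alpha, "beta": beta, "max_iter": max_iter, "tol": tol,
            "converged": converged, "final_energy": float(e),
            "energy_history": history}
    if not converged:
        warnings.warn("variational field did not converge; returning last "
                      "iterate", RuntimeWarning)
    if dmap is not None:
        v = v[dmap.retained]
    return OrientationField(v, "variational", surface, provenance=prov)


# ---------------------------------------------------------------------------
# angular statistics

def angular_difference(v1: np.ndarray, v2: np.ndarray) -> np.ndarray | float:
    """Angle between vectors in degrees in [0, 180], via atan2(||v1×v2||, v1·v2).

    Numerically stable near 0° and 180° (unlike arccos of the clamped dot
    product).  Broadcasts over leading dimensions.
    """
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if np.any(np.linalg.norm(v1, axis=-1) == 0) or \
       np.any(np.linalg.norm(v2, axis=-1) == 0):
        raise ValueError("zero vector has no direction")
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.einsum("...i,...i->...", v1, v2)
    ang = np.degrees(np.arctan2(cross, dot))
    return float(ang) if ang.ndim == 0 else ang


@dataclass
class FieldDifference:
    """Per-vertex angular differences between two orientation fields."""

    angles_deg: np.ndarray
    mean: float
    sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def field_difference_summary(f1: OrientationField, f2: OrientationField,
                             fold: bool = False,
                             bins: int = 36) -> FieldDifference:
    """Angular differences plus mean/SD/histogram between two fields.

    ``fold=True`` folds angles to [0, 90°], treating v and −v as the same
    axis (orientation sign is arbitrary for covariance-based inversion).
    """
    if f1.n_vectors != f2.n_vectors:
        raise ValueError("orientation fields have different vertex counts")
    ang = angular_difference(f1.vectors, f2.vectors)
    hi = 180.0
    if fold:
        ang = np.minimum(ang, 180.0 - ang)
        hi = 90.0
    counts, edges = np.histogram(ang, bins=bins, range=(0.0, hi))
    return FieldDifference(ang, float(ang.mean()), float(ang.std()),
                           counts, edges)


def rotate_on_cone(v: np.ndarray, angle_deg: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Random vector(s) at exactly ``angle_deg`` from ``v`` (uniform azimuth).

    ``v`` may be a single 3-vector or an (N, 3) field; non-unit input is
    normalized silently.  The output lies on the cone of half-angle
    ``angle_deg`` around each input vector.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("cone angle must be in [0, 180] degrees")
    single = np.asarray(v).ndim == 1
    v = np.atleast_2d(np.asarray(v, dtype=np.float64))
    v = _normalize(v)
    # orthonormal frame per vector: pick the axis least aligned with v
    helper = np.zeros_like(v)
    helper[np.arange(len(v)), np.argmin(np.abs(v), axis=1)] = 1.0
    e1 = _normalize(np.cross(v, helper))
    e2 = np.cross(v, e1)
    theta = np.radians(angle_deg)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=len(v))
    out = (np.cos(theta) * v
           + np.sin(theta) * (np.cos(phi)[:, None] * e1
                              + np.sin(phi)[:, None] * e2))
    out = _normalize(out)
    return out[0] if single else out


def rotate_field_on_cone(fld: OrientationField, angle_deg: float,
                         rng: np.random.Generator) -> OrientationField:
    """Rotate every vector of a field by ``angle_deg`` with random azimuths."""
    if angle_deg == 0.0:
        return OrientationField(fld.vectors.copy(), fld.method, fld.surface,
                                dict(fld.provenance, cone_angle_deg=0.0))
    vecs = rotate_on_cone(fld.vectors, angle_deg, rng)
    prov = dict(fld.provenance, cone_angle_deg=float(angle_deg))
    return OrientationField(vecs, fld.method, fld.surface, prov)


# ---------------------------------------------------------------------------
# I/O

def write_orientation_field(fld: OrientationField, path: str | Path) -> None:
    """Write as 3-column TSV plus a JSON sidecar, or GIFTI if ``.gii``."""
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib
        img = nib.gifti.GiftiImage(darrays=[nib.gifti.GiftiDataArray(
            fld.vectors.astype(np.float32), intent="NIFTI_INTENT_VECTOR")])
        nib.save(img, str(path))
        sidecar = path.with_suffix(".json")
    else:
        np.savetxt(path, fld.vectors, delimiter="\t",
                   header="vx\tvy\tvz", comments="", fmt="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"method": fld.method, "surface": fld.surface,
            "provenance": {k: (v if not isinstance(v, np.generic) else v.item())
                           for k, v in fld.provenance.items()}}
    sidecar.write_text(json.dumps(meta, indent=2))


def read_orientation_field(path: str | Path) -> OrientationField:
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib
        vecs = np.asarray(nib.load(str(path)).darrays[0].data, dtype=np.float64)
        sidecar = path.with_suffix(".json")
    else:
        vecs = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return OrientationField(vecs, meta.get("method", "unknown"),
                            meta.get("surface", "unknown"),
                            meta.get("provenance", {}))
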