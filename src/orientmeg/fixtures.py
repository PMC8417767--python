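"""Synthetic anatomy, sensor helmets, and simulation-experiment drivers.

The cortical fixture is an icosphere "head" (pial radius 70 mm) radially
displaced by a band-limited random spherical-harmonic field to emulate
folding, with the white surface displaced inward along smoothed vertex
normals by the cortical thickness — the pair has exact one-to-one vertex
correspondence by construction, and a fold amplitude of zero yields
concentric spheres (the analytic limit where every orientation estimator
must agree with the radial direction).

Two experiment drivers replicate the simulation designs at desk scale:
an SNR sweep and a co-registration-error sweep, each comparing a
true-orientation (link vector) reference inversion against models whose
orientations are rotated on cones of increasing angle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .forward import (SensorArray, apply_coregistration_error, fit_sphere,
                      sphere_leadfield)
from .inversion import InversionComponents, invert, reduce_data
from .mesh_core import (CorticalSurfacePair, MeshError, TriangleMesh,
                        decimate_pair, face_normals, geodesic_kernel,
                        vertex_adjacency, vertex_normals)
from .orientation import OrientationField, link_vectors, rotate_field_on_cone
from .simulate import simulate_dataset


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) fanned out from a master seed."""
    h = zlib.crc32(stage.encode("utf-8"))
    return int((h ^ (master_seed * 2654435761)) & 0x7FFFFFFF)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


@dataclass
class ExperimentSpec:
    """Parameters of the simulation experiments.

    Defaults are desk scale (20 locations, 128 trials); the full-scale study
    conditions (100 locations, 515 trials, six SNR levels, six
    co-registration levels, rotations 7–63° in 7° steps) are reachable by
    overriding fields.
    """

    n_locations: int = 20
    snr_levels_db: tuple = (-50.0, -40.0, -30.0, -20.0, -10.0, 0.0)
    coreg_levels: tuple = ((0.0, 0.0), (2.0, 2.0), (4.0, 4.0),
                           (6.0, 6.0), (8.0, 8.0), (10.0, 10.0))
    rotation_angles_deg: tuple = (7.0, 14.0, 21.0, 28.0, 35.0,
                                  42.0, 49.0, 56.0, 63.0)
    n_trials: int = 128
    n_samples: int = 251
    fs: float = 250.0
    seed: int = 0
    decimation_factor: float = 10.0
    n_temporal_modes: int = 4
    window_ms: float = 100.0
    coherence_fwhm_mm: float = 5.0
    patch_fwhm_mm: float = 5.0

    def __post_init__(self):
        if not self.snr_levels_db or not self.coreg_levels \
                or not self.rotation_angles_deg:
            raise ValueError("level lists must be non-empty")
        if any(not 0 < a < 180 for a in self.rotation_angles_deg):
            raise ValueError("rotation angles must lie in (0, 180)")


# ---------------------------------------------------------------------------
# anatomy & helmet

def _real_sh_field(dirs: np.ndarray, max_degree: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Band-limited random real spherical-harmonic field on unit directions."""
    from scipy.special import sph_harm_y
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))   # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])            # azimuth
    f = np.zeros(len(dirs))
    for ell in range(1, max_degree + 1):
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            f += rng.normal() * y.real
            if m > 0:
                f += rng.normal() * y.imag
    return f


def make_cortical_pair(subdivisions: int = 4, fold_amplitude_mm: float = 8.0,
                       fold_degree: int = 12, thickness_mm: float = 2.5,
                       seed: int = 0, radius_mm: float = 70.0
                       ) -> CorticalSurfacePair:
    """Synthetic folded pial/white surface pair with exact correspondence.

    The pial surface is an icosphere of ``radius_mm`` radially displaced by a
    random spherical-harmonic field (degrees 1..``fold_degree``, RMS
    ``fold_amplitude_mm``); the white surface lies ``thickness_mm`` inward
    along the smoothed pial vertex-normal field.  ``fold_amplitude_mm=0``
    yields concentric spheres.  Fully determined by ``seed``.
    """
    if subdivisions < 2:
        raise ValueError("need at least 2 icosphere subdivisions")
    if thickness_mm <= 0 or fold_amplitude_mm < 0:
        raise ValueError("thickness must be > 0 and fold amplitude >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=np.int64)

    r = np.full(len(dirs), radius_mm)
    if fold_amplitude_mm > 0:
        rng = np.random.default_rng(seed)
        f = _real_sh_field(dirs, fold_degree, rng)
        f *= fold_amplitude_mm / np.sqrt((f ** 2).mean())
        r = r + f
    pial = TriangleMesh(dirs * r[:, None], faces)

    # inward displacement along a smoothed vertex-normal field
    n = vertex_normals(pial)
    adj = vertex_adjacency(pial)
    for _ in range(2):
        sm = np.array([n[[i, *a]].mean(axis=0)
                       for i, a in enumerate(adj)])
        n = sm / np.linalg.norm(sm, axis=1, keepdims=True)
    white = TriangleMesh(pial.vertices - thickness_mm * n, faces.copy())

    wn = face_normals(white)
    centers = white.vertices[white.faces].mean(axis=1)
    centers -= white.vertices.mean(axis=0)
    if np.any(np.einsum("ij,ij->i", wn, centers) <= 0) or \
            np.any(np.linalg.norm(white.vertices, axis=1) <= 0):
        raise MeshError("white surface self-intersects; reduce thickness_mm "
                        "or fold_amplitude_mm")
    return CorticalSurfacePair(pial, white)


def make_helmet(n_sensors: int = 275, radius_mm: float = 110.0,
                kind: str = "axial_gradiometer",
                baseline_mm: float = 50.0) -> SensorArray:
    """Quasi-uniform (Fibonacci) sensor coverage of the upper 2/3 sphere cap.

    Sensitive axes are radial; fiducials sit at canonical nasion/LPA/RPA
    points.  Deterministic — no RNG involved.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    z0 = -1.0 / 3.0   # cap covering 2/3 of the sphere's area
    k = np.arange(n_sensors)
    z = 1.0 - (k + 0.5) * (1.0 - z0) / n_sensors
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z ** 2)
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    fid = {"nasion": np.array([0.0, 90.0, 0.0]),
           "lpa": np.array([-90.0, 0.0, 0.0]),
           "rpa": np.array([90.0, 0.0, 0.0])}
    baseline = baseline_mm if kind == "axial_gradiometer" else None
    return SensorArray(radius_mm * dirs, dirs, kind, baseline, fid)


# ---------------------------------------------------------------------------
# experiment drivers

class _ExperimentContext:
    """Shared state for one experiment: decimated pair, lead fields, kernel."""

    def __init__(self, spec: ExperimentSpec, pair: CorticalSurfacePair,
                 helmet: SensorArray):
        self.spec = spec
        self.helmet = helmet
        self.dec_pair, self.dmap = decimate_pair(pair, spec.decimation_factor)
        self.center, _ = fit_sphere(self.dec_pair.pial.vertices)
        self.link = link_vectors(self.dec_pair)
        self.kernel = geodesic_kernel(self.dec_pair.pial,
                                      spec.coherence_fwhm_mm)
        self.mesh = self.dec_pair.pial
        self.true_leadfield = sphere_leadfield(
            self.mesh.vertices, self.link.vectors, helmet, self.center)
        rng = stage_rng(spec.seed, "locations")
        self.locations = np.sort(rng.choice(
            self.mesh.n_vertices, size=spec.n_locations, replace=False))

    def rotated_field(self, loc: int, angle: float) -> OrientationField:
        rng = stage_rng(self.spec.seed, f"rot/loc{loc}/angle{angle}")
        return rotate_field_on_cone(self.link, angle, rng)

    def dataset(self, loc: int, snr_db: float):
        seed = stage_seed(self.spec.seed, f"sim/loc{loc}/snr{float(snr_db)}")
        return simulate_dataset(
            self.mesh, self.true_leadfield, int(loc), snr_db,
            n_trials=self.spec.n_trials, fs=self.spec.fs,
            n_samples=self.spec.n_samples,
            patch_fwhm_mm=self.spec.patch_fwhm_mm, seed=seed)

    def invert_models(self, loc: int, snr_db: float,
                      sensors: SensorArray) -> dict[float, float]:
        """Free energy per rotation angle (0 = reference) for one location."""
        ds = self.dataset(loc, snr_db)
        reduced = reduce_data(ds, n_temporal_modes=self.spec.n_temporal_modes,
                              window_ms=self.spec.window_ms)
        comp = InversionComponents(
            coherence_fwhm_mm=self.spec.coherence_fwhm_mm)
        out: dict[float, float] = {}
        from .inversion import SourceModel
        for angle in (0.0, *self.spec.rotation_angles_deg):
            fld = self.link if angle == 0.0 else self.rotated_field(loc, angle)
            lf = sphere_leadfield(self.mesh.vertices, fld.vectors,
                                  sensors, self.center)
            model = SourceModel("pial", fld, self.mesh.vertices, lf, self.mesh)
            res = invert(reduced, model, comp, smoothing_kernel=self.kernel)
            out[angle] = res.F
        return out


def run_snr_experiment(spec: ExperimentSpec, pair: CorticalSurfacePair,
                       helmet: SensorArray) -> pd.DataFrame:
    """SNR sweep: ΔF of cone-rotated orientation models vs the link-vector
    reference, per source location and per-trial SNR level (no
    co-registration error).

    Returns a tidy table (location, snr_db, angle, F_ref, F_model, delta_F);
    the angle-0 row is the reference itself (ΔF = 0 exactly).
    """
    ctx = _ExperimentContext(spec, pair, helmet)
    rows = []
    for snr in spec.snr_levels_db:
        for loc in ctx.locations:
            fs = ctx.invert_models(int(loc), float(snr), helmet)
            f_ref = fs[0.0]
            for angle, f in fs.items():
                rows.append({"location": int(loc), "snr_db": float(snr),
                             "angle": float(angle), "F_ref": f_ref,
                             "F_model": f, "delta_F": f - f_ref})
    return pd.DataFrame(rows)


def run_coreg_experiment(spec: ExperimentSpec, pair: CorticalSurfacePair,
                         helmet: SensorArray,
                         snr_db: float = 0.0) -> pd.DataFrame:
    """Co-registration sweep at fixed SNR (default 0 dB).

    Data are simulated with the true sensor geometry; inversion lead fields
    use a rigidly perturbed copy of the array (one random transform per
    location and error level, seeded).  The (0 mm, 0°) level reproduces the
    SNR experiment's matching rows under the same seed.
    """
    ctx = _ExperimentContext(spec, pair, helmet)
    rows = []
    for trans, rot in spec.coreg_levels:
        for loc in ctx.locations:
            rng = stage_rng(spec.seed, f"coreg/loc{int(loc)}/t{trans}r{rot}")
            pert = apply_coregistration_error(helmet, trans, rot, rng)
            fs = ctx.invert_models(int(loc), float(snr_db), pert)
            f_ref = fs[0.0]
            for angle, f in fs.items():
                rows.append({"location": int(loc),
                             "translation_mm": float(trans),
                             "rotation_deg": float(rot),
                             "angle": float(angle), "F_ref": f_ref,
                             "F_model": f, "delta_F": f - f_ref})
    return pd.DataFrame(rows)


def mean_delta_f(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Mean and standard error of ΔF over locations, per group."""
    rotated = table[table["angle"] > 0]
    g = rotated.groupby(by)["delta_F"]
    out = g.agg(mean_delta_F="mean",
                se_delta_F=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
    return out.reset_index()
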