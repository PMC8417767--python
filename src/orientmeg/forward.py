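"""Sensor geometry and spherical-conductor MEG lead fields.

The conductor model is the analytic field of a current dipole in a
homogeneous conducting sphere (Sarvas formula): the magnetic field outside
the sphere depends only on the dipole, the sphere center and the field
point, and a purely radial dipole produces no external field.  Users with
realistic anatomy can plug an external forward solver in through the
:class:`LeadField` container.

Units are fixed package-wide: positions in mm, dipole moments in nA·m,
magnetic fields in fT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.spatial.transform import Rotation

#: unit conversions applied around the SI-internal Sarvas evaluation
UNITS = {
    "position_mm_to_m": 1e-3,
    "moment_nAm_to_Am": 1e-9,
    "field_T_to_fT": 1e15,
    "mu0_over_4pi": 1e-7,
}


class ForwardError(ValueError):
    """Raised for geometrically invalid forward-model input."""


@dataclass
class SensorArray:
    """MEG sensor positions/orientations with fiducial landmarks.

    ``kind`` is ``"magnetometer"`` or ``"axial_gradiometer"``; gradiometers
    measure the field difference between two coaxial coils separated by
    ``baseline_mm`` along the sensitive axis.
    """

    positions: np.ndarray
    orientations: np.ndarray
    kind: str = "magnetometer"
    baseline_mm: float | None = None
    fiducials: dict = field(default_factory=dict)
    names: list[str] | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.orientations = np.asarray(self.orientations, dtype=np.float64)
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ForwardError("sensor orientations must be unit length")
        if self.kind == "axial_gradiometer" and not self.baseline_mm:
            raise ForwardError("axial gradiometer requires a baseline")
        if self.names is None:
            self.names = [f"MEG{i + 1:03d}" for i in range(len(self.positions))]

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class LeadField:
    """Channels × sources gain matrix for unit-oriented dipoles (fT / nA·m)."""

    gain: np.ndarray
    source_positions: np.ndarray
    source_orientations: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.gain)):
            raise ForwardError("lead field contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def dipole_field(positions: np.ndarray, moments: np.ndarray,
                 field_points: np.ndarray,
                 sphere_center: np.ndarray) -> np.ndarray:
    """Magnetic field (fT) of current dipoles in a conducting sphere.

    Sarvas closed form: with r0 the dipole and r the field point (both
    relative to the sphere center), a = r − r0,

        F  = a (r a + r² − r0·r)
        ∇F = (a²/r + a·r/a + 2a + 2r) r − (a + 2r + a·r/a) r0
        B  = μ0/(4π F²) [ F (Q × r0) − ((Q × r0)·r) ∇F ]

    Parameters are broadcast: positions/moments (V, 3), field_points (S, 3);
    returns (S, V, 3).
    """
    c = np.asarray(sphere_center, dtype=np.float64)
    r0 = (np.atleast_2d(positions) - c) * UNITS["position_mm_to_m"]
    r = (np.atleast_2d(field_points) - c) * UNITS["position_mm_to_m"]
    q = np.atleast_2d(moments) * UNITS["moment_nAm_to_Am"]

    if np.any(np.linalg.norm(r0, axis=1) < 1e-12):
        bad = int(np.nonzero(np.linalg.norm(r0, axis=1) < 1e-12)[0][0])
        raise ForwardError(f"source {bad} at the sphere center is degenerate")
    src_radius = np.linalg.norm(r0, axis=1).max()
    if np.any(np.linalg.norm(r, axis=1) <= src_radius):
        raise ForwardError("a field point lies inside the source radius")

    a_vec = r[:, None, :] - r0[None, :, :]          # (S, V, 3)
    a = np.linalg.norm(a_vec, axis=2)               # (S, V)
    rn = np.linalg.norm(r, axis=1)[:, None]         # (S, 1)
    r0_dot_r = np.einsum("vk,sk->sv", r0, r)
    a_dot_r = np.einsum("svk,sk->sv", a_vec, r)
    F = a * (rn * a + rn ** 2 - r0_dot_r)
    if np.any(F <= 0):
        raise ForwardError("degenerate source/sensor geometry (F <= 0)")
    gF = ((a ** 2 / rn + a_dot_r / a + 2 * a + 2 * rn)[..., None] * r[:, None, :]
          - (a + 2 * rn + a_dot_r / a)[..., None] * r0[None, :, :])
    qxr0 = np.cross(q, r0)                          # (V, 3)
    qxr0_dot_r = np.einsum("vk,sk->sv", qxr0, r)
    B = (F[..., None] * qxr0[None, :, :] - qxr0_dot_r[..., None] * gF)
    B *= UNITS["mu0_over_4pi"] / (F ** 2)[..., None]
    return B * UNITS["field_T_to_fT"]


def magnetic_scalar_potential(positions, moments, field_points,
                              sphere_center) -> np.ndarray:
    """Magnetic scalar potential U = (μ0/4π)(Q×r0·r)/F outside the sphere.

    Scaled so that the numerical gradient over mm gives the field in fT:
    B_fT = −∇_mm U.  Serves as an independent finite-difference oracle for
    the analytic ∇F formula in :func:`dipole_field`.
    """
    c = np.asarray(sphere_center, dtype=np.float64)
    r0 = (np.atleast_2d(positions) - c) * UNITS["position_mm_to_m"]
    r = (np.atleast_2d(field_points) - c) * UNITS["position_mm_to_m"]
    q = np.atleast_2d(moments) * UNITS["moment_nAm_to_Am"]
    a_vec = r[:, None, :] - r0[None, :, :]
    a = np.linalg.norm(a_vec, axis=2)
    rn = np.linalg.norm(r, axis=1)[:, None]
    r0_dot_r = np.einsum("vk,sk->sv", r0, r)
    F = a * (rn * a + rn ** 2 - r0_dot_r)
    qxr0_dot_r = np.einsum("vk,sk->sv", np.cross(q, r0), r)
    return (-UNITS["mu0_over_4pi"] * qxr0_dot_r / F
            * UNITS["field_T_to_fT"] / UNITS["position_mm_to_m"])


def sphere_leadfield(positions: np.ndarray, orientations: np.ndarray,
                     sensors: SensorArray,
                     sphere_center: np.ndarray) -> LeadField:
    """Lead field of unit dipoles (1 nA·m along ``orientations``).

    Each gain column is the field of one oriented dipole projected onto every
    sensor's sensitive axis; axial gradiometers subtract the field at the
    outer coil (position + baseline·orientation).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=np.float64))
    B = dipole_field(positions, orientations, sensors.positions, sphere_center)
    gain = np.einsum("svk,sk->sv", B, sensors.orientations)
    if sensors.kind == "axial_gradiometer":
        outer = sensors.positions + sensors.baseline_mm * sensors.orientations
        B2 = dipole_field(positions, orientations, outer, sphere_center)
        gain = gain - np.einsum("svk,sk->sv", B2, sensors.orientations)
    return LeadField(gain, positions.copy(), orientations.copy())


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit; returns (center, radius)."""
    p = np.asarray(points, dtype=np.float64)
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = (p ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + (center ** 2).sum()))
    return center, radius


def apply_coregistration_error(sensors: SensorArray, translation_mm: float,
                               rotation_deg: float,
                               rng: np.random.Generator) -> SensorArray:
    """Rigidly perturb the sensor array to emulate co-registration error.

    One rigid transform: rotation of magnitude ``rotation_deg`` about a
    uniformly random axis through the fiducial centroid, composed with a
    translation of magnitude ``translation_mm`` in a uniformly random
    direction.  Equivalent to perturbing the fiducial coils and
    re-co-registering.  (0 mm, 0°) returns an identical copy.
    """
    if translation_mm < 0 or rotation_deg < 0:
        raise ForwardError("perturbation magnitudes must be non-negative")
    if translation_mm == 0 and rotation_deg == 0:
        out = SensorArray(sensors.positions.copy(),
                          sensors.orientations.copy(), sensors.kind,
                          sensors.baseline_mm,
                          {k: np.asarray(v, dtype=np.float64).copy()
                           for k, v in sensors.fiducials.items()},
                          list(sensors.names))
        out.transform = {"rotation_matrix": np.eye(3).tolist(),
                         "translation_mm": [0.0, 0.0, 0.0],
                         "center": [0.0, 0.0, 0.0]}
        return out

    def rand_dir():
        d = rng.normal(size=3)
        return d / np.linalg.norm(d)

    if sensors.fiducials:
        center = np.mean([np.asarray(v, dtype=np.float64)
                          for v in sensors.fiducials.values()], axis=0)
    else:
        center = sensors.positions.mean(axis=0)
    if rotation_deg > 0:
        R = Rotation.from_rotvec(np.radians(rotation_deg) * rand_dir())
    else:
        R = Rotation.identity()
    t = translation_mm * rand_dir() if translation_mm > 0 else np.zeros(3)

    new_pos = R.apply(sensors.positions - center) + center + t
    new_ori = R.apply(sensors.orientations)
    new_fid = {k: R.apply(np.asarray(v, dtype=np.float64) - center) + center + t
               for k, v in sensors.fiducials.items()}
    out = SensorArray(new_pos, new_ori, sensors.kind, sensors.baseline_mm,
                      new_fid, list(sensors.names))
    out.transform = {"rotation_matrix": R.as_matrix().tolist(),
                     "translation_mm": t.tolist(),
                     "center": center.tolist()}
    return out


# ---------------------------------------------------------------------------
# I/O

def write_sensors(sensors: SensorArray, path: str | Path) -> None:
    """TSV of (name, x, y, z, ox, oy, oz, kind, baseline) + JSON fiducials."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("name\tx\ty\tz\tox\toy\toz\tkind\tbaseline\n")
        for name, p, o in zip(sensors.names, sensors.positions,
                              sensors.orientations):
            fh.write(f"{name}\t" + "\t".join(f"{x:.17g}" for x in p) + "\t"
                     + "\t".join(f"{x:.17g}" for x in o)
                     + f"\t{sensors.kind}\t{sensors.baseline_mm or 0}\n")
    fid = {k: np.asarray(v).tolist() for k, v in sensors.fiducials.items()}
    path.with_suffix(".fiducials.json").write_text(json.dumps(fid, indent=2))


def read_sensors(path: str | Path) -> SensorArray:
    path = Path(path)
    names, pos, ori, kinds, bases = [], [], [], [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            names.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            ori.append([float(x) for x in parts[4:7]])
            kinds.append(parts[7])
            bases.append(float(parts[8]))
    fidpath = path.with_suffix(".fiducials.json")
    fid = ({k: np.asarray(v, dtype=np.float64) for k, v in
            json.loads(fidpath.read_text()).items()} if fidpath.exists() else {})
    baseline = bases[0] if bases and bases[0] > 0 else None
    return SensorArray(np.array(pos), np.array(ori), kinds[0], baseline,
                       fid, names)


def write_leadfield(lf: LeadField, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("source_positions", data=lf.source_positions)
        f.create_dataset("source_orientations", data=lf.source_orientations)
        f.attrs["units"] = "fT per nA.m; positions mm"


def read_leadfield(path: str | Path) -> LeadField:
    with h5py.File(path, "r") as f:
        return LeadField(f["gain"][()], f["source_positions"][()],
                         f["source_orientations"][()])
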