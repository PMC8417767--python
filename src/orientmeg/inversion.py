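"""Empirical Bayesian beamformer (EBB) source inversion with free energy.

The inversion estimates source currents J from reduced sensor data Y under a
Gaussian model Y ~ N(0, C), C = exp(λ₁)·Qε + exp(λ₂)·L Q Lᵀ, where Qε is the
sensor covariance (identity by default) and Q is an empirical source prior:
a diagonal beamformer variance estimate per source, smoothed with a geodesic
spatial-coherence kernel.  The two hyperparameters are optimized on the log
scale by Fisher-scoring ReML under weak Gaussian hyperpriors, and each model
is scored by its variational free energy

    F = accuracy − complexity,

a lower bound on the log model evidence: accuracy measures data fit
(−Nt/2·tr(C_Y C⁻¹) − Nt/2·log|C| − Nc·Nt/2·log 2π) and complexity the KL
divergence of the hyperparameter posterior from its prior.  ΔF between
candidate source models (e.g. differing dipole orientations) approximates
the log Bayes factor.

Because the two covariance components are an identity (after whitening) and
one fixed matrix, the model is simultaneously diagonalizable: one
eigendecomposition per inversion makes every ReML iteration O(Nc).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import linalg, sparse

from .forward import LeadField, SensorArray, fit_sphere, sphere_leadfield
from .mesh_core import (CorticalSurfacePair, DecimationMap, TriangleMesh,
                        geodesic_kernel)
from .orientation import (OrientationField, cortical_patch_statistics,
                          downsampled_normals, link_vectors, original_normals,
                          variational_field)
from .simulate import SimulatedDataset

LOG2PI = np.log(2.0 * np.pi)


class InversionError(ValueError):
    pass


@dataclass
class ReducedData:
    """Windowed data projected onto leading temporal modes.

    ``Y`` is the trial-averaged reduced data (channels × modes) used for the
    source estimate; ``Y_trials`` concatenates the per-trial reduced data
    (channels × modes·trials) and carries the covariance the hyperparameters
    are fit to — per-trial noise enters it unaveraged, so the per-trial SNR
    is what the inversion sees.
    """

    Y: np.ndarray                 # channels × temporal modes (trial average)
    Y_trials: np.ndarray          # channels × (modes × trials)
    temporal_projector: np.ndarray  # window samples × temporal modes
    window: slice
    fs: float
    singular_values: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.Y.shape[0]

    @property
    def n_modes(self) -> int:
        return self.Y.shape[1]

    @property
    def n_cov_samples(self) -> int:
        return self.Y_trials.shape[1]


@dataclass
class SourceModel:
    """Source locations + dipole orientations + their lead field.

    ``location_surface`` and the orientation field's surface tag may differ
    (cross models); a combined location surface stacks pial then white
    sources and has exactly twice the single-surface source count.
    """

    location_surface: str
    orientation: OrientationField
    positions: np.ndarray
    leadfield: LeadField
    mesh: TriangleMesh

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def combined(self) -> bool:
        return self.location_surface == "combined"


@dataclass
class InversionComponents:
    """Prior covariance configuration for one inversion."""

    Q_eps: np.ndarray | None = None   # sensor covariance; None -> identity
    lambda_reg: float = 0.0           # beamformer regularization constant
    coherence_fwhm_mm: float = 5.0


@dataclass
class ReMLResult:
    lambda_hat: np.ndarray
    Sigma_lambda: np.ndarray
    F: float
    accuracy: float
    complexity: float
    n_iter: int
    converged: bool


@dataclass
class InversionResult:
    """Source estimate, hyperparameters and free-energy decomposition."""

    J_hat: np.ndarray
    F: float
    accuracy: float
    complexity: float
    lambda_hat: np.ndarray
    Sigma_lambda: np.ndarray
    prior_mean: np.ndarray
    prior_precision: np.ndarray
    C_i: np.ndarray
    C_Y: np.ndarray
    Gamma: np.ndarray
    temporal_projector: np.ndarray
    window: slice
    provenance: dict = field(default_factory=dict)


def reduce_data(dataset: SimulatedDataset | np.ndarray, fs: float | None = None,
                n_temporal_modes: int = 4, window_ms: float = 100.0,
                window_center: int | None = None) -> ReducedData:
    """Trial-average, window and SVD-reduce sensor data.

    The analysis window (default 100 ms, i.e. 25 samples at 250 Hz) is
    centered on ``window_center`` (defaults to the dataset's simulated peak
    sample, else the epoch center).  The temporal projector is the top
    ``n_temporal_modes`` right singular vectors of the trial-averaged
    windowed data (the evoked subspace); spatial dimension is kept at full
    channel rank.  The projector is applied to the trial average (→ ``Y``)
    and to every single trial (→ ``Y_trials``, the covariance samples).
    """
    trials = None
    if isinstance(dataset, SimulatedDataset):
        trials = dataset.data
        avg = dataset.average()
        fs = dataset.fs
        if window_center is None:
            window_center = dataset.truth.get(
                "peak_sample", (dataset.n_samples - 1) // 2)
    else:
        avg = np.asarray(dataset, dtype=np.float64)
        if fs is None:
            raise InversionError("fs required for raw-array input")
        if window_center is None:
            window_center = (avg.shape[1] - 1) // 2
    n_win = int(round(window_ms * fs / 1000.0))
    if n_win < n_temporal_modes:
        raise InversionError(
            f"window of {n_win} samples shorter than {n_temporal_modes} modes")
    start = window_center - n_win // 2
    if start < 0 or start + n_win > avg.shape[1]:
        raise InversionError("analysis window extends outside the epoch")
    win = slice(start, start + n_win)
    Yw = avg[:, win]
    U, s, Vt = np.linalg.svd(Yw, full_matrices=False)
    T = Vt[:n_temporal_modes].T                       # (n_win, modes)
    Ybar = Yw @ T
    if trials is not None:
        Yt = np.einsum("kcw,wm->ckm", trials[:, :, win], T)
        Yt = Yt.reshape(Yt.shape[0], -1)
    else:
        Yt = Ybar
    return ReducedData(Ybar, Yt, T, win, fs, s[:n_temporal_modes])


def ebb_prior(L: np.ndarray, Y: np.ndarray,
              lambda_reg: float = 0.0) -> np.ndarray:
    """Diagonal beamformer source-variance prior Γ from the sensor data.

    Γ(i) = [L_iᵀ (YYᵀ)⁻¹ L_i + λ]⁻¹ / (L_iᵀ L_i), the classic beamformer
    power estimate normalized by lead-field strength.  With λ = 0 the inverse
    of the (generally rank-deficient) reduced-data covariance is taken with a
    machine-precision ridge, so the default is well defined for any data
    rank.
    """
    L = np.asarray(L, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    YY = Y @ Y.T
    nc = YY.shape[0]
    scale = np.abs(YY).max()
    if scale == 0:
        raise InversionError("all-zero data covariance; EBB prior undefined "
                             "(supply lambda_reg > 0 and non-zero data)")
    tol = max(np.spacing(scale) * nc, np.exp(-32.0) * scale)
    M = np.linalg.inv(YY + tol * np.eye(nc))
    quad = np.einsum("ci,cd,di->i", L, M, L)
    nrm2 = (L ** 2).sum(axis=0)
    if np.any(nrm2 == 0):
        raise InversionError("zero lead-field column")
    return 1.0 / ((quad + lambda_reg) * nrm2)


def coherence_smooth(Gamma: np.ndarray, mesh: TriangleMesh,
                     fwhm_mm: float = 5.0,
                     kernel: sparse.spmatrix | None = None) -> np.ndarray:
    """Spatial-coherence prior Q = G·diag(Γ)·Gᵀ.

    G is the row-normalized geodesic Gaussian kernel (FWHM ``fwhm_mm``,
    truncated at 3σ) on the source mesh; ``fwhm_mm=0`` returns diag(Γ).
    A precomputed ``kernel`` may be supplied to amortize the geodesics.
    """
    Gamma = np.asarray(Gamma, dtype=np.float64)
    if np.any(Gamma < 0):
        raise InversionError("beamformer prior variances must be >= 0")
    G = geodesic_kernel(mesh, fwhm_mm) if kernel is None else kernel
    n = G.shape[0]
    if len(Gamma) == n:
        Q = (G.multiply(Gamma[None, :]) @ G.T).toarray()
    elif len(Gamma) == 2 * n:   # combined surface: block-diagonal smoothing
        Q = np.zeros((2 * n, 2 * n))
        for b in range(2):
            g = Gamma[b * n:(b + 1) * n]
            Q[b * n:(b + 1) * n, b * n:(b + 1) * n] = \
                (G.multiply(g[None, :]) @ G.T).toarray()
    else:
        raise InversionError("Gamma length does not match the source mesh")
    return 0.5 * (Q + Q.T)


def reml_optimize(C_Y: np.ndarray, components: tuple[np.ndarray, np.ndarray],
                  n_samples: int, prior_mean: np.ndarray | None = None,
                  prior_precision: np.ndarray | None = None,
                  max_iter: int = 128, tol: float = 1e-3,
                  free_energy_convention: str = "nt") -> ReMLResult:
    """Fisher-scoring ReML for C = exp(λ₁)·Q₀ + exp(λ₂)·Q₁.

    Maximizes the restricted log likelihood of the sample covariance ``C_Y``
    (from ``n_samples`` columns) plus Gaussian hyperpriors N(υ, Π⁻¹) on the
    log-scale hyperparameters, with step halving to keep the objective
    non-decreasing.  Whitening by Q₀ and one eigendecomposition of whitened
    Q₁ reduce each iteration to O(Nc).

    Returns the hyperparameter posterior (λ̂, Σλ) and the free energy split
    F = accuracy − complexity, with complexity the (non-negative) divergence
    of the hyperparameter posterior from its prior.
    ``free_energy_convention="nc"`` reports the accuracy prefactors with the
    channel count in place of the sample count.
    """
    Q0, Q1 = components
    nc = C_Y.shape[0]
    nt = int(n_samples)
    nu = np.full(2, -32.0) if prior_mean is None else np.asarray(
        prior_mean, dtype=np.float64)
    Pi = 1e-8 * np.eye(2) if prior_precision is None else np.asarray(
        prior_precision, dtype=np.float64)

    R = np.linalg.cholesky(Q0)
    logdet_Q0 = 2.0 * np.sum(np.log(np.diag(R)))
    Bw = linalg.solve_triangular(R, Q1, lower=True)
    Bw = linalg.solve_triangular(R, Bw.T, lower=True).T
    s, U = np.linalg.eigh(0.5 * (Bw + Bw.T))
    s = np.clip(s, 0.0, None)
    Cw = linalg.solve_triangular(R, C_Y, lower=True)
    Cw = linalg.solve_triangular(R, Cw.T, lower=True).T
    d = np.einsum("ij,ij->j", U, (0.5 * (Cw + Cw.T)) @ U)
    d = np.clip(d, 0.0, None)

    dmean = max(d.mean(), 1e-32)
    smean = max(s.mean(), 1e-32)
    lam = np.array([np.log(dmean / 2.0), np.log(dmean / 2.0 / smean)])

    prefac = nc if free_energy_convention == "nc" else nt

    def objective(lm):
        c = np.exp(lm[0]) + np.exp(lm[1]) * s
        if np.any(c <= 0):
            return -np.inf
        e = lm - nu
        return (-0.5 * nt * (np.log(c).sum() + logdet_Q0 + (d / c).sum())
                - 0.5 * nc * nt * LOG2PI - 0.5 * e @ Pi @ e)

    obj = objective(lam)
    n_iter = 0
    converged = False
    H = Pi.copy()
    for n_iter in range(1, max_iter + 1):
        c = np.exp(lam[0]) + np.exp(lam[1]) * s
        dc = np.stack([np.full_like(s, np.exp(lam[0])), np.exp(lam[1]) * s])
        grad = (-0.5 * nt * ((1.0 / c - d / c ** 2)[None, :] * dc).sum(axis=1)
                - Pi @ (lam - nu))
        H = 0.5 * nt * (dc[:, None, :] * dc[None, :, :] / c ** 2).sum(axis=2) \
            + Pi
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(H)
        t = 1.0
        for _ in range(32):
            new = objective(lam + t * step)
            if new >= obj - 1e-12:
                break
            t *= 0.5
        else:
            raise InversionError("ReML step halving failed to find ascent")
        lam = lam + t * step
        if abs(new - obj) < tol:
            obj = new
            converged = True
            break
        obj = new

    c = np.exp(lam[0]) + np.exp(lam[1]) * s
    dc = np.stack([np.full_like(s, np.exp(lam[0])), np.exp(lam[1]) * s])
    H = 0.5 * nt * (dc[:, None, :] * dc[None, :, :] / c ** 2).sum(axis=2) + Pi
    Sigma = np.linalg.inv(H)
    e = lam - nu
    accuracy = (-0.5 * prefac * (d / c).sum()
                - 0.5 * prefac * (np.log(c).sum() + logdet_Q0)
                - 0.5 * nc * nt * LOG2PI)
    sign, ld = np.linalg.slogdet(Sigma @ Pi)
    if sign <= 0:
        raise InversionError("non-positive-definite hyperparameter posterior")
    complexity = 0.5 * e @ Pi @ e - 0.5 * ld
    return ReMLResult(lam, Sigma, float(accuracy - complexity),
                      float(accuracy), float(complexity), n_iter, converged)


def invert(reduced: ReducedData, model: SourceModel,
           components: InversionComponents | None = None,
           smoothing_kernel: sparse.spmatrix | None = None,
           max_iter: int = 128, tol: float = 1e-3,
           free_energy_convention: str = "nt") -> InversionResult:
    """Full EBB inversion of reduced data under one source model.

    Builds the beamformer prior, applies coherence smoothing, optimizes the
    hyperparameter mixture by ReML and returns Ĵ = Q Lᵀ (Qε + L Q Lᵀ)⁻¹ Y
    with the optimized scalings folded into Qε and Q.  Data are normalized to
    unit mean square internally (and the estimate rescaled back), so the free
    energy is invariant to a global rescaling of Y.
    """
    comp = components or InversionComponents()
    L = model.leadfield.gain
    Y = reduced.Y
    Yt = reduced.Y_trials
    nc = Y.shape[0]
    ncov = reduced.n_cov_samples
    s_y = float(np.sqrt((Yt ** 2).mean()))
    Ys = Y / s_y if s_y > 0 else Y
    Yts = Yt / s_y if s_y > 0 else Yt

    Gamma = ebb_prior(L, Yts, comp.lambda_reg) if s_y > 0 else \
        np.ones(L.shape[1])
    Q = coherence_smooth(Gamma, model.mesh, comp.coherence_fwhm_mm,
                         kernel=smoothing_kernel)
    B = L @ Q @ L.T
    t2 = np.trace(B) / nc
    if t2 <= 0:
        raise InversionError("degenerate source-covariance component")
    B = B / t2
    Q_eps = np.eye(nc) if comp.Q_eps is None else np.asarray(
        comp.Q_eps, dtype=np.float64)
    t1 = np.trace(Q_eps) / nc
    if t1 <= 0:
        raise InversionError("sensor covariance must be positive definite")
    Q_eps = Q_eps / t1

    # Covariance estimated over all trials; the evidence is for the reduced
    # trial-averaged data, so the sample count entering F is the number of
    # temporal modes (Nt = 4 by default), as in the reference implementation.
    C_Y = Yts @ Yts.T / ncov
    reml = reml_optimize(C_Y, (Q_eps, B), reduced.n_modes,
                         max_iter=max_iter, tol=tol,
                         free_energy_convention=free_energy_convention)
    e1, e2 = np.exp(reml.lambda_hat)
    C = e1 * Q_eps + e2 * B
    J = (e2 / t2) * (Q @ (L.T @ np.linalg.solve(C, Ys))) * s_y
    prov = {"method": model.orientation.method,
            "orientation_surface": model.orientation.surface,
            "location_surface": model.location_surface,
            "lambda_reg": comp.lambda_reg,
            "coherence_fwhm_mm": comp.coherence_fwhm_mm,
            "data_scale": s_y, "component_scales": [float(t1), float(t2)],
            "reml_iterations": reml.n_iter, "reml_converged": reml.converged,
            "free_energy_convention": free_energy_convention}
    return InversionResult(
        J_hat=J, F=reml.F, accuracy=reml.accuracy, complexity=reml.complexity,
        lambda_hat=reml.lambda_hat, Sigma_lambda=reml.Sigma_lambda,
        prior_mean=np.full(2, -32.0), prior_precision=1e-8 * np.eye(2),
        C_i=C, C_Y=C_Y, Gamma=Gamma,
        temporal_projector=reduced.temporal_projector, window=reduced.window,
        provenance=prov)


def peak_vertex(result: InversionResult) -> tuple[int, np.ndarray]:
    """Source with maximal temporal-mode power and its window time course.

    Ties break to the lowest vertex index (``argmax`` convention); the time
    course is reconstructed through the stored temporal projector and has one
    value per analysis-window sample.
    """
    power = (result.J_hat ** 2).sum(axis=1)
    idx = int(np.argmax(power))
    return idx, result.J_hat[idx] @ result.temporal_projector.T


# ---------------------------------------------------------------------------
# source-model construction (location surface × orientation method/surface)

def make_source_model(decimated_pair: CorticalSurfacePair,
                      dmap: DecimationMap,
                      sensors: SensorArray,
                      method: str = "link_vectors",
                      location_surface: str = "pial",
                      orientation_surface: str | None = None,
                      original_pair: CorticalSurfacePair | None = None,
                      sphere_center: np.ndarray | None = None,
                      orientation_override: OrientationField | None = None
                      ) -> SourceModel:
    """Assemble a :class:`SourceModel` for a given location/orientation choice.

    ``orientation_surface`` defaults to the location surface.  Methods using
    the original mesh (cortical_patch_statistics, original_normals,
    variational) require ``original_pair``.  ``orientation_override`` installs
    a precomputed field (e.g. cone-rotated perturbations) directly.
    """
    if orientation_surface is None:
        orientation_surface = location_surface
    if sphere_center is None:
        sphere_center, _ = fit_sphere(decimated_pair.pial.vertices)

    def field_for(surface: str) -> OrientationField:
        dec_mesh = (decimated_pair.pial if surface == "pial"
                    else decimated_pair.white)
        if method == "downsampled_normals":
            return downsampled_normals(dec_mesh, surface)
        if method == "link_vectors":
            fld = link_vectors(decimated_pair, surface)
            return fld if surface == "pial" else fld.negated()
        if original_pair is None:
            raise InversionError(f"method {method!r} needs the original pair")
        orig = (original_pair.pial if surface == "pial"
                else original_pair.white)
        if method == "cortical_patch_statistics":
            return cortical_patch_statistics(orig, dmap, surface)
        if method == "original_normals":
            return original_normals(orig, dmap, surface)
        if method == "variational":
            return variational_field(original_pair, dmap, surface=surface)
        raise InversionError(f"unknown orientation method {method!r}")

    if orientation_override is not None:
        fld = orientation_override
    elif orientation_surface == "combined":
        if location_surface != "combined":
            raise InversionError("combined orientation surface requires the "
                                 "combined location surface")
        fp, fw = field_for("pial"), field_for("white")
        fld = OrientationField(np.vstack([fp.vectors, fw.vectors]),
                               method, "combined")
    else:
        fld = field_for(orientation_surface)

    if location_surface == "combined":
        positions = np.vstack([decimated_pair.pial.vertices,
                               decimated_pair.white.vertices])
        vecs = fld.vectors if fld.n_vectors == positions.shape[0] else \
            np.vstack([fld.vectors, fld.vectors])
        mesh = decimated_pair.pial
    else:
        positions = (decimated_pair.pial.vertices
                     if location_surface == "pial"
                     else decimated_pair.white.vertices)
        if fld.n_vectors != positions.shape[0]:
            raise InversionError("orientation field size mismatch")
        vecs = fld.vectors
        mesh = (decimated_pair.pial if location_surface == "pial"
                else decimated_pair.white)
    use_fld = OrientationField(vecs, fld.method, fld.surface, fld.provenance)
    lf = sphere_leadfield(positions, vecs, sensors, sphere_center)
    return SourceModel(location_surface, use_fld, positions, lf, mesh)


# ---------------------------------------------------------------------------
# I/O

def write_inversion_result(res: InversionResult, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("J_hat", data=res.J_hat)
        f.create_dataset("F", data=res.F)
        f.create_dataset("accuracy", data=res.accuracy)
        f.create_dataset("complexity", data=res.complexity)
        f.create_dataset("lambda_hat", data=res.lambda_hat)
        f.create_dataset("Sigma_lambda", data=res.Sigma_lambda)
        f.create_dataset("temporal_projector", data=res.temporal_projector)
        f.attrs["window"] = [res.window.start, res.window.stop]
        f.attrs["provenance"] = json.dumps(res.provenance)


def read_inversion_result(path: str | Path) -> dict:
    """Load the serialized fields of an inversion result as a dict."""
    with h5py.File(path, "r") as f:
        start, stop = (int(x) for x in f.attrs["window"])
        return {"J_hat": f["J_hat"][()], "F": float(f["F"][()]),
                "accuracy": float(f["accuracy"][()]),
                "complexity": float(f["complexity"][()]),
                "lambda_hat": f["lambda_hat"][()],
                "Sigma_lambda": f["Sigma_lambda"][()],
                "temporal_projector": f["temporal_projector"][()],
                "window": slice(start, stop),
                "provenance": json.loads(f.attrs["provenance"])}
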