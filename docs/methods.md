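# Methods

## Problem setting

MEG source inversion with cortical constraints needs, per source vertex, a
location (which cortical surface) and a dipole orientation (an estimate of
the local cortical-column axis). `orientmeg` implements five orientation
estimators on paired pial/white surface meshes and quantifies, by forward
simulation and Bayesian model comparison, how much orientation accuracy
matters to inversion quality and how that depends on SNR and co-registration
accuracy.

## Surface model and decimation

A `CorticalSurfacePair` holds pial and white triangle meshes with identical
face lists and one-to-one vertex correspondence, so the thickness vector
wᵢ − pᵢ is defined at every vertex. Decimation must preserve that
correspondence: `decimate_pair` runs a greedy edge collapse on the pial mesh
in which every collapse snaps onto an existing vertex — vertices are
removed, never moved, so decimated coordinates are a bit-exact subset of the
originals — and the resulting face list is copied to the white mesh.
Collapses are prioritized by shortest edge with deterministic tie-breaking;
validity requires the edge link condition (manifoldness), no duplicate
faces, no face-normal flips, and valence bounds (no vertex left below
valence 4 or pushed above 8). Among the two possible survivors the one
giving the better worst-triangle shape quality (4√3·area/Σedge², 1 for
equilateral) is kept, a quality floor rejects sliver-prone collapses until
no alternatives remain, and a final Delaunay-style edge-flip pass evens out
the tessellation. No randomness is involved anywhere.

At the default factor 10 on a 2562-vertex sphere of radius 70 mm
(≈ 256 retained vertices, ≈ 17 mm edges), decimated-mesh vertex normals
deviate from radial by 2.2° on average (p95 < 5°, worst vertex ≈ 6°). That
residual distortion is intrinsic to coarse vertex-subset decimation and is
precisely the bias that motivates estimating orientation from the original
surfaces instead.

## Orientation estimators

All five produce unit per-vertex fields and are equivariant to rigid
rotations.

* `downsampled_normals`: mean of adjacent unit face normals on the decimated
  mesh, renormalized.
* `cortical_patch_statistics`: mean of original-mesh vertex normals over the
  1-ring neighbors of the corresponding original vertex (the center vertex
  itself excluded — the inclusive variant differs by < 2° on our fixtures).
* `original_normals`: original-mesh vertex normals at the retained vertices.
* `link_vectors`: normalize(wᵢ − pᵢ), fixed as pial→white (inward). The
  white-surface field is the exact negation; sign is immaterial to
  covariance-based inversion, so no global sign harmonization is applied and
  reports may optionally fold angles to [0, 90°].
* `variational`: projected gradient descent on
  E(v) = Σᵢ [α(1 − vᵢ·nᵢᵖ) + α(1 − vᵢ·nᵢʷ) + β Σ_{j∈N(i)}(1 − vᵢ·vⱼ)]
  over unit vectors on the original mesh, α = 1, β = 0.5, initial step 0.1
  halved by backtracking, tol 1e−8 on the energy decrement, max 1000
  iterations, then sampled at the retained vertices. The functional is this
  package's concrete choice for the two stated pressures (normality to both
  surfaces, mutual parallelism). Initialization is the link-vector field
  with each vector sign-aligned to nᵢᵖ + nᵢʷ: on concentric spheres the raw
  link vectors are exactly antipodal to the normals, which is a stationary
  point of projected descent; since orientation sign is physically
  arbitrary, the aligned start is a pure numerical device.

Angular differences use atan2(‖v₁×v₂‖, v₁·v₂), stable near 0° and 180°
(verified against the arccos form to 1e−6° on 10⁶ random pairs).
`rotate_on_cone` draws vectors at an exact angular distance with uniform
azimuth, used to build orientation models with controlled error.

## Forward model

The conductor is the analytic current dipole in a homogeneous conducting
sphere. Units are mm / nA·m / fT throughout, with conversion constants in
one module table. Axial gradiometers subtract the field at an outer coil
50 mm along the radial axis. Two independent oracles pin the
implementation: the radial field component outside any spherically
symmetric conductor equals that of the primary Biot–Savart term alone
(closed form, agrees to 1e−9 relative), and the analytic field matches a
finite-difference gradient of the magnetic scalar potential. A purely
radial dipole is silent — a physical degeneracy that shapes several design
choices below. Real-data users can substitute any external forward solver
through the `LeadField` container.

Co-registration error is modeled as one rigid transform of the sensor array
(rotation about a random axis through the fiducial centroid composed with a
random-direction translation), equivalent to perturbing the fiducial coils
and re-co-registering; the transform is redrawn per source location and
error level from seeded generators.

## Simulation

A source is a Gaussian moment pulse (FWHM 25 ms — "width" read as FWHM —
peak 10 nA·m at the epoch center) at a chosen vertex, spread over the
surface by a geodesic Gaussian patch (FWHM 5 mm, truncated at 3σ,
σ = FWHM/2.355). Space and time factorize, which is equivalent to smoothing
the single-pulse time course spatially. Sensor data are the lead-field
projection repeated over trials with independent white Gaussian noise,
scaled so the per-trial amplitude SNR — mean over channels of
20·log₁₀(RMS signal / RMS noise) — hits the requested level (verified to
0.1 dB across −50…0 dB). Noise is added per trial and averaging happens in
the analysis, mirroring acquisition. Datasets are bit-reproducible from the
recorded seed.

## Inversion and free energy

The analysis window is 100 ms (25 samples at 250 Hz) centered on the event;
the temporal projector is the top 4 right singular vectors of the
trial-averaged windowed data. The projector is applied both to the average
(for the source estimate) and to every trial: the data covariance C_Y is
accumulated over all trials' reduced data, so per-trial noise enters it
unaveraged and the covariance is well conditioned. The model evidence is
evaluated for the reduced averaged data, i.e. with the temporal-mode count
(4) as the sample count in the accuracy term; weighting by modes × trials
instead inflates every ΔF by two orders of magnitude and makes orientation
models "significant" even at −50 dB, contradicting the regime the
experiments are designed to exhibit.

The EBB prior is the printed beamformer form
Γ(i) = [Lᵢᵀ(YYᵀ)⁻¹Lᵢ + λ]⁻¹/(LᵢᵀLᵢ) with λ = 0; the covariance inverse
uses a machine-precision ridge (as reference implementations do) so the
λ = 0 default is well defined for any data rank. Γ is smoothed into
Q = G·diag(Γ)·Gᵀ with the row-normalized 5 mm geodesic kernel (at the
decimated source spacing of ~17 mm the kernel is effectively the identity;
it becomes active on denser meshes). Sensor covariance Qε defaults to the
identity; a measured covariance may be supplied.

ReML maximizes the evidence of C = exp(λ₁)Qε + exp(λ₂)LQLᵀ by Fisher
scoring on log-scale hyperparameters with weak Gaussian hyperpriors
(υ = −32, Π = 1e−8·I) and step halving. Because there are exactly two
components and Qε is whitened away, the problem is simultaneously
diagonalizable: one eigendecomposition per inversion makes each iteration
O(N_c). Components are trace-normalized and the data rescaled to unit power
internally (folded back out of Ĵ), so F is invariant to global rescaling of
Y. Free energy is reported as accuracy − complexity with
accuracy = −Nt/2·tr(C_Y C⁻¹) − Nt/2·log|C| − N_c·Nt/2·log 2π and
complexity = ½(λ̂−υ)ᵀΠ(λ̂−υ) − ½·log|Σλ·Π|, the non-negative Gaussian
divergence of the hyperparameter posterior from its prior; a
`free_energy_convention` switch exposes the variant with N_c prefactors in
the accuracy term. Parameter recovery on synthetic covariance mixtures
(2·Qε + 3·B, 10⁴ samples) is within 10% over 20 seeds.

## Model comparison

ΔF between models approximates a log Bayes factor; the ±3 threshold
corresponds to ≈ 20:1 odds (exp(3) ≈ 20.09), with the boundary itself
classed indistinguishable. Family inference is random-effects Bayesian
model selection: per-subject family evidence is the log-sum-exp of member
free energies minus log member count (uniform within-family prior), family
frequencies get a Dirichlet(1) prior, and a Gibbs sampler (10³ burn-in,
10⁵ draws by default, seeded) alternates subject assignments and
frequencies; the exceedance probability of a family is the fraction of
draws in which it is most frequent, so EPs sum to one exactly. A
deterministic oracle (exact enumeration of assignments with Beta-CDF
integration) checks the 2-family case to 0.01. Groupings by method,
location surface, orientation surface, and method × location are built in.

## Synthetic study conditions

The anatomy generator emulates folded cortex on a closed topology: a
70 mm-radius icosphere radially displaced by a band-limited random
spherical-harmonic field (degrees 1–12, RMS 8 mm), with the white surface
2.5 mm inward along smoothed vertex normals. The fold scale was chosen so
the link-vector column axes tilt broadly away from the head radius (mean
≈ 31°, p90 ≈ 47° on the study fixture) — the regime real sulci and gyri
occupy. This matters because the spherical conductor silences radial
dipoles: a near-spherical fixture would make the reference orientations
near-silent, a degenerate regime with no real-data counterpart. Zero fold
amplitude gives concentric spheres, the analytic limit in which all five
estimators agree with the radial axis. The helmet is a Fibonacci lattice of
275 radial axial gradiometers (baseline 50 mm) on the upper 2/3 cap of a
110 mm sphere.

What the generator does not emulate: an open (cut) cortical sheet with
boundary, realistic gyral anisotropy and curvature statistics, position-
dependent thickness, correlated or structured sensor noise, and a realistic
(non-spherical) conductor. Passing tests therefore demonstrate the
correctness and the qualitative SNR/co-registration behavior of the
pipeline, not quantitative agreement with any particular human dataset.

Experiments run at desk scale by default — 20 source locations and 128
trials rather than 100 and 515, with ~256 decimated sources rather than
~30 000 — chosen to keep a full sweep in the minutes range on one CPU;
full-scale values are plain parameters. At these conditions the mean ΔF of
rotated-orientation models at 0 dB saturates near −10³ nats by ~21° and
partially recovers toward 63° (the badly wrong models' own adaptive priors
soak up generic fit), so the evidence-vs-angle curve is monotone only up to
the saturation point; at −50 dB all rotated models stay within ±1 nat of
the reference, and under co-registration errors up to 10 mm/10° the 7°
rotation remains significantly worse than the reference while the largest
rotations lose significance at the highest error levels.

## Numerical conventions and degenerate inputs

0-based vertex indices; mm everywhere; geodesics are graph (edge-path)
distances, adequate at 5 mm kernel scale on ~1–5 mm edges and checked
against a relaxation oracle. Ties in peak-power selection break to the
lowest vertex index. Zero data yield a zero source estimate rather than an
error; an all-zero noiseless simulation (exactly radial source) raises with
advice to pick another vertex; degenerate meshes (zero-area faces, isolated
vertices, exactly cancelling normals) raise naming the offending element.
Master seeds fan out to per-stage seeds by CRC-32 hashing of stage names,
keeping every derived seed below 2³¹ and decoupling pipeline stages.
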