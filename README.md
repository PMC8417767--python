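# orientmeg

Cortical-column dipole-orientation models for MEG source inversion.

MEG source reconstruction commonly constrains dipoles to a cortical surface
mesh and orients them normal to that surface, as a proxy for the axis of the
underlying cortical columns. But the cortex has two bounding surfaces — the
white/gray boundary and the pial surface — and normals estimated from a
single decimated mesh are biased by the decimation itself, while the column
axis need not be normal to either surface. `orientmeg` implements and
compares five per-vertex orientation estimators on paired pial/white meshes
with one-to-one vertex correspondence:

* **downsampled surface normals** — vertex normals of the decimated mesh
  (the common default);
* **cortical patch statistics** — average original-mesh vertex normals over
  the 1-ring of the corresponding original vertex;
* **original surface normals** — original-mesh vertex normals sampled at the
  retained vertices;
* **link vectors** — vᵢ = wᵢ − pᵢ, the vector joining corresponding
  white and pial vertices;
* **variational vector field** — unit vectors minimizing
  E(v) = Σᵢ [α(1 − vᵢ·nᵢᵖ) + α(1 − vᵢ·nᵢʷ) + β Σ_{j∈N(i)} (1 − vᵢ·vⱼ)],
  rewarding normality to both surfaces and mutual parallelism.

Around the estimators the package provides the full evaluation pipeline:
correspondence-preserving mesh decimation (vertices removed, never moved;
the decimated pial topology is copied to the white mesh), an analytic
current-dipole-in-conducting-sphere forward model (fT per nA·m), patch-source
simulation at controlled per-trial amplitude SNR, empirical Bayesian
beamformer (EBB) inversion with ReML-optimized covariance mixing, and model
scoring by variational free energy

    F = accuracy − complexity,
    Ĵ = Q Lᵀ (Qε + L Q Lᵀ)⁻¹ Y,

where the source prior Q carries a data-derived diagonal beamformer variance
Γ(i) = [Lᵢᵀ(YYᵀ)⁻¹Lᵢ + λ]⁻¹ / (LᵢᵀLᵢ) under a 5 mm geodesic coherence
kernel. ΔF = Fᵢ − Fⱼ approximates a log Bayes factor; |ΔF| > 3 (≈ 20:1
odds) is the conventional significance threshold. Families of models are
compared across subjects with random-effects Bayesian model selection
(Dirichlet-multinomial Gibbs sampling → exceedance probabilities).

## Worked example

```python
import numpy as np
from orientmeg import (decimate_pair, link_vectors, simulate_dataset,
                       sphere_leadfield, reduce_data, invert, peak_vertex,
                       SourceModel, significant)
from orientmeg.fixtures import make_cortical_pair, make_helmet
from orientmeg.forward import fit_sphere
from orientmeg.mesh_core import geodesic_kernel
from orientmeg.orientation import (rotate_field_on_cone,
                                   field_difference_summary,
                                   downsampled_normals)

pair = make_cortical_pair(seed=11)          # folded pial/white pair, 2562 vertices
dec, dmap = decimate_pair(pair, factor=10)  # 256-source meshes, shared topology
helmet = make_helmet()                      # 275 axial gradiometers
center, _ = fit_sphere(dec.pial.vertices)

link = link_vectors(dec)                    # column-axis estimate
normals = downsampled_normals(dec.pial)
diff = field_difference_summary(link, normals, fold=True)
print(f"link vs decimated-normal orientations: mean {diff.mean:.1f} deg")

lf = sphere_leadfield(dec.pial.vertices, link.vectors, helmet, center)
ds = simulate_dataset(dec.pial, lf, center_vertex=42, snr_db=0.0,
                      n_trials=128, seed=5)
reduced = reduce_data(ds)                   # 100 ms window, 4 temporal modes
kernel = geodesic_kernel(dec.pial, 5.0)

ref = invert(reduced, SourceModel("pial", link, dec.pial.vertices, lf,
                                  dec.pial), smoothing_kernel=kernel)
vtx, _ = peak_vertex(ref)
print(f"reference model: F = {ref.F:.1f}, peak vertex {vtx} (true 42)")

rot = rotate_field_on_cone(link, 21.0, np.random.default_rng(0))
lf21 = sphere_leadfield(dec.pial.vertices, rot.vectors, helmet, center)
alt = invert(reduced, SourceModel("pial", rot, dec.pial.vertices, lf21,
                                  dec.pial), smoothing_kernel=kernel)
dF = alt.F - ref.F
print(f"21 deg-rotated model: dF = {dF:.1f} ({significant(dF)[0]})")
```

Output:

```
link vs decimated-normal orientations: mean 18.0 deg
reference model: F = 2105.0, peak vertex 42 (true 42)
21 deg-rotated model: dF = -915.1 (worse)
```

The two orientation estimators disagree by ~18° on the folded fixture; a
clean 0 dB dataset is localized exactly at the simulated vertex; and
rotating the inversion model's orientations 21° away from the truth drops
the model evidence far past the −3 significance line.

## Command line

`orientmeg` installs a CLI with subcommands `fixtures`, `orient`,
`simulate`, `invert`, `compare`, and `experiment snr|coreg`, e.g.

```sh
orientmeg --seed 1 --outdir out fixtures
orientmeg --outdir out orient --pial out/pial.surf.gii \
    --white out/white.surf.gii --method link_vectors
orientmeg --seed 1 --outdir out experiment snr --locations 5 --trials 32
```

Every run writes a provenance JSON (config, package version, seeds) next to
its outputs.

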