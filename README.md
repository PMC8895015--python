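# specklekit

Coherent diffraction imaging (CDI) records only the far-field intensity of a
coherently illuminated object — the phases of the diffracted wavefield are
lost, and with them the image. When the object is weakly scattering (a
fixed organelle in a synchrotron beam, say) the recorded speckle pattern is
also photon-starved, and independent phase-retrieval runs disagree:
averaging them blindly blurs the image and makes any resolution claim
unreliable. specklekit is a toolkit for exactly this regime. It is aimed at
people who phase noisy 2-D speckle patterns and need to (a) pick the
mutually consistent reconstructions out of an ensemble before averaging,
(b) put an honest number on the resolution of the average, and (c) quantify
how the specimen's electron density changes across a radiation-dose series.

## What is inside

* **`simulate`** — synthetic study conditions: compact elongated phantoms
  with internal high/low-density structure, far-field diffraction with
  Poisson photon noise, an off-centre beamstop whose shadow is refilled by
  Friedel centrosymmetry `I(f) = I(−f)`, detector binning with
  contrast-restoring deconvolution, and a cumulative dose-degradation series
  (dense regions fade monotonically; sparse regions transiently swell by
  aggregation, then collapse).
* **`phase_retrieval`** — the oversampling-smoothness (OSS) engine as a
  scikit-learn-style estimator (`OssReconstructor.fit(pattern)` →
  `image_`, `error_history_`). OSS alternates the Fourier-magnitude
  projection with a hybrid input-output (HIO) update, and replaces the
  region outside the support with a Gaussian-low-pass-filtered copy of
  itself, the filter narrowing over ten stages; with infinite filter widths
  it reduces exactly to plain HIO. Convergence is tracked with the Fourier
  R-factor `R = Σ| |F(ρ)| − √I | / Σ √I`.
* **`clustering`** — `ReconstructionClusterer`: registers the ensemble
  (integer shifts + Friedel twins), embeds each image with a fixed,
  training-free multi-scale convolution bank, reduces with PCA, partitions
  with k-means++, selects the lowest-mean-R cluster and averages its best
  members. A pairwise-correlation hierarchical baseline is included for
  comparison, and alternative feature backbones can be plugged in.
* **`quality`** — the phase-retrieval transfer function
  `PRTF(f) = ⟨|F(ρ̄)|⟩ / √I(f)` per resolution shell (floor `1/√N ≈ 0.2`
  for N = 24 unconverged members), a constant noise floor estimated from the
  high-frequency tail of the power spectrum, the Wiener weight
  `W = S/(S+N)`, the weighted wPRTF with resolution read at the 1/e
  crossing (`d = 1/f`), shell variance of member amplitudes, and per-shell /
  global Pearson cross-correlations between patterns.
* **`damage`** — electron totals by integrating the image over the support,
  fractional electron-loss series, fixed-rectangle region density
  trajectories, and vertically averaged lateral profiles, all on a common
  registered frame.
* **`io` / CLI** — CXI-style HDF5 containers, float TIFF interchange, tidy
  CSV curves, schema-versioned JSON reports, and a
  `specklekit {simulate,reconstruct,cluster,metrics,damage,pipeline}`
  command-line surface.

## Worked example

```python
import numpy as np
from specklekit import simulate, quality
from specklekit.phase_retrieval import make_support, run_ensemble
from specklekit.clustering import ReconstructionClusterer
from specklekit.types import OssSchedule

phantom = simulate.make_phantom(seed=1, grid_size=64, object_fraction=0.08)
pattern = simulate.add_poisson_noise(simulate.diffract(phantom), 1e6, seed=7)
pattern = simulate.apply_beamstop_and_symmetrize(pattern, 3, (1, 2))

support = make_support(pattern)
ensemble = run_ensemble(pattern, support=support,
                        schedule=OssSchedule(n_iterations=600, n_stages=10),
                        n_runs=8, base_seed=0)
print(f"ensemble R-factors: {np.round(ensemble.rfactors(), 3)}")

clusterer = ReconstructionClusterer(k=2, n_best=8, random_state=0).fit(ensemble)
print(f"selected cluster {clusterer.selected_} "
      f"({clusterer.report_['n_averaged']} members, "
      f"mean R = {clusterer.report_['mean_rfactor']:.3f})")

shells = quality.build_shells(pattern.shape, pattern.freq_per_pixel)
prtf = quality.prtf(clusterer.average_image_, pattern, shells)
wiener = quality.wiener_weight(pattern, shells)
res = quality.resolution_from_curve(quality.wprtf(prtf, wiener))
print(f"wPRTF resolution: {res.d_nm:.1f} nm (1/e crossing at {res.f_star:.2f} um^-1)")
```

This prints:

```
ensemble R-factors: [0.076 0.081 0.084 0.082 0.078 0.08  0.076 0.083]
selected cluster 0 (2 members, mean R = 0.080)
wPRTF resolution: 43.1 nm (1/e crossing at 23.22 um^-1)
```

Eight OSS runs on a million-photon pattern converge to Fourier R-factors
near 0.08 (the residual is shot noise, not stagnation); the clusterer keeps
the tightest, lowest-R group and averages it; and the Wiener-weighted PRTF
of that average stays above 1/e out to 23.2 µm⁻¹, i.e. the image is
trustworthy down to a 43 nm full-period length scale at this pixel size.

The same flow from a shell:

```bash
specklekit simulate --seed 1 --out run/
specklekit reconstruct run/pattern_0.cxi run/stack.h5 --runs 24 --seed 0
specklekit cluster run/stack.h5 run/avg.h5 --k 4 --n-best 24
specklekit metrics run/pattern_0.cxi run/avg.h5 --out run/metrics
```

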