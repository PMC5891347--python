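# cypdyn

Analysis toolkit for molecular-dynamics trajectories of two-domain proteins
that interconvert between an **extended** and a **compact** arrangement of
their domains — the behaviour of cyclophilin 40 (Cyp40), whose N-terminal
peptidyl-prolyl-isomerase domain and C-terminal TPR domain are joined by a
charged flexible linker. It is aimed at structural-bioinformatics users who
have a reference structure plus a Cα trajectory (DCD or multi-model PDB)
and want the standard essential-dynamics/conformer-population readouts as
tested, scriptable building blocks.

## What it computes

* **Essential dynamics** — Kabsch superposition onto a fixed reference,
  the 3N×3N Cα positional covariance C = ⟨(R−⟨R⟩)(R−⟨R⟩)ᵀ⟩, its
  eigendecomposition C = Σᵢ σᵢ pᵢ pᵢᵀ (PC1 = largest collective motion),
  per-frame projections, and free-energy surfaces A = −kT ln f + const
  from Boltzmann inversion of projection densities.
* **Geometric descriptors** — interdomain Cα-centroid distance, salt-bridge
  center-of-mass distances (acid side-chain O vs base side-chain N), helix
  axes (per-frame positional PC1) and interhelix angles
  θ = atan2(‖a×b‖, a·b), RMSF/B-factors (B = (8π²/3)·⟨ΔR²⟩), and the
  coordination-shell radius R_g,i = (Σ_j R_ij²/n_i)^½, a per-residue
  compactness metric averaged over the protein.
* **Comparative maps** — trajectory-mean Cα–Cα distance matrices and
  distance-change maps between systems ([−10, −4] Å decreases,
  [4, 10] Å increases), dynamic cross-correlation matrices,
  anticorrelation-difference maps, and per-domain-aligned intradomain
  correlations/fluctuations.
* **Two-state classification** — normalised distributions of a descriptor,
  peak finding, extended/compact frame labels split at the between-peak
  density minimum, compact-population fractions, and population free-energy
  differences ΔA = −kT ln(f_ext/f_comp).
* **Synthetic two-state generator** — a Cα toy protein (globular domain,
  flexible linker, helix-bundle domain, proxy salt-bridge atoms) whose
  frames switch basins by a two-state Markov chain with Gaussian positional
  noise. Ground-truth labels and analytic expectations make it the test
  bed for every estimator above.

See `docs/methods.md` for conventions, defaults, and limitations.

## Worked example

Generate a wild-type-like synthetic ensemble (14 400 frames at 50 ps, basins
at 43.8/34.0 Å, switch probabilities 0.003/0.007 per frame) and classify its
conformers:

```python
import numpy as np
from cypdyn.synthetic import SyntheticSpec, generate_two_state_trajectory
from cypdyn.descriptors import interdomain_distance_series
from cypdyn.states import (classify_states, estimate_distribution,
                           population_free_energy_difference)
from cypdyn.pca import thermal_energy

spec = SyntheticSpec(p_ec=0.003, p_ce=0.007, n_frames=14400, seed=1)
traj, truth = generate_two_state_trajectory(spec)
series = interdomain_distance_series(traj, spec.domain1_range, spec.domain2_range)
dist = estimate_distribution(series, "histogram", 0.5)
a = classify_states(series, dist)
kT = thermal_energy(310.0)
print(f"peaks (A):        {np.round(a.peak_locations, 1)}")
print(f"boundary (A):     {a.boundary:.1f}")
print(f"fraction compact: {a.fraction_compact:.3f}")
print(f"true occupancy:   {truth.occupancies['compact']:.3f}")
print(f"dA (kcal/mol):    {population_free_energy_difference(a, kT):+.3f}")
```

prints

```
peaks (A):        [33.9 43.9]
boundary (A):     35.4
fraction compact: 0.334
true occupancy:   0.334
dA (kcal/mol):    -0.424
```

The distribution is bimodal with peaks at the two basin distances; the
classifier's compact fraction matches the generator's realised occupancy
exactly here (the Markov chain's stationary expectation is 0.30), and the
negative ΔA says the extended basin is the lower-free-energy, more
populated state by ~0.4 kcal/mol at 310 K.

The same pipeline is scriptable from the shell:

```sh
cypdyn synthesize --seed 1 --config my.yaml --out run/
cypdyn analyze  --config my.yaml --topology run/topology.pdb \
                --trajectory run/trajectory.dcd --out wt/
cypdyn compare  --config my.yaml --wt wt/ --mut mutant/ --out diff/
```

A packaged Cyp40 configuration (`cypdyn.structio.default_config_path()`)
carries the domain ranges (cyclophilin 1–183, linker 184–213, TPR 216–362),
the TPR helices P–V, the linker salt bridges, and all descriptor defaults.

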