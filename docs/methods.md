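# Methods

`cypdyn` analyses molecular-dynamics trajectories of two-domain proteins of
the Cyp40 type — an N-terminal globular (cyclophilin/PPIase) domain joined
by a charged flexible linker to a C-terminal helical (TPR) domain — whose
dominant slow motion is a switch between an *extended* and a *compact*
arrangement of the two domains. This note records the models, conventions,
parameter choices, and limitations.

## Essential dynamics

All frames are superposed onto a fixed reference structure (normally the
crystal structure) by least-squares rigid-body superposition (Kabsch, proper
rotations only) over a Cα selection. The alignment is single-pass against
that reference, not iterated against the evolving mean; per-domain alignment
(used for intradomain correlation and fluctuation analysis) is a separate
path that superposes each frame on the domain's own Cα atoms.

The positional covariance over the 3N-dimensional Cα configuration vector R
is

    C = ⟨(R − ⟨R⟩)(R − ⟨R⟩)ᵀ⟩,

with *population* normalisation (divide by the number of frames T), matching
the ensemble-average definition; at small T this differs from the sample
(T−1) convention, which is why it is fixed here. Eigendecomposition
C = Σᵢ σᵢ pᵢ pᵢᵀ gives principal components sorted by descending variance.
The eigenvector sign is arbitrary; we fix it by making each component's
largest-magnitude entry positive so projections are reproducible across
runs and platforms. Eigenvalues more negative than −1e-8·trace(C) indicate a
non-covariance input and raise; smaller negative round-off is clamped to 0.

Projections are score_i(t) = pᵢ·(R(t) − ⟨R⟩). Free-energy surfaces follow
from Boltzmann inversion of the histogrammed score density f:
A = −kT ln f + const, shifted so the lowest finite value is 0; empty bins
are reported as +∞, never capped. k = 0.0019872 kcal/mol/K; the default
temperature is 310 K (kT ≈ 0.616 kcal/mol), configurable.

## Geometric descriptors

* **Interdomain distance** — Euclidean distance between the unweighted Cα
  centroids of the two domain residue ranges (defaults 1–183 and 216–362).
* **Salt-bridge distance** — distance between the center of mass of the
  acidic side chain's oxygens (OD1/OD2/OE1/OE2) and the basic side chain's
  nitrogens (NZ/NH1/NH2/NE/ND1/NE2); with single-element sets the mass
  weighting is uniform. A formation threshold of 4.5 Å (COM–COM) is used
  only for optional summary tables and always reported.
* **Helix axis / interhelix angle** — the axis is the dominant principal
  axis of a helix's Cα cloud within a single frame, sign-fixed N→C; the
  angle between two axes of the *same* frame is θ = atan2(‖a×b‖, a·b) in
  [0°, 180°), the numerically stable equivalent of arccos of the dot
  product. For short helices the finite-length positional PC1 is tilted
  from the geometric axis by O(1/n) — about 2–3° at 15 residues, under 1°
  beyond ~30; interhelix angles inherit this as a small systematic.
* **RMSF / B-factor** — RMSF_i = ⟨|R_i − ⟨R_i⟩|²⟩^½ on an aligned
  trajectory; B_i = (8π²/3)·RMSF_i². Domain averages are arithmetic means
  of the per-residue *fluctuation* (Å), not of B — the convention used in
  domain-average fluctuation tables.
* **Coordination-shell radius** — per residue,
  R_g,i = (Σ_j R_ij²/n_i)^½ over Cα neighbours j ≠ i within a cutoff;
  isolated residues are excluded from the protein average. The cutoff is a
  free parameter of the metric; the default is 10 Å, which puts per-residue
  radii in the 6–7 Å range on globular proteins, and it is stamped into all
  outputs. By default radii are computed per frame and averaged over frames;
  evaluating the mean structure instead is available as a flag.

## Comparative maps

Mean distance matrices average the full Cα–Cα distance matrix over frames
(no alignment needed; distances are rigid-motion invariant). Distance-change
maps classify Δ_ij = d_ij(perturbed) − d_ij(reference) into decreases within
[−10, −4] Å and increases within [4, 10] Å, both ends inclusive; by default
the windows are strict (|Δ| > 10 Å is left unclassified), with a saturating
variant available since larger changes are arguably still "changes".

Dynamic cross-correlations use the standard normalisation
c_ij = ⟨ΔR_i·ΔR_j⟩ / (⟨ΔR_i²⟩⟨ΔR_j²⟩)^½ built from the 3×3 residue blocks of
C. Anticorrelation-difference maps consider only pairs with c < −0.1 in at
least one system (threshold configurable) and classify a pair as less/more
anticorrelated when the correlation changed by more than a margin δ = 0.05.
Neither threshold has a canonical literature value; both are config-exposed
and written into output headers.

## Two-state classification

The interdomain-distance series is turned into a normalised density
(histogram, 0.5 Å bins for distances and 2° for angles — matching the
visual granularity such distributions are usually drawn at; Gaussian KDE
with Silverman bandwidth as an alternative) on a grid spanning the data by
±3 bin widths. Peaks are local maxima with prominence ≥ 5% of the maximum
density. With two peaks, the state boundary is the density minimum between
them; frames below it (smaller distance) are compact, ties count as
extended. With one peak the ensemble is reported as entirely extended
(fraction compact 0) unless the caller supplies a reference boundary from
another system — the simplest defensible reading of a unimodal,
crystal-like ensemble, and the choice is recorded in output metadata. More
than two peaks raises, prompting a bandwidth adjustment rather than a
silent multi-state split.

Population free-energy differences are ΔA(compact→extended) =
−kT ln(f_ext/f_comp), ±∞ when a state is unpopulated.

## Synthetic two-state generator

The generator emulates the statistical structure of the real ensembles at
Cα resolution: domain 1 is a compact lattice-ball cluster (3.8 Å spacing),
the linker an interpolated strand, domain 2 an antiparallel bundle of ideal
α-helices (rise 1.5 Å/residue, 100°/residue, radius 2.3 Å). Two basin
reference structures differ by a rigid translation of domain 2 along the
centroid–centroid axis — defaults 43.8 Å (extended) and 34.0 Å (compact),
the two-basin geometry of the wild-type ensemble. Proxy side-chain atoms
(two O at ±1.2 Å about a point 2.5 Å off the Cα for acids; one N 3.5 Å off
the Cα for bases) make salt-bridge COM distances analytic.

Frames follow a two-state Markov chain — defaults p(ext→comp) = 0.003 and
p(comp→ext) = 0.007 per 50 ps frame over 14 400 frames, whose stationary
compact fraction 0.003/0.010 = 30% reproduces the wild-type compact
population — with iid isotropic Gaussian noise per atom per frame
(σ = 1.5 Å; linker atoms ×3, emulating the elevated linker fluctuations of
the real protein). These simplifications are deliberate: the stationary
fraction, per-basin means, RMSF ratios and misclassification rates are all
analytic, so every downstream estimator has an exact recovery target.

What the generator does *not* emulate: temporal correlation of the noise
within a basin, anharmonic intra-domain motion, gradual (non-instantaneous)
basin transitions, solvent and side-chain degrees of freedom. Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not fidelity to explicit-solvent MD.

## Numerical choices and edge cases

* PDB parsing keeps the first model only, resolves altlocs by highest
  occupancy then first listed, and treats trajectory time metadata as
  config-owned (DCD header time fields are unreliable across writers).
  PDB text stores 3 decimals, so PDB round-trips are exact to 5×10⁻⁴ Å;
  DCD round-trips to about 10⁻⁴ Å (float32).
* Superposition requires ≥3 non-collinear selection atoms (second singular
  value > 1e-8 of the first); degenerate frames raise with the frame index.
* A helix axis with nearly equal first and second principal variances
  (within 5%) triggers a warning: its direction is ill-defined.
* Zero-variance residues in correlation matrices are flagged and NaN-ed
  rather than propagating division noise.
* All randomness flows through a single `numpy` Generator seeded from the
  spec/CLI seed; identical (config, seed) reproduce outputs bit-identically.

## Problem sizes

Unit and property tests run the generator at reduced size (24+6+24 residues,
a few hundred frames), where every assertion's sampling error is still
analytic. The end-to-end occupancy-recovery checks and the acceptance
script use the full 130-residue, 14 400-frame configuration; the tolerance
on recovered occupancies is three autocorrelation-adjusted standard errors,
var = π(1−π)/T · (1+ρ)/(1−ρ) with ρ = 1 − p_ec − p_ce.

## Known limitations

* The two-state classifier assumes at most two basins of the descriptor; it
  refuses (rather than guesses) on multimodal distributions.
* Unimodal ensembles are labelled extended by convention; a compact-only
  ensemble would need an explicit reference boundary.
* Coordination-shell averages depend on the cutoff; cross-system
  comparisons are only meaningful at a shared, reported cutoff.
* The analysis is single-chain; multi-chain structures require an explicit
  chain choice in the config.
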