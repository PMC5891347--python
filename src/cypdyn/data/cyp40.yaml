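# Analysis configuration for two-domain Cyp40-like proteins.
# Residue ranges are 1-based and inclusive on both ends.
chain: A

domains:
  cyclophilin: [1, 183]
  linker: [184, 213]
  tpr: [216, 362]

# TPR helices P-V
helices:
  P: [216, 235]
  Q: [239, 259]
  R: [262, 285]
  S: [289, 300]
  T: [307, 319]
  U: [323, 336]
  V: [341, 362]

# (acidic resid, basic resid) pairs: linker aspartates vs helix-Q lysines
salt_bridges:
  - [200, 245]
  - [200, 248]
  - [204, 248]

pca_residue_range: [2, 365]
combined_pca: true

temperature: 310.0          # K
frame_interval_ps: 50.0     # recording interval
production_length_ns: 720.0 # per run
n_runs: 8

distance_bin_width: 0.5     # Å, histogram bin for distance distributions
angle_bin_width: 2.0        # degrees, histogram bin for angle distributions
shell_cutoff: 10.0          # Å, coordination-shell neighbour cutoff
anticorr_threshold: 0.1     # |c| above which a pair counts as anticorrelated
correlation_margin: 0.05    # significance margin for correlation changes
decrease_window: [-10.0, -4.0]  # Å, distance-change classification
increase_window: [4.0, 10.0]
min_prominence: 0.05        # peak prominence, fraction of max density
salt_bridge_formed_max: 4.5 # Å, COM distance counted as a formed bridge
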