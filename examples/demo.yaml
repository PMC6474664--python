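# Scaled-down demonstration run: six simulated treatments, full analysis.
# Usage: angiocompendium run --config examples/demo.yaml
output_dir: scratch/demo
seed: 1
simulation:
  n_genes: 2000
  n_replicates: 12
  treatments: [PNF-1, SC-3-141, SC-3-143, SC-3-263, VEGF, endostatin]
  pathway_sizes:
    Ang1: [8, 16]
    bFGF: [8, 16]
    CCL2: [8, 16]
    NR3C1: [8, 16]
    PDGF: [8, 16]
    PGF: [8, 16]
    TGF-beta: [8, 16]
    TNF-alpha: [8, 16]
    VEGF: [8, 16]
  de_background_rate: 0.05
  noise_sd: 0.25
thresholds:
  de_p: 0.003
  z: 2.0
  p_max: 0.01
  size_cap: 35
  n_networks: 3
plsr_holdout: PNF-1
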