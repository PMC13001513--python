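# Demonstration run: simulate a reciprocal selection-shift experiment and
# execute every analysis stage.  `evoltraj run --config examples/pipeline_demo.yaml`
# completes on one CPU in a few minutes; scale sim.n_loci up for larger studies.
out_dir: evoltraj_demo_run
seed: 1
stages: [simulate, filter, pca, bb_scan, het, hidden, converge, loo]
sim:
  n_loci: 1000
  n_selected: 150
  n_balanced: 150
min_cov: 20
min_maf: 0.02
alpha: 0.05
hidden_alpha: 0.005
pseudocount: 1
n_pcs: 10
pc_alpha: 0.005
fdr: 0.05
min_dp: 0.02
n_perm: 10000
deep_min_cov: 100
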