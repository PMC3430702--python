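# Demo pipeline on a small simulated cohort: two tumor archetypes, two
# samples each, run through segmentation, copy-number estimation, calling,
# frequency/recurrence mapping, cross-species projection and clustering.
seed: 7
simulate:
  n_chromosomes: 5
  chrom_length: 30000000
  probes_per_chromosome: 100
  probe_length: 60
  noise_sd: 0.15
  genes_per_chromosome: 2
  target_positions_per_chromosome: 120
  archetypes:
    archA:
      purity: 0.9
      target_ploidy: 2
      aberrations: {n_gains: 2, n_losses: 2, n_hd: 1, n_amplicons: 1,
                    gain_length: [15, 40], loss_length: [15, 40],
                    hd_length: [5, 10], amplicon_length: [6, 15]}
    archB:
      purity: 0.8
      target_ploidy: 2
      aberrations: {n_gains: 1, n_losses: 3, n_hd: 1, n_amplicons: 0,
                    gain_length: [15, 40], loss_length: [15, 40],
                    hd_length: [5, 10], amplicon_length: [6, 15]}
  samples:
    - {id: A1, archetype: archA}
    - {id: A2, archetype: archA}
    - {id: B1, archetype: archB}
    - {id: B2, archetype: archB}
segmentation: {alpha: 0.0001, n_permutations: 10000, min_width: 2}
estimation: {c_max: 12}
calling: {gain_loss_threshold: 0.377, amplification_threshold: 0.811}
genes: {min_samples: 1}
recurrent:
  classes: [amplification, gain, loss, homozygous_deletion]
similarity: {min_overlap: 10}
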