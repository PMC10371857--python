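# Small synthetic world for a quick end-to-end pipeline run.
# Four pooled populations, a 4-Mb genome at pool-seq SNP density, and one
# planted 25-kb sweep in the focal population on chr1.
seed: 1

simulate:
  pop_names: [focal, east, west, south]
  focal: focal
  genome:
    chr1: 2000000
    chr2: 2000000
  n_snps: 20000          # ~5 SNPs / kb
  baseline_f: 0.05
  sweeps:
    - {chrom: chr1, start: 600000, end: 625000, sweep_f: 0.6}
  pool_diploids: 8
  depth_mean: 20
  depth_shape: 5
  n_genes: 60
  gene_len: 2000

scan:
  window: 5000
  step: 4000
  min_cov: 4
  max_cov: 40            # twice the mean pool depth
  min_sites: 5
  min_minor_count: 2
  top_fraction: 0.01     # ~1000 windows in this small genome; 0.1% would be a single window
  min_support: 2
  flank_bp: 50000

variants:
  daf_floor: 0.5
  alpha: 0.05
  # effects: path/to/effects.tsv   # omit to synthesise PROVEAN/SIFT-like scores
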