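# Compact synthetic study for quick end-to-end runs: every stage has
# planted truth, expression carries Poisson noise.
genome:
  n_chrom: 2
  chrom_len: 600000
  n_genes: 30
  gene_length: 800
rare:
  n_sites: 20
  proximal_distances: [2000, -4000, 6000, -8000]
  distal_abs_mean: 13000.0
  distal_abs_sd: 2000.0
  distal_abs_min: 10500.0
  distal_abs_max: 15000.0
cds:
  n: 60
  n_high: 10
  codons_per_cds: 150
phylostrat:
  n_proteins: 500
  n_short: 3
expression:
  n_genes: 120
  noise: true
  sets:
    myosin_heavy_like: {size: 7, multiplier: 8.8}
    myosin_light_like: {size: 21, multiplier: 17.0}
families:
  n_families: 150
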