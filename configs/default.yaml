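# The default synthetic study conditions (mirrors
# medusa_kit.synthio.default_config): a 30-Mb genome with 500 planted
# response elements averaging ~13-14 kb from the nearest TSS and four
# Hox-like genes with elements inside +-10 kb; a 10,000-gene cohort that
# is 80/3/17% ancient/middle/young; 100 strongly GC3-biased CDS among
# 600; bell-vs-tentacle expression with 8.8x and 17x biased myosin-like
# sets under Poisson noise; three two-species class-like groups for the
# family Venn; and a 20-accession target domain census.
genome:
  n_chrom: 6
  chrom_len: 5000000
  n_genes: 540
  gene_length: 1000
rare:
  n_sites: 500
  proximal_distances: [2000, -4000, 6000, -8000]
  distal_abs_mean: 13000.0
  distal_abs_sd: 3000.0
  distal_abs_min: 10500.0
  distal_abs_max: 24000.0
  class_weights: {DR5: 0.6, DR1: 0.2, DR2: 0.2}
cds:
  n: 600
  n_high: 100
  high_range: [0.85, 0.95]
  background_range: [0.2, 0.7]
  codons_per_cds: 300
phylostrat:
  n_proteins: 10000
  era_probs: {ancient: 0.80, middle: 0.03, young: 0.17}
  n_short: 10
  fn_rate: 0.0
  spurious_rate: 0.0
expression:
  n_genes: 500
  total_fragments: 5000000
  noise: true
  sets:
    myosin_heavy_like: {size: 7, multiplier: 8.8}
    myosin_light_like: {size: 21, multiplier: 17.0}
families:
  groups:
    Scyphozoa: [Nemopilema_synthetica, Aurelia_synthetica]
    Hydrozoa: [Hydra_synthetica, Clytia_synthetica]
    Anthozoa: [Acropora_synthetica, Nematostella_synthetica]
  n_families: 2000
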