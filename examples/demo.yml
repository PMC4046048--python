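# Demo pipeline: synthetic population with a planted causative variant.
# Run:  concordqtl run --config examples/demo.yml --outdir demo_out
seed: 1
outdir: demo_out

simulate:
  n_animals: 300
  n_sequenced: 100       # keeps >= 60 statused sequenced animals even when
                         # a middle cluster is set to unknown
  n_seq_variants: 1000
  marker_spacing: 10
  qtl_variant_index: 495
  genotype_error_rate: 0.02

deregression:
  h2: 0.3

bayesc:                  # desk-scale chain; full-scale: 180000 / 20000 / 50
  n_iter: 6000
  burn_in: 1000
  thin: 5

regions:
  L: 40
  K: 20

status:
  interval: 10

concordance:
  gq_min: 20
  fraction_min: 0.90
  min_het: 5
  min_hom: 5
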