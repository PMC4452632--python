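# Synthetic study preset loosely modelled on patient 1 of the source study:
# normal-liver activity concentration 620 Bq/mg at administration, tumour
# enrichment 3.2.  Tissue block scaled down to bench size (16 g) so a full
# study runs in seconds.
seed: 1
liver:
  target_mass_mg: 16000
  lobules_per_layer: 1000
  tumour_fraction: 0.2
deposition:
  mode: structured
  normal_concentration_bq_per_mg: 620
  tnc_target: 3.2
  element_cv: 2.0
  element_size_mm: 1.6
sampling:
  compartment: normal
  plan:
    - {diameter_mm: 8.0, count: 30, thickness_mm: 1.8}
    - {diameter_mm: 6.0, count: 28, thickness_mm: 1.2}
    - {diameter_mm: 3.0, count: 29, thickness_mm: 1.0}
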