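# Curated brain cell-type marker probesets (Affymetrix U133) used to build
# reference expression signals for Huntington's disease motor cortex (BA4).
neuron:
  221805_at: NEFL
  221801_x_at: NEFL
  221916_at: NEFL
  201313_at: ENO2
  210040_at: SLC12A5
  205737_at: KCNQ2
  210432_s_at: SCN3A
astrocyte:
  203540_at: GFAP
  210068_s_at: AQP4
  210906_x_at: AQP4
  201667_at: GJA1
oligodendrocyte:
  211836_s_at: MOG
  214650_x_at: MOG
  216617_s_at: MAG
  207659_s_at: MOBP
  207323_s_at: MBP
  209072_at: MBP
microglia:
  204192_at: CD37
  215051_x_at: AIF1
  209901_x_at: AIF1
  213095_x_at: AIF1
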