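{
  "name": "ten_gs_synthetic",
  "rank_scope": "all_panel_genes",
  "rank_direction": "ascending",
  "note": "Synthetic placeholder coefficients for the 10-gene rank-linear radiosensitivity surrogate score. The published coefficients are not bundled; supply your own signature CSV for real analyses."
}
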