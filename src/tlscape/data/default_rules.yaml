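# Built-in phenotype rules: marker conjunctions -> population name.
# priority: lower number wins when assigning the single primary_label.
- {name: Tumor, require_pos: [PanCK], priority: 0}
- {name: TCF1_PD1_CD8T, require_pos: [CD8, PD1, TCF1], priority: 7}
- {name: TIM3_PD1_CD8T, require_pos: [CD8, PD1, TIM-3], priority: 8}
- {name: PD1_CD8T, require_pos: [CD8, PD1], priority: 9}
- {name: CD8T, require_pos: [CD8], priority: 10}
- {name: GZMB_CD8T, require_pos: [CD8, GZMB], priority: 11}
- {name: TFH, require_pos: [CD4, CXCR5, PD1], require_neg: [FoxP3], priority: 18}
- {name: Treg, require_pos: [CD4, FoxP3], priority: 19}
- {name: CD4T, require_pos: [CD4], priority: 20}
- {name: Bcell, require_pos: [CD20], priority: 30}
- {name: DC, require_pos: [DC-LAMP], priority: 40}
- {name: M2TAM, require_pos: [CD68, CD163], priority: 50}
- {name: TAM, require_pos: [CD68], priority: 51}
- {name: FDC21_23, require_pos: [CD21, CD23], priority: 60}
- {name: FDC21, require_pos: [CD21], priority: 61}
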