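# Cross-species blood markers of antipsychotic-induced weight-gain proneness:
# genes elevated in weight-gain-prone individuals in both the mouse and the
# human studies, with the published prone/resistant fold changes.
gene	fc_mouse	fc_human
Ifit1	1.32	1.72
Ifitm3	1.25	1.28
Rhd	1.94	1.45
Rsad2	1.54	2.56
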