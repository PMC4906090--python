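# Synthetic toy phantom S-value table for testing; units mGy per MBq*h.
# Rows: target regions; columns: source regions.
target,kidneys,liver,heart,bladder_contents,bone,red_marrow,total_body
kidneys,0.27,0.0008,0.0002,0.0001,0.0003,0.0003,0.001929
liver,0.0008,0.044,0.0006,0.0001,0.0002,0.0002,0.001903
heart,0.0002,0.0006,0.26,5e-05,0.0003,0.0004,0.001954
bladder_wall,0.0001,0.0001,5e-05,0.04,0.0001,0.0001,0.0007716
osteogenic_cells,0.0003,0.0002,0.0003,0.0001,0.02,0.004,0.003723
red_marrow,0.0003,0.0002,0.0004,0.0001,0.01,0.076,0.003393
total_body,0.00115,0.00115,0.00115,0.001,0.00115,0.00115,0.00115
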