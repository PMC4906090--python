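# Synthetic toy phantom organ masses (kg).
region,mass_kg
kidneys,0.31
liver,1.91
heart,0.33
bladder_contents,0.2
bone,10.5
red_marrow,1.12
total_body,73.7
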