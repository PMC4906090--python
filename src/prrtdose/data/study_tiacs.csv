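# Measured time-integrated activity coefficients (hours) per organ for the
# five subjects of the Lu-177-OPS201 pig biodistribution study.
# kidneys = sum of both kidneys; bone derived from spine (19% of skeleton mass).
organ,pig1,pig2,pig3,pig4,pig5
whole_body,81.73,72.23,60.95,75.09,80.08
remainder,44.63,53.95,41.46,47.32,45.17
liver,4.98,3.48,2.66,4.51,5.57
kidney_right,4.76,3.29,4.69,7.82,2.94
kidney_left,4.57,4.18,4.11,7.59,3.14
kidneys,9.34,7.47,8.80,15.40,6.07
heart,0.53,3.89,0.41,0.79,0.65
bladder_contents,0.90,0.43,0.02,5.27,0.51
spine,4.03,0.57,1.42,0.29,4.16
bone,21.22,3.00,7.47,1.55,21.91
red_marrow,0.12,0.01,0.13,0.22,0.18
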