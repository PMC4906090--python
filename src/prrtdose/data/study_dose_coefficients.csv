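# Absorbed dose coefficients (mGy/MBq) per target organ for the five
# subjects of the Lu-177-OPS201 pig study (adult male phantom, MIRD schema).
target,pig1,pig2,pig3,pig4,pig5
adrenals,6.82E-02,7.69E-02,6.12E-02,7.39E-02,6.69E-02
brain,5.80E-02,6.74E-02,5.24E-02,5.90E-02,5.88E-02
breasts,5.59E-02,6.74E-02,5.14E-02,5.87E-02,5.66E-02
gallbladder_wall,6.61E-02,7.55E-02,5.91E-02,7.08E-02,6.61E-02
lli_wall,6.06E-02,7.10E-02,5.49E-02,6.55E-02,6.10E-02
small_intestine,6.20E-02,7.25E-02,5.65E-02,6.65E-02,6.21E-02
stomach_wall,6.13E-02,7.23E-02,5.61E-02,6.55E-02,6.13E-02
uli_wall,6.19E-02,7.24E-02,5.64E-02,6.62E-02,6.20E-02
heart_wall,1.10E-01,4.44E-01,9.35E-02,1.38E-01,1.23E-01
kidneys,2.71E+00,2.17E+00,2.55E+00,4.46E+00,1.76E+00
liver,2.37E-01,1.68E-01,1.27E-01,2.17E-01,2.64E-01
lungs,5.94E-02,7.10E-02,5.39E-02,6.19E-02,6.01E-02
muscle,5.89E-02,6.92E-02,5.36E-02,6.20E-02,5.93E-02
ovaries,6.10E-02,7.16E-02,5.54E-02,6.60E-02,6.14E-02
pancreas,6.57E-02,7.60E-02,5.95E-02,7.09E-02,6.51E-02
red_marrow,2.17E-01,7.72E-02,1.05E-01,7.00E-02,2.25E-01
osteogenic_cells,1.34E+00,3.75E-01,5.73E-01,2.76E-01,1.38E+00
skin,5.58E-02,6.62E-02,5.11E-02,5.85E-02,5.64E-02
spleen,6.48E-02,7.48E-02,5.95E-02,7.13E-02,6.34E-02
testes,5.73E-02,6.81E-02,5.24E-02,6.16E-02,5.79E-02
thymus,5.84E-02,7.21E-02,5.35E-02,6.12E-02,5.92E-02
thyroid,5.85E-02,6.91E-02,5.34E-02,6.04E-02,5.92E-02
urinary_bladder_wall,2.44E-01,1.58E-01,5.78E-02,1.15E+00,1.64E-01
uterus,6.13E-02,7.19E-02,5.53E-02,6.96E-02,6.14E-02
total_body,1.02E-01,8.76E-02,7.64E-02,8.87E-02,9.98E-02
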