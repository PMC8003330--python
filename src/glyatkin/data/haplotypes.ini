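# Two-substrate Hill parameters for the three kinetically characterised
# GLYAT haplotypes.  Units: vf umol/min/mg, kcat 1/s, s05_gly mM,
# s05_benz uM, Hill coefficients dimensionless, molar_mass g/mol.
[156Asn>Ser]
vf = 0.85
kcat = 0.48
s05_gly = 23.0
h_gly = 1.6
s05_benz = 97.0
h_benz = 2.1
molar_mass = 33900.0

[17Ser>Thr,156Asn>Ser]
vf = 0.62
kcat = 0.35
s05_gly = 29.0
h_gly = 1.3
s05_benz = 118.0
h_benz = 1.5
molar_mass = 33900.0

[156Asn>Ser,199Arg>Cys]
vf = 0.083
kcat = 0.047
s05_gly = 30.0
h_gly = 1.4
s05_benz = 61.0
h_benz = 3.5
molar_mass = 33900.0
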