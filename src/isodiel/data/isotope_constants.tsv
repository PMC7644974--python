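# Physical constants used for exact-mass arithmetic (all masses in Da).
# monoisotopic: mass of the most abundant (lightest) stable isotope.
# Heavy-isotope mass differences drive the label-induced m/z shifts:
#   delta_13C = m(13C) - m(12C), delta_15N = m(15N) - m(14N).
# Values from the 2021 AME / CODATA compilations, rounded to 7 decimals.
key	value	unit
monoisotopic_C	12.0	Da
monoisotopic_H	1.0078250	Da
monoisotopic_N	14.0030740	Da
monoisotopic_O	15.9949146	Da
monoisotopic_P	30.9737616	Da
monoisotopic_S	31.9720710	Da
delta_13C	1.0033548	Da
delta_15N	0.9970349	Da
electron_mass	0.0005486	Da
natural_13C_abundance	0.0107	fraction
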