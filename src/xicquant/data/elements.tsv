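# Monoisotopic masses (Da) and natural isotopic abundances, frozen so that
# theoretical envelopes are bit-reproducible across versions.
# neutron_offset is the nominal-mass shift relative to the lightest isotope.
element	neutron_offset	mass	abundance
C	0	12.0	0.9893
C	1	13.0033548350	0.0107
H	0	1.0078250319	0.999885
H	1	2.0141017779	0.000115
N	0	14.0030740044	0.99636
N	1	15.0001088989	0.00364
O	0	15.9949146196	0.99757
O	1	16.9991317565	0.00038
O	2	17.9991596129	0.00205
S	0	31.9720711744	0.9499
S	1	32.9714589098	0.0075
S	2	33.9678670040	0.0425
S	4	35.9670807100	0.0001
P	0	30.9737619984	1.0
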