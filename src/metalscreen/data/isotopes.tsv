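# Stable-isotope masses (Da) and fractional abundances, IUPAC/CIAAW 2021
# representative values. Columns: element<TAB>mass<TAB>abundance.
# Abundances per element sum to 1 within 1e-4; masses ascending per element.
H	1.00782503207	0.999885
H	2.01410177812	0.000115
C	12.0000000	0.9893
C	13.00335483507	0.0107
N	14.00307400443	0.99636
N	15.00010889888	0.00364
O	15.99491461957	0.99757
O	16.99913175650	0.00038
O	17.99915961286	0.00205
F	18.99840316273	1.0
Na	22.98976928	1.0
P	30.97376199842	1.0
S	31.9720711744	0.9499
S	32.9714589098	0.0075
S	33.967867004	0.0425
S	35.96708071	0.0001
Cl	34.968852682	0.7576
Cl	36.965902602	0.2424
K	38.9637064864	0.932581
K	39.963998166	0.000117
K	40.9618252579	0.067302
Mn	54.93804391	1.0
Cu	62.92959772	0.6915
Cu	64.92778970	0.3085
Br	78.9183376	0.5069
Br	80.9162897	0.4931
Ru	95.90759025	0.0554
Ru	97.9052868	0.0187
Ru	98.9059341	0.1276
Ru	99.9042143	0.1260
Ru	100.9055769	0.1706
Ru	101.9043441	0.3155
Ru	103.9054275	0.1862
Ag	106.9050916	0.51839
Ag	108.9047553	0.48161
I	126.9044719	1.0
Re	184.9529545	0.374
Re	186.9557501	0.626
Ir	190.9605893	0.373
Ir	192.9629216	0.627
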