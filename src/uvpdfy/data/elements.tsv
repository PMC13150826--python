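# uvpdfy element isotope table, v1 (CODATA/IUPAC 2021 monoisotopic masses and natural abundances)
# columns: symbol	isotope_mass_da	abundance
H	1.0078250319	0.999885
H	2.0141017779	0.000115
C	12.0000000000	0.9893
C	13.0033548378	0.0107
N	14.0030740052	0.99636
N	15.0001088984	0.00364
O	15.9949146221	0.99757
O	16.9991315000	0.00038
O	17.9991604000	0.00205
S	31.9720706900	0.9499
S	32.9714585000	0.0075
S	33.9678668300	0.0425
S	35.9670808800	0.0001
Zn	63.9291422000	0.4917
Zn	65.9260334000	0.2773
Zn	66.9271273000	0.0404
Zn	67.9248442000	0.1845
Zn	69.9253193000	0.0061
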