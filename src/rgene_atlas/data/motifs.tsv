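motif_id	nbs_label	consensus	bold_core
1	RNBS-D	TCLLYLSAFPEDYEIERERLVRRWIAEGF	CLLYLSAFPED
2	P-loop	VRKLNVVSIVGFGGLGKTTLAKQVYDKIR	GGLGKTTLA
3	GLPL	CPDMFKEVSNEILKKCGGLPLAIISISSL	ILKKCGGLPLAI
4	other	ALYLSYDELPHHLKQCFLYCALYTEDSII	ALYLSYDELPHHLK
5	other	EETAEEYYYELIHRNLLQPDG
6	MHDV	ACRVHDMVLDLICSLSSEENF	RVHDMVLDLICSLSSEE
7	Kinase-2	FLKDKRYLIVIDDIWSTSAWR	KRYLIVIDDIW
8	CC-assoc	NDTVRTWVKQVRDLANDVEDCLLDFVLYS
9	P-loop	VLSIVGFGGLGKTTLAKAVYR	GFGGLGKTTLAK
10	RNBS-B	IKCAFPDNEKGSRIIITTRNEDVANICCC	RIIITTR
11	other	NLRYIGLRRTNVKSLPDSIENLSNLQTLD
12	other	VSAADGALGPLLGKLATLLAEEYSRLKGVRGEIRSLKSELTSMHGALKKY
13	other	IQTIPDCIANLIHLRLLNLDGTEISCLPESIGSLINLQILN
14	RNBS-A	GSFNIQAWVCVSQDYNEVSLLKEVLRNIG	EVSLLKEVLR
15	GLPL	SAHPNLEIIGMEIVKKLKGLPLAAKAIGSLL	GLPLA
16	other	PPLWQLPNLKYLRIEGAAAVTKIGPEFVG
17	other	QLRPPGNLENLWIHGFFGRRYPTWFGTTF
18	Kinase-2	QGETIGELQRKLAETIEGKSFFLVLDDVW	FFLVLDDVW
19	RNBS-C	IYRMKPLSDDYSRRLFYKRIF	PLSDDY
20	RNBS-B	LRTPLHATTAGVILVTTRDDQIAMRIGVEDIHRVDLMSVEVGWELLWKSM	LVTTR
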