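family	fold_type	label
SBF_1	BART	8H-2BH-Nin
SBF_2	BART	7H-2BH-Nin
SBFlike	BART	8H-2BH-Nin
KdgT	BART	8H-2BH-Nin
Mem_trans	BART	8H-2BH-Nout
Sbt_1	BART	8H-2BH-Nout
Na_H_antiport_1	CPA-broken	10H-2BH-Nin
NA_H_Exchanger_1	CPA-broken	11H-2BH-Nout
NA_H_Exchanger_2	CPA-broken	12H-2BH-Nin
Asp_Al_Ex	CPA-reentrant	10H-2RH-Nout
Glt_symporter	CPA-reentrant	10H-2RH-Nout
DUF819	CPA-reentrant	10H-2RH-Nout
AbrB	CPA-reentrant	10H-2RH-Nin
2HCT	CPA-reentrant	11H-2RH-Nin
OAD_beta	CPA-reentrant	10H-2RH-Nout
PSE_1	RHR	9H-2RH-Nin
PSE_2	RHR	11H-2RH-Nin
LysAB	RHR	8H-2RH-Nout
LysA	RHR	3H-Nout
LysB	RHR	5H-2RH-Nin
LrgAB	RHR	11H-2RH-Nin
LrgB	RHR	6H-2RH-Nout
LrgA	RHR	4H-Nin
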