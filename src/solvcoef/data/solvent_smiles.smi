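# Curated SMILES for the structural solvents of the measured coefficient table
# (artifact-supplied curation by name; mixtures and peanut oil have no single
# structure and are omitted).  Format: SMILES<TAB>name
CC(=O)OC	methyl acetate
CCOC(C)=O	ethyl acetate
CCCCOC(C)=O	butyl acetate
CCCCCCCCCCCCCC(=O)OC(C)C	isopropyl myristate
CNC(C)=O	N-methylacetamide
CCNC(C)=O	N-ethylacetamide
CN(C)C(C)=O	dimethylacetamide
CCN(CC)C(C)=O	N,N-diethylacetamide
NC=O	formamide
CNC=O	N-methylformamide
CCNC=O	N-ethylformamide
CN(C)C=O	DMF
CCCCN(CCCC)C=O	dibutylformamide
CO	methanol
CCO	ethanol
O	water
CCCO	1-propanol
CC(C)O	2-propanol
CC(C)CO	2-methyl-1-propanol
CC(C)(C)O	2-methyl-2-propanol
CCCCO	1-butanol
CCC(C)O	2-butanol
CC(C)CCO	3-methyl-1-butanol
CCCCCO	1-pentanol
CCCC(C)O	2-pentanol
CCCCCCO	1-hexanol
CCCCCCCO	1-heptanol
CCCCCCCCO	1-octanol
CCCCCCCCCCO	1-decanol
CCCCCCCCCCCCCCCCCCO	octadecanol
CCCCC	pentane
CCCCCC	hexane
CCCCCCC	heptane
CCCCCCCC	octane
CCCCCCCCC	nonane
CCCCCCCCCC	decane
CCCCCCCCCCC	undecane
CCCCCCCCCCCC	dodecane
CCCCCCCCCCCCCCCC	hexadecane
CC(C)CC(C)(C)C	2,2,4-trimethylpentane
C=CCCCCCCC=C	1,9-decadiene
CCCCCCCCCCCCCCC=C	1-hexadecene
ClCCCl	1,2-dichloroethane
CCCCCl	1-chlorobutane
ClCCl	dichloromethane
ClC(Cl)Cl	chloroform
ClC(Cl)(Cl)Cl	carbon tetrachloride
OCC(F)(F)F	trifluoroethanol
CCOCC	diethyl ether
CCCCOCCCC	dibutyl ether
COC(C)(C)C	methyl tert-butyl ether
c1ccccc1	benzene
Fc1ccccc1	fluorobenzene
Clc1ccccc1	chlorobenzene
Brc1ccccc1	bromobenzene
Ic1ccccc1	iodobenzene
Cc1ccccc1	toluene
CCc1ccccc1	ethylbenzene
Cc1cccc(C)c1	m-xylene
Cc1ccccc1C	o-xylene
Cc1ccc(C)cc1	p-xylene
O=[N+]([O-])c1ccccc1	nitrobenzene
C1CCCCC1	cyclohexane
C[N+](=O)[O-]	nitromethane
CC1CCCCC1	methylcyclohexane
C1CCOC1	THF
C1COCCO1	1,4-dioxane
CC1COC(=O)O1	propylene carbonate
O=C1CCCCC1	cyclohexanone
CN1CCCC1=O	N-methylpyrrolidinone
CN1CCCCC1=O	N-methyl-2-piperidone
O=CN1CCOCC1	N-formylmorpholine
N#Cc1ccccc1	benzonitrile
CC#N	acetonitrile
OCCO	ethylene glycol
CC(C)=O	acetone
CCC(C)=O	butanone
CS(C)=O	DMSO
S=C=S	carbon disulfide
O=S1(=O)CCCC1	sulfolane
CCCCOP(=O)(OCCCC)OCCCC	tributyl phosphate
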