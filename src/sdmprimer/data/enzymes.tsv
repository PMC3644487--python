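# Default restriction-enzyme catalog: a REBASE-derived subset of common,
# commercially available Type II endonucleases (recognition sequences only;
# cut positions are irrelevant to silent-site screening).
# Format: NAME<tab>SITE  (IUPAC ambiguity codes allowed)
AatII	GACGTC
AflII	CTTAAG
AgeI	ACCGGT
AluI	AGCT
ApaI	GGGCCC
AscI	GGCGCGCC
AseI	ATTAAT
AvaI	CYCGRG
AvrII	CCTAGG
BamHI	GGATCC
BclI	TGATCA
BglII	AGATCT
BsaI	GGTCTC
BsrGI	TGTACA
BstBI	TTCGAA
ClaI	ATCGAT
DdeI	CTNAG
DraI	TTTAAA
EcoRI	GAATTC
EcoRV	GATATC
FseI	GGCCGGCC
HaeIII	GGCC
HincII	GTYRAC
HindIII	AAGCTT
HinfI	GANTC
HpaI	GTTAAC
KpnI	GGTACC
MboI	GATC
MluI	ACGCGT
MseI	TTAA
NcoI	CCATGG
NdeI	CATATG
NheI	GCTAGC
NotI	GCGGCCGC
NsiI	ATGCAT
PacI	TTAATTAA
PmeI	GTTTAAAC
PstI	CTGCAG
PvuI	CGATCG
PvuII	CAGCTG
RsaI	GTAC
SacI	GAGCTC
SalI	GTCGAC
SbfI	CCTGCAGG
ScaI	AGTACT
SmaI	CCCGGG
SnaBI	TACGTA
SpeI	ACTAGT
SspI	AATATT
StuI	AGGCCT
TaqI	TCGA
XbaI	TCTAGA
XhoI	CTCGAG
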