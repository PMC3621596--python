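# Single-nucleotide variations identified in the evolved butanol-tolerant strains
# IMS0344 and IMS0351 by whole-genome resequencing against the parental genome.
# Coding rows give the reported ORF-internal nucleotide change and amino-acid change;
# upstream rows give the reported distance 5' of the start codon.
# The upstream row of allele stt4-2 names the gene "SST4" (sic) — preserved verbatim.
strain	allele	gene	location	nt_change	nt_ref	nt_alt	cds_pos	upstream_distance	aa_change	aa_ref	aa_codon	aa_alt
IMS0344	rpn4-1	RPN4	coding	G1518C	G	C	1518	.	K506N	K	506	N
IMS0344	rtg1-1	RTG1	coding	A235G	A	G	235	.	K79E	K	79	E
IMS0344	ssk2-1	SSK2	coding	C3974A	C	A	3974	.	P1325Q	P	1325	Q
IMS0344	ubr1-1	UBR1	coding	A3194G	A	G	3194	.	E1065G	E	1065	G
IMS0351	rpn4-2	RPN4	coding	C1546T	C	T	1546	.	Q516*	Q	516	*
IMS0351	rtg1-2	RTG1	coding	C256A	C	A	256	.	L86I	L	86	I
IMS0351	nma111-2	NMA111	coding	C545A	C	A	545	.	S182*	S	182	*
IMS0351	ubr1-2	UBR1	coding	C2129A	C	A	2129	.	S710*	S	710	*
IMS0351	sto1-2	STO1	coding	T2543G	T	G	2543	.	F736V	F	736	V
IMS0351	rpl10-2	RPL10	upstream	G>C 296 bp upstream	G	C	.	296	.	.	.	.
IMS0351	stt4-2	SST4	upstream	T>C 984 bp upstream	T	C	.	984	.	.	.	.
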