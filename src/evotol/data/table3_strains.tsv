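# Strains of the study: references, marker-deletion crossing partners, the two evolved
# lineages, and the diploids/haploid segregants of three backcross cycles per lineage.
# generation: evolved, F1/F2/F3 (selected haploid segregants), D0..D2 (intermediate diploids).
# alleles: evolved mutant alleles carried (haploids; semicolon-separated, "." = none).
# The IMS0351 genotype lists "sst4-2" (sic, cf. allele stt4-2 of the variant table).
strain	ploidy	mating_type	generation	alleles	description
BY4741	haploid	a	.	.	MATa his3d1 leu2d met15d ura3d
KO_collection	haploid	a	.	.	MATa his3d1 leu2d met15d ura3d ORFd::KanMX
CEN.PK113-7D	haploid	a	.	.	MATa prototrophic reference
CEN.PK113-1A	haploid	alpha	.	.	MATalpha prototrophic reference
IMK439	haploid	alpha	.	.	MATalpha ura3d::KanMX
IMK440	haploid	a	.	.	MATa ura3d::KanMX
IMS0344	haploid	a	evolved	rpn4-1;rtg1-1;ubr1-1;ssk2-1	evolved lineage 1 isolate
IMS0345	diploid	a/alpha	D0	rpn4-1;rtg1-1;ubr1-1;ssk2-1	IMS0344 x IMK439; heterozygous at all four loci and URA3
IMS0346	haploid	alpha	F1	rpn4-1;rtg1-1;ubr1-1;ssk2-1	tolerant F1 segregant, lineage 1
IMS0347	diploid	a/alpha	D1	rpn4-1;rtg1-1;ubr1-1;ssk2-1	IMS0346 x IMK440
IMS0348	haploid	alpha	F2	rpn4-1;rtg1-1;ubr1-1;ssk2-1	tolerant F2 segregant, lineage 1
IMS0349	diploid	a/alpha	D2	rpn4-1;rtg1-1;ubr1-1;ssk2-1	IMS0348 x IMK440
IMS0350	haploid	a	F3	rpn4-1;rtg1-1;ssk2-1	tolerant F3 segregant, lineage 1 (ubr1-1 lost)
IMS0351	haploid	a	evolved	rpn4-2;rtg1-2;ubr1-2;nma111-2;rpl10-2;sto1-2;sst4-2	evolved lineage 2 isolate
IMS0352	diploid	a/alpha	D0	rpn4-2;rtg1-2;ubr1-2;nma111-2;rpl10-2;sto1-2;sst4-2	IMS0351 x IMK439
IMS0353	haploid	a	F1	rpn4-2;rtg1-2;nma111-2;rpl10-2	tolerant F1 segregant, lineage 2
IMS0354	diploid	a/alpha	D1	rpn4-2;rtg1-2;nma111-2;rpl10-2	IMS0353 x crossing partner
IMS0355	haploid	a	F2	rpn4-2;rtg1-2;nma111-2;rpl10-2	tolerant F2 segregant, lineage 2
IMS0356	diploid	a/alpha	D2	rpn4-2;rtg1-2;nma111-2;rpl10-2	IMS0355 x crossing partner
IMS0357	haploid	a	F3	rpn4-2;rtg1-2;nma111-2	tolerant F3 segregant, lineage 2
IMI218	haploid	a	.	rpn4-1	reverse-engineered rpn4-1 in the reference background
IMI238	haploid	a	.	rtg1-1	reverse-engineered rtg1-1 in the reference background
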