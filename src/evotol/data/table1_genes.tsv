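# 35 genes whose deletion confers n-butanol sensitivity in both the BY4741 and CEN.PK113-7D backgrounds.
# category groups the two protein-degradation clusters used as planted enrichment truth:
#   UPS = ubiquitin-proteasome system, MVB = multivesicular-body / ESCRT pathway, other = everything else.
gene	category	function
PRE9	UPS	alpha-3 subunit of the 20S proteasome; the only nonessential proteasome subunit
UMP1	UPS	chaperone for 20S proteasome maturation
YLR224W	UPS	F-box subunit of SCF ubiquitin ligase complexes; recognizes misfolded proteins
UBP3	UPS	ubiquitin-specific protease; deubiquitination and maintenance of the free-ubiquitin pool
BRE5	UPS	cofactor of Ubp3 in deubiquitination
STP22	MVB	ESCRT-I component; sorts ubiquitinated membrane proteins into multivesicular bodies
SNF8	MVB	ESCRT-II component; MVB protein sorting
DID4	MVB	ESCRT-III component; MVB protein sorting
BRO1	MVB	deubiquitination in the MVB; maintenance of the free-ubiquitin pool
VPS34	other	phosphatidylinositol 3-kinase subunit; endosomal membrane trafficking and protein sorting
VPS15	other	regulatory subunit of the Vps34 kinase complex
PIH1	other	R2TP complex component; assembly of large protein complexes with Hsp90
SWI6	other	transcription cofactor required for the unfolded protein response
GET1	other	GET complex subunit; insertion of tail-anchored proteins into the ER
GET2	other	GET complex subunit; insertion of tail-anchored proteins into the ER
VMA7	other	subunit F of the V1 domain of the vacuolar H+-ATPase
VMA22	other	peripheral membrane protein required for vacuolar H+-ATPase function
SHE4	other	regulator of myosin function; endocytosis
GND1	other	6-phosphogluconate dehydrogenase; oxidative-stress adaptation
ANP1	other	alpha-1,6-mannosyltransferase complex subunit; osmotic sensitivity
GEP5	other	protein of unknown function; mitochondrial genome maintenance
THP2	other	THO complex subunit; transcription elongation and telomere maintenance
MFT1	other	THO complex subunit; transcription elongation and telomere maintenance
SLA1	other	cortical actin cytoskeleton assembly
SEC28	other	epsilon-COP coatomer subunit; retrograde Golgi-to-ER traffic
MSE1	other	mitochondrial glutamyl-tRNA synthetase
NKP2	other	nonessential kinetochore protein; Ctf19 complex
ALD6	other	cytosolic aldehyde dehydrogenase; acetaldehyde to acetate
SNT309	other	NineTeen Complex member; nuclear pre-mRNA splicing
REG1	other	regulatory subunit of Glc7; glucose repression
HTL1	other	RSC chromatin-remodeling complex component; telomere maintenance
POL32	other	third subunit of DNA polymerase delta; chromosomal replication
DHH1	other	cytoplasmic DExD/H-box helicase; mRNA decapping
VRP1	other	actin-associated protein; cytoskeletal organization and cytokinesis
HOM2	other	aspartate beta-semialdehyde dehydrogenase; methionine/threonine biosynthesis
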