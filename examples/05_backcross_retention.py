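"""Allele retention across three backcross cycles, lineage-1 layout.

The evolved haploid carries four mutant alleles; selection keeps the two
causal ones (the tolerance phenotype needs both) and the functional URA3
marker.  Each cycle halves the survival odds of an unselected, unlinked
allele, so after three cycles a neutral allele persists with probability
(1/2)^3 = 0.125 — the null against which a retained allele's relevance
should be judged.
"""

from evotol import BackcrossConfig, estimate_retention
from evotol.backcross import ims0344_scenario

loci, evolved, naive, phenotype = ims0344_scenario()
retention = estimate_retention(
    evolved, naive, loci, phenotype,
    BackcrossConfig(n_cycles=3), n_replicates=10_000, seed=17,
)
print(retention.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(
    "\ncausal alleles (rpn4-1, rtg1-1) are retained in every replicate; the "
    "neutral alleles sit near the (1/2)^3 = 0.125 null; the marker is kept "
    "by the uracil selection."
)
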