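"""Post-calling SNV filtering of a synthetic evolved-strain call set.

Builds a call table containing planted evolved-specific SNVs, variants
shared with the non-evolved parent, and noise calls that each violate one
filter rule, then runs the four-rule chain: drop ambiguous-base calls,
require Phred quality >= 20, require depth in [10, 400], and subtract
parental-shared variants.
"""

from evotol import run_filter_chain
from evotol.synthetic import SyntheticVariantSpec, generate_variants
from evotol.variants import calls_from_frame

spec = SyntheticVariantSpec(
    n_evolved_specific=4, n_parental_shared=6, n_noise_calls=9, seed=1
)
evolved, parental, truth = generate_variants(spec)
report = run_filter_chain(calls_from_frame(evolved), calls_from_frame(parental))

print(report.summary())
print("\nsurvivors:")
for c in report.survivors:
    print(f"  {c.chrom}:{c.pos} {c.ref}>{c.alt}  qual={c.qual:g} depth={c.depth}")
# The survivors are exactly the planted evolved-specific mutations — the
# calls a reverse-engineering effort would carry forward.
planted = truth[truth["label"] == "evolved_specific"]
assert len(report.survivors) == len(planted)
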