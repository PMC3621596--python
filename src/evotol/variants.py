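"""Post-calling SNV filter chain for evolved-strain resequencing call sets.

Variant callers applied to evolved-versus-parent comparisons leave false
positives that a short rule chain removes: (i) calls whose consensus
involves ambiguous bases, (ii) calls below a Phred variant quality of 20,
(iii) calls outside a read-depth window of 10-400x, and (iv) calls shared
with the non-evolved parental strain, which are pre-existing background
differences rather than mutations acquired during the evolution.  The chain
is SNV-only: insertions/deletions are set aside with their own provenance
tag before the rules run.

Boundary semantics: quality 20, depth 10 and depth 400 are all kept
(quality "at least 20"; depth "below 10 discarded"; 400 is a caller-side
cap, hence attainable).  Parental subtraction matches on (chrom, pos, ref,
alt) — allele-aware, so a genuinely different allele at a shared site is
not masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VariantCall",
    "FilterConfig",
    "FilterReport",
    "filter_ambiguous",
    "filter_thresholds",
    "subtract_parental",
    "run_filter_chain",
]

_ACGT = frozenset("ACGT")

#: canonical rule order; a removed call's provenance is its first failing rule
RULE_ORDER = ("not_snv", "ambiguous", "quality", "depth", "parental")


@dataclass(frozen=True)
class VariantCall:
    """One called variant: coordinates, alleles, Phred quality, read depth."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def is_unambiguous(self) -> bool:
        return set(self.ref.upper()) <= _ACGT and set(self.alt.upper()) <= _ACGT


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 20.0
    min_depth: int = 10
    max_depth: int = 400

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")


def _split(calls, keep_fn):
    kept, removed = [], []
    for c in calls:
        (kept if keep_fn(c) else removed).append(c)
    return kept, removed


def filter_ambiguous(calls):
    """Rule i: keep only calls whose ref and alt are plain A/C/G/T strings."""
    return _split(calls, VariantCall.is_unambiguous)


def filter_thresholds(calls, config: FilterConfig = FilterConfig()):
    """Rules ii-iii: keep qual >= min_qual and min_depth <= depth <= max_depth."""
    return _split(
        calls,
        lambda c: c.qual >= config.min_qual
        and config.min_depth <= c.depth <= config.max_depth,
    )


def subtract_parental(calls, parental_calls):
    """Rule iv: drop calls with an exact (chrom, pos, ref, alt) parental match."""
    calls = list(calls)
    parental = list(parental_calls)
    if calls and parental:
        chroms = {c.chrom for c in calls}
        pchroms = {c.chrom for c in parental}
        if not chroms & pchroms:
            warnings.warn(
                "evolved and parental call sets share no chromosome names; "
                "possible coordinate-system mismatch",
                stacklevel=2,
            )
    parental_keys = {c.key for c in parental}
    return _split(calls, lambda c: c.key not in parental_keys)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the full chain: survivors plus per-rule provenance."""

    survivors: tuple
    removed: tuple  # (call, rule) pairs, rule = first failing rule
    config: FilterConfig
    n_input: int
    counts: dict = field(init=False)

    def __post_init__(self) -> None:
        counts = {rule: 0 for rule in RULE_ORDER}
        for _, rule in self.removed:
            counts[rule] += 1
        object.__setattr__(self, "counts", counts)
        if len(self.survivors) + len(self.removed) != self.n_input:
            raise AssertionError("removals + survivors must equal input count")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
             "qual": c.qual, "depth": c.depth, "status": "pass", "rule": "."}
            for c in self.survivors
        ] + [
            {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
             "qual": c.qual, "depth": c.depth, "status": "removed", "rule": rule}
            for c, rule in self.removed
        ]
        df = pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", "qual", "depth", "status", "rule"],
        )
        return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    def summary(self) -> str:
        lines = [f"input calls:      {self.n_input}"]
        label = {
            "not_snv": "not an SNV (indel)",
            "ambiguous": "ambiguous base",
            "quality": f"quality < {self.config.min_qual:g}",
            "depth": f"depth outside [{self.config.min_depth}, {self.config.max_depth}]",
            "parental": "shared with parental strain",
        }
        for rule in RULE_ORDER:
            lines.append(f"removed, {label[rule]:<34} {self.counts[rule]}")
        lines.append(f"surviving SNVs:   {len(self.survivors)}")
        return "\n".join(lines)


def run_filter_chain(
    calls, parental_calls=(), config: FilterConfig = FilterConfig()
) -> FilterReport:
    """Apply the rules in canonical order; tag each removal with its first
    failing rule; survivors are sorted by (chrom, pos)."""
    calls = list(calls)
    parental_keys = {c.key for c in parental_calls}
    survivors, removed = [], []
    for c in calls:
        if not c.is_snv:
            removed.append((c, "not_snv"))
        elif not c.is_unambiguous():
            removed.append((c, "ambiguous"))
        elif c.qual < config.min_qual:
            removed.append((c, "quality"))
        elif not (config.min_depth <= c.depth <= config.max_depth):
            removed.append((c, "depth"))
        elif c.key in parental_keys:
            removed.append((c, "parental"))
        else:
            survivors.append(c)
    survivors.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return FilterReport(
        survivors=tuple(survivors),
        removed=tuple(removed),
        config=config,
        n_input=len(calls),
    )


def calls_from_frame(df: pd.DataFrame) -> list[VariantCall]:
    """Build calls from a chrom/pos/ref/alt/qual/depth table (TSV dialect)."""
    return [
        VariantCall(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            qual=float(r.qual), depth=int(r.depth),
        )
        for r in df.itertuples(index=False)
    ]
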