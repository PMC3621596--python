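"""Codon-level annotation of SNVs against intronless gene models.

Coding positions are ORF-internal and 1-based, so coding nucleotide p lies
in codon ceil(p / 3) at within-codon offset ((p - 1) mod 3) + 1.  A variant
falling inside a CDS is converted to its coding position (reverse-
complemented on minus-strand genes); a variant within a configurable
window 5' of the start codon is classed upstream, with the base immediately
5' of the A of ATG at distance 1; anything else is intergenic.

Reported amino-acid changes are verified by codon arithmetic over the
standard nuclear genetic code without requiring the reference sequence:
a change "X<codon_no>Z" is *consistent* with a nucleotide change at coding
position p when some codon of X carries the reference base at the computed
offset and yields a codon of Z after the substitution.  Consistency is
compatibility-with-some-codon, not proof — the true codon would need the
reference sequence.  A codon-number disagreement is reported as
``position_mismatch`` (one such row exists in the evolved-strain variant
table and is deliberately not "corrected").
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "GeneModel",
    "NtChange",
    "AaChange",
    "AnnotatedVariant",
    "codon_index",
    "consistency_check",
    "classify_location",
    "count_by_class",
    "verify_reported_variants",
]

_TABLE = unambiguous_dna_by_id[1]  # standard nuclear code
CODON_TO_AA = {**_TABLE.forward_table, **{c: "*" for c in _TABLE.stop_codons}}
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codon_index(cds_pos: int) -> tuple[int, int]:
    """(codon number, within-codon offset in {1,2,3}) of a 1-based coding position."""
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


@dataclass(frozen=True)
class NtChange:
    """Single-base substitution at a 1-based position within the coding sequence."""

    ref_base: str
    alt_base: str
    cds_pos: int

    def __post_init__(self) -> None:
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"base must be one of A/C/G/T, got {b!r}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if self.cds_pos < 1:
            raise ValueError(f"cds_pos must be >= 1, got {self.cds_pos}")

    @classmethod
    def parse(cls, text: str) -> "NtChange":
        """Parse the compact 'G1518C' notation."""
        return cls(ref_base=text[0], alt_base=text[-1], cds_pos=int(text[1:-1]))


@dataclass(frozen=True)
class AaChange:
    """Reported amino-acid substitution, '*' meaning a stop codon."""

    ref_aa: str
    codon_no: int
    alt_aa: str

    def __post_init__(self) -> None:
        for a in (self.ref_aa, self.alt_aa):
            if a not in AA_TO_CODONS:
                raise ValueError(f"unknown amino-acid symbol {a!r}")
        if self.codon_no < 1:
            raise ValueError(f"codon_no must be >= 1, got {self.codon_no}")

    @classmethod
    def parse(cls, text: str) -> "AaChange":
        return cls(ref_aa=text[0], codon_no=int(text[1:-1]), alt_aa=text[-1])


def consistency_check(nt: NtChange, aa: AaChange) -> str:
    """'consistent', 'inconsistent' or 'position_mismatch' for a reported change.

    position_mismatch: the coding position does not fall in the reported
    codon.  consistent: some codon of the reported reference amino acid has
    nt.ref_base at the computed offset and encodes the reported alternate
    amino acid after the substitution.
    """
    codon_no, offset = codon_index(nt.cds_pos)
    if codon_no != aa.codon_no:
        return "position_mismatch"
    for codon in AA_TO_CODONS[aa.ref_aa]:
        if codon[offset - 1] != nt.ref_base:
            continue
        mutated = codon[: offset - 1] + nt.alt_base + codon[offset:]
        if CODON_TO_AA[mutated] == aa.alt_aa:
            return "consistent"
    return "inconsistent"


@dataclass(frozen=True)
class GeneModel:
    """Intronless CDS span on a chromosome; coordinates 1-based inclusive."""

    gene: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    intronless: bool = True
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.cds_start <= self.cds_end:
            raise ValueError(
                f"need 1 <= cds_start <= cds_end, got {self.cds_start}..{self.cds_end}"
            )
        if self.complete and (self.cds_end - self.cds_start + 1) % 3:
            raise ValueError(f"complete CDS of {self.gene} not divisible by 3")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def genomic_to_cds(self, pos: int) -> int:
        if not self.cds_start <= pos <= self.cds_end:
            raise ValueError(f"position {pos} outside CDS of {self.gene}")
        return pos - self.cds_start + 1 if self.strand == "+" else self.cds_end - pos + 1

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.length:
            raise ValueError(f"cds_pos {cds_pos} outside CDS of {self.gene}")
        return (
            self.cds_start + cds_pos - 1
            if self.strand == "+"
            else self.cds_end - cds_pos + 1
        )

    def upstream_distance(self, pos: int) -> int | None:
        """bp 5' of the start codon (ATG-1 -> 1); None if not strictly upstream."""
        if self.strand == "+":
            d = self.cds_start - pos
        else:
            d = pos - self.cds_end
        return d if d >= 1 else None


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    location_class: str  # coding | upstream | intergenic
    cds_pos: int | None = None
    codon_no: int | None = None
    codon_offset: int | None = None
    cds_ref: str | None = None   # strand-corrected alleles (coding only)
    cds_alt: str | None = None
    upstream_distance: int | None = None
    ambiguous: bool = False      # position hit by several gene models


def classify_location(
    call, gene_models, upstream_window: int = 1000
) -> list[AnnotatedVariant]:
    """Annotate one call against all gene models it touches.

    ``call`` needs chrom/pos/ref/alt attributes.  Coding hits take priority
    over upstream hits; multiple hits of the same rank are all returned
    with ``ambiguous=True``.  With no hit a single intergenic record is
    returned.
    """
    coding, upstream = [], []
    for m in gene_models:
        if m.chrom != call.chrom:
            continue
        if m.cds_start <= call.pos <= m.cds_end:
            cds_pos = m.genomic_to_cds(call.pos)
            codon_no, offset = codon_index(cds_pos)
            flip = m.strand == "-"
            coding.append(
                AnnotatedVariant(
                    chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
                    gene=m.gene, location_class="coding", cds_pos=cds_pos,
                    codon_no=codon_no, codon_offset=offset,
                    cds_ref=revcomp(call.ref) if flip else call.ref,
                    cds_alt=revcomp(call.alt) if flip else call.alt,
                )
            )
        else:
            d = m.upstream_distance(call.pos)
            if d is not None and d <= upstream_window:
                upstream.append(
                    AnnotatedVariant(
                        chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
                        gene=m.gene, location_class="upstream", upstream_distance=d,
                    )
                )
    hits = coding or upstream
    if not hits:
        return [
            AnnotatedVariant(
                chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
                gene=None, location_class="intergenic",
            )
        ]
    if len(hits) > 1:
        hits = [
            AnnotatedVariant(**{**h.__dict__, "ambiguous": True}) for h in hits
        ]
    return hits


def annotate_calls(calls, gene_models, upstream_window: int = 1000) -> pd.DataFrame:
    """Annotate a call collection; one row per (call, hit gene model)."""
    rows = []
    for call in calls:
        for a in classify_location(call, gene_models, upstream_window):
            rows.append(a.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "location_class", "cds_pos",
            "codon_no", "codon_offset", "cds_ref", "cds_alt",
            "upstream_distance", "ambiguous",
        ],
    )


def count_by_class(annotated: pd.DataFrame, strain: str | None = None) -> tuple[int, int]:
    """(n_coding, n_noncoding) rows, optionally restricted to one strain."""
    df = annotated
    if strain is not None:
        df = df[df["strain"] == strain]
    coding = int((df["location_class"] == "coding").sum())
    return coding, int(len(df) - coding)


def verify_reported_variants(table: pd.DataFrame) -> pd.DataFrame:
    """Run the codon-arithmetic consistency check over a reported variant table.

    Expects the packaged variant-table layout (strain, allele, location,
    nt_ref/nt_alt/cds_pos, aa_ref/aa_codon/aa_alt).  Coding rows get codon
    number/offset and a verdict; upstream rows get verdict
    ``not_applicable``.
    """
    rows = []
    for r in table.itertuples(index=False):
        row = {
            "strain": r.strain, "allele": r.allele, "gene": r.gene,
            "location_class": r.location, "nt_change": r.nt_change,
            "reported_aa": r.aa_change,
            "codon_no": None, "codon_offset": None, "verdict": "not_applicable",
        }
        if r.location == "coding":
            nt = NtChange(r.nt_ref, r.nt_alt, int(r.cds_pos))
            aa = AaChange(r.aa_ref, int(r.aa_codon), r.aa_alt)
            codon_no, offset = codon_index(nt.cds_pos)
            row.update(
                codon_no=codon_no,
                codon_offset=offset,
                verdict=consistency_check(nt, aa),
            )
        rows.append(row)
    return pd.DataFrame(rows)
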