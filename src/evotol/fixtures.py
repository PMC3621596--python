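"""Packaged study tables: confirmed sensitive genes, evolved-strain SNVs, strains.

Three plain-TSV tables ship inside the package so every downstream stage can
be exercised without network access:

``table1_genes``
    the 35 genes whose deletion confers butanol sensitivity in both screen
    backgrounds, with the ubiquitin-proteasome (UPS) and multivesicular-body
    (MVB) cluster labels used as planted enrichment truth;
``table2_variants``
    the 11 single-nucleotide variations of the two evolved lineages
    (9 coding with reported amino-acid changes, 2 promoter-proximal);
``table3_genotypes``
    the strain roster, including the F1-F3 backcross segregants whose
    genotypes record which evolved alleles survived each cycle.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["FIXTURE_NAMES", "load_fixture", "f3_retained_alleles"]

_FILES = {
    "table1_genes": "table1_genes.tsv",
    "table2_variants": "table2_variants.tsv",
    "table3_genotypes": "table3_strains.tsv",
}
FIXTURE_NAMES = tuple(_FILES)

# the strain table spells the STT4-promoter allele "sst4-2" while the variant
# table calls it "stt4-2" (gene printed as "SST4"); normalise for set algebra
_ALLELE_SYNONYMS = {"sst4-2": "stt4-2"}


def load_fixture(name: str) -> pd.DataFrame:
    """Return one packaged table as a DataFrame ('' never NaN, '.' = missing)."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FILES)}")
    ref = resources.files("evotol").joinpath("data", _FILES[name])
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _normalise(alleles) -> set[str]:
    return {_ALLELE_SYNONYMS.get(a, a) for a in alleles if a and a != "."}


def strain_alleles(strain: str) -> set[str]:
    """Evolved mutant alleles carried by a strain, per the strain table."""
    table = load_fixture("table3_genotypes")
    row = table[table["strain"] == strain]
    if row.empty:
        raise KeyError(f"strain {strain!r} not in the strain table")
    return _normalise(row.iloc[0]["alleles"].split(";"))


def f3_retained_alleles(evolved_strain: str, f3_strain: str) -> dict:
    """Allele attrition across three backcross cycles, from the study tables.

    Compares the evolved strain's variant-table alleles with the F3
    segregant's genotype; returns the retained and lost sets and their sizes.
    """
    table2 = load_fixture("table2_variants")
    evolved = _normalise(table2.loc[table2["strain"] == evolved_strain, "allele"])
    if not evolved:
        raise KeyError(f"{evolved_strain!r} has no alleles in the variant table")
    f3 = strain_alleles(f3_strain)
    return {
        "evolved": evolved,
        "f3": f3,
        "retained": evolved & f3,
        "lost": evolved - f3,
        "n_evolved": len(evolved),
        "n_retained": len(evolved & f3),
        "n_lost": len(evolved - f3),
    }
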