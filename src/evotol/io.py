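"""Readers and writers for the pipeline's interchange formats.

TSV (tab-separated, header row, '#' comment lines) is the interchange
dialect everywhere; variants additionally round-trip through a minimal VCF
v4 subset (CHROM POS ID REF ALT QUAL FILTER INFO with DP= depth,
multi-allelic records split into per-allele calls).  The VCF reader
collects malformed records into an error report instead of silently
dropping them; a missing header line is a format error.  Ontologies load
from an OBO file (via obonet; is_a edges, part_of behind a flag) or from a
two-column child/parent TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import obonet
import pandas as pd
import yaml

from .annotation import GeneModel
from .variants import VariantCall

__all__ = [
    "MalformedRecord",
    "VcfParseResult",
    "read_vcf_min",
    "write_vcf_min",
    "read_variant_tsv",
    "write_variant_tsv",
    "read_plate_tsv",
    "write_plate_tsv",
    "read_gene_models_tsv",
    "read_gene_models_gff3",
    "read_annotations_tsv",
    "read_ontology_obo",
    "read_ontology_tsv",
    "read_config",
    "write_config",
]


@dataclass(frozen=True)
class MalformedRecord:
    line_no: int
    line: str
    reason: str


@dataclass(frozen=True)
class VcfParseResult:
    calls: list
    errors: list

    def raise_on_errors(self) -> "VcfParseResult":
        if self.errors:
            detail = "; ".join(f"line {e.line_no}: {e.reason}" for e in self.errors[:5])
            raise ValueError(f"{len(self.errors)} malformed VCF record(s): {detail}")
        return self


def _parse_dp(info: str) -> int:
    for part in info.split(";"):
        if part.startswith("DP="):
            return int(part[3:])
    raise ValueError("INFO lacks DP=")


def read_vcf_min(path) -> VcfParseResult:
    """Parse a minimal VCF v4 file into per-allele variant calls.

    Multi-allelic ALT fields are split into one call per allele.  Records
    that cannot be parsed are returned in ``errors`` with their line number
    and reason; the file must start with a ``##fileformat=VCF`` header.
    """
    calls: list[VariantCall] = []
    errors: list[MalformedRecord] = []
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("##fileformat=VCF"):
        raise ValueError(f"{path}: missing ##fileformat=VCF header line")
    for no, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            errors.append(MalformedRecord(no, line, "fewer than 8 columns"))
            continue
        chrom, pos, _id, ref, alt, qual, _filt, info = fields[:8]
        try:
            for allele in alt.split(","):
                calls.append(
                    VariantCall(
                        chrom=chrom,
                        pos=int(pos),
                        ref=ref,
                        alt=allele,
                        qual=float(qual),
                        depth=_parse_dp(info),
                    )
                )
        except (ValueError, TypeError) as exc:
            errors.append(MalformedRecord(no, line, str(exc)))
    return VcfParseResult(calls=calls, errors=errors)


def write_vcf_min(calls, path, *, source: str = "evotol") -> None:
    """Write calls as minimal VCF v4.2 (QUAL column, DP in INFO)."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    contigs = sorted({c.chrom for c in calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.qual:g}\t.\tDP={c.depth}\n"
            )


_VARIANT_COLS = ["chrom", "pos", "ref", "alt", "qual", "depth"]


def read_variant_tsv(path) -> list:
    """TSV dialect equivalent of the minimal VCF: chrom/pos/ref/alt/qual/depth."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = set(_VARIANT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant TSV lacks columns {sorted(missing)}")
    return [
        VariantCall(
            chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            qual=float(r.qual), depth=int(r.depth),
        )
        for r in df.itertuples(index=False)
    ]


def write_variant_tsv(calls, path) -> None:
    pd.DataFrame(
        [
            {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
             "qual": c.qual, "depth": c.depth}
            for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
        ],
        columns=_VARIANT_COLS,
    ).to_csv(path, sep="\t", index=False)


_PLATE_COLS = ["strain", "well", "concentration", "time_h", "od660"]


def read_plate_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_PLATE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: plate TSV lacks columns {sorted(missing)}")
    return df


def write_plate_tsv(plates: pd.DataFrame, path) -> None:
    plates.to_csv(path, sep="\t", index=False, columns=_PLATE_COLS)


def read_gene_models_tsv(path) -> list:
    """gene / chrom / strand / cds_start / cds_end table -> gene models."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"gene", "chrom", "strand", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene-model TSV lacks columns {sorted(missing)}")
    return [
        GeneModel(
            gene=r.gene, chrom=r.chrom, strand=r.strand,
            cds_start=int(r.cds_start), cds_end=int(r.cds_end),
        )
        for r in df.itertuples(index=False)
    ]


def read_gene_models_gff3(path) -> list:
    """CDS lines of a GFF3 file, one intronless gene model per CDS feature.

    The gene symbol is taken from the attribute Name=, ID= or Parent=
    (first found).  Multi-segment CDS groups are out of scope and rejected.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(
        path, sep="\t", comment="#", names=cols, dtype=str, keep_default_na=False
    )
    cds = df[df["type"] == "CDS"]
    models, seen = [], {}
    for r in cds.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in r.attributes.split(";") if "=" in kv
        )
        gene = attrs.get("Name") or attrs.get("ID") or attrs.get("Parent")
        if not gene:
            raise ValueError(f"{path}: CDS line without Name/ID/Parent attribute")
        if gene in seen:
            raise ValueError(
                f"{path}: multi-segment CDS for {gene!r}; intronless models only"
            )
        seen[gene] = True
        models.append(
            GeneModel(
                gene=gene, chrom=r.seqid, strand=r.strand,
                cds_start=int(r.start), cds_end=int(r.end),
            )
        )
    return models


def read_annotations_tsv(path) -> pd.DataFrame:
    """GAF-lite two-column gene / term annotation table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = {"gene", "term"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation TSV lacks columns {sorted(missing)}")
    return df[["gene", "term"]]


def read_ontology_tsv(path) -> pd.DataFrame:
    """Two-column child / parent is_a edge table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = {"child", "parent"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ontology TSV lacks columns {sorted(missing)}")
    return df[["child", "parent"]]


def read_ontology_obo(path, include_part_of: bool = False):
    """OBO term hierarchy -> (child/parent edge table, term-name map)."""
    graph = obonet.read_obo(path)
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" or (include_part_of and key == "part_of"):
            edges.append((child, parent))
    names = {
        node: data.get("name", "") for node, data in graph.nodes(data=True)
    }
    return pd.DataFrame(edges, columns=["child", "parent"]), names


def write_ontology_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, columns=["child", "parent"])


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key/value mapping")
    return cfg


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
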