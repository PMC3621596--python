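"""Backcross-segregation simulation: isolating causal alleles by repeated crossing.

An evolved haploid carrying several mutant alleles is crossed to a naive
isogenic partner, the diploid is sporulated, and one haploid segregant with
the evolved phenotype is selected; the cycle is repeated (three times in
the study design).  Each cycle halves the expected retention of an
unselected, unlinked mutant allele, while alleles required for the selected
phenotype are retained with certainty — after n cycles an unlinked neutral
allele survives with probability (1/2)^n and an allele at recombination
fraction r from a selected locus with probability (1 - r)^n.

Meiosis is modelled at the spore level: per chromosome a gamete inherits a
phase chain that switches between the two parental genomes with the
Haldane (default) or Kosambi recombination fraction between adjacent
mapped loci; a tetrad is two independent gametes plus their complements,
which guarantees 2:2 segregation at every heterozygous locus and a
per-spore recombination fraction equal to the map value.  Chiasma-level
four-strand bookkeeping (chromatid interference, tetrad-class ratios) is
not modelled; every quantity reported here is a spore-level frequency.

Marker selection mirrors the auxotrophy trick of the study: the naive
crossing partner carries a deleted marker locus, so demanding the
functional allele guarantees each selected "segregant" is a true
recombinant haploid and not the naive parent; with the marker unlinked to
the causal loci it only thins the eligible spores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "HaploidGenotype",
    "PhenotypeModel",
    "BackcrossConfig",
    "recombination_fraction",
    "meiosis",
    "select_segregant",
    "run_backcross_series",
    "estimate_retention",
    "ims0344_scenario",
    "ims0351_scenario",
]

EVOLVED, NAIVE = "evolved", "naive"


def recombination_fraction(d_cM: float, map_function: str = "haldane") -> float:
    """Map distance (cM) -> recombination fraction r in [0, 0.5)."""
    if d_cM < 0:
        raise ValueError(f"map distance must be >= 0, got {d_cM}")
    x = 2.0 * d_cM / 100.0
    if map_function == "haldane":
        return 0.5 * (1.0 - math.exp(-x))
    if map_function == "kosambi":
        return 0.5 * math.tanh(x)
    raise ValueError(f"unknown map function {map_function!r}")


@dataclass(frozen=True)
class Locus:
    """A mapped allele: role 'causal' (selected), 'neutral', or 'marker'."""

    id: str
    chrom: str
    map_pos: float  # centiMorgan
    role: str = "neutral"
    effect: float = 0.0  # additive phenotype weight (causal loci)

    def __post_init__(self) -> None:
        if self.map_pos < 0:
            raise ValueError(f"map_pos must be >= 0, got {self.map_pos}")
        if self.role not in ("causal", "neutral", "marker"):
            raise ValueError(f"unknown locus role {self.role!r}")
        if self.effect < 0:
            raise ValueError("effect sizes must be >= 0")


@dataclass(frozen=True)
class HaploidGenotype:
    """Allele state (evolved/naive) per locus id, plus mating type."""

    alleles: dict
    mating_type: str = "a"

    def __post_init__(self) -> None:
        if self.mating_type not in ("a", "alpha"):
            raise ValueError(f"mating type must be 'a' or 'alpha', got {self.mating_type!r}")
        bad = {v for v in self.alleles.values()} - {EVOLVED, NAIVE}
        if bad:
            raise ValueError(f"allele states must be evolved/naive, got {sorted(bad)}")

    def carries(self, locus_id: str) -> bool:
        return self.alleles[locus_id] == EVOLVED


@dataclass(frozen=True)
class PhenotypeModel:
    """Which spores count as 'same tolerance as the evolved strain'.

    rule 'all_causal_required': the spore must carry every causal allele
    (the study's two-locus synergy).  rule 'additive_threshold': the sum of
    per-locus effects over carried causal alleles must come within
    ``epsilon`` of the evolved strain's score.
    """

    causal: frozenset
    rule: str = "all_causal_required"
    effects: dict = field(default_factory=dict)
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.rule not in ("all_causal_required", "additive_threshold"):
            raise ValueError(f"unknown phenotype rule {self.rule!r}")
        if not self.causal:
            raise ValueError("causal locus set must be non-empty")
        object.__setattr__(self, "causal", frozenset(self.causal))


@dataclass(frozen=True)
class BackcrossConfig:
    n_cycles: int = 3
    marker_selection: bool = True
    max_tetrads: int = 1000  # tetrads sampled per cycle before declaring failure
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.max_tetrads < 1:
            raise ValueError("max_tetrads must be >= 1")


class _LocusMap:
    """Ordered loci with per-chromosome adjacent recombination fractions."""

    def __init__(self, loci, map_function: str = "haldane"):
        loci = list(loci)
        ids = [l.id for l in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")
        self.loci = sorted(loci, key=lambda l: (l.chrom, l.map_pos, l.id))
        self.ids = [l.id for l in self.loci]
        self.index = {i: j for j, i in enumerate(self.ids)}
        self.chrom_slices: list[tuple[int, int]] = []
        self.r_adjacent: list[np.ndarray] = []
        start = 0
        for j in range(1, len(self.loci) + 1):
            if j == len(self.loci) or self.loci[j].chrom != self.loci[start].chrom:
                self.chrom_slices.append((start, j))
                d = np.diff([l.map_pos for l in self.loci[start:j]])
                self.r_adjacent.append(
                    np.array([recombination_fraction(x, map_function) for x in d])
                )
                start = j
        self.causal_idx = np.array(
            [j for j, l in enumerate(self.loci) if l.role == "causal"], dtype=int
        )
        self.marker_idx = np.array(
            [j for j, l in enumerate(self.loci) if l.role == "marker"], dtype=int
        )
        self.effects = np.array([l.effect for l in self.loci])

    def vector(self, genotype: HaploidGenotype) -> np.ndarray:
        missing = set(self.ids) - set(genotype.alleles)
        if missing:
            raise ValueError(f"genotype lacks loci: {sorted(missing)}")
        return np.array([genotype.alleles[i] == EVOLVED for i in self.ids])

    def genotype(self, vec: np.ndarray, mating_type: str = "a") -> HaploidGenotype:
        return HaploidGenotype(
            {i: (EVOLVED if v else NAIVE) for i, v in zip(self.ids, vec)},
            mating_type=mating_type,
        )

    def draw_phases(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, n_loci) gamete phase matrix: 0 = first parent, 1 = second."""
        phases = np.empty((n, len(self.ids)), dtype=np.int8)
        for (a, b), r in zip(self.chrom_slices, self.r_adjacent):
            first = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
            if b - a > 1:
                switch = (rng.random((n, b - a - 1)) < r).astype(np.int8)
                chain = np.concatenate([first, switch], axis=1)
                phases[:, a:b] = np.bitwise_xor.accumulate(chain, axis=1)
            else:
                phases[:, a:b] = first
        return phases

    def tetrads(
        self, mother: np.ndarray, father: np.ndarray, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        """(n, 4, n_loci) boolean spore alleles for n tetrads.

        Spores 0 and 1 are independent gametes; spores 2 and 3 their
        complements, so every heterozygous locus segregates 2:2.
        """
        mother = np.broadcast_to(mother, (n, len(self.ids)))
        pa = self.draw_phases(n, rng)
        pb = self.draw_phases(n, rng)
        father = np.broadcast_to(father, (n, len(self.ids)))
        spores = np.empty((n, 4, len(self.ids)), dtype=bool)
        spores[:, 0] = np.where(pa == 0, mother, father)
        spores[:, 1] = np.where(pb == 0, mother, father)
        spores[:, 2] = np.where(pa == 1, mother, father)
        spores[:, 3] = np.where(pb == 1, mother, father)
        return spores


def _eligible(
    spores: np.ndarray,
    lmap: _LocusMap,
    phenotype: PhenotypeModel,
    config: BackcrossConfig,
    evolved_score: float,
) -> np.ndarray:
    """Boolean eligibility over the last-but-one spore axis."""
    ok = np.ones(spores.shape[:-1], dtype=bool)
    if config.marker_selection and lmap.marker_idx.size:
        ok &= spores[..., lmap.marker_idx].all(axis=-1)
    if phenotype.rule == "all_causal_required":
        ok &= spores[..., lmap.causal_idx].all(axis=-1)
    else:
        score = (spores[..., lmap.causal_idx] * lmap.effects[lmap.causal_idx]).sum(axis=-1)
        ok &= evolved_score - score <= phenotype.epsilon
    return ok


def meiosis(mother: HaploidGenotype, father: HaploidGenotype, loci, rng=None):
    """One tetrad: the four haploid spores of a single meiosis."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lmap = loci if isinstance(loci, _LocusMap) else _LocusMap(loci)
    spores = lmap.tetrads(lmap.vector(mother), lmap.vector(father), 1, rng)[0]
    mts = ["a", "a", "alpha", "alpha"]
    return [lmap.genotype(s, mt) for s, mt in zip(spores, mts)]


def select_segregant(
    spores,
    phenotype: PhenotypeModel,
    loci,
    rng=None,
    config: BackcrossConfig = BackcrossConfig(),
):
    """Uniform pick among spores passing marker + phenotype selection; None if none."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lmap = loci if isinstance(loci, _LocusMap) else _LocusMap(loci)
    vecs = np.array([lmap.vector(s) for s in spores])
    evolved_score = float(lmap.effects[lmap.causal_idx].sum())
    ok = _eligible(vecs, lmap, phenotype, config, evolved_score)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    return spores[int(rng.choice(idx))]


def _check_scenario(evolved_vec, naive_vec, lmap, phenotype):
    if not set(phenotype.causal) <= set(lmap.ids):
        raise ValueError(
            f"causal loci absent from the map: {sorted(set(phenotype.causal) - set(lmap.ids))}"
        )
    causal_pos = [lmap.index[c] for c in phenotype.causal]
    if not evolved_vec[causal_pos].all():
        raise ValueError("phenotype unsatisfiable: evolved strain lacks a causal allele")
    if naive_vec[causal_pos].any():
        raise ValueError("naive strain must not carry causal alleles")


def _simulate_batch(
    evolved_vec: np.ndarray,
    naive_vec: np.ndarray,
    lmap: _LocusMap,
    phenotype: PhenotypeModel,
    config: BackcrossConfig,
    n_series: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_series, n_cycles, n_loci) selected-segregant genotypes."""
    evolved_score = float(lmap.effects[lmap.causal_idx].sum())
    current = np.broadcast_to(evolved_vec, (n_series, len(lmap.ids))).copy()
    out = np.empty((n_series, config.n_cycles, len(lmap.ids)), dtype=bool)
    for cycle in range(config.n_cycles):
        pending = np.arange(n_series)
        selected = np.empty((n_series, len(lmap.ids)), dtype=bool)
        for _ in range(config.max_tetrads):
            spores = lmap.tetrads(current[pending], naive_vec, len(pending), rng)
            ok = _eligible(spores, lmap, phenotype, config, evolved_score)  # (m, 4)
            any_ok = ok.any(axis=1)
            if any_ok.any():
                m_ok = np.flatnonzero(any_ok)
                # uniform pick among eligible spores of each successful tetrad
                w = ok[m_ok].astype(float)
                picks = (rng.random(len(m_ok))[:, None] * w.sum(1, keepdims=True) <
                         np.cumsum(w, axis=1)).argmax(axis=1)
                selected[pending[m_ok]] = spores[m_ok, picks]
                pending = pending[~any_ok]
            if pending.size == 0:
                break
        else:
            raise RuntimeError(
                f"no eligible segregant in {config.max_tetrads} tetrads "
                f"(cycle {cycle + 1})"
            )
        current = selected
        out[:, cycle] = selected
    return out


def run_backcross_series(
    evolved: HaploidGenotype,
    naive: HaploidGenotype,
    loci,
    phenotype: PhenotypeModel,
    config: BackcrossConfig = BackcrossConfig(),
    seed=None,
) -> dict:
    """One full backcross series; returns the selected F1..Fn genotypes and
    which evolved alleles remain in the final segregant."""
    lmap = _LocusMap(loci, config.map_function)
    rng = np.random.default_rng(seed)
    ev, nv = lmap.vector(evolved), lmap.vector(naive)
    _check_scenario(ev, nv, lmap, phenotype)
    path = _simulate_batch(ev, nv, lmap, phenotype, config, 1, rng)[0]
    mts = ["alpha" if (c % 2 == 0) else "a" for c in range(config.n_cycles)]
    generations = {
        f"F{c + 1}": lmap.genotype(path[c], mts[c]) for c in range(config.n_cycles)
    }
    final = path[-1]
    return {
        "generations": generations,
        "retained": {i: bool(v) for i, v in zip(lmap.ids, final) if ev[lmap.index[i]]},
    }


def estimate_retention(
    evolved: HaploidGenotype,
    naive: HaploidGenotype,
    loci,
    phenotype: PhenotypeModel,
    config: BackcrossConfig = BackcrossConfig(),
    n_replicates: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Per-locus frequency of evolved-allele retention in the final segregant.

    Monte Carlo over ``n_replicates`` independent series; the 95% CI is the
    normal approximation p +/- 1.96 sqrt(p(1-p)/n).  Causal loci retain with
    frequency exactly 1 by construction of the selection rule.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    lmap = _LocusMap(loci, config.map_function)
    rng = np.random.default_rng(seed)
    ev, nv = lmap.vector(evolved), lmap.vector(naive)
    _check_scenario(ev, nv, lmap, phenotype)
    final = _simulate_batch(ev, nv, lmap, phenotype, config, n_replicates, rng)[:, -1]
    p = final.mean(axis=0)
    half = 1.96 * np.sqrt(p * (1 - p) / n_replicates)
    return pd.DataFrame(
        {
            "locus": lmap.ids,
            "role": [l.role for l in lmap.loci],
            "n_cycles": config.n_cycles,
            "retention": p,
            "ci_low": np.clip(p - half, 0, 1),
            "ci_high": np.clip(p + half, 0, 1),
        }
    )


def _scenario(allele_roles, causal):
    """Loci on one linkage group each (unlinked), evolved/naive genotypes,
    and the all-causal-required phenotype.  The evolved strain carries every
    evolved-state allele including the functional marker; the naive crossing
    partner carries none (its marker locus is deleted)."""
    loci = [
        Locus(id=a, chrom=f"LG{i + 1:02d}", map_pos=50.0, role=r)
        for i, (a, r) in enumerate(allele_roles)
    ]
    evolved = HaploidGenotype({l.id: EVOLVED for l in loci}, mating_type="a")
    naive = HaploidGenotype({l.id: NAIVE for l in loci}, mating_type="alpha")
    return loci, evolved, naive, PhenotypeModel(causal=frozenset(causal))


def ims0344_scenario():
    """Lineage-1 layout: four mutant alleles, each on its own linkage group,
    plus the URA3 marker; the selected phenotype requires both causal
    alleles (the two-transcription-factor synergy)."""
    spec = [
        ("rpn4-1", "causal"),
        ("rtg1-1", "causal"),
        ("ubr1-1", "neutral"),
        ("ssk2-1", "neutral"),
        ("URA3", "marker"),
    ]
    return _scenario(spec, causal={"rpn4-1", "rtg1-1"})


def ims0351_scenario():
    """Lineage-2 layout: seven mutant alleles, each on its own linkage
    group, plus the URA3 marker; causal alleles as in lineage 1."""
    spec = [
        ("rpn4-2", "causal"),
        ("rtg1-2", "causal"),
        ("ubr1-2", "neutral"),
        ("nma111-2", "neutral"),
        ("sto1-2", "neutral"),
        ("rpl10-2", "neutral"),
        ("stt4-2", "neutral"),
        ("URA3", "marker"),
    ]
    return _scenario(spec, causal={"rpn4-2", "rtg1-2"})
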