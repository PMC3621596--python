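"""Meiosis model, segregant selection, allele-retention closed forms."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from evotol import (
    BackcrossConfig,
    HaploidGenotype,
    Locus,
    PhenotypeModel,
    estimate_retention,
    meiosis,
    recombination_fraction,
    run_backcross_series,
    select_segregant,
)
from evotol.backcross import _LocusMap, ims0344_scenario, ims0351_scenario


class TestRecombinationFraction:
    def test_closed_form_values(self):
        assert recombination_fraction(0.0) == 0.0
        assert recombination_fraction(10.0) == pytest.approx(
            0.5 * (1 - math.exp(-0.2)), abs=1e-12
        )
        assert recombination_fraction(1e6) == pytest.approx(0.5, abs=1e-9)

    def test_kosambi_option(self):
        assert recombination_fraction(10.0, "kosambi") == pytest.approx(
            0.5 * math.tanh(0.2), abs=1e-12
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            recombination_fraction(-1.0)


def two_locus_setup(d_cM=10.0, same_chrom=True):
    loci = [
        Locus("a", "chr1", 0.0, role="neutral"),
        Locus("b", "chr1" if same_chrom else "chr2", d_cM if same_chrom else 0.0,
              role="neutral"),
    ]
    evolved = HaploidGenotype({"a": "evolved", "b": "evolved"})
    naive = HaploidGenotype({"a": "naive", "b": "naive"})
    return loci, evolved, naive


class TestMeiosis:
    def test_two_to_two_segregation_every_tetrad(self):
        loci, evolved, naive = two_locus_setup()
        rng = np.random.default_rng(0)
        lmap = _LocusMap(loci)
        for _ in range(300):
            spores = meiosis(evolved, naive, lmap, rng)
            for locus in ("a", "b"):
                carriers = sum(s.carries(locus) for s in spores)
                assert carriers == 2

    def test_unlinked_loci_assort_independently(self):
        loci, evolved, naive = two_locus_setup(same_chrom=False)
        lmap = _LocusMap(loci)
        rng = np.random.default_rng(1)
        spores = lmap.tetrads(
            lmap.vector(evolved), lmap.vector(naive), 10_000, rng
        ).reshape(-1, 2)
        classes = spores[:, 0].astype(int) * 2 + spores[:, 1].astype(int)
        observed = np.bincount(classes, minlength=4)
        stat, p = chisquare(observed)
        assert p > 1e-3

    def test_linked_recombinant_frequency_matches_map(self):
        d = 10.0
        loci, evolved, naive = two_locus_setup(d_cM=d)
        lmap = _LocusMap(loci)
        rng = np.random.default_rng(2)
        spores = lmap.tetrads(
            lmap.vector(evolved), lmap.vector(naive), 10_000, rng
        ).reshape(-1, 2)
        recombinant = spores[:, 0] != spores[:, 1]
        assert recombinant.mean() == pytest.approx(recombination_fraction(d), abs=0.01)


def scenario_loci():
    return [
        Locus("causal1", "c1", 0.0, role="causal"),
        Locus("causal2", "c2", 0.0, role="causal"),
        Locus("neutral", "c3", 0.0, role="neutral"),
        Locus("URA3", "c4", 0.0, role="marker"),
    ]


class TestSelection:
    def genotype(self, carried):
        ids = ["causal1", "causal2", "neutral", "URA3"]
        return HaploidGenotype({i: ("evolved" if i in carried else "naive") for i in ids})

    def test_full_carrier_is_eligible(self):
        phenotype = PhenotypeModel(causal={"causal1", "causal2"})
        spore = self.genotype({"causal1", "causal2", "URA3"})
        picked = select_segregant([spore], phenotype, scenario_loci(), rng=0)
        assert picked is spore

    def test_missing_causal_never_selected(self):
        phenotype = PhenotypeModel(causal={"causal1", "causal2"})
        spore = self.genotype({"causal1", "URA3"})
        assert select_segregant([spore], phenotype, scenario_loci(), rng=0) is None

    def test_marker_selection_enforced(self):
        phenotype = PhenotypeModel(causal={"causal1", "causal2"})
        spore = self.genotype({"causal1", "causal2"})  # lost functional URA3
        assert select_segregant([spore], phenotype, scenario_loci(), rng=0) is None

    def test_additive_threshold_rule(self):
        loci = [
            Locus("a", "c1", 0.0, role="causal", effect=1.0),
            Locus("b", "c2", 0.0, role="causal", effect=1.0),
        ]
        phenotype = PhenotypeModel(causal={"a", "b"}, rule="additive_threshold",
                                   epsilon=1.0)
        one_of_two = HaploidGenotype({"a": "evolved", "b": "naive"})
        none_of_two = HaploidGenotype({"a": "naive", "b": "naive"})
        assert select_segregant([one_of_two], phenotype, loci, rng=0) is one_of_two
        assert select_segregant([none_of_two], phenotype, loci, rng=0) is None


class TestBackcrossSeries:
    def test_f3_always_retains_causal_alleles(self):
        loci, evolved, naive, phenotype = ims0344_scenario()
        for seed in range(20):
            record = run_backcross_series(
                evolved, naive, loci, phenotype, BackcrossConfig(n_cycles=3), seed=seed
            )
            assert record["retained"]["rpn4-1"] and record["retained"]["rtg1-1"]
            assert record["retained"]["URA3"]
            assert set(record["generations"]) == {"F1", "F2", "F3"}

    def test_unsatisfiable_phenotype_rejected(self):
        loci, evolved, naive, phenotype = ims0344_scenario()
        stripped = HaploidGenotype(
            {**evolved.alleles, "rpn4-1": "naive"}, evolved.mating_type
        )
        with pytest.raises(ValueError, match="unsatisfiable"):
            run_backcross_series(stripped, naive, loci, phenotype)


class TestRetention:
    def test_causal_retention_is_exactly_one(self):
        loci, evolved, naive, phenotype = ims0344_scenario()
        ret = estimate_retention(
            evolved, naive, loci, phenotype, n_replicates=500, seed=3
        ).set_index("locus")
        assert ret.loc["rpn4-1", "retention"] == 1.0
        assert ret.loc["rtg1-1", "retention"] == 1.0

    def test_single_cycle_unlinked_neutral_is_half(self):
        loci, evolved, naive, phenotype = ims0344_scenario()
        ret = estimate_retention(
            evolved, naive, loci, phenotype, BackcrossConfig(n_cycles=1),
            n_replicates=10_000, seed=4,
        ).set_index("locus")
        assert ret.loc["ubr1-1", "retention"] == pytest.approx(0.5, abs=0.015)

    def test_lineage2_neutral_attrition(self):
        loci, evolved, naive, phenotype = ims0351_scenario()
        ret = estimate_retention(
            evolved, naive, loci, phenotype, BackcrossConfig(n_cycles=3),
            n_replicates=4000, seed=5,
        ).set_index("locus")
        for locus in ("ubr1-2", "nma111-2", "sto1-2", "rpl10-2", "stt4-2"):
            assert ret.loc[locus, "retention"] == pytest.approx(0.125, abs=0.02)

    def test_retention_monotone_in_cycles_and_linkage(self):
        # closed forms: (1/2)^n unlinked, (1-r)^n linked; retention must fall
        # with more cycles and rise with tighter linkage
        def linked_retention(d_cM, n_cycles, seed):
            loci = [
                Locus("causal", "c1", 0.0, role="causal"),
                Locus("neutral", "c1", d_cM, role="neutral"),
            ]
            evolved = HaploidGenotype({"causal": "evolved", "neutral": "evolved"})
            naive = HaploidGenotype({"causal": "naive", "neutral": "naive"})
            phenotype = PhenotypeModel(causal={"causal"})
            ret = estimate_retention(
                evolved, naive, loci, phenotype, BackcrossConfig(n_cycles=n_cycles),
                n_replicates=4000, seed=seed,
            ).set_index("locus")
            return float(ret.loc["neutral", "retention"])

        margin = 3 * math.sqrt(0.25 / 4000)
        by_cycles = [linked_retention(25.0, n, seed=6) for n in (1, 2, 3)]
        assert by_cycles[0] >= by_cycles[1] - margin >= by_cycles[2] - 2 * margin
        by_linkage = [linked_retention(d, 3, seed=7) for d in (5.0, 25.0, 400.0)]
        assert by_linkage[0] + margin >= by_linkage[1] + margin >= by_linkage[2]
        for d, est in zip((5.0, 25.0, 400.0), by_linkage):
            expected = (1 - recombination_fraction(d)) ** 3
            assert est == pytest.approx(expected, abs=3 * math.sqrt(0.25 / 4000))
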