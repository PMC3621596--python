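"""Post-calling SNV filter chain: rules, boundaries, provenance, invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evotol import (
    FilterConfig,
    VariantCall,
    filter_ambiguous,
    filter_thresholds,
    run_filter_chain,
    subtract_parental,
)
from evotol.synthetic import SyntheticVariantSpec, generate_variants
from evotol.variants import calls_from_frame

from conftest import random_call_set


def call(chrom="chr1", pos=100, ref="A", alt="G", qual=30.0, depth=30):
    return VariantCall(chrom, pos, ref, alt, qual, depth)


class TestRules:
    @pytest.mark.parametrize(
        "ref,alt,kept",
        [("A", "G", True), ("A", "N", False), ("A", "R", False), ("a", "g", True)],
    )
    def test_ambiguous_bases(self, ref, alt, kept):
        kept_calls, removed = filter_ambiguous([call(ref=ref, alt=alt)])
        assert bool(kept_calls) is kept and bool(removed) is not kept

    @pytest.mark.parametrize(
        "qual,depth,kept",
        [
            (19, 30, False),   # quality just below the threshold
            (20, 10, True),    # both boundaries inclusive
            (30, 9, False),    # depth just below
            (30, 400, True),   # cap inclusive
            (30, 401, False),
        ],
    )
    def test_threshold_boundaries(self, qual, depth, kept):
        kept_calls, removed = filter_thresholds([call(qual=qual, depth=depth)])
        assert bool(kept_calls) is kept

    def test_parental_subtraction_is_allele_aware(self):
        evolved = [call(pos=100, ref="A", alt="G"), call(pos=200, ref="A", alt="G")]
        parental = [call(pos=100, ref="A", alt="G"), call(pos=200, ref="A", alt="T")]
        kept, removed = subtract_parental(evolved, parental)
        assert [c.pos for c in kept] == [200]
        assert [c.pos for c in removed] == [100]

    def test_empty_parental_keeps_all(self):
        kept, removed = subtract_parental([call()], [])
        assert len(kept) == 1 and not removed

    def test_disjoint_chromosomes_warn(self):
        with pytest.warns(UserWarning, match="coordinate"):
            subtract_parental([call(chrom="chr1")], [call(chrom="2")])


class TestChain:
    def toy_set(self):
        return [
            call(pos=1, qual=19, depth=30),              # fails quality
            call(pos=2, qual=30, depth=9),               # fails depth (low)
            call(pos=3, qual=30, depth=450),             # fails depth (high)
            call(pos=4, alt="N"),                        # ambiguous
            call(pos=5),                                 # parental-shared
            call(pos=6),                                 # clean
        ]

    def test_toy_set_single_survivor_with_provenance(self):
        report = run_filter_chain(self.toy_set(), parental_calls=[call(pos=5)])
        assert len(report.survivors) == 1
        assert report.survivors[0].pos == 6
        assert report.counts == {
            "not_snv": 0, "ambiguous": 1, "quality": 1, "depth": 2, "parental": 1,
        }

    def test_all_clean_input_survives(self):
        calls = [call(pos=p) for p in range(1, 11)]
        report = run_filter_chain(calls)
        assert set(report.survivors) == set(calls)

    def test_indels_get_their_own_provenance(self):
        report = run_filter_chain([call(ref="AT", alt="A"), call()])
        assert report.counts["not_snv"] == 1
        assert len(report.survivors) == 1

    def test_first_failing_rule_wins(self):
        # violates ambiguity, quality and depth at once -> tagged ambiguous
        report = run_filter_chain([call(alt="N", qual=5, depth=1)])
        assert report.removed[0][1] == "ambiguous"

    def test_survivors_sorted_by_position(self):
        report = run_filter_chain([call(pos=500), call(pos=3), call(chrom="chr0", pos=9)])
        keys = [(c.chrom, c.pos) for c in report.survivors]
        assert keys == sorted(keys)


class TestChainInvariances:
    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            calls = random_call_set(rng, 40)
            parental = random_call_set(rng, 10)
            report = run_filter_chain(calls, parental)
            assert set(report.survivors) <= set(calls)
            again = run_filter_chain(report.survivors, parental)
            assert tuple(again.survivors) == tuple(report.survivors)

    def test_rule_order_invariance(self):
        # rules i-iii commute pairwise; the survivor set cannot depend on order
        rng = np.random.default_rng(1)
        stages = {
            "ambiguous": filter_ambiguous,
            "thresholds": lambda cs: filter_thresholds(cs, FilterConfig()),
        }
        for trial in range(20):
            calls = random_call_set(rng, 50)
            parental = random_call_set(rng, 10)
            outcomes = set()
            for order in itertools.permutations(stages):
                current = [c for c in calls if c.is_snv]
                for name in order:
                    current, _ = stages[name](current)
                current, _ = subtract_parental(current, parental)
                outcomes.add(frozenset(current))
            chain = frozenset(run_filter_chain(calls, parental).survivors)
            assert outcomes == {chain}

    @settings(max_examples=50, deadline=None)
    @given(
        quals=st.lists(st.integers(0, 60), min_size=0, max_size=20),
        depths=st.lists(st.integers(0, 500), min_size=0, max_size=20),
    )
    def test_counts_always_balance(self, quals, depths):
        calls = [
            call(pos=i + 1, qual=q, depth=d)
            for i, (q, d) in enumerate(zip(quals, depths))
        ]
        report = run_filter_chain(calls)
        assert len(report.survivors) + len(report.removed) == len(calls)


class TestSyntheticVariants:
    def test_truth_labels_partition_and_match_rules(self):
        spec = SyntheticVariantSpec(
            n_evolved_specific=5, n_parental_shared=3, n_noise_calls=6, seed=2
        )
        evolved, parental, truth = generate_variants(spec)
        assert len(evolved) == 14
        assert len(truth) == len(evolved)
        cfg = FilterConfig()
        for row, c in zip(truth.itertuples(index=False), calls_from_frame(evolved)):
            violations = []
            if not c.is_unambiguous():
                violations.append("noise:ambiguous")
            if c.qual < cfg.min_qual:
                violations.append("noise:quality")
            if not cfg.min_depth <= c.depth <= cfg.max_depth:
                violations.append("noise:depth")
            if row.label.startswith("noise:"):
                assert violations == [row.label]
            else:
                assert violations == []

    def test_filter_chain_recovers_exactly_the_evolved_specific_calls(self):
        spec = SyntheticVariantSpec(
            n_evolved_specific=5, n_parental_shared=3, n_noise_calls=4, seed=3
        )
        evolved, parental, truth = generate_variants(spec)
        report = run_filter_chain(
            calls_from_frame(evolved), calls_from_frame(parental)
        )
        survivors = {(c.chrom, c.pos) for c in report.survivors}
        planted = {
            (r.chrom, int(r.pos))
            for r in truth.itertuples(index=False)
            if r.label == "evolved_specific"
        }
        assert survivors == planted

    def test_no_noise_no_parental_all_pass(self):
        spec = SyntheticVariantSpec(
            n_evolved_specific=7, n_parental_shared=0, n_noise_calls=0, seed=4
        )
        evolved, parental, _ = generate_variants(spec)
        report = run_filter_chain(calls_from_frame(evolved), calls_from_frame(parental))
        assert len(report.survivors) == 7

    def test_positions_unique_per_chromosome(self):
        spec = SyntheticVariantSpec(
            genome={"c": 2000}, n_evolved_specific=50, n_parental_shared=50,
            n_noise_calls=50, seed=5,
        )
        evolved, _, _ = generate_variants(spec)
        assert not evolved.duplicated(["chrom", "pos"]).any()

    def test_collision_exhaustion_raises(self):
        spec = SyntheticVariantSpec(
            genome={"c": 3}, n_evolved_specific=10, n_parental_shared=0,
            n_noise_calls=0, seed=6,
        )
        with pytest.raises(RuntimeError, match="collision"):
            generate_variants(spec)
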