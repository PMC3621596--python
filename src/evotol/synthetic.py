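"""Synthetic inputs for every pipeline stage, with planted ground truth.

Everything the pipeline consumes can be generated here, seeded and
reproducible: deletion-collection plate screens with planted sensitivity
classes, variant call tables with planted evolved-specific / parental-shared
/ noise calls, and GO annotation tables with planted enriched categories.
The generators emulate the study conditions: sealed-plate 48-h incubations
read every 30 min, 8 replicate wells per condition, a reference background
whose stationary OD at 1% butanol is half the unstressed value, and variant
calls shaped like a short-read pipeline's output (Phred quality, read
depth, occasional ambiguous consensus bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import DoseResponseParams, calibrate_reference

__all__ = [
    "SyntheticScreenSpec",
    "SyntheticVariantSpec",
    "generate_screen",
    "generate_variants",
    "generate_go_annotations",
    "reference_params",
]

#: planted BSI band sampled per sensitivity class (noise-free index);
#: hypersensitive strains are modelled as complete non-growers at 1% butanol.
CLASS_BSI_BANDS = {
    "reference_like": (1.90, 2.10),
    "sensitive": (2.5, 8.0),
    "tolerant": (1.1, 1.7),
}


def reference_params(noise_sd: float = 0.0) -> DoseResponseParams:
    """Reference-background dose-response parameters.

    Anchored to the two observed calibration points of the screen
    background: a 50% stationary-OD reduction at 1% butanol (OD ratio 2.0)
    and no growth above 1.45% v/v.
    """
    return calibrate_reference(2.0, 1.45, noise_sd=noise_sd)


@dataclass(frozen=True)
class SyntheticScreenSpec:
    """Layout of a synthetic deletion-collection screen.

    class_proportions maps sensitivity class -> fraction of strains planted
    in it (fractions sum to 1); replicates is wells per strain and
    condition (the study used 8).
    """

    n_strains: int
    class_proportions: dict = field(
        default_factory=lambda: {
            "reference_like": 0.90,
            "sensitive": 0.05,
            "hypersensitive": 0.03,
            "tolerant": 0.02,
        }
    )
    replicates: int = 8
    seed: int = 0
    noise_sd: float = 0.0
    interval_min: float = 30.0
    duration_h: float = 48.0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - (set(CLASS_BSI_BANDS) | {"hypersensitive"})
        if unknown:
            raise ValueError(f"unknown sensitivity classes: {sorted(unknown)}")

    @classmethod
    def from_counts(cls, counts: dict, n_strains: int, **kwargs) -> "SyntheticScreenSpec":
        """Plant exact per-class counts; unlisted strains are reference-like."""
        rest = n_strains - sum(counts.values())
        if rest < 0:
            raise ValueError("class counts exceed n_strains")
        props = {k: v / n_strains for k, v in counts.items()}
        props["reference_like"] = props.get("reference_like", 0.0) + rest / n_strains
        return cls(n_strains=n_strains, class_proportions=props, **kwargs)

    def class_counts(self) -> dict:
        """Integer strains per class (largest-remainder rounding, order-stable)."""
        items = sorted(self.class_proportions.items())
        raw = {k: v * self.n_strains for k, v in items}
        counts = {k: int(np.floor(v)) for k, v in raw.items()}
        short = self.n_strains - sum(counts.values())
        by_rem = sorted(items, key=lambda kv: raw[kv[0]] - counts[kv[0]], reverse=True)
        for k, _ in by_rem[:short]:
            counts[k] += 1
        return counts


def generate_screen(spec: SyntheticScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two-condition screen; return (plate table, truth table).

    The plate table is long-format (strain, well, concentration, time_h,
    od660) with conditions 0% and 1% butanol; the truth table records each
    strain's planted class and noise-free index.  Identical specs (same
    seed) reproduce byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    ref = reference_params()
    counts = spec.class_counts()

    classes = np.concatenate(
        [np.repeat(k, n) for k, n in sorted(counts.items())] or [np.array([], dtype=str)]
    )
    classes = classes[rng.permutation(spec.n_strains)]
    # planted noise-free BSI and the implied shared inhibition factor at 1%
    bsi = np.empty(spec.n_strains)
    for klass, (lo, hi) in CLASS_BSI_BANDS.items():
        mask = classes == klass
        bsi[mask] = rng.uniform(lo, hi, mask.sum())
    hyper = classes == "hypersensitive"
    bsi[hyper] = ref.K0 / ref.od0  # non-grower: OD stays at the inoculum
    f = np.where(hyper, 0.0, 1.0 / bsi)

    t = np.arange(0.0, spec.duration_h + 1e-9, spec.interval_min / 60.0)
    T, S, R = len(t), spec.n_strains, spec.replicates
    od_ctrl = np.minimum(ref.od0 * np.exp(ref.mu0 * t), ref.K0)          # (T,)
    grow = ref.od0 * np.exp(ref.mu0 * f[:, None] * t[None, :])           # (S, T)
    od_but = np.where(f[:, None] > 0, np.minimum(grow, ref.K0 * f[:, None]), ref.od0)

    od = np.empty((2, S, R, T))
    od[0] = np.broadcast_to(od_ctrl, (S, R, T))
    od[1] = np.broadcast_to(od_but[:, None, :], (S, R, T))
    if spec.noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, spec.noise_sd, size=od.shape))

    strains = np.array([f"S{i:05d}" for i in range(S)])
    plates = pd.DataFrame(
        {
            "strain": pd.Categorical.from_codes(
                np.tile(np.repeat(np.arange(S), R * T), 2), categories=strains
            ),
            "well": pd.Categorical.from_codes(
                np.tile(np.repeat(np.arange(R), T), 2 * S),
                categories=[f"r{j}" for j in range(R)],
            ),
            "concentration": np.repeat([0.0, 1.0], S * R * T),
            "time_h": np.tile(t, 2 * S * R),
            "od660": od.ravel(),
        }
    )
    truth = pd.DataFrame({"strain": strains, "class": classes, "planted_bsi": bsi})
    return plates, truth


@dataclass(frozen=True)
class SyntheticVariantSpec:
    """Composition of a synthetic resequencing call set.

    genome maps chromosome -> length (bp).  The evolved call set holds
    n_evolved_specific clean evolved-only SNVs, n_parental_shared SNVs also
    present in the parental strain's calls, and n_noise_calls each violating
    exactly one post-calling filter rule (ambiguous base, low quality, or
    out-of-range depth, cycled in that order).  evolved_regions optionally
    confines evolved-specific positions to (chrom, start, end) intervals.
    """

    genome: dict = field(
        default_factory=lambda: {"chrI": 230_000, "chrII": 810_000, "chrIII": 320_000}
    )
    n_evolved_specific: int = 5
    n_parental_shared: int = 10
    n_noise_calls: int = 12
    seed: int = 0
    evolved_regions: tuple = ()

    def __post_init__(self) -> None:
        if min(self.n_evolved_specific, self.n_parental_shared, self.n_noise_calls) < 0:
            raise ValueError("call counts must be >= 0")
        if not self.genome or min(self.genome.values()) < 1:
            raise ValueError("genome must map chromosomes to positive lengths")


_BASES = np.array(list("ACGT"))
_AMBIGUOUS = np.array(list("NRYW"))
NOISE_RULES = ("ambiguous", "quality", "depth")


def _draw_positions(spec, rng, n: int, regions=None, taken=None, max_retries: int = 1000):
    """n unique (chrom, pos) pairs, avoiding ``taken``; error on exhaustion."""
    taken = taken if taken is not None else set()
    chroms = sorted(spec.genome)
    lengths = np.array([spec.genome[c] for c in chroms], dtype=float)
    out = []
    for _ in range(n):
        for attempt in range(max_retries):
            if regions:
                c, lo, hi = regions[rng.integers(len(regions))]
                pos = int(rng.integers(lo, hi + 1))
            else:
                c = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
                pos = int(rng.integers(1, spec.genome[c] + 1))
            if (c, pos) not in taken:
                taken.add((c, pos))
                out.append((c, pos))
                break
        else:
            raise RuntimeError(f"position collision persisted after {max_retries} retries")
    return out


def _clean_call(rng, chrom, pos) -> dict:
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice(_BASES[_BASES != ref]))
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "qual": int(rng.integers(25, 61)),
        "depth": int(rng.integers(20, 101)),
    }


def generate_variants(
    spec: SyntheticVariantSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (evolved calls, parental calls, truth labels).

    Truth labels partition the evolved call set: ``evolved_specific``,
    ``parental_shared``, or ``noise:<rule>`` where <rule> names the single
    filter rule that call violates.
    """
    rng = np.random.default_rng(spec.seed)
    taken: set = set()
    rows, labels = [], []

    for chrom, pos in _draw_positions(
        spec, rng, spec.n_evolved_specific, spec.evolved_regions or None, taken
    ):
        rows.append(_clean_call(rng, chrom, pos))
        labels.append("evolved_specific")

    parental_rows = []
    for chrom, pos in _draw_positions(spec, rng, spec.n_parental_shared, None, taken):
        call = _clean_call(rng, chrom, pos)
        rows.append(call)
        labels.append("parental_shared")
        shared = dict(call)
        shared["qual"] = int(rng.integers(25, 61))
        shared["depth"] = int(rng.integers(20, 101))
        parental_rows.append(shared)

    for i, (chrom, pos) in enumerate(
        _draw_positions(spec, rng, spec.n_noise_calls, None, taken)
    ):
        call = _clean_call(rng, chrom, pos)
        rule = NOISE_RULES[i % len(NOISE_RULES)]
        if rule == "ambiguous":
            call["alt"] = str(rng.choice(_AMBIGUOUS))
        elif rule == "quality":
            call["qual"] = int(rng.integers(0, 20))
        else:  # depth out of [10, 400], alternating low / high
            call["depth"] = (
                int(rng.integers(0, 10)) if i % 2 == 0 else int(rng.integers(401, 601))
            )
        rows.append(call)
        labels.append(f"noise:{rule}")

    cols = ["chrom", "pos", "ref", "alt", "qual", "depth"]
    evolved = pd.DataFrame(rows, columns=cols)
    parental = pd.DataFrame(parental_rows, columns=cols)
    truth = evolved[["chrom", "pos", "ref", "alt"]].copy()
    truth["label"] = labels
    order = ["chrom", "pos"]
    return (
        evolved.sort_values(order, kind="stable").reset_index(drop=True),
        parental.sort_values(order, kind="stable").reset_index(drop=True),
        truth.sort_values(order, kind="stable").reset_index(drop=True),
    )


def generate_go_annotations(
    population,
    planted: dict,
    *,
    n_background_terms: int = 150,
    term_size_range: tuple[int, int] = (5, 80),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Gene->term annotations with planted enriched categories.

    ``planted`` maps term id -> (term name, iterable of member genes); each
    planted term is padded with random population genes up to the low end of
    ``term_size_range`` so its population count is realistic.  Background
    terms annotate random gene subsets.  Returns (annotation table with
    columns gene/term, is_a edge table with columns child/parent, term-name
    map).  The hierarchy is a small DAG: one root, one intermediate parent
    over the planted terms, background terms directly under the root.
    """
    rng = np.random.default_rng(seed)
    population = list(population)
    root, stem = "GO:9000000", "GO:9000001"
    names = {root: "biological_process", stem: "protein catabolic process"}
    edges = [(stem, root)]
    ann: list[tuple[str, str]] = []

    pad_to = term_size_range[0] + (term_size_range[1] - term_size_range[0]) // 2
    for term, (name, genes) in planted.items():
        names[term] = name
        edges.append((term, stem))
        members = set(genes)
        extra = [g for g in population if g not in members]
        n_pad = max(0, pad_to - len(members))
        members |= set(rng.choice(extra, size=min(n_pad, len(extra)), replace=False))
        ann.extend((g, term) for g in sorted(members))

    for i in range(n_background_terms):
        term = f"GO:8{i:06d}"
        names[term] = f"background process {i}"
        edges.append((term, root))
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(population, size=min(size, len(population)), replace=False)
        ann.extend((g, term) for g in sorted(members))

    annotations = pd.DataFrame(ann, columns=["gene", "term"])
    edge_df = pd.DataFrame(edges, columns=["child", "parent"])
    return annotations, edge_df, names
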