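"""Plate-screen analysis: sensitivity index, classification, growth-rate fits.

The screen compares each deletion strain's 48-h OD660 without solvent to its
48-h OD660 with 1% n-butanol.  The butanol sensitivity index

    BSI = OD660(48 h, 0% butanol) / OD660(48 h, 1% butanol)

is ~2 for the reference background, between 2 and 10 for sensitive strains
that still grow at 1% (final OD > 0.1), and above 10 for hypersensitive
strains that fail to grow (final OD < 0.08).  Strains with BSI between 1
and 2 would be more tolerant than the reference.  The thresholds leave
deliberate gaps (OD in [0.08, 0.1]); records falling there are classed
``indeterminate`` rather than silently binned.

Replicates are aggregated by taking the BSI of the replicate-mean ODs, not
the mean of per-replicate BSIs: the ratio of means is far less sensitive to
a single near-zero butanol well than the mean of ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthCurve

__all__ = [
    "SENSITIVITY_CLASSES",
    "StrainScreenRecord",
    "GrowthFit",
    "TriageSummary",
    "compute_bsi",
    "classify_strain",
    "fit_growth_rate",
    "screen_plates",
    "triage_screen",
]

SENSITIVITY_CLASSES = (
    "tolerant",
    "reference_like",
    "sensitive",
    "hypersensitive",
    "indeterminate",
)

#: default BSI denominator floor (OD units) making non-growers finite and sortable
DEFAULT_FLOOR = 0.01
#: half-width of the reference-like tie band around BSI = 2
DEFAULT_REFERENCE_DELTA = 0.25


def compute_bsi(od_control: float, od_butanol: float, floor: float = DEFAULT_FLOOR) -> float:
    """Sensitivity index: 48-h OD without butanol over 48-h OD with 1% butanol.

    The denominator is floored at ``floor`` so wells with no measurable
    growth yield a large finite index instead of dividing by zero.
    """
    if not od_control > 0:
        raise ValueError(
            f"control well OD must be positive (dead/failed control), got {od_control}"
        )
    if od_butanol < 0:
        raise ValueError(f"butanol well OD must be >= 0, got {od_butanol}")
    return od_control / max(od_butanol, floor)


def classify_strain(
    bsi: float,
    od_butanol: float,
    *,
    reference_delta: float = DEFAULT_REFERENCE_DELTA,
) -> str:
    """Assign one of the five sensitivity classes from (BSI, final butanol OD).

    Precedence in the band overlaps: the reference tie band [2-d, 2+d] is
    checked first, then hypersensitive (BSI > 10 and OD < 0.08), sensitive
    (2 < BSI <= 10 and OD > 0.1), tolerant (1 <= BSI < 2); anything left
    (including the deliberate OD gap [0.08, 0.1] and BSI < 1) is
    indeterminate.  Every record receives exactly one class.
    """
    if abs(bsi - 2.0) <= reference_delta:
        return "reference_like"
    if bsi > 10 and od_butanol < 0.08:
        return "hypersensitive"
    if 2 < bsi <= 10 and od_butanol > 0.1:
        return "sensitive"
    if 1 <= bsi < 2:
        return "tolerant"
    return "indeterminate"


@dataclass(frozen=True)
class StrainScreenRecord:
    """Per-strain screen outcome: replicate-mean 48-h ODs, BSI and class."""

    strain: str
    od_final_control: float
    od_final_butanol: float
    bsi: float
    n_replicates: int
    sensitivity_class: str

    @classmethod
    def from_ods(
        cls,
        strain: str,
        od_control: float,
        od_butanol: float,
        n_replicates: int = 1,
        *,
        floor: float = DEFAULT_FLOOR,
        reference_delta: float = DEFAULT_REFERENCE_DELTA,
    ) -> "StrainScreenRecord":
        bsi = compute_bsi(od_control, od_butanol, floor)
        klass = classify_strain(bsi, od_butanol, reference_delta=reference_delta)
        return cls(strain, od_control, od_butanol, bsi, n_replicates, klass)


@dataclass(frozen=True)
class GrowthFit:
    mu: float              # apparent specific growth rate, h^-1
    window: tuple[float, float]  # [t_start, t_end] of the fitted window, hours
    r2: float
    non_grower: bool = False


def fit_growth_rate(
    curve: GrowthCurve,
    window_points: int = 8,
    detection_od: float = 0.05,
) -> GrowthFit:
    """Maximal log-linear slope over a sliding window of ``window_points`` readings.

    mu is the largest slope of ln(OD) over any contiguous window whose
    readings all exceed ``detection_od``; r2 is that window's linear-fit
    quality.  With no such window the well is flagged a non-grower (mu = 0).
    The early exponential phase of either trajectory shape is log-linear, so
    the estimator recovers mu(c) exactly on noise-free curves.
    """
    if window_points < 2:
        raise ValueError("window_points must be >= 2")
    t, y = curve.times, curve.od
    above = y > detection_od
    best = None
    n = len(t)
    for i in range(0, n - window_points + 1):
        j = i + window_points
        if not above[i:j].all():
            continue
        tw, lw = t[i:j], np.log(y[i:j])
        slope, intercept = np.polyfit(tw, lw, 1)
        pred = slope * tw + intercept
        ss_res = float(np.sum((lw - pred) ** 2))
        ss_tot = float(np.sum((lw - lw.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        if best is None or slope > best[0]:
            best = (slope, (float(tw[0]), float(tw[-1])), r2)
    if best is None or best[0] <= 0:
        window = best[1] if best else (float(t[0]), float(t[-1]))
        return GrowthFit(mu=0.0, window=window, r2=0.0, non_grower=True)
    return GrowthFit(mu=float(best[0]), window=best[1], r2=best[2])


def screen_plates(
    plates: pd.DataFrame,
    *,
    control_concentration: float = 0.0,
    test_concentration: float = 1.0,
    endpoint_h: float = 48.0,
    floor: float = DEFAULT_FLOOR,
    reference_delta: float = DEFAULT_REFERENCE_DELTA,
) -> pd.DataFrame:
    """Reduce a long-format plate table to one screen record per strain.

    ``plates`` columns: strain, well, concentration, time_h, od660 (the
    long-format dialect written by the synthetic screen generator).  Per
    strain and condition, the reading nearest ``endpoint_h`` in each well is
    averaged over replicate wells; the BSI of those replicate means is then
    computed and classified.  Returns a frame with columns strain,
    od_control, od_butanol, bsi, class, n_replicates.
    """
    required = {"strain", "well", "concentration", "time_h", "od660"}
    missing = required - set(plates.columns)
    if missing:
        raise ValueError(f"plate table lacks columns: {sorted(missing)}")
    # endpoint reading per well = reading at the time closest to endpoint_h
    idx = (
        (plates["time_h"] - endpoint_h)
        .abs()
        .groupby(
            [plates["strain"], plates["concentration"], plates["well"]], observed=True
        )
        .idxmin()
    )
    finals = plates.loc[idx.to_numpy()]
    means = (
        finals.groupby(["strain", "concentration"], observed=True)["od660"]
        .agg(["mean", "size"])
        .reset_index()
    )
    rows = []
    for strain, grp in means.groupby("strain", sort=True, observed=True):
        grp = grp.set_index("concentration")
        if control_concentration not in grp.index or test_concentration not in grp.index:
            raise ValueError(f"strain {strain!r} lacks one of the two screen conditions")
        odc = float(grp.loc[control_concentration, "mean"])
        odb = float(grp.loc[test_concentration, "mean"])
        nrep = int(grp["size"].min())
        rec = StrainScreenRecord.from_ods(
            str(strain), odc, odb, nrep, floor=floor, reference_delta=reference_delta
        )
        rows.append(
            {
                "strain": rec.strain,
                "od_control": rec.od_final_control,
                "od_butanol": rec.od_final_butanol,
                "bsi": rec.bsi,
                "class": rec.sensitivity_class,
                "n_replicates": rec.n_replicates,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TriageSummary:
    """Bookkeeping of the hypersensitive-hit confirmation in a second background.

    Hits found in the primary screen background are re-made in a second
    genetic background, excluding dubious ORFs and adding a few extra picks;
    some transformations fail; the remainder are re-scored and only a subset
    confirms.  n_tested = |hits| - |dubious| + |extra|; n_viable = n_tested -
    |failures|; n_confirmed = |confirmed ∩ viable|.
    """

    hits: frozenset
    dubious_orfs: frozenset
    extra_picks: frozenset
    transformation_failures: frozenset
    confirmed: frozenset
    n_hits: int = field(init=False)
    n_tested: int = field(init=False)
    n_viable: int = field(init=False)
    n_confirmed: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_hits", len(self.hits))
        object.__setattr__(self, "n_tested", len(self.tested_set))
        object.__setattr__(self, "n_viable", len(self.viable_set))
        object.__setattr__(self, "n_confirmed", len(self.confirmed & self.viable_set))

    @property
    def tested_set(self) -> frozenset:
        return (self.hits - self.dubious_orfs) | self.extra_picks

    @property
    def viable_set(self) -> frozenset:
        return self.tested_set - self.transformation_failures


def triage_screen(
    hits,
    dubious_orfs=(),
    extra_picks=(),
    transformation_failures=(),
    confirmed=(),
) -> TriageSummary:
    """Validate the gene lists and tally the triage counts.

    ``dubious_orfs`` must be a subset of ``hits``; ``extra_picks`` must not
    overlap ``hits`` (they are additions beyond the primary hit list).
    """
    hits = frozenset(hits)
    dubious = frozenset(dubious_orfs)
    extra = frozenset(extra_picks)
    failures = frozenset(transformation_failures)
    confirmed = frozenset(confirmed)
    if not dubious <= hits:
        raise ValueError(f"dubious ORFs not among hits: {sorted(dubious - hits)}")
    if extra & hits:
        raise ValueError(f"extra picks overlap hits: {sorted(extra & hits)}")
    return TriageSummary(hits, dubious, extra, failures, confirmed)
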