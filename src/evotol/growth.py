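"""Dose-dependent batch-growth model for solvent-inhibition plate cultures.

A strain growing in a sealed microtiter well is described by a maximal
specific growth rate ``mu0`` and an unstressed stationary OD ``K0``.  Butanol
at concentration ``c`` (% v/v) scales *both* down by one shared Hill-type
inhibition factor

    f(c) = max(0, 1 - (c / c_max) ** h)

so that mu(c) = mu0 * f(c) and K(c) = K0 * f(c).  ``c_max`` is the
concentration at which growth ceases entirely and ``h`` sets how sharply
inhibition turns on.  Because sealed-plate cultures exhaust their glucose
well within the 48-h incubation, the noise-free trajectory is modelled as
exponential growth at mu(c) capped at the carrying capacity K(c): the 48-h
OD *equals* K(c) whenever the culture has time to reach stationary phase,
which makes stationary-phase OD ratios exact.  A smooth logistic trajectory
(which only approaches K asymptotically) is available via ``shape``.

Calibration is anchored to two observable quantities: the ratio of the
unstressed 48-h OD to the 48-h OD at 1% butanol (the sensitivity index of
the screen), and the lowest concentration at which no growth occurs.  Both
pin down ``h`` in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseParams",
    "GrowthCurve",
    "inhibition_factor",
    "calibrate_reference",
    "generate_growth_curve",
]


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of the shared-factor Hill dose-response growth model.

    mu0
        maximal specific growth rate without solvent (h^-1)
    K0
        unstressed stationary-phase OD660 (carrying capacity)
    c_max
        solvent concentration at which growth ceases (% v/v)
    h
        Hill steepness of the inhibition factor (dimensionless)
    od0
        inoculum OD660
    noise_sd
        sigma of the multiplicative lognormal reading noise (0 = noise-free)
    """

    mu0: float
    K0: float
    c_max: float
    h: float
    od0: float = 0.05
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if not (self.K0 > self.od0 > 0):
            raise ValueError(f"need K0 > od0 > 0, got K0={self.K0}, od0={self.od0}")
        if not self.c_max > 0:
            raise ValueError(f"c_max must be positive, got {self.c_max}")
        if not self.h > 0:
            raise ValueError(f"h must be positive, got {self.h}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def with_noise(self, noise_sd: float) -> "DoseResponseParams":
        return replace(self, noise_sd=noise_sd)


@dataclass(frozen=True)
class GrowthCurve:
    """One well's blank-corrected OD660 time series at a fixed concentration."""

    strain: str
    concentration: float
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray     # OD660 readings, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and od must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("od readings must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)

    @property
    def od_final(self) -> float:
        return float(self.od[-1])

    def to_frame(self, well: str = "A1") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": self.strain,
                "well": well,
                "concentration": self.concentration,
                "time_h": self.times,
                "od660": self.od,
            }
        )


def inhibition_factor(params: DoseResponseParams, concentration: float) -> float:
    """Shared Hill factor f(c) scaling both growth rate and plateau; in [0, 1]."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return max(0.0, 1.0 - (concentration / params.c_max) ** params.h)


def calibrate_reference(
    target_od_ratio_at_1pct: float,
    c_no_growth: float,
    *,
    mu0: float = 0.40,
    K0: float = 1.0,
    od0: float = 0.05,
    noise_sd: float = 0.0,
) -> DoseResponseParams:
    """Solve the Hill steepness so the model matches two plate observables.

    The anchors are the stationary-OD ratio control/1%-butanol
    (``target_od_ratio_at_1pct``; the reference strain of the screen shows 2.0,
    i.e. a 50% OD reduction at 1% butanol) and the lowest concentration with
    no growth (``c_no_growth``, observed near 1.45-1.57% v/v).  With
    K(c) = K0 * (1 - (c/c_max)**h) and c_max = c_no_growth:

        K0 / K(1) = ratio  =>  h = log(1 - 1/ratio) / log(1 / c_max)

    which is well-defined (h > 0) exactly when ratio > 1 and c_no_growth > 1.
    """
    r = float(target_od_ratio_at_1pct)
    c = float(c_no_growth)
    if not r > 1:
        raise ValueError(
            f"target OD ratio must exceed 1 (some inhibition at 1%), got {r}"
        )
    if not c > 1:
        raise ValueError(f"no-growth concentration must exceed 1% v/v, got {c}")
    h = math.log(1.0 - 1.0 / r) / math.log(1.0 / c)
    return DoseResponseParams(mu0=mu0, K0=K0, c_max=c, h=h, od0=od0, noise_sd=noise_sd)


def _trajectory(
    params: DoseResponseParams, concentration: float, t: np.ndarray, shape: str
) -> np.ndarray:
    f = inhibition_factor(params, concentration)
    mu = params.mu0 * f
    K = params.K0 * f
    if f <= 0 or K <= params.od0:
        # fully inhibited (or plateau at/below inoculum): the well sits at od0
        return np.full_like(t, params.od0)
    if shape == "batch":
        return np.minimum(params.od0 * np.exp(mu * t), K)
    if shape == "logistic":
        a = (K - params.od0) / params.od0
        return K / (1.0 + a * np.exp(-mu * t))
    raise ValueError(f"unknown trajectory shape {shape!r}")


def generate_growth_curve(
    params: DoseResponseParams,
    concentration: float,
    *,
    duration: float = 48.0,
    interval: float = 30.0,
    seed: int | None = None,
    strain: str = "strain",
    shape: str = "batch",
) -> GrowthCurve:
    """Simulate one well: OD660 every ``interval`` minutes for ``duration`` hours.

    Noise-free output is deterministic and monotone non-decreasing with
    OD(0) = od0.  When ``noise_sd > 0``, each reading is multiplied by an
    independent lognormal factor exp(N(0, noise_sd)) drawn from a generator
    seeded with ``seed`` (bit-for-bit reproducible).
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if interval <= 0:
        raise ValueError(f"interval must be positive minutes, got {interval}")
    t = np.arange(0.0, duration + 1e-9, interval / 60.0)
    od = _trajectory(params, concentration, t, shape)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od * np.exp(rng.normal(0.0, params.noise_sd, size=od.shape))
    return GrowthCurve(strain=strain, concentration=concentration, times=t, od=od)
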