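"""Reduction of three-point bending tests on slender stems.

A stem segment rests on two supports a span l apart and is loaded at midspan
by a series of weights; the slope b of the force (N) vs. midspan deflection
(mm) line gives the flexural stiffness

    EI = l^3 b / 48        (N mm^2),

the cross section is approximated as an ellipse whose second moment of area
about the horizontal axis is

    I = (pi/4) a^3 b_h     (mm^4),

with a and b_h the mean vertical (load-direction) and horizontal semi-axes of
three caliper measurements (center, 25% proximal, 25% distal), and the
structural Young's modulus is E = EI / I in MPa (N mm^2 / mm^4 = N/mm^2).

Shear deflection contaminates EI at small span-to-depth ratios; the
span-to-depth screening analysis locates the smallest tested ratio at which
the apparent modulus has plateaued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from stemflex.morpho import ellipse_I

#: midspan deflections outside this window (mm) flag a possible departure
#: from the small-deflection elastic regime (typical good tests deflect 1-3 mm)
ELASTIC_WINDOW_MM = (0.2, 5.0)

#: force-deflection fits below this R^2 are flagged as suspect
R2_WARN = 0.99


@dataclass
class BendingTest:
    """One three-point bending record.

    ``a_semi`` / ``b_semi`` are the three caliper measurements of the vertical
    and horizontal semi-axes (center, proximal, distal), in mm. ``points`` is
    the loading sequence of (cumulative force N, midspan deflection mm).
    """

    span: float
    a_semi: tuple[float, float, float]
    b_semi: tuple[float, float, float]
    points: list[tuple[float, float]]
    specimen_id: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError("span must be positive")
        if len(self.points) < 3:
            raise ValueError("need at least 3 loading points")
        F = np.array([f for f, _ in self.points])
        if not (np.diff(F) > 0).all():
            raise ValueError("forces must be strictly increasing")
        if min(self.a_semi) <= 0 or min(self.b_semi) <= 0:
            raise ValueError("all caliper radii must be positive")

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.a_semi))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.b_semi))

    @property
    def depth(self) -> float:
        """Specimen depth along the load: vertical diameter 2*mean(a)."""
        return 2.0 * self.mean_a


@dataclass
class MechanicalTraits:
    """Derived mechanical traits of one bending test."""

    slope: float          # N/mm
    EI: float             # N mm^2
    I: float              # mm^4
    E: float              # MPa
    diameter: float       # mm, mean of vertical and horizontal diameters
    span_to_depth: float
    r_squared: float
    flags: list[str] = field(default_factory=list)
    specimen_id: str | None = None


def fit_slope(points) -> tuple[float, float]:
    """Least-squares slope of force against deflection.

    The intercept is fitted (pannier settling offsets are absorbed) and only
    the slope is returned, with the R^2 of the fit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 loading points")
    F, d = pts[:, 0], pts[:, 1]
    if np.ptp(d) == 0:
        raise ValueError("deflections have zero variance; cannot fit a slope")
    res = _sps.linregress(d, F)
    r2 = float(res.rvalue ** 2)
    return float(res.slope), r2


def flexural_stiffness(span: float, slope: float) -> float:
    """EI = l^3 b / 48 in N mm^2."""
    if span <= 0 or slope <= 0:
        raise ValueError("span and slope must be positive")
    return span ** 3 * slope / 48.0


def caliper_ellipse_I(a_semi, b_semi) -> float:
    """Elliptical I from three caliper measurements of each semi-axis.

    I = (pi/4) abar^3 bbar with arithmetic means of the three vertical (a) and
    horizontal (b) semi-axis measurements.
    """
    a = np.asarray(a_semi, dtype=float)
    b = np.asarray(b_semi, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("caliper radii must be positive")
    return ellipse_I(float(a.mean()), float(b.mean()))


def youngs_modulus(EI: float, I: float) -> float:
    """Structural Young's modulus E = EI / I (MPa)."""
    if I <= 0:
        raise ValueError("I must be positive")
    return EI / I


def reduce_test(test: BendingTest) -> MechanicalTraits:
    """Full reduction of one bending record: slope -> EI -> I -> E.

    Flags (non-fatal) are carried over from the record and extended with a
    low-R^2 warning when the force-deflection fit has R^2 < 0.99, which
    usually indicates loading beyond the elastic regime.
    """
    slope, r2 = fit_slope(test.points)
    EI = flexural_stiffness(test.span, slope)
    I = caliper_ellipse_I(test.a_semi, test.b_semi)
    E = youngs_modulus(EI, I)
    flags = list(test.flags)
    if r2 < R2_WARN:
        flags.append("low_r_squared")
    return MechanicalTraits(
        slope=slope, EI=EI, I=I, E=E,
        diameter=test.mean_a + test.mean_b,
        span_to_depth=test.span / test.depth,
        r_squared=r2, flags=flags, specimen_id=test.specimen_id,
    )


@dataclass
class SpanTestResult:
    """Outcome of a span-to-depth screening series."""

    ratios: np.ndarray          # tested span-to-depth ratios, ascending
    apparent_E: np.ndarray      # apparent modulus per ratio (MPa)
    threshold: float | None     # smallest adequate ratio, None if none qualify
    adequate: bool

    def __iter__(self):  # convenience unpacking
        yield self.threshold
        yield self.adequate


def span_to_depth_analysis(tests: list[BendingTest],
                           plateau_frac: float = 0.95) -> SpanTestResult:
    """Find the minimal adequate span-to-depth ratio from a span-test series.

    The same stem region is tested at several spans; shear deflection deflates
    the apparent modulus at short spans. Returns the smallest tested ratio s
    whose apparent E(s) is at least ``plateau_frac`` of the apparent E at the
    largest tested span. The largest span always matches itself, so a plateau
    is only considered confirmed when some *shorter* span also qualifies; if
    none does, every tested span is still shear-affected and the series is
    flagged inadequate with no ratio returned.
    """
    if len(tests) < 3:
        raise ValueError("need at least 3 spans for a span test")
    spans = [t.span for t in tests]
    if len(set(spans)) != len(spans):
        raise ValueError("spans must be distinct")
    traits = sorted((reduce_test(t) for t in tests), key=lambda m: m.span_to_depth)
    ratios = np.array([m.span_to_depth for m in traits])
    E = np.array([m.E for m in traits])
    qualify = E >= plateau_frac * E[-1]
    first = int(np.argmax(qualify))
    if first == len(ratios) - 1:
        return SpanTestResult(ratios, E, None, False)
    return SpanTestResult(ratios, E, float(ratios[first]), True)


def aggregate_traits(traits: list[MechanicalTraits]) -> dict[str, float]:
    """Per-specimen aggregate (mean) of one to seven bending tests."""
    if not traits:
        raise ValueError("no traits to aggregate")
    return {
        "n_tests": len(traits),
        "EI": float(np.mean([m.EI for m in traits])),
        "I": float(np.mean([m.I for m in traits])),
        "E": float(np.mean([m.E for m in traits])),
        "diameter": float(np.mean([m.diameter for m in traits])),
    }
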