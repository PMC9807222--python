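"""Synthetic stem cross sections and bending records with known ground truth.

Emulates the four growth categories of a liana trellis — self-supporting,
pendulous, climbing, and fixed stems — as nested concentric elliptical tissue
regions (pith, TYPE I wood, TYPE II lianoid wood, cortex). TYPE II wood can be
absent, a set of discontinuous lobes at the periphery of the TYPE I cylinder
(early attachment / pendulous pockets), or a complete ring (established
climbing and fixed stems). Bending records are simulated from a ground-truth
flexural stiffness with an optional Timoshenko shear term and Gaussian
measurement noise, so the forward model inverts exactly under the standard
three-point reduction when noise and shear are off.

Geometry conventions
--------------------
All region boundaries are similar ellipses sharing the aspect ratio
``ellipse_ratio`` = b/a of the outer boundary, with ``a`` the vertical
(load-direction) semi-axis. ``outer_diameter`` is the vertical diameter 2a.
Lobe angular extents are expressed in the parametric angle of the ellipse
(phi such that a point is (b rho cos phi, a rho sin phi)); with this
convention sector areas and second moments have exact closed forms that the
rasterizer reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from stemflex.morpho import LABELS, LabeledSection, TISSUES
from stemflex.mech import BendingTest, ELASTIC_WINDOW_MM

G_MS2 = 9.81  # standard gravity, converts pannier masses (kg) to forces (N)

CATEGORIES = ("self-supporting", "pendulous", "climbing", "fixed")


class InfeasibleLayout(ValueError):
    """Requested tissue fractions cannot be realized by the layout geometry."""


@dataclass(frozen=True)
class LayoutSpec:
    """Target geometry of one synthetic cross section.

    ``target_fractions`` are the (pith, wood1, wood2, cortex) area fractions,
    summing to 1. ``wood2_mode`` selects how the TYPE II wood fraction is
    realized: ``"none"`` (fraction must be 0), ``"lobes"`` (``lobe_count``
    arcs of ``lobe_arc`` degrees each within the wood annulus, remainder
    assigned to TYPE I wood), or ``"ring"`` (complete annulus).
    """

    category: str
    outer_diameter: float                      # mm, vertical diameter
    target_fractions: tuple[float, float, float, float]
    ellipse_ratio: float = 1.0                 # b/a of the outer boundary
    wood2_mode: str = "ring"
    lobe_count: int = 0
    lobe_arc: float = 0.0                      # degrees per lobe
    lobe_phase: float = 0.0                    # degrees, rotation of the lobe set

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.outer_diameter <= 0:
            raise ValueError("outer_diameter must be positive")
        f = np.asarray(self.target_fractions, dtype=float)
        if f.shape != (4,) or (f < 0).any() or (f > 1).any():
            raise ValueError("target_fractions must be four proportions in [0,1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("target_fractions must sum to 1 within 1e-9")
        if not 0 < self.ellipse_ratio <= 1:
            raise ValueError("ellipse_ratio must lie in (0, 1]")
        if self.wood2_mode not in ("none", "lobes", "ring"):
            raise ValueError(f"unknown wood2_mode {self.wood2_mode!r}")
        if self.lobe_count < 0 or self.lobe_arc < 0:
            raise ValueError("lobe_count and lobe_arc must be non-negative")
        if self.lobe_count * self.lobe_arc > 360 + 1e-9:
            raise ValueError("total lobe arc exceeds 360 degrees")


@dataclass(frozen=True)
class TissueLayout:
    """Realized nested-ellipse geometry of a cross section.

    ``a`` holds the four vertical semi-axes of the pith/wood1, wood1/wood2,
    wood2/cortex and cortex/outside boundaries (mm, non-decreasing);
    horizontal semi-axes are ``ratio * a``. ``lobes`` holds the parametric
    angle intervals (radians) occupied by TYPE II wood when discontinuous.
    """

    a: tuple[float, float, float, float]
    ratio: float
    wood2_mode: str
    lobes: tuple[tuple[float, float], ...] = ()
    category: str = "self-supporting"

    @property
    def b(self) -> tuple[float, ...]:
        return tuple(self.ratio * ai for ai in self.a)

    @property
    def outer_diameter(self) -> float:
        return 2.0 * self.a[3]

    def _lobe_arc_fraction(self) -> float:
        return sum(hi - lo for lo, hi in self.lobes) / (2 * math.pi)

    def tissue_areas(self) -> dict[str, float]:
        """Closed-form tissue areas in mm^2."""
        r = self.ratio
        ann = [math.pi * r * (self.a[i] ** 2 - (self.a[i - 1] ** 2 if i else 0.0))
               for i in range(4)]
        wood_ann = ann[2]
        if self.wood2_mode == "ring":
            w2, extra_w1 = wood_ann, 0.0
        elif self.wood2_mode == "none":
            w2, extra_w1 = 0.0, wood_ann
        else:
            frac = self._lobe_arc_fraction()
            w2, extra_w1 = wood_ann * frac, wood_ann * (1 - frac)
        return {"pith": ann[0], "wood1": ann[1] + extra_w1, "wood2": w2,
                "cortex": ann[3]}

    def tissue_second_moments(self) -> dict[str, float]:
        """Closed-form second moments (mm^4) about the horizontal axis.

        Annulus: (pi/4) r (a_o^4 - a_i^4). Parametric-angle sector of an
        annulus: (r a_o^4/4 - r a_i^4/4) * [phi/2 - sin(2 phi)/4] evaluated
        over the interval.
        """
        r = self.ratio
        a = (0.0,) + self.a

        def annulus_I(i_out: int, i_in: int) -> float:
            return math.pi / 4.0 * r * (a[i_out] ** 4 - a[i_in] ** 4)

        def sector_weight(lo: float, hi: float) -> float:
            f = lambda p: p / 2.0 - math.sin(2 * p) / 4.0
            return f(hi) - f(lo)

        wood_ann = annulus_I(3, 2)
        if self.wood2_mode == "ring":
            w2, extra_w1 = wood_ann, 0.0
        elif self.wood2_mode == "none":
            w2, extra_w1 = 0.0, wood_ann
        else:
            quarter = r * (a[3] ** 4 - a[2] ** 4) / 4.0
            w2 = sum(quarter * sector_weight(lo, hi) for lo, hi in self.lobes)
            extra_w1 = wood_ann - w2
        return {"pith": annulus_I(1, 0), "wood1": annulus_I(2, 1) + extra_w1,
                "wood2": w2, "cortex": annulus_I(4, 3)}

    def total_I(self) -> float:
        return math.pi / 4.0 * self.ratio * self.a[3] ** 4

    def total_area(self) -> float:
        return math.pi * self.ratio * self.a[3] ** 2


def build_layout(spec: LayoutSpec) -> TissueLayout:
    """Realize a LayoutSpec as nested ellipse boundaries.

    Boundary semi-axes follow from cumulative area fractions
    (a_i = a_outer * sqrt(cum_i)); in lobe mode the wood1/wood2 boundary is
    pushed inward so that the lobe arcs alone hold the TYPE II fraction.

    Raises
    ------
    InfeasibleLayout
        If the TYPE II fraction cannot be realized in the requested mode
        (nonzero fraction with mode "none" or zero total lobe arc, or lobes
        too narrow so the wood1/wood2 boundary would fall inside the pith).
    """
    f_pith, f_w1, f_w2, f_cortex = spec.target_fractions
    a4 = spec.outer_diameter / 2.0
    a1 = a4 * math.sqrt(f_pith)
    a3 = a4 * math.sqrt(f_pith + f_w1 + f_w2)
    lobes: tuple[tuple[float, float], ...] = ()

    if spec.wood2_mode == "none":
        if f_w2 > 1e-12:
            raise InfeasibleLayout(
                "wood2_mode='none' cannot realize a nonzero TYPE II fraction")
        a2 = a3
    elif spec.wood2_mode == "ring":
        a2 = a4 * math.sqrt(f_pith + f_w1)
    else:  # lobes
        arc_total = spec.lobe_count * spec.lobe_arc
        if f_w2 > 1e-12 and arc_total <= 0:
            raise InfeasibleLayout(
                "lobe mode with zero total arc cannot hold a TYPE II fraction")
        if f_w2 <= 1e-12:
            a2 = a3
        else:
            a2_sq = a3 ** 2 - f_w2 * a4 ** 2 * (360.0 / arc_total)
            if a2_sq < a1 ** 2 - 1e-12:
                raise InfeasibleLayout(
                    "lobe arcs too narrow: wood1/wood2 boundary would fall "
                    "inside the pith; increase lobe_count or lobe_arc")
            a2 = math.sqrt(max(a2_sq, a1 ** 2))
        if spec.lobe_count > 0 and spec.lobe_arc > 0:
            half = math.radians(spec.lobe_arc) / 2.0
            centers = (np.arange(spec.lobe_count) * 2 * math.pi / spec.lobe_count
                       + math.radians(spec.lobe_phase))
            lobes = tuple((float(c - half), float(c + half)) for c in centers)

    return TissueLayout(a=(a1, a2, a3, a4), ratio=spec.ellipse_ratio,
                        wood2_mode=spec.wood2_mode, lobes=lobes,
                        category=spec.category)


def rasterize(layout: TissueLayout, pixel_size: float,
              pad_pixels: int = 2, specimen_id: str | None = None) -> LabeledSection:
    """Rasterize a layout to a labeled image by pixel-center membership.

    Each pixel takes the label of the region containing its center point (no
    anti-aliasing); the canvas pads the section by at least ``pad_pixels``
    background pixels on every side.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    max_px = layout.outer_diameter / 20.0
    if pixel_size > max_px:
        raise ValueError(
            f"pixel_size {pixel_size} mm too coarse; need <= outer_diameter/20 "
            f"= {max_px} mm")
    a4, b4 = layout.a[3], layout.b[3]
    nrows = int(math.ceil(2 * a4 / pixel_size)) + 2 * pad_pixels
    ncols = int(math.ceil(2 * b4 / pixel_size)) + 2 * pad_pixels
    yc, xc = nrows * pixel_size / 2.0, ncols * pixel_size / 2.0
    y = (np.arange(nrows) + 0.5) * pixel_size - yc
    x = (np.arange(ncols) + 0.5) * pixel_size - xc
    YY, XX = np.meshgrid(y / a4, x / b4, indexing="ij")  # normalized coords
    rho = np.hypot(YY, XX)

    rho_b = np.array(layout.a) / a4  # boundary radii in normalized units
    labels = np.zeros((nrows, ncols), dtype=np.uint8)
    inside = rho <= 1.0
    labels[inside] = LABELS["cortex"]
    labels[rho <= rho_b[2]] = LABELS["wood2"] if layout.wood2_mode == "ring" \
        else LABELS["wood1"]
    if layout.wood2_mode == "lobes" and layout.lobes:
        in_ann = (rho > rho_b[1]) & (rho <= rho_b[2])
        phi = np.mod(np.arctan2(YY, XX), 2 * math.pi)
        in_lobe = np.zeros_like(in_ann)
        for lo, hi in layout.lobes:
            lo_m, hi_m = lo % (2 * math.pi), hi % (2 * math.pi)
            if lo_m <= hi_m:
                in_lobe |= (phi >= lo_m) & (phi < hi_m)
            else:  # interval wraps through 0
                in_lobe |= (phi >= lo_m) | (phi < hi_m)
        labels[in_ann & in_lobe] = LABELS["wood2"]
    labels[rho <= rho_b[1]] = LABELS["wood1"]
    labels[rho <= rho_b[0]] = LABELS["pith"]
    return LabeledSection(labels=labels, pixel_size=pixel_size,
                          specimen_id=specimen_id)


# ---------------------------------------------------------------------------
# bending-test simulation

@dataclass(frozen=True)
class ShearModel:
    """Timoshenko midspan shear term for three-point bending.

    delta_shear = f_s F l / (4 G A); with G = E / e_over_g and the circular
    relation I/A = depth^2/16 this reduces to
    delta_shear = f_s * F * l * e_over_g * depth^2 / (64 EI),
    which only needs the specimen depth and the ground-truth EI.
    """

    e_over_g: float = 20.0
    shear_factor: float = 10.0 / 9.0   # circular cross section
    depth: float = 0.0                 # mm; 0 disables the term

    def deflection(self, F: np.ndarray, span: float, EI: float) -> np.ndarray:
        if self.depth <= 0:
            return np.zeros_like(F)
        return (self.shear_factor * F * span * self.e_over_g * self.depth ** 2
                / (64.0 * EI))


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: deflection readings and caliper radii (mm SD)."""

    deflection_sd: float = 0.0
    radius_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.deflection_sd < 0 or self.radius_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_bending(EI_true: float, span: float, masses,
                     shear: ShearModel | None = None,
                     noise: NoiseModel | None = None,
                     rng: np.random.Generator | None = None,
                     a_semi: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     b_semi: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     specimen_id: str | None = None,
                     elastic_window: tuple[float, float] = ELASTIC_WINDOW_MM,
                     ) -> BendingTest:
    """Forward-simulate one three-point bending record.

    Weights are added cumulatively: F_k = g * sum(masses[:k+1]); the
    noiseless midspan deflection is delta_k = F_k l^3 / (48 EI) plus the
    optional shear term. Deflections landing outside ``elastic_window``
    (default 0.2-5 mm) set an ``elastic_window`` warning flag on the record
    rather than rejecting it. A noiseless, shear-free record inverts exactly
    under EI = l^3 b / 48.
    """
    masses = np.asarray(masses, dtype=float)
    if not 3 <= masses.size <= 7:
        raise ValueError("need between 3 and 7 loading steps")
    if (masses <= 0).any():
        raise ValueError("masses must be positive")
    if EI_true <= 0 or span <= 0:
        raise ValueError("EI_true and span must be positive")
    F = G_MS2 * np.cumsum(masses)
    delta = F * span ** 3 / (48.0 * EI_true)
    if shear is not None:
        delta = delta + shear.deflection(F, span, EI_true)
    flags = []
    if (delta < elastic_window[0]).any() or (delta > elastic_window[1]).any():
        flags.append("elastic_window")
    if noise is not None and noise.deflection_sd > 0:
        if rng is None:
            raise ValueError("rng required for noisy simulation")
        delta = delta + rng.normal(0.0, noise.deflection_sd, size=delta.shape)
    return BendingTest(span=span, a_semi=tuple(a_semi), b_semi=tuple(b_semi),
                       points=list(zip(F.tolist(), delta.tolist())),
                       specimen_id=specimen_id, flags=flags)


# ---------------------------------------------------------------------------
# cohort generation

#: per-category mean tissue area fractions (pith, wood1, wood2, cortex),
#: normalized; narrow-stem profile of each growth category
CATEGORY_FRACTIONS: dict[str, tuple[float, float, float, float]] = {
    "self-supporting": (0.3362, 0.3235, 0.0067, 0.3336),
    "pendulous": (0.27747, 0.38916, 0.01390, 0.31947),
    "climbing": (0.27453, 0.26353, 0.10171, 0.36024),
    "fixed": (0.2844, 0.2257, 0.1254, 0.3645),
}

#: how each category realizes TYPE II wood
CATEGORY_WOOD2_MODE = {
    "self-supporting": "lobes",   # near-zero fraction, tiny pockets if any
    "pendulous": "lobes",         # small peripheral pockets
    "climbing": "ring",           # nearly continuous lianoid layer
    "fixed": "ring",
}

#: ground-truth tissue moduli (MPa): dense TYPE I wood is stiff, lianoid
#: TYPE II wood and the soft pith/cortex are compliant
DEFAULT_MODULI = {"pith": 300.0, "wood1": 5000.0, "wood2": 500.0,
                  "cortex": 800.0}


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Diameters are sampled uniformly per category on ``diameter_range``; with
    ``enforce_threshold`` on, unattached categories (self-supporting,
    pendulous) are capped at ``threshold_diameter`` — the developmental rule
    that only attached stems keep growing past 5-6 mm. ``moduli`` set the
    ground-truth EI = sum_t E_t I_t used to simulate bending; they are not an
    inference target. Bending is simulated at ``span_to_depth`` times the
    vertical diameter with 5-6 weights tuned to a ~2.5 mm max deflection.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 12 for c in CATEGORIES})
    seed: int = 0
    diameter_range: tuple[float, float] = (1.8, 10.0)
    threshold_diameter: float = 5.9
    enforce_threshold: bool = True
    ellipse_ratio: float = 1.0
    fraction_jitter_sd: float = 0.03
    moduli: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MODULI))
    noise: NoiseModel = field(default_factory=NoiseModel)
    shear_enabled: bool = False
    e_over_g: float = 20.0
    span_to_depth: float = 40.0
    tests_per_specimen: tuple[int, int] = (1, 3)
    pixel_fraction: float = 1.0 / 200.0   # pixel_size = diameter * this
    lobe_count: int = 4
    lobe_arc: float = 20.0
    rasterize_sections: bool = True

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("counts must be non-negative")
        for c in self.counts:
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c!r}")


@dataclass
class Specimen:
    """One synthetic specimen with its ground truth."""

    specimen_id: str
    category: str
    layout: TissueLayout
    section: LabeledSection | None
    tests: list[BendingTest]
    truth: dict[str, float]   # EI, E, I, area, per-tissue fractions


def _jitter_fractions(base, sd, rng, allow_wood2: bool):
    f = np.asarray(base, dtype=float)
    if sd > 0:
        f = np.clip(f + rng.normal(0.0, sd, size=4), 0.0, None)
    if not allow_wood2:
        f[1] += f[2]
        f[2] = 0.0
    s = f.sum()
    if s <= 0:
        raise ValueError("degenerate fraction jitter")
    return tuple(float(v) for v in f / s)


def generate_cohort(config: CohortConfig) -> list[Specimen]:
    """Generate a deterministic cohort of specimens with ground truth.

    Each specimen gets a category, a realized tissue layout, (optionally) its
    rasterized section, one to a few bending tests simulated from the
    ground-truth EI = sum_t E_t I_t, and a truth record. Identical configs
    (including seed) produce identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.diameter_range
    specimens: list[Specimen] = []
    for category in CATEGORIES:
        n = config.counts.get(category, 0)
        for k in range(n):
            sid = f"{category[:4]}-{k:03d}"
            d_hi = hi
            if config.enforce_threshold and category in (
                    "self-supporting", "pendulous"):
                d_hi = min(hi, config.threshold_diameter)
            diameter = float(rng.uniform(lo, d_hi))
            mode = CATEGORY_WOOD2_MODE[category]
            fractions = _jitter_fractions(
                CATEGORY_FRACTIONS[category], config.fraction_jitter_sd, rng,
                allow_wood2=mode != "none")
            phase = float(rng.uniform(0.0, 360.0))
            spec = LayoutSpec(
                category=category, outer_diameter=diameter,
                target_fractions=fractions, ellipse_ratio=config.ellipse_ratio,
                wood2_mode=mode,
                lobe_count=config.lobe_count if mode == "lobes" else 0,
                lobe_arc=config.lobe_arc if mode == "lobes" else 0.0,
                lobe_phase=phase)
            try:
                layout = build_layout(spec)
            except InfeasibleLayout:
                # tiny jittered wood2 fraction can exceed what narrow lobes
                # hold on very small piths; widen arcs for this specimen
                spec = replace(spec, lobe_arc=min(
                    90.0, 360.0 / max(spec.lobe_count, 1)))
                layout = build_layout(spec)

            I_t = layout.tissue_second_moments()
            A_t = layout.tissue_areas()
            EI_true = sum(config.moduli[t] * I_t[t] for t in TISSUES)
            I_total = layout.total_I()
            E_true = EI_true / I_total

            section = None
            if config.rasterize_sections:
                section = rasterize(layout, diameter * config.pixel_fraction,
                                    specimen_id=sid)

            span = config.span_to_depth * diameter
            shear = ShearModel(e_over_g=config.e_over_g, depth=diameter) \
                if config.shear_enabled else None
            n_tests = int(rng.integers(config.tests_per_specimen[0],
                                       config.tests_per_specimen[1] + 1))
            a_true = layout.a[3]
            b_true = layout.b[3]
            tests = []
            for _ in range(n_tests):
                n_steps = int(rng.integers(5, 7))
                F_max = 2.5 * 48.0 * EI_true / span ** 3
                masses = np.full(n_steps, F_max / G_MS2 / n_steps)
                if config.noise.radius_sd > 0:
                    a_meas = tuple(a_true + rng.normal(0, config.noise.radius_sd)
                                   for _ in range(3))
                    b_meas = tuple(b_true + rng.normal(0, config.noise.radius_sd)
                                   for _ in range(3))
                else:
                    a_meas = (a_true,) * 3
                    b_meas = (b_true,) * 3
                tests.append(simulate_bending(
                    EI_true, span, masses, shear=shear, noise=config.noise,
                    rng=rng, a_semi=a_meas, b_semi=b_meas, specimen_id=sid))

            truth = {"EI": EI_true, "E": E_true, "I": I_total,
                     "area": layout.total_area(), "diameter": diameter}
            for t in TISSUES:
                truth[f"frac_{t}"] = A_t[t] / layout.total_area()
                truth[f"I_{t}"] = I_t[t]
            specimens.append(Specimen(
                specimen_id=sid, category=category, layout=layout,
                section=section, tests=tests, truth=truth))
    return specimens
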