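"""Cross-section morphometrics from labeled tissue rasters.

A stem cross section is represented as an integer label image (one label per
pixel: 0 background, 1 pith, 2 TYPE I wood, 3 TYPE II lianoid wood, 4 cortex)
with a physical pixel size in mm. From it we compute per-tissue areas (mm^2),
per-tissue second moments of area (mm^4) about the horizontal bending axis
through the whole-section centroid, and percent contributions of each tissue
to total area and to total I.

Conventions
-----------
Row 0 is the top of the image and the y coordinate increases downward; pixel
centers sit at half-integer grid positions, i.e. pixel (row i, col j) has
center (x, y) = ((j + 0.5) * p, (i + 0.5) * p) with p the pixel size. The
bending axis is the horizontal line through the area centroid of all
non-background pixels; every tissue's I is taken about this one shared axis
(parallel-axis contributions included), so tissue I values add up exactly to
the whole-section I. Each pixel contributes (y_c - ybar)^2 * p^2 + p^4 / 12,
the second term being the pixel's own inertia about its center (exact for an
axis-aligned square).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: tissue label -> name; 0 is background
TISSUES = ("pith", "wood1", "wood2", "cortex")
LABELS = {name: i + 1 for i, name in enumerate(TISSUES)}


@dataclass
class LabeledSection:
    """A labeled cross-section raster with physical pixel size.

    Parameters
    ----------
    labels : ndarray of int, shape (rows, cols)
        Tissue labels in {0..4}.
    pixel_size : float
        Edge length of one pixel in mm.
    specimen_id : str, optional
        Identifier carried through to tidy outputs.
    """

    labels: np.ndarray
    pixel_size: float
    specimen_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label grid must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.labels.min() < 0 or self.labels.max() > 4:
            raise ValueError("labels must lie in {0..4}")
        if not (self.labels > 0).any():
            raise ValueError("section has no non-background pixels")


@dataclass
class TissueMetrics:
    """Per-tissue areas, second moments, and percent contributions."""

    area: dict[str, float]            # mm^2 per tissue
    second_moment: dict[str, float]   # mm^4 per tissue, shared centroidal axis
    pct_area: dict[str, float]
    pct_I: dict[str, float]
    area_total: float
    I_total: float
    centroid: tuple[float, float]     # (x, y) mm
    diameter_vertical: float          # mm, extent along y through centroid
    diameter_horizontal: float        # mm, extent along x through centroid
    specimen_id: str | None = None

    @property
    def diameter(self) -> float:
        """Image-measured diameter: mean of vertical and horizontal extents."""
        return 0.5 * (self.diameter_vertical + self.diameter_horizontal)

    def to_dict(self) -> dict:
        d = {"specimen_id": self.specimen_id,
             "area_total_mm2": self.area_total,
             "I_total_mm4": self.I_total,
             "diameter_mm": self.diameter}
        for t in TISSUES:
            d[f"area_{t}_mm2"] = self.area[t]
            d[f"I_{t}_mm4"] = self.second_moment[t]
            d[f"pct_area_{t}"] = self.pct_area[t]
            d[f"pct_I_{t}"] = self.pct_I[t]
        return d


def tissue_areas(section: LabeledSection) -> dict[str, float]:
    """Per-tissue cross-sectional areas in mm^2 (pixel count times pixel area)."""
    p2 = section.pixel_size ** 2
    counts = np.bincount(section.labels.ravel(), minlength=5)
    return {t: float(counts[LABELS[t]] * p2) for t in TISSUES}


def section_centroid(section: LabeledSection) -> tuple[float, float]:
    """Area centroid (x, y) in mm of all non-background pixels."""
    rows, cols = np.nonzero(section.labels)
    p = section.pixel_size
    return (float((cols + 0.5).mean() * p), float((rows + 0.5).mean() * p))


def tissue_second_moments(section: LabeledSection) -> dict[str, float]:
    """Per-tissue second moments of area (mm^4) about the horizontal axis
    through the whole-section centroid.

    Values are additive: their sum equals the whole-section I about the same
    axis, which is the I entering E = EI / I.
    """
    p = section.pixel_size
    _, ybar = section_centroid(section)
    out: dict[str, float] = {}
    for t in TISSUES:
        rows, _ = np.nonzero(section.labels == LABELS[t])
        if rows.size == 0:
            out[t] = 0.0
            continue
        y = (rows + 0.5) * p
        out[t] = float(np.sum((y - ybar) ** 2 * p * p) + rows.size * p ** 4 / 12.0)
    return out


def _extent_through_centroid(section: LabeledSection) -> tuple[float, float]:
    # vertical / horizontal chord lengths of the non-background mask through
    # the centroid pixel column / row
    p = section.pixel_size
    xbar, ybar = section_centroid(section)
    col = min(int(xbar / p), section.labels.shape[1] - 1)
    row = min(int(ybar / p), section.labels.shape[0] - 1)
    col_mask = np.nonzero(section.labels[:, col])[0]
    row_mask = np.nonzero(section.labels[row, :])[0]
    dv = (col_mask.max() - col_mask.min() + 1) * p if col_mask.size else 0.0
    dh = (row_mask.max() - row_mask.min() + 1) * p if row_mask.size else 0.0
    return float(dv), float(dh)


def compute_metrics(section: LabeledSection) -> TissueMetrics:
    """Full morphometric reduction of one labeled section.

    Raises
    ------
    ValueError
        If the section is empty (no labeled pixels).
    """
    area = tissue_areas(section)
    I = tissue_second_moments(section)
    area_total = sum(area.values())
    I_total = sum(I.values())
    if area_total <= 0:
        raise ValueError("section has zero labeled area")
    if I_total <= 0:
        raise ValueError("section has zero second moment of area")
    pct_area = {t: 100.0 * area[t] / area_total for t in TISSUES}
    pct_I = {t: 100.0 * I[t] / I_total for t in TISSUES}
    dv, dh = _extent_through_centroid(section)
    return TissueMetrics(
        area=area, second_moment=I, pct_area=pct_area, pct_I=pct_I,
        area_total=area_total, I_total=I_total,
        centroid=section_centroid(section),
        diameter_vertical=dv, diameter_horizontal=dh,
        specimen_id=section.specimen_id,
    )


def ellipse_I(a: float, b: float) -> float:
    """Second moment of area of a full ellipse about its horizontal axis.

    ``a`` is the vertical semi-axis (along the load), ``b`` the horizontal one;
    I = (pi/4) a^3 b.
    """
    if a < 0 or b < 0:
        raise ValueError("semi-axes must be non-negative")
    return np.pi / 4.0 * a ** 3 * b


def ellipse_annulus_I(a_out: float, b_out: float, a_in: float, b_in: float) -> float:
    """Second moment of area of an elliptical annulus: (pi/4)(a_o^3 b_o - a_i^3 b_i)."""
    if min(a_out, b_out, a_in, b_in) < 0:
        raise ValueError("semi-axes must be non-negative")
    if a_in > a_out or b_in > b_out:
        raise ValueError("inner ellipse exceeds outer ellipse")
    return ellipse_I(a_out, b_out) - ellipse_I(a_in, b_in)


# ---------------------------------------------------------------------------
# I/O: single-channel 8-bit TIFF with a JSON sidecar carrying pixel_size_mm

def write_section(section: LabeledSection, path: str | Path) -> Path:
    """Write a section as 8-bit TIFF plus ``<stem>.json`` sidecar; returns the image path."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, section.labels.astype(np.uint8))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"pixel_size_mm": section.pixel_size, "specimen_id": section.specimen_id}))
    return path


def read_section(path: str | Path) -> LabeledSection:
    """Read a section written by :func:`write_section`."""
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LabeledSection(
        labels=tifffile.imread(path),
        pixel_size=float(meta["pixel_size_mm"]),
        specimen_id=meta.get("specimen_id"),
    )
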