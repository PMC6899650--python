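"""Bedding-plane map data model, file I/O and geometric corrections.

A census surface is represented as a :class:`BedSurfaceMap`: one
:class:`SpecimenRecord` per fossil (taxon label, planar position in metres,
optional morphometrics) inside an :class:`ObservationWindow` (a simple
polygon, also in metres).  Maps are carried as plain CSV specimen tables
with an optional WKT polygon sidecar, so every analysis input is a small
text file.

Geometric corrections cover tectonic strain: elongated holdfast discs that
were originally circular record the strain ellipse, and
:func:`estimate_strain` / :func:`retrodeform` restore the surface to its
pre-deformation geometry by an inverse pure shear.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Polygon, box

from .errors import FormatError, InsufficientDataError, ParseError

GROUP_CLASSES = ("described_taxon", "bin_group", "taphomorph", "organ_taxon")

#: morphometric columns, all in metres, all optional
MORPHOMETRIC_FIELDS = (
    "disc_width",
    "disc_length",
    "stem_length",
    "stem_width",
    "frond_length",
    "frond_width",
)


@dataclass(frozen=True)
class SpecimenRecord:
    """One fossil specimen: identity, position (m) and optional dimensions (m)."""

    specimen_id: str
    taxon: str
    x: float
    y: float
    disc_width: float | None = None
    disc_length: float | None = None
    stem_length: float | None = None
    stem_width: float | None = None
    frond_length: float | None = None
    frond_width: float | None = None
    group_class: str = "described_taxon"

    def __post_init__(self):
        if not self.taxon:
            raise ValueError("taxon label must be non-empty")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.specimen_id!r}")
        if self.group_class not in GROUP_CLASSES:
            raise ValueError(f"unknown group_class {self.group_class!r}")
        for name in MORPHOMETRIC_FIELDS:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


class ObservationWindow:
    """Observation window: a simple polygon in metres.

    Wraps a :mod:`shapely` polygon and adds the geometric services the
    estimators need: uniform sampling, point-in-window tests, distances to
    the boundary and translation-correction areas ``|W ∩ W_shifted|``.
    Axis-aligned rectangles get exact vectorised fast paths.
    """

    def __init__(self, boundary: Polygon | Sequence[tuple[float, float]]):
        poly = boundary if isinstance(boundary, Polygon) else Polygon(boundary)
        if not poly.is_valid:
            raise ValueError("window polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValueError("window area must be positive")
        self.polygon = poly

    # -- constructors -------------------------------------------------
    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "ObservationWindow":
        return cls(box(xmin, ymin, xmax, ymax))

    @classmethod
    def from_wkt(cls, wkt: str) -> "ObservationWindow":
        return cls(shapely.from_wkt(wkt))

    # -- basic properties ---------------------------------------------
    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def is_rectangle(self) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return abs(self.area - (xmax - xmin) * (ymax - ymin)) <= 1e-12 * max(self.area, 1.0)

    @property
    def diameter(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return math.hypot(xmax - xmin, ymax - ymin)

    def to_wkt(self) -> str:
        return self.polygon.wkt

    def __eq__(self, other) -> bool:
        return isinstance(other, ObservationWindow) and self.polygon.equals_exact(
            other.polygon, 0.0
        )

    def __repr__(self) -> str:
        return f"ObservationWindow(area={self.area:.4f} m²)"

    # -- geometric services -------------------------------------------
    def contains(self, x, y) -> np.ndarray:
        """Vectorised inside-or-on-boundary test."""
        return shapely.intersects_xy(self.polygon, np.asarray(x, float), np.asarray(y, float))

    def boundary_distance(self, x, y) -> np.ndarray:
        """Distance from interior points to the window boundary."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.distance(self.polygon.exterior, pts)

    def translation_area(self, dx, dy) -> np.ndarray:
        """Area of ``W ∩ (W + (dx, dy))`` — the translation edge correction."""
        dx = np.atleast_1d(np.asarray(dx, float))
        dy = np.atleast_1d(np.asarray(dy, float))
        if self.is_rectangle:
            xmin, ymin, xmax, ymax = self.bounds
            w = np.maximum((xmax - xmin) - np.abs(dx), 0.0)
            h = np.maximum((ymax - ymin) - np.abs(dy), 0.0)
            return w * h
        out = np.empty(dx.shape, float)
        for i, (ddx, ddy) in enumerate(zip(dx, dy)):
            shifted = shapely.affinity.translate(self.polygon, ddx, ddy)
            out[i] = self.polygon.intersection(shifted).area
        return out

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n i.i.d. uniform points in the window (rejection from the bbox)."""
        xmin, ymin, xmax, ymax = self.bounds
        pts = np.empty((n, 2), float)
        filled = 0
        # acceptance ratio = area / bbox area; rectangles accept everything
        while filled < n:
            m = max(int(1.5 * (n - filled)) + 8, 16)
            x = rng.uniform(xmin, xmax, m)
            y = rng.uniform(ymin, ymax, m)
            keep = self.contains(x, y)
            k = min(int(keep.sum()), n - filled)
            pts[filled : filled + k, 0] = x[keep][:k]
            pts[filled : filled + k, 1] = y[keep][:k]
            filled += k
        return pts

    def transformed(self, matrix: np.ndarray) -> "ObservationWindow":
        """Window mapped through a 2x2 linear transform."""
        coords = np.asarray(self.polygon.exterior.coords)
        new = coords @ matrix.T
        return ObservationWindow(Polygon(new))


@dataclass(frozen=True)
class StrainEstimate:
    """Tectonic strain: ellipse axis ratio (>= 1) and long-axis orientation [0, π)."""

    ratio: float
    orientation: float

    def __post_init__(self):
        if not (self.ratio >= 1.0):
            raise ValueError("strain ratio must be >= 1")
        object.__setattr__(self, "orientation", self.orientation % math.pi)


class BedSurfaceMap:
    """A census surface: specimen records inside an observation window."""

    def __init__(
        self,
        surface_name: str,
        records: Sequence[SpecimenRecord],
        window: ObservationWindow,
    ):
        records = list(records)
        ids = [r.specimen_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("specimen_ids must be unique")
        if records:
            xs = np.array([r.x for r in records])
            ys = np.array([r.y for r in records])
            inside = window.contains(xs, ys)
            if not inside.all():
                bad = [records[i].specimen_id for i in np.flatnonzero(~inside)]
                raise ValueError(f"records outside window: {bad[:10]}")
        self.surface_name = surface_name
        self.records = records
        self.window = window

    # -- views ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def coords(self, taxon: str | None = None) -> np.ndarray:
        recs = self.records if taxon is None else [r for r in self.records if r.taxon == taxon]
        if not recs:
            return np.empty((0, 2), float)
        return np.array([(r.x, r.y) for r in recs], float)

    def taxon_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.taxon] = out.get(r.taxon, 0) + 1
        return out

    @property
    def density(self) -> float:
        """Overall specimen density, individuals per m²."""
        return len(self.records) / self.window.area

    def subset(self, keep: Iterable[SpecimenRecord], window: ObservationWindow | None = None):
        return BedSurfaceMap(self.surface_name, list(keep), window or self.window)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BedSurfaceMap)
            and self.surface_name == other.surface_name
            and self.records == other.records
            and self.window == other.window
        )


# ---------------------------------------------------------------------------
# File I/O: CSV specimen table + WKT window sidecar
# ---------------------------------------------------------------------------

_BASE_COLUMNS = {"specimen_id": "specimen_id", "taxon": "taxon", "x": "x_m", "y": "y_m"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".window.wkt")


def write_surface_map(surface_map: BedSurfaceMap, path: str | Path) -> None:
    """Write a map as CSV (+ ``<path>.window.wkt`` sidecar with the polygon).

    Morphometric columns that are absent on every record are omitted.
    """
    path = Path(path)
    rows = []
    present = [
        f for f in MORPHOMETRIC_FIELDS if any(getattr(r, f) is not None for r in surface_map.records)
    ]
    for r in surface_map.records:
        row = {
            "specimen_id": r.specimen_id,
            "taxon": r.taxon,
            "group_class": r.group_class,
            "x_m": repr(r.x),
            "y_m": repr(r.y),
        }
        for f in present:
            v = getattr(r, f)
            row[f + "_m"] = "" if v is None else repr(v)
        rows.append(row)
    cols = ["specimen_id", "taxon", "group_class", "x_m", "y_m"] + [f + "_m" for f in present]
    buf = io.StringIO()
    buf.write(f"# surface: {surface_map.surface_name}\n")
    pd.DataFrame(rows, columns=cols).to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    _sidecar_path(path).write_text(surface_map.window.to_wkt() + "\n")


def read_surface_map(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    window: ObservationWindow | None = None,
    outside: str = "error",
) -> BedSurfaceMap:
    """Read a CSV specimen table into a :class:`BedSurfaceMap`.

    Parameters
    ----------
    column_map:
        Optional mapping from logical names (``taxon``, ``x``, ``y``, ...)
        to the file's column names; defaults to the canonical schema
        (``taxon``, ``x_m``, ``y_m``).
    window:
        Explicit window; otherwise the WKT sidecar is used, falling back to
        the bounding box of the points.
    outside:
        ``"error"`` (default) raises listing records outside the window;
        ``"drop"`` removes them with a warning naming each one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(_BASE_COLUMNS)
    if column_map:
        colmap.update(column_map)

    name = path.stem
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# surface:"):
        name = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)

    for logical in ("taxon", "x", "y"):
        if colmap[logical] not in df.columns:
            raise FormatError(f"missing mandatory column {colmap[logical]!r} in {path}")

    def _num(col: str, i: int, required: bool):
        s = df[col].iloc[i].strip()
        if s == "":
            if required:
                raise ParseError(f"empty value in column {col!r}", row=i)
            return None
        try:
            return float(s)
        except ValueError:
            raise ParseError(f"non-numeric value {s!r} in column {col!r}", row=i) from None

    records = []
    for i in range(len(df)):
        sid = (
            df[colmap["specimen_id"]].iloc[i]
            if colmap["specimen_id"] in df.columns
            else str(i)
        )
        morpho = {}
        for f in MORPHOMETRIC_FIELDS:
            col = f + "_m"
            if col in df.columns:
                morpho[f] = _num(col, i, required=False)
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                taxon=df[colmap["taxon"]].iloc[i],
                x=_num(colmap["x"], i, required=True),
                y=_num(colmap["y"], i, required=True),
                group_class=(
                    df["group_class"].iloc[i] if "group_class" in df.columns else "described_taxon"
                ),
                **morpho,
            )
        )

    if window is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            window = ObservationWindow.from_wkt(sidecar.read_text().strip())
        elif records:
            xs = [r.x for r in records]
            ys = [r.y for r in records]
            window = ObservationWindow.rectangle(min(xs), min(ys), max(xs), max(ys))
        else:
            raise FormatError(f"no window sidecar and no records to infer one from in {path}")

    if records:
        xs = np.array([r.x for r in records])
        ys = np.array([r.y for r in records])
        out_mask = ~window.contains(xs, ys)
        if out_mask.any():
            bad = [records[i].specimen_id for i in np.flatnonzero(out_mask)]
            if outside == "drop":
                warnings.warn(
                    f"{len(bad)} record(s) outside window dropped: {bad}", stacklevel=2
                )
                records = [r for r, o in zip(records, out_mask) if not o]
            else:
                raise ValueError(f"records outside window: {bad}")
    return BedSurfaceMap(name, records, window)


# ---------------------------------------------------------------------------
# Tectonic strain
# ---------------------------------------------------------------------------


def estimate_strain(discs: Sequence[tuple[float, float, float]]) -> StrainEstimate:
    """Estimate tectonic strain from deformed (originally circular) discs.

    Parameters
    ----------
    discs:
        ``(long_axis, short_axis, orientation_rad)`` per disc, axes > 0.

    Returns
    -------
    StrainEstimate
        ``ratio`` is the median of long/short ratios (robust to outliers);
        ``orientation`` is the axial circular mean of long-axis orientations
        (period π).
    """
    discs = list(discs)
    if len(discs) < 3:
        raise InsufficientDataError("strain estimation needs at least 3 discs")
    arr = np.asarray(discs, float)
    if np.any(arr[:, :2] <= 0):
        raise ValueError("disc axes must be > 0")
    ratios = arr[:, 0] / arr[:, 1]
    ratio = float(np.median(np.maximum(ratios, 1.0 / ratios)))
    # axial data: double the angle, average on the circle, halve back
    theta = arr[:, 2]
    orientation = 0.5 * math.atan2(float(np.sin(2 * theta).sum()), float(np.cos(2 * theta).sum()))
    return StrainEstimate(ratio=ratio, orientation=orientation % math.pi)


def _strain_matrix(strain: StrainEstimate, area_preserving: bool) -> np.ndarray:
    """Forward pure-shear matrix: stretch along the strain long axis."""
    if area_preserving:
        s_long, s_short = math.sqrt(strain.ratio), 1.0 / math.sqrt(strain.ratio)
    else:
        s_long, s_short = strain.ratio, 1.0
    c, s = math.cos(strain.orientation), math.sin(strain.orientation)
    rot = np.array([[c, -s], [s, c]])
    return rot @ np.diag([s_long, s_short]) @ rot.T


def _transform_map(surface_map: BedSurfaceMap, matrix: np.ndarray, disc_scale: tuple[float, float]):
    """Apply a linear map to coordinates and window; rescale disc axes.

    ``disc_scale = (long_factor, short_factor)`` is applied to the larger /
    smaller of (disc_length, disc_width), which by convention store the
    strain-parallel / strain-normal disc axes.
    """
    new_window = surface_map.window.transformed(matrix)
    f_long, f_short = disc_scale
    new_records = []
    for r in surface_map.records:
        x, y = matrix @ np.array([r.x, r.y])
        changes: dict = {"x": float(x), "y": float(y)}
        if r.disc_length is not None and r.disc_width is not None:
            lo, hi = sorted((r.disc_width, r.disc_length))
            changes["disc_length"] = hi * f_long
            changes["disc_width"] = lo * f_short
        new_records.append(replace(r, **changes))
    return BedSurfaceMap(surface_map.surface_name, new_records, new_window)


def retrodeform(
    surface_map: BedSurfaceMap, strain: StrainEstimate, area_preserving: bool = True
) -> BedSurfaceMap:
    """Undo tectonic strain: inverse pure shear of coordinates, window and discs.

    With ``area_preserving=True`` (the default, the structural-geology
    convention) the forward strain scales axes by √ratio and 1/√ratio so the
    inverse preserves areas and densities; otherwise a uniaxial stretch by
    ``ratio`` is inverted.
    """
    fwd = _strain_matrix(strain, area_preserving)
    inv = np.linalg.inv(fwd)
    if area_preserving:
        f_long, f_short = 1.0 / math.sqrt(strain.ratio), math.sqrt(strain.ratio)
    else:
        f_long, f_short = 1.0 / strain.ratio, 1.0
    return _transform_map(surface_map, inv, (f_long, f_short))


# ---------------------------------------------------------------------------
# Pattern-preparation filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """What :func:`filter_analysis_taxa` removed, per exclusion class."""

    taphomorphs: int = 0
    organ_taxa: int = 0
    bin_groups: int = 0
    low_abundance: dict[str, int] = field(default_factory=dict)


def filter_analysis_taxa(
    surface_map: BedSurfaceMap, abundance_threshold: int = 30
) -> tuple[BedSurfaceMap, FilterReport]:
    """Drop taphomorphs, organ taxa, bin groups and low-abundance taxa.

    A taxon is retained when its specimen count is >= ``abundance_threshold``
    (default 30; use 16 for sparse surfaces where taxa with more than 15
    specimens are admitted).  Idempotent.
    """
    if abundance_threshold < 1:
        raise ValueError("abundance_threshold must be >= 1")
    report = FilterReport()
    kept_class = []
    for r in surface_map.records:
        if r.group_class == "taphomorph":
            report.taphomorphs += 1
        elif r.group_class == "organ_taxon":
            report.organ_taxa += 1
        elif r.group_class == "bin_group":
            report.bin_groups += 1
        else:
            kept_class.append(r)
    counts: dict[str, int] = {}
    for r in kept_class:
        counts[r.taxon] = counts.get(r.taxon, 0) + 1
    for taxon, n in counts.items():
        if n < abundance_threshold:
            report.low_abundance[taxon] = n
    kept = [r for r in kept_class if r.taxon not in report.low_abundance]
    return surface_map.subset(kept), report


def extract_rect_subwindow(
    surface_map: BedSurfaceMap, rect: tuple[float, float, float, float]
) -> BedSurfaceMap:
    """Clip a map to an axis-aligned rectangle ``(xmin, ymin, xmax, ymax)``.

    The returned map's window is the rectangle itself (needed by the
    toroidal-shift independence test, which requires a rectangular window).
    """
    xmin, ymin, xmax, ymax = rect
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("rectangle must have positive extent")
    window = ObservationWindow.rectangle(xmin, ymin, xmax, ymax)
    kept = [
        r for r in surface_map.records if xmin <= r.x <= xmax and ymin <= r.y <= ymax
    ]
    return surface_map.subset(kept, window=window)


def largest_inscribed_rectangle(
    window: ObservationWindow, resolution: float = 0.1
) -> tuple[float, float, float, float]:
    """Largest axis-aligned rectangle inside the window, by grid search.

    Rasterises the window interior at ``resolution`` metres and runs the
    maximal-rectangle-in-binary-matrix algorithm (histogram stack).  For an
    axis-aligned rectangular window the bounding box is returned exactly.
    """
    if window.is_rectangle:
        return window.bounds
    xmin, ymin, xmax, ymax = window.bounds
    nx = max(int((xmax - xmin) / resolution), 2)
    ny = max(int((ymax - ymin) / resolution), 2)
    xs = xmin + (np.arange(nx) + 0.5) * (xmax - xmin) / nx
    ys = ymin + (np.arange(ny) + 0.5) * (ymax - ymin) / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    mask = window.contains(gx.ravel(), gy.ravel()).reshape(nx, ny)

    best = (0, 0, 0, 0, 0)  # area (cells), i0, i1, j0, j1 (inclusive cell indices)
    heights = np.zeros(ny, int)
    for i in range(nx):
        heights = np.where(mask[i], heights + 1, 0)
        # largest rectangle in histogram (classic stack algorithm)
        hs = np.append(heights, 0)
        stack: list[int] = []
        for j in range(ny + 1):
            while stack and hs[stack[-1]] > hs[j]:
                k = stack.pop()
                h = int(hs[k])
                left = stack[-1] + 1 if stack else 0
                area = h * (j - left)
                if area > best[0]:
                    best = (area, i - h + 1, i, left, j - 1)
            stack.append(j)
    _, i0, i1, j0, j1 = best
    dx = (xmax - xmin) / nx
    dy = (ymax - ymin) / ny
    return (xmin + i0 * dx, ymin + j0 * dy, xmin + (i1 + 1) * dx, ymin + (j1 + 1) * dy)
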