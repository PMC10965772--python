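"""Cross-sectional geometry of the avian coelom and the EIT phantom.

The reconstruction plane is the transverse slice of the body at the level of
the electrode belt (caudal to the shoulder joints).  The slice is described by
closed 2-D contours — the outer body wall, the two lungs and the cardiac
silhouette — from which a finite-element phantom with 32 boundary electrodes
and a 32x32 reconstruction pixel grid is built.

Coordinate convention: x increases from the subject's right towards the left,
y increases from ventral to dorsal.  Pixel images are displayed radiologically
(row 0 = dorsal-most row, column 0 = subject's right); all physical
computations use the y-up convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LinearRing, LineString, Point, Polygon

__all__ = [
    "Contour",
    "ContourSet",
    "Phantom",
    "PixelGrid",
    "resample_contour",
    "mean_contour",
    "build_phantom",
    "make_pixel_mask",
    "default_chicken_contours",
    "load_contours",
    "save_contours",
]

LABELS = ("background", "lung_r", "lung_l", "cardiac", "airsac")
LABEL_CODE = {name: i for i, name in enumerate(LABELS)}


@dataclass
class Contour:
    """A simple closed polygon in millimetres (first point not repeated)."""

    points: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError(f"contour {self.name!r} needs >=3 (x, y) points")
        ring = LinearRing(pts)
        if not ring.is_simple or not ring.is_valid:
            raise ValueError(f"contour {self.name!r} is self-intersecting")
        if ring.length <= 0:
            raise ValueError(f"contour {self.name!r} has zero perimeter")
        # normalise to counter-clockwise orientation
        if not ring.is_ccw:
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def perimeter(self) -> float:
        return LinearRing(self.points).length

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    def translated(self, delta) -> "Contour":
        return Contour(self.points + np.asarray(delta, float), self.name)


def _ventral_start_arc(c: Contour) -> float:
    """Arc-length position of the point where the ventral midline (the
    vertical line through the centroid, below it) crosses the contour."""
    ring = LinearRing(c.points)
    cx, cy = c.centroid
    ymin = float(c.points[:, 1].min())
    probe = LineString([(cx, ymin - 1.0), (cx, cy)])
    hit = probe.intersection(ring)
    if hit.is_empty:
        # fall back to the ventral-most vertex
        i = int(np.argmin(c.points[:, 1]))
        return float(ring.project(Point(c.points[i])))
    pts = []
    if hit.geom_type == "Point":
        pts = [hit]
    else:
        pts = [g for g in getattr(hit, "geoms", []) if g.geom_type == "Point"]
        if not pts:  # e.g. a collinear overlap
            pts = [Point(co) for co in hit.coords]
    best = min(pts, key=lambda p: p.y)
    return float(ring.project(best))


def resample_contour(c: Contour, n: int) -> Contour:
    """Resample to ``n`` points equally spaced by arc length.

    The first output point is where the ventral midline axis meets the
    contour, and orientation (counter-clockwise) is preserved, so contours
    from different subjects are brought into point-wise correspondence.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    ring = LinearRing(c.points)
    per = ring.length
    if per <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    s0 = _ventral_start_arc(c)
    s = (s0 + per * np.arange(n) / n) % per
    pts = np.array([ring.interpolate(si).coords[0] for si in s])
    return Contour(pts, c.name)


def mean_contour(contours, n: int = 128) -> Contour:
    """Point-wise mean of contours after arc-length resampling.

    Each contour is resampled with the common ventral start-point rule and
    translated so its centroid sits at the origin; the averaged shape is then
    placed at the mean of the original centroids.  No rotation or scaling is
    applied (subjects are imaged in a fixed posture and absolute size matters).
    """
    contours = list(contours)
    if not contours:
        raise ValueError("mean_contour needs at least one contour")
    resampled = [resample_contour(c, n) for c in contours]
    centroids = np.array([c.centroid for c in resampled])
    stack = np.array([c.points - c.centroid for c in resampled])
    return Contour(stack.mean(axis=0) + centroids.mean(axis=0), contours[0].name)


@dataclass
class ContourSet:
    """One subject's slice: outer body wall, both lungs, cardiac silhouette."""

    outer: Contour
    lung_r: Contour
    lung_l: Contour
    cardiac: Contour
    subject_id: str = ""

    def __post_init__(self) -> None:
        outer = self.outer.polygon
        for c in (self.lung_r, self.lung_l, self.cardiac):
            if not outer.contains(c.polygon):
                raise ValueError(
                    f"contour {c.name!r} does not lie strictly inside the outer contour"
                )

    def interior(self):
        return {"lung_r": self.lung_r, "lung_l": self.lung_l, "cardiac": self.cardiac}


@dataclass
class PixelGrid:
    """Square 32x32 reconstruction raster covering the outer contour.

    The raster is the smallest centred square covering the outer-contour
    bounding box; ``origin`` is the (x, y) of the square's lower-left corner
    and ``pixel_size`` its pixel edge length.  Row 0 is the dorsal-most row.
    """

    mask: np.ndarray
    origin: np.ndarray
    pixel_size: float
    shape: tuple = (32, 32)

    def pixel_centres(self):
        """(x, y) centre of every pixel, as two (32, 32) arrays."""
        nrow, ncol = self.shape
        cols = np.arange(ncol)
        rows = np.arange(nrow)
        x = self.origin[0] + (cols + 0.5) * self.pixel_size
        y = self.origin[1] + (nrow - rows - 0.5) * self.pixel_size
        return np.meshgrid(x, y)[0], np.tile(y[:, None], (1, ncol))


@dataclass
class Phantom:
    """FE mesh + electrodes + ROI labels + pixel raster for one geometry."""

    nodes: np.ndarray
    elements: np.ndarray
    electrode_nodes: np.ndarray
    element_labels: np.ndarray  # integer codes into LABELS
    grid: PixelGrid
    pixel_elements: list
    contours: ContourSet
    airsac_band_mm: float = 8.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def pixel_mask(self) -> np.ndarray:
        return self.grid.mask

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def elements_with_label(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.element_labels == LABEL_CODE[name])

    def pixel_roi_mask(self, name: str) -> np.ndarray:
        """In-mask pixels whose centre falls inside a named ROI contour.

        For ``airsac`` (not a segmentable contour) the rule mirrors the
        element labelling: ventral of the lungs' ventral-most extent and
        outside the cardiac silhouette.
        """
        px, py = self.grid.pixel_centres()
        flat_x, flat_y = px.ravel(), py.ravel()
        if name in ("lung_r", "lung_l", "cardiac"):
            poly = self.contours.interior()[name].polygon
            inside = shapely.contains_xy(poly, flat_x, flat_y)
        elif name == "lungs":
            inside = shapely.contains_xy(
                self.contours.lung_r.polygon, flat_x, flat_y
            ) | shapely.contains_xy(self.contours.lung_l.polygon, flat_x, flat_y)
        elif name == "airsac":
            y_cut = min(
                self.contours.lung_r.points[:, 1].min(),
                self.contours.lung_l.points[:, 1].min(),
            )
            inside = (flat_y < y_cut - self.airsac_band_mm) & ~shapely.contains_xy(
                self.contours.cardiac.polygon, flat_x, flat_y
            )
        else:
            raise KeyError(name)
        return inside.reshape(self.grid.shape) & self.grid.mask


def _electrode_arc_positions(outer: Contour, n_electrodes: int) -> np.ndarray:
    ring = LinearRing(outer.points)
    per = ring.length
    s0 = _ventral_start_arc(outer)
    return (s0 + per * np.arange(n_electrodes) / n_electrodes) % per


def _hex_grid(bounds, h: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = bounds
    dy = h * np.sqrt(3.0) / 2.0
    rows = []
    y = ymin
    k = 0
    while y <= ymax:
        xoff = 0.0 if k % 2 == 0 else h / 2.0
        xs = np.arange(xmin + xoff, xmax + 1e-9, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        k += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def build_phantom(
    cs: ContourSet, mesh_size: float, n_electrodes: int = 32,
    airsac_band_mm: float = 8.0,
) -> Phantom:
    """Triangulate the slice and attach electrodes, labels and pixel raster.

    Electrodes are placed equidistantly in arc length on the outer contour,
    numbered counter-clockwise starting at the ventral midline.  Elements are
    labelled by centroid containment: ``lung_r``/``lung_l``/``cardiac`` from
    the ROI contours, ``airsac`` for the region ventral of the band at the
    lungs' ventral-most extent (excluding cardiac), ``background`` otherwise.
    The band thickness ``airsac_band_mm`` models the non-ventilating tissue
    between the lung's ventral face and the air-sac spaces (mediastinum,
    tracheal bifurcation, oesophagus all lie in this plane).  The ``airsac``
    label exists for simulation ground truth only; reconstruction and
    analysis use just the outer contour.
    """
    if mesh_size <= 0:
        raise ValueError("mesh_size must be positive")
    interior = cs.interior()
    names = list(interior)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if interior[a].polygon.intersects(interior[b].polygon) and not interior[
                a
            ].polygon.touches(interior[b].polygon):
                raise ValueError(f"ROI contours overlap: {a!r} and {b!r}")

    outer_poly = cs.outer.polygon
    ring = LinearRing(cs.outer.points)
    per = ring.length
    h = float(mesh_size)

    # boundary nodes: electrodes first, then subdivided inter-electrode arcs
    elec_s = _electrode_arc_positions(cs.outer, n_electrodes)
    boundary_s = []
    for i in range(n_electrodes):
        s_a = elec_s[i]
        s_b = elec_s[(i + 1) % n_electrodes]
        arc = (s_b - s_a) % per
        nsub = max(1, int(round(arc / h)))
        boundary_s.extend(((s_a + arc * k / nsub) % per) for k in range(nsub))
    boundary_s = np.array(boundary_s)
    boundary_pts = np.array([ring.interpolate(s).coords[0] for s in boundary_s])
    electrode_idx = np.array(
        [int(np.argmin(np.abs((boundary_s - s + per / 2) % per - per / 2)))
         for s in elec_s]
    )

    # interior nodes: hexagonal grid plus resampled ROI rings, kept away
    # from the outer boundary and from each other
    eroded = outer_poly.buffer(-0.55 * h)
    cand = [_hex_grid(outer_poly.bounds, h)]
    for c in interior.values():
        n_roi = max(8, int(round(c.perimeter / h)))
        cand.append(resample_contour(c, n_roi).points)
    cand = np.vstack(cand)
    keep = shapely.contains_xy(eroded, cand[:, 0], cand[:, 1])
    cand = cand[keep]
    if len(cand):
        tree = cKDTree(boundary_pts)
        d, _ = tree.query(cand)
        cand = cand[d > 0.5 * h]
    if len(cand):
        # greedy thinning so no two interior nodes are closer than 0.4 h
        tree = cKDTree(cand)
        pairs = tree.query_pairs(0.4 * h, output_type="ndarray")
        drop = np.zeros(len(cand), bool)
        for a, b in pairs:
            if not drop[a] and not drop[b]:
                drop[b] = True
        cand = cand[~drop]

    nodes = np.vstack([boundary_pts, cand])
    try:
        tri = Delaunay(nodes)
    except Exception as exc:  # pragma: no cover - degenerate input
        raise RuntimeError(f"mesh generation failed: {exc}") from exc
    elements = tri.simplices
    cent = nodes[elements].mean(axis=1)
    inside = shapely.contains_xy(outer_poly, cent[:, 0], cent[:, 1])
    v1 = nodes[elements[:, 1]] - nodes[elements[:, 0]]
    v2 = nodes[elements[:, 2]] - nodes[elements[:, 0]]
    area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    elements = elements[inside & (np.abs(area2) > 1e-12 * h * h)]
    # enforce consistent (counter-clockwise) node order per element
    v1 = nodes[elements[:, 1]] - nodes[elements[:, 0]]
    v2 = nodes[elements[:, 2]] - nodes[elements[:, 0]]
    flip = (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]) < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    # drop unused nodes, remap indices
    used = np.zeros(len(nodes), bool)
    used[elements.ravel()] = True
    if not used[electrode_idx].all():
        raise RuntimeError("mesh generation failed: electrode node detached")
    remap = np.cumsum(used) - 1
    nodes = nodes[used]
    elements = remap[elements]
    electrode_nodes = remap[electrode_idx]

    cent = nodes[elements].mean(axis=1)
    labels = np.zeros(len(elements), dtype=np.int8)
    for name in ("lung_r", "lung_l", "cardiac"):
        inside = shapely.contains_xy(interior[name].polygon, cent[:, 0], cent[:, 1])
        labels[inside] = LABEL_CODE[name]
    y_cut = min(cs.lung_r.points[:, 1].min(), cs.lung_l.points[:, 1].min())
    airsac = (labels == 0) & (cent[:, 1] < y_cut - airsac_band_mm)
    labels[airsac] = LABEL_CODE["airsac"]

    phantom = Phantom(
        nodes=nodes,
        elements=elements,
        electrode_nodes=electrode_nodes,
        element_labels=labels,
        grid=None,  # type: ignore[arg-type]
        pixel_elements=[],
        contours=cs,
        airsac_band_mm=float(airsac_band_mm),
    )
    grid, pixel_elements = make_pixel_mask(phantom)
    phantom.grid = grid
    phantom.pixel_elements = pixel_elements
    return phantom


def make_pixel_mask(p: Phantom, shape=(32, 32)):
    """Build the square pixel raster and the pixel-to-element mapping.

    Pixels whose centre lies inside the outer contour are in-mask.  Each
    in-mask pixel maps to the elements whose centroid falls inside it; pixels
    near the boundary that catch no centroid are assigned their nearest
    element so every masked pixel maps to at least one element.
    """
    outer = p.contours.outer
    xmin, ymin = outer.points.min(axis=0)
    xmax, ymax = outer.points.max(axis=0)
    side = max(xmax - xmin, ymax - ymin)
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    origin = np.array([cx - side / 2.0, cy - side / 2.0])
    d = side / shape[0]
    grid = PixelGrid(mask=np.zeros(shape, bool), origin=origin, pixel_size=d,
                     shape=shape)
    px, py = grid.pixel_centres()
    inside = shapely.contains_xy(outer.polygon, px.ravel(), py.ravel())
    grid.mask = inside.reshape(shape)

    cent = p.element_centroids()
    col = np.floor((cent[:, 0] - origin[0]) / d).astype(int)
    row = np.floor((origin[1] + side - cent[:, 1]) / d).astype(int)
    col = np.clip(col, 0, shape[1] - 1)
    row = np.clip(row, 0, shape[0] - 1)
    buckets = {}
    for e, (r, c) in enumerate(zip(row, col)):
        buckets.setdefault((r, c), []).append(e)
    tree = cKDTree(cent)
    pixel_elements = []
    for r in range(shape[0]):
        for c in range(shape[1]):
            if not grid.mask[r, c]:
                pixel_elements.append(np.empty(0, dtype=int))
                continue
            found = buckets.get((r, c))
            if found:
                pixel_elements.append(np.asarray(found, dtype=int))
            else:
                x = origin[0] + (c + 0.5) * d
                y = origin[1] + side - (r + 0.5) * d
                _, nearest = tree.query([x, y])
                pixel_elements.append(np.array([int(nearest)]))
    return grid, pixel_elements


def _ellipse(centre, a, b, n=96, name=""):
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([centre[0] + a * np.cos(th), centre[1] + b * np.sin(th)])
    return Contour(pts, name)


def default_chicken_contours(subject_id: str = "reference") -> ContourSet:
    """Parameterised chicken cross-section at the belt plane.

    Synthetic stand-in for a segmented CT slice (no public segmentations
    exist): an elliptical body outline, two dorsal lung lobes against the
    vertebral column, and a central-ventral cardiac silhouette surrounded by
    the cranial-air-sac space.  Dimensions are millimetres, plausible for an
    adult ~1.9 kg hen.
    """
    outer = _ellipse((0.0, 0.0), 45.0, 40.0, n=128, name="outer")
    lung_r = _ellipse((-17.0, 21.0), 12.5, 8.5, name="lung_r")
    lung_l = _ellipse((17.0, 21.0), 12.5, 8.5, name="lung_l")
    cardiac = _ellipse((0.0, -9.0), 12.0, 11.0, name="cardiac")
    return ContourSet(outer, lung_r, lung_l, cardiac, subject_id=subject_id)


def save_contours(cs: ContourSet, path) -> None:
    payload = {
        "subject_id": cs.subject_id,
        "units": "mm",
        "contours": {
            "outer": cs.outer.points.tolist(),
            "lung_r": cs.lung_r.points.tolist(),
            "lung_l": cs.lung_l.points.tolist(),
            "cardiac": cs.cardiac.points.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_contours(path) -> ContourSet:
    payload = json.loads(Path(path).read_text())
    c = payload["contours"]
    return ContourSet(
        outer=Contour(np.asarray(c["outer"]), "outer"),
        lung_r=Contour(np.asarray(c["lung_r"]), "lung_r"),
        lung_l=Contour(np.asarray(c["lung_l"]), "lung_l"),
        cardiac=Contour(np.asarray(c["cardiac"]), "cardiac"),
        subject_id=payload.get("subject_id", ""),
    )
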