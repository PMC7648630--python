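"""Synthetic parenchyma generators with known chord-length ground truth.

Two geometries are provided: an axis-aligned square lattice whose airspace
chord statistics are known in closed form, and a seeded Voronoi tessellation
whose ground truth is obtained by brute-force horizontal-line sampling of the
continuous (pre-rasterization) geometry.  Degradations — capillary-like
lumens punched into walls and additive Gaussian render noise — exercise the
lumen-filling and thresholding stages of the morphometry pipeline.

Everything is a pure function of its spec, including the RNG seed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from skimage.morphology import disk

from .morphometry import AIRSPACE, WALL, BinaryMask, GrayImage, chord_runs

logger = logging.getLogger(__name__)

#: ground-truth sampling density relative to the default 20-line analysis grid
GT_LINE_FACTOR = 10
ANALYSIS_LINES = 20


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatticeSpec:
    """Square-airspace lattice: airspaces of side ``airspace_side`` µm
    separated (and framed) by walls of ``wall_thickness`` µm."""

    airspace_side: float
    wall_thickness: float
    pixel_size: float
    n_cells_x: int
    n_cells_y: int

    def __post_init__(self) -> None:
        if not self.airspace_side > 0:
            raise ValueError("airspace_side must be > 0")
        if not self.wall_thickness > 0:
            raise ValueError("wall_thickness must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells_x < 1 or self.n_cells_y < 1:
            raise ValueError("n_cells_x and n_cells_y must be >= 1")
        if self.airspace_side / self.pixel_size < 4:
            raise ValueError(
                "airspace_side must span at least 4 pixels to be resolvable"
            )


@dataclass(frozen=True)
class VoronoiSpec:
    """Voronoi-cell parenchyma on a rectangular field, walls along ridges."""

    n_seeds: int
    field_width: float
    field_height: float
    wall_thickness: float
    pixel_size: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.n_seeds < 2:
            raise ValueError("n_seeds must be >= 2")
        for name in ("field_width", "field_height", "wall_thickness", "pixel_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RenderSpec:
    """Brightfield rendering: bright airspace, dark walls, Gaussian noise."""

    airspace_intensity: float = 220.0
    wall_intensity: float = 60.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.wall_intensity <= 255 or not 0 <= self.airspace_intensity <= 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.airspace_intensity <= self.wall_intensity:
            raise ValueError(
                "brightfield convention requires airspace_intensity > wall_intensity"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruthGeometry:
    """Chord-length ground truth of a generated geometry (the oracle)."""

    true_mean_airspace_chord: float
    true_mean_wall_chord: float
    chord_sample: np.ndarray
    provenance: str  # "analytic" | "brute_force_sampled"

    def __post_init__(self) -> None:
        self.chord_sample = np.asarray(self.chord_sample, dtype=float)
        if (self.chord_sample <= 0).any():
            raise ValueError("all ground-truth chords must be positive")
        if self.provenance not in ("analytic", "brute_force_sampled"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_lattice(spec: LatticeSpec) -> tuple[BinaryMask, GroundTruthGeometry]:
    """Axis-aligned lattice of square airspaces.

    Every horizontal chord through an airspace equals ``airspace_side``, so
    the ground truth is analytic and exact.
    """
    a = round(spec.airspace_side / spec.pixel_size)
    w = round(spec.wall_thickness / spec.pixel_size)
    if w < 1:
        raise ValueError("wall_thickness must span at least 1 pixel")
    H = spec.n_cells_y * a + (spec.n_cells_y + 1) * w
    W = spec.n_cells_x * a + (spec.n_cells_x + 1) * w
    phase = np.full((H, W), WALL, dtype=np.uint8)
    for iy in range(spec.n_cells_y):
        r0 = w + iy * (a + w)
        for ix in range(spec.n_cells_x):
            c0 = w + ix * (a + w)
            phase[r0 : r0 + a, c0 : c0 + a] = AIRSPACE
    gt = GroundTruthGeometry(
        true_mean_airspace_chord=spec.airspace_side,
        true_mean_wall_chord=spec.wall_thickness,
        chord_sample=np.array([spec.airspace_side]),
        provenance="analytic",
    )
    return BinaryMask(phase, pixel_size=spec.pixel_size), gt


def _voronoi_seeds(spec: VoronoiSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.rng_seed)
    seeds = rng.uniform(
        (0.0, 0.0), (spec.field_width, spec.field_height), size=(spec.n_seeds, 2)
    )
    # collinear seeds give a degenerate tessellation; perturb and retry
    for _ in range(10):
        centered = seeds - seeds.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) >= 2:
            return seeds
        logger.warning("degenerate (collinear) Voronoi seeds; perturbing")
        jitter = rng.normal(0, 1e-3 * min(spec.field_width, spec.field_height),
                            size=seeds.shape)
        seeds = np.clip(seeds + jitter, 0, (spec.field_width, spec.field_height))
    raise RuntimeError("could not obtain a non-degenerate seed set")


def _wall_indicator(tree: cKDTree, pts: np.ndarray, wall_thickness: float) -> np.ndarray:
    """True where a point lies within the dilated ridge region.

    A point belongs to the wall when the gap between its two nearest-seed
    distances is at most the wall thickness — the distance to the ridge
    (perpendicular bisector) is (d2 - d1) / 2.
    """
    d, _ = tree.query(pts, k=2)
    return (d[:, 1] - d[:, 0]) <= wall_thickness


def generate_voronoi(spec: VoronoiSpec) -> tuple[BinaryMask, GroundTruthGeometry]:
    """Voronoi parenchyma with brute-force-sampled chord ground truth.

    The mask rasterises the continuous wall indicator at pixel centres; the
    ground truth samples the same continuous geometry along horizontal lines
    at >= 10x the analysis line density and sub-pixel x resolution, keeping
    complete chords only (bounded by wall on both ends).
    """
    seeds = _voronoi_seeds(spec)
    tree = cKDTree(seeds)
    W = round(spec.field_width / spec.pixel_size)
    H = round(spec.field_height / spec.pixel_size)
    xs = (np.arange(W) + 0.5) * spec.pixel_size
    ys = (np.arange(H) + 0.5) * spec.pixel_size
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    phase = _wall_indicator(tree, pts, spec.wall_thickness).reshape(H, W)
    mask = BinaryMask(phase.astype(np.uint8), pixel_size=spec.pixel_size)

    n_lines = GT_LINE_FACTOR * ANALYSIS_LINES
    step = spec.pixel_size / 4.0
    gx = np.arange(step / 2.0, spec.field_width, step)
    gy = (np.arange(n_lines) + 0.5) * spec.field_height / n_lines
    air_chords: list[np.ndarray] = []
    wall_chords: list[np.ndarray] = []
    for y in gy:
        line_pts = np.column_stack([gx, np.full_like(gx, y)])
        wall_line = _wall_indicator(tree, line_pts, spec.wall_thickness)
        a_len, _ = chord_runs(wall_line.astype(np.uint8), AIRSPACE)
        w_len, _ = chord_runs(wall_line.astype(np.uint8), WALL)
        air_chords.append(a_len * step)
        wall_chords.append(w_len * step)
    air = np.concatenate(air_chords)
    wall = np.concatenate(wall_chords)
    if air.size == 0:
        raise RuntimeError("ground-truth sampling found no complete airspace chords")
    gt = GroundTruthGeometry(
        true_mean_airspace_chord=float(air.mean()),
        true_mean_wall_chord=float(wall.mean()) if wall.size else float("nan"),
        chord_sample=air,
        provenance="brute_force_sampled",
    )
    return mask, gt


def punch_lumens(
    mask: BinaryMask, n_holes: int, hole_radius_px: int, rng_seed: int
) -> BinaryMask:
    """Punch airspace-phase disks strictly interior to walls.

    Hole centres are drawn (without replacement, seeded) from wall pixels
    whose Euclidean distance to the airspace phase exceeds ``hole_radius_px``,
    so no hole touches the input's airspace.  If fewer candidate centres
    exist than requested, as many holes as possible are placed and a warning
    reports the count.
    """
    if n_holes < 0 or hole_radius_px < 0:
        raise ValueError("n_holes and hole_radius_px must be >= 0")
    phase = mask.phase.copy()
    if n_holes == 0:
        return replace(mask, phase=phase)
    dist = distance_transform_edt(phase)
    candidates = np.argwhere(dist > hole_radius_px)
    rng = np.random.default_rng(rng_seed)
    n_place = min(n_holes, len(candidates))
    if n_place < n_holes:
        logger.warning(
            "only %d of %d requested lumens fit strictly inside walls",
            n_place,
            n_holes,
        )
    if n_place == 0:
        return replace(mask, phase=phase)
    chosen = candidates[rng.choice(len(candidates), size=n_place, replace=False)]
    fp = disk(hole_radius_px).astype(bool)
    r = hole_radius_px
    H, W = phase.shape
    for cy, cx in chosen:
        y0, y1 = cy - r, cy + r + 1
        x0, x1 = cx - r, cx + r + 1
        fy0, fx0 = max(0, -y0), max(0, -x0)
        fy1 = fp.shape[0] - max(0, y1 - H)
        fx1 = fp.shape[1] - max(0, x1 - W)
        view = phase[max(0, y0) : min(H, y1), max(0, x0) : min(W, x1)]
        view[fp[fy0:fy1, fx0:fx1]] = AIRSPACE
    return replace(mask, phase=phase)


def render_grayscale(mask: BinaryMask, spec: RenderSpec) -> GrayImage:
    """Render a phase mask as an 8-bit brightfield-like grayscale image.

    Airspace and wall pixels get their nominal intensity plus i.i.d. Gaussian
    noise, clipped to [0, 255] and quantised with round-half-up.
    """
    rng = np.random.default_rng(spec.rng_seed)
    base = np.where(
        mask.phase == WALL, spec.wall_intensity, spec.airspace_intensity
    ).astype(np.float64)
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    img = np.floor(np.clip(base, 0, 255) + 0.5).astype(np.uint8)
    return GrayImage(img, pixel_size=mask.pixel_size, source_path="<synthetic>")


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(
    out_dir: str | Path,
    mask: BinaryMask,
    ground_truth: GroundTruthGeometry,
    spec,
    render_spec: RenderSpec | None = None,
    image_format: str = "png",
) -> dict[str, Path]:
    """Write a synthetic fixture: image, mask, chord CSV and a JSON sidecar.

    Returns the paths written, keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_spec = render_spec or RenderSpec()
    image = render_grayscale(mask, render_spec)
    if image_format not in ("png", "tif", "tiff"):
        raise ValueError("image_format must be png or tif")
    paths = {
        "image": out / f"image.{image_format}",
        "mask": out / "mask.png",
        "chords": out / "chords.csv",
        "meta": out / "meta.json",
    }
    iio.imwrite(paths["image"], image.intensities)
    iio.imwrite(paths["mask"], (mask.phase * 255).astype(np.uint8))
    with open(paths["chords"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chord_um"])
        for c in ground_truth.chord_sample:
            writer.writerow([f"{c:.6g}"])
    meta = {
        "spec": asdict(spec),
        "spec_type": type(spec).__name__,
        "render": asdict(render_spec),
        "pixel_size": mask.pixel_size,
        "true_mean_airspace_chord": ground_truth.true_mean_airspace_chord,
        "true_mean_wall_chord": ground_truth.true_mean_wall_chord,
        "provenance": ground_truth.provenance,
    }
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=2)
    return paths
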