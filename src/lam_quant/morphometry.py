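"""Mean linear intercept (MLI) and alveolar septal thickness (AST) morphometry.

The pipeline goes from a brightfield histology image file to per-image chord
statistics:

1. load the image as 8-bit grayscale (RGB is reduced to Rec. 601 luminance),
2. binarize with a global Otsu threshold,
3. morphologically close the wall phase to fill capillary lumens,
4. carry the result in an explicit airspace=0 / wall=1 phase convention,
5. lay a horizontal grid of equally spaced test lines over the image,
6. measure airspace and wall chords and wall intersections along the lines,
7. summarise the chord-length histograms (MLI, SD, dispersion index, AST).

All lengths are reported in micrometres using the user-supplied pixel size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing
from skimage.morphology import disk

logger = logging.getLogger(__name__)

AIRSPACE = 0
WALL = 1

#: the single phase convention used throughout the package
CONVENTION = "airspace0_wall1"


class EmptyResultError(ValueError):
    """Raised when no complete chords are available for statistics."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GrayImage:
    """2-D 8-bit intensity raster with physical pixel size.

    Parameters
    ----------
    intensities : numpy.ndarray
        ``(H, W)`` array of dtype ``uint8``.
    pixel_size : float
        Edge length of one pixel in micrometres.
    source_path : str
        Origin of the image, for bookkeeping only.
    """

    intensities: np.ndarray
    pixel_size: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 2-D array")
        if self.intensities.dtype != np.uint8:
            raise ValueError("intensities must be uint8 (0-255)")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class BinaryMask:
    """2-D phase raster: airspace pixels are 0, wall (tissue) pixels are 1."""

    phase: np.ndarray
    pixel_size: float
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase).astype(np.uint8)
        if self.phase.ndim != 2 or self.phase.size == 0:
            raise ValueError("phase must be a non-empty 2-D array")
        if not np.isin(self.phase, (0, 1)).all():
            raise ValueError("phase values must be 0 (airspace) or 1 (wall)")
        if self.convention != CONVENTION:
            raise ValueError(f"unsupported phase convention {self.convention!r}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    def wall_fraction(self) -> float:
        return float(self.phase.mean())


@dataclass(frozen=True)
class LineGrid:
    """Horizontal test lines given as strictly increasing pixel row indices."""

    rows: tuple[int, ...]

    def __post_init__(self) -> None:
        rows = tuple(int(r) for r in self.rows)
        object.__setattr__(self, "rows", rows)
        if len(rows) == 0:
            raise ValueError("grid must contain at least one line")
        if any(b <= a for a, b in zip(rows, rows[1:])):
            raise ValueError("grid rows must be strictly increasing")
        if rows[0] < 0:
            raise ValueError("grid rows must be non-negative")

    @property
    def n_lines(self) -> int:
        return len(self.rows)


@dataclass
class InterceptSet:
    """Chord lengths (µm) and wall-intersection counts measured on a grid.

    ``airspace_chords`` and ``wall_chords`` hold complete chords only, i.e.
    runs bounded by the opposite phase on both ends.  Runs cut off by the
    image border are tallied in ``n_truncated`` (airspace phase) and excluded
    unless the caller asked otherwise.
    """

    airspace_chords: np.ndarray
    wall_chords: np.ndarray
    wall_intersections: int
    n_truncated: int
    per_line_counts: list[int]
    total_line_length_um: float = 0.0

    def __post_init__(self) -> None:
        self.airspace_chords = np.asarray(self.airspace_chords, dtype=float)
        self.wall_chords = np.asarray(self.wall_chords, dtype=float)
        if (self.airspace_chords <= 0).any() or (self.wall_chords <= 0).any():
            raise ValueError("all chord lengths must be positive")
        if self.wall_intersections < 0:
            raise ValueError("wall_intersections must be >= 0")


@dataclass
class MorphometryResult:
    """Per-image summary of the chord-length histograms."""

    mli: float
    mli_sd: float
    dispersion_index: float
    ast: float
    ast_sd: float
    n_chords: int
    image_id: str = ""
    n_truncated: int = 0
    threshold: int | None = None
    #: classic count-based estimate: total line length / wall intersections
    mli_count_based: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "mli": self.mli,
            "mli_sd": self.mli_sd,
            "dispersion_index": self.dispersion_index,
            "ast": self.ast,
            "ast_sd": self.ast_sd,
            "n_chords": self.n_chords,
            "n_truncated": self.n_truncated,
            "threshold": self.threshold,
            "mli_count_based": self.mli_count_based,
        }


@dataclass
class MorphometryConfig:
    """Tunable parameters of :func:`analyze_image`."""

    pixel_size: float
    n_lines: int = 20
    closing_radius: int = 3
    min_chord: float = 0.0
    keep_truncated: bool = False
    dispersion: str = "variance_over_mean"  # or "cv"
    dump_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.min_chord < 0:
            raise ValueError("min_chord must be >= 0")
        if self.dispersion not in ("variance_over_mean", "cv"):
            raise ValueError("dispersion must be 'variance_over_mean' or 'cv'")


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def load_grayscale(path: str | Path, pixel_size: float) -> GrayImage:
    """Read a TIFF/PNG/JPEG image as an 8-bit grayscale :class:`GrayImage`.

    RGB(A) input is converted to luminance with Rec. 601 weights
    (0.299, 0.587, 0.114) and rounded half-up; 16-bit input is rescaled
    to the 0-255 range.
    """
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise OSError(f"could not read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    is_16bit = arr.dtype == np.uint16
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0].astype(np.float64)
        else:
            rgb = arr[:, :, :3].astype(np.float64)
            arr = rgb @ np.array([0.299, 0.587, 0.114])
    elif arr.ndim == 2:
        arr = arr.astype(np.float64)
    else:
        raise OSError(f"unsupported image dimensionality in {path}: {arr.shape}")
    if is_16bit:
        arr = arr / 65535.0 * 255.0
    arr = np.floor(np.clip(arr, 0, 255) + 0.5).astype(np.uint8)
    return GrayImage(arr, pixel_size=pixel_size, source_path=str(path))


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold of a 256-bin histogram.

    Returns the lowest t in [0, 254] maximising the between-class variance
    of the classes {intensity <= t} and {intensity > t}.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("histogram has fewer than 2 distinct intensities")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    m0 = np.cumsum(hist * levels)[:-1]
    mu_total = float((hist * levels).sum())
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=valid)
    mu1 = np.divide(mu_total - m0, w1, out=np.zeros_like(m0), where=valid)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximiser


def binarize_otsu(image: GrayImage) -> tuple[int, BinaryMask]:
    """Global Otsu binarization.

    Pixels brighter than the threshold are airspace (brightfield convention:
    stained tissue dark, airspace bright); the returned mask already encodes
    the airspace=0 / wall=1 convention, i.e. the inversion step of the
    pipeline is folded in here.
    """
    hist = np.bincount(image.intensities.ravel(), minlength=256)
    try:
        threshold = otsu_threshold(hist)
    except ValueError as exc:
        raise ValueError(
            f"cannot threshold image {image.source_path or '<array>'}: {exc}"
        ) from exc
    wall = (image.intensities <= threshold).astype(np.uint8)
    return threshold, BinaryMask(wall, pixel_size=image.pixel_size)


def fill_lumens(mask: BinaryMask, radius_px: int) -> BinaryMask:
    """Fill capillary lumens by morphological closing of the wall phase.

    Closing = dilation then erosion with a disk of ``radius_px``; airspace
    holes inside walls with diameter <= 2*radius_px become wall.  The border
    is padded with airspace so that airspace touching the image edge is never
    spuriously closed.
    """
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    if radius_px == 0:
        return replace(mask, phase=mask.phase.copy())
    pad = radius_px + 1
    padded = np.pad(mask.phase.astype(bool), pad, constant_values=False)
    closed = binary_closing(padded, structure=disk(radius_px).astype(bool))
    out = closed[pad:-pad, pad:-pad].astype(np.uint8)
    return replace(mask, phase=out)


def make_line_grid(height_px: int, n_lines: int = 20) -> LineGrid:
    """Equally spaced horizontal lines, centered in ``height_px`` rows.

    Line i sits at row floor((i + 0.5) * height_px / n_lines), which keeps
    lines off the extreme border rows.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if height_px < n_lines:
        raise ValueError(
            f"image height {height_px} px cannot hold {n_lines} distinct lines"
        )
    idx = np.arange(n_lines)
    rows = np.floor((idx + 0.5) * height_px / n_lines).astype(int)
    return LineGrid(tuple(rows))


def chord_runs(line: np.ndarray, phase_value: int) -> tuple[np.ndarray, int]:
    """Run lengths (px) of ``phase_value`` along a 1-D line.

    Returns ``(complete_lengths, n_truncated)``: runs bounded by the opposite
    phase on both ends, and the number of runs touching either line end.
    """
    line = np.asarray(line)
    is_phase = line == phase_value
    if not is_phase.any():
        return np.empty(0, dtype=int), 0
    padded = np.concatenate(([False], is_phase, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    lengths = ends - starts
    complete = (starts > 0) & (ends < line.size)
    return lengths[complete], int((~complete).sum())


def measure_intercepts(
    mask: BinaryMask,
    grid: LineGrid,
    include_truncated: bool = False,
) -> InterceptSet:
    """Measure airspace/wall chords and wall intersections along grid lines.

    A chord is a maximal run of one phase along a line; it is complete when
    bounded by the opposite phase on both ends.  ``wall_intersections`` counts
    airspace-to-wall transitions along all lines.
    """
    if grid.n_lines == 0:
        raise ValueError("empty line grid")
    H, W = mask.shape
    if grid.rows[-1] >= H:
        raise ValueError(
            f"grid row {grid.rows[-1]} outside mask of height {H}"
        )
    px = mask.pixel_size
    air: list[np.ndarray] = []
    wall: list[np.ndarray] = []
    per_line_counts: list[int] = []
    n_truncated = 0
    intersections = 0
    for r in grid.rows:
        line = mask.phase[r]
        a_len, a_trunc = chord_runs(line, AIRSPACE)
        w_len, _ = chord_runs(line, WALL)
        if include_truncated:
            padded = np.concatenate(([False], line == AIRSPACE, [False]))
            diff = np.diff(padded.astype(np.int8))
            a_len = np.flatnonzero(diff == -1) - np.flatnonzero(diff == 1)
        air.append(a_len)
        wall.append(w_len)
        per_line_counts.append(int(a_len.size))
        n_truncated += a_trunc
        intersections += int(((line[:-1] == AIRSPACE) & (line[1:] == WALL)).sum())
    airspace_chords = np.concatenate(air) * px if air else np.empty(0)
    wall_chords = np.concatenate(wall) * px if wall else np.empty(0)
    return InterceptSet(
        airspace_chords=airspace_chords,
        wall_chords=wall_chords,
        wall_intersections=intersections,
        n_truncated=n_truncated,
        per_line_counts=per_line_counts,
        total_line_length_um=float(grid.n_lines * W * px),
    )


def compute_mli(
    intercepts: InterceptSet,
    dispersion: str = "variance_over_mean",
    image_id: str = "",
) -> MorphometryResult:
    """Summarise an :class:`InterceptSet` into MLI / AST statistics.

    MLI is the arithmetic mean of the complete airspace chord lengths; its SD
    uses the n-1 denominator; the dispersion index is the sample variance
    divided by the mean (or the coefficient of variation when
    ``dispersion="cv"``).  AST is computed identically on the wall chords.
    """
    ac = intercepts.airspace_chords
    if ac.size == 0:
        raise EmptyResultError(
            "no complete airspace chords; cannot compute MLI "
            f"(n_truncated={intercepts.n_truncated})"
        )
    mli = float(ac.mean())
    mli_sd = float(ac.std(ddof=1)) if ac.size > 1 else 0.0
    if dispersion == "variance_over_mean":
        disp = mli_sd**2 / mli
    elif dispersion == "cv":
        disp = mli_sd / mli
    else:
        raise ValueError(f"unknown dispersion formula {dispersion!r}")
    wc = intercepts.wall_chords
    if wc.size == 0:
        logger.warning("no complete wall chords in %s; AST reported as NaN", image_id)
        ast, ast_sd = float("nan"), float("nan")
    else:
        ast = float(wc.mean())
        ast_sd = float(wc.std(ddof=1)) if wc.size > 1 else 0.0
    if intercepts.wall_intersections > 0 and intercepts.total_line_length_um > 0:
        mli_count = intercepts.total_line_length_um / intercepts.wall_intersections
    else:
        mli_count = float("nan")
    return MorphometryResult(
        mli=mli,
        mli_sd=mli_sd,
        dispersion_index=float(disp),
        ast=ast,
        ast_sd=ast_sd,
        n_chords=int(ac.size),
        image_id=image_id,
        n_truncated=intercepts.n_truncated,
        mli_count_based=mli_count,
    )


def _apply_min_chord(intercepts: InterceptSet, min_chord: float) -> InterceptSet:
    if min_chord <= 0:
        return intercepts
    keep = intercepts.airspace_chords >= min_chord
    return replace(intercepts, airspace_chords=intercepts.airspace_chords[keep])


def analyze_mask(
    mask: BinaryMask,
    config: MorphometryConfig,
    image_id: str = "",
    threshold: int | None = None,
) -> MorphometryResult:
    """Run the grid/intercept/statistics stages on a binary mask."""
    filled = fill_lumens(mask, config.closing_radius)
    grid = make_line_grid(filled.shape[0], config.n_lines)
    intercepts = measure_intercepts(filled, grid, include_truncated=config.keep_truncated)
    intercepts = _apply_min_chord(intercepts, config.min_chord)
    result = compute_mli(intercepts, dispersion=config.dispersion, image_id=image_id)
    result.threshold = threshold
    if config.dump_dir is not None:
        _dump_intermediates(config.dump_dir, image_id, filled, grid)
    return result


def analyze_image(path: str | Path, config: MorphometryConfig) -> MorphometryResult:
    """Full deterministic pipeline: file -> MorphometryResult.

    Stage failures are re-raised with the stage name so batch runs can report
    which image and step failed.
    """
    path = Path(path)
    image_id = path.name
    try:
        image = load_grayscale(path, config.pixel_size)
    except Exception as exc:
        raise type(exc)(f"[load] {exc}") from exc
    try:
        threshold, mask = binarize_otsu(image)
    except ValueError as exc:
        raise ValueError(f"[binarize] {exc}") from exc
    return analyze_mask(mask, config, image_id=image_id, threshold=threshold)


def _dump_intermediates(
    dump_dir: str | Path, image_id: str, mask: BinaryMask, grid: LineGrid
) -> None:
    out = Path(dump_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = Path(image_id).stem or "image"
    overlay = (mask.phase * 255).astype(np.uint8)
    overlay[list(grid.rows), :] = 128
    iio.imwrite(out / f"{stem}_mask.png", (mask.phase * 255).astype(np.uint8))
    iio.imwrite(out / f"{stem}_grid.png", overlay)


def aggregate_by_subject(
    results: Sequence[MorphometryResult],
    subject_map: Mapping[str, str],
) -> pd.DataFrame:
    """Average per-image results per subject (e.g. per lung).

    Returns one row per subject with mean and SD of per-image MLI and AST and
    the image count.  Every image_id must be present in ``subject_map``.
    """
    missing = [r.image_id for r in results if r.image_id not in subject_map]
    if missing:
        raise ValueError(f"images without subject mapping: {missing}")
    frame = pd.DataFrame([r.to_dict() for r in results])
    frame["subject_id"] = frame["image_id"].map(dict(subject_map))
    grouped = frame.groupby("subject_id", sort=True)
    out = pd.DataFrame(
        {
            "n_images": grouped.size(),
            "mli_mean": grouped["mli"].mean(),
            "mli_sd": grouped["mli"].std(ddof=1).fillna(0.0),
            "ast_mean": grouped["ast"].mean(),
            "ast_sd": grouped["ast"].std(ddof=1).fillna(0.0),
        }
    ).reset_index()
    return out
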