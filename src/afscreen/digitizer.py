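"""ECG chart digitization: from a scanned/exported chart image to a signal.

The pipeline mirrors how a human would read a printed strip:

1.  rasterize the file (PNG/JPEG directly; PDF via optional pypdfium2),
2.  crop away headers and margins,
3.  wipe the background grid by mapping a colour box to white,
4.  binarize on darkness,
5.  drop small connected components (scanner specks, residual grid),
6.  thin the stroke so vertical runs tighten around the pen line,
7.  scan columns left to right collecting the vertical ink span per
    column, reduce each span to one row using the modal stroke thickness
    (thin columns keep the lower edge; thick columns — QRS flanks — keep
    the edge farthest from the running reference row),
8.  fill gaps by linear interpolation and convert rows/columns to
    mV/seconds using the chart geometry (paper speed, gain, dpi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import stats
from skimage.morphology import remove_small_objects, thin

from .core import ChartRenderConfig, Signal

__all__ = [
    "RasterImage",
    "BinaryImage",
    "ColumnSpans",
    "TraceVector",
    "rasterize",
    "crop",
    "remove_grid",
    "binarize",
    "despeckle",
    "shrink",
    "vertical_scan",
    "spans_to_trace",
    "interpolate_gaps",
    "trace_to_signal",
    "digitize",
]

#: reference despeckle area (px) at the reference scan resolution (600 dpi)
DEFAULT_MIN_AREA = 1260
REFERENCE_DPI = 600.0


@dataclass(frozen=True)
class RasterImage:
    """An RGB raster with its physical resolution."""

    pixels: np.ndarray  # rows x cols x 3, uint8
    dpi: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a rows x cols x 3 array")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BinaryImage:
    """Boolean trace mask (True = ink) with the source resolution."""

    mask: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class ColumnSpans:
    """Per-column vertical ink spans: (column, top_row, bottom_row).

    This is the chart's two-records-per-column representation: the span
    from row 27 to 28 in column 12 is the record (12, 27, 28).
    """

    records: List[Tuple[int, int, int]]

    def __post_init__(self) -> None:
        cols = [r[0] for r in self.records]
        if any(c2 < c1 for c1, c2 in zip(cols, cols[1:])):
            raise ValueError("columns must be non-decreasing")
        if any(t > b for _, t, b in self.records):
            raise ValueError("top_row must be <= bottom_row")


@dataclass(frozen=True)
class TraceVector:
    """One row coordinate per column; NaN marks a gap before interpolation."""

    y: np.ndarray  # float rows, NaN = gap
    mu: float  # modal vertical stroke thickness, pixels
    col_offset: int = 0

    @property
    def columns(self) -> int:
        return int(self.y.size)

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.y).any())


def rasterize(path: str | Path, dpi: float = 600.0) -> RasterImage:
    """Load a chart file as an RGB raster.

    PNG/JPEG pixels are passed through unchanged with ``dpi`` annotated
    (file metadata wins when present).  PDF input is rasterized at the
    requested dpi via pypdfium2 when installed (``pip install
    afscreen[pdf]``); only the first page is used, with a warning for
    multi-page documents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".pdf":
        try:
            import pypdfium2  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "PDF input requires pypdfium2 (install the 'pdf' extra); "
                "alternatively export the chart as PNG/JPEG"
            ) from exc
        doc = pypdfium2.PdfDocument(str(path))  # pragma: no cover
        if len(doc) > 1:  # pragma: no cover
            warnings.warn(f"{path} has {len(doc)} pages; using the first")
        page = doc[0]  # pragma: no cover
        bitmap = page.render(scale=dpi / 72.0)  # pragma: no cover
        arr = np.asarray(bitmap.to_pil().convert("RGB"))  # pragma: no cover
        return RasterImage(arr, dpi)  # pragma: no cover
    with Image.open(path) as im:
        file_dpi = im.info.get("dpi")
        arr = np.asarray(im.convert("RGB"))
    if file_dpi and file_dpi[0] > 0:
        dpi = float(file_dpi[0])
    return RasterImage(arr, dpi)


def crop(image: RasterImage, region: Tuple[int, int, int, int]) -> RasterImage:
    """Crop to ``(top, left, height, width)`` in pixel coordinates."""
    top, left, height, width = region
    rows, cols = image.shape
    if top < 0 or left < 0 or height <= 0 or width <= 0:
        raise ValueError("crop region must be non-negative with positive size")
    if top + height > rows or left + width > cols:
        raise ValueError("crop region exceeds image bounds")
    return RasterImage(image.pixels[top : top + height, left : left + width], image.dpi)


def remove_grid(
    image: RasterImage,
    lower: Sequence[int],
    upper: Sequence[int],
) -> RasterImage:
    """Map every pixel inside the RGB box [lower, upper] to white.

    This is the grid-removal threshold: the chart's background grid colours
    are enclosed in the box and wiped, leaving the trace untouched.
    """
    lower = np.asarray(lower, dtype=int)
    upper = np.asarray(upper, dtype=int)
    px = image.pixels.copy()
    inside = np.all((px >= lower) & (px <= upper), axis=2)
    px[inside] = 255
    return RasterImage(px, image.dpi)


def binarize(image: RasterImage, darkness_threshold: int = 128) -> BinaryImage:
    """Mark ink pixels: True where min(R, G, B) < darkness_threshold (strict)."""
    mask = image.pixels.min(axis=2) < darkness_threshold
    return BinaryImage(mask, image.dpi)


def despeckle(mask: BinaryImage, min_area: Optional[int] = None) -> BinaryImage:
    """Remove 8-connected components smaller than ``min_area`` pixels.

    A component of exactly ``min_area`` pixels is retained (strict <).
    The default area 1260 px refers to a 600 dpi scan and is rescaled by
    (dpi/600)^2 for other resolutions.
    """
    if min_area is None:
        min_area = int(round(DEFAULT_MIN_AREA * (mask.dpi / REFERENCE_DPI) ** 2))
    # strict <: a component of exactly min_area pixels survives
    cleaned = remove_small_objects(mask.mask, max_size=min_area - 1, connectivity=2)
    return BinaryImage(cleaned, mask.dpi)


def shrink(mask: BinaryImage, iterations: int = 2) -> BinaryImage:
    """Thin the stroke by morphological thinning, preserving connectivity."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask
    thinned = thin(mask.mask, max_num_iter=iterations)
    return BinaryImage(thinned, mask.dpi)


def vertical_scan(mask: BinaryImage) -> ColumnSpans:
    """Collect the per-column vertical ink span, left to right.

    Columns without ink emit no record.  When a column holds several
    disjoint runs (e.g. trace crossing a residual grid remnant), the run
    whose centre is closest to the previous column's kept span is used.
    """
    records: List[Tuple[int, int, int]] = []
    prev_centre: Optional[float] = None
    m = mask.mask
    for col in range(m.shape[1]):
        rows = np.flatnonzero(m[:, col])
        if rows.size == 0:
            continue
        # split into consecutive runs
        breaks = np.flatnonzero(np.diff(rows) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [rows.size - 1]])
        runs = [(int(rows[s]), int(rows[e])) for s, e in zip(starts, ends)]
        if len(runs) == 1:
            top, bottom = runs[0]
        elif prev_centre is None:
            # no history yet: prefer the longest run (most likely the trace)
            top, bottom = max(runs, key=lambda r: r[1] - r[0])
        else:
            top, bottom = min(
                runs, key=lambda r: abs((r[0] + r[1]) / 2 - prev_centre)
            )
        records.append((col, top, bottom))
        prev_centre = (top + bottom) / 2
    return ColumnSpans(records)


def spans_to_trace(spans: ColumnSpans) -> TraceVector:
    """Reduce column spans to one row per column via the modal-thickness rule.

    mu is the mode of the span thickness (bottom - top) over all columns.
    A column whose thickness is within mu keeps its bottom row, which also
    updates the running reference lambda.  A thicker column is a steep
    stroke (QRS flank): it keeps whichever edge lies farthest from lambda,
    so ascending flanks resolve to the R-peak side.  Columns between the
    first and last inked column that carry no ink become NaN gaps.
    """
    if not spans.records:
        raise ValueError("spans are empty — nothing to trace")
    cols = np.array([r[0] for r in spans.records])
    tops = np.array([r[1] for r in spans.records])
    bottoms = np.array([r[2] for r in spans.records])
    thickness = bottoms - tops
    mu = float(stats.mode(thickness, keepdims=False).mode)

    first, last = int(cols[0]), int(cols[-1])
    y = np.full(last - first + 1, np.nan)
    lam: Optional[float] = None
    for col, top, bottom, thick in zip(cols, tops, bottoms, thickness):
        if lam is None or thick <= mu:
            val = float(bottom)
        else:
            val = float(top) if abs(top - lam) > abs(bottom - lam) else float(bottom)
        y[col - first] = val
        lam = val
    return TraceVector(y, mu=mu, col_offset=first)


def interpolate_gaps(trace: TraceVector) -> TraceVector:
    """Fill NaN gaps by linear interpolation (edges by nearest value)."""
    y = trace.y.copy()
    good = ~np.isnan(y)
    if good.sum() < 2:
        raise ValueError("need at least two non-gap columns to interpolate")
    idx = np.arange(y.size)
    y = np.interp(idx, idx[good], y[good])  # np.interp extends edges by nearest
    return TraceVector(y, mu=trace.mu, col_offset=trace.col_offset)


def trace_to_signal(
    trace: TraceVector,
    cfg: ChartRenderConfig = ChartRenderConfig(),
    target_rate: float = 300.0,
) -> Signal:
    """Convert a trace to a uniformly sampled signal in mV.

    The baseline is the median trace row (robust; a vertical offset only
    adds a constant to the signal and cannot affect RR intervals or any
    ordinal-pattern feature).  Rows above baseline are positive mV.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if trace.has_gaps:
        trace = interpolate_gaps(trace)
    baseline = float(np.median(trace.y))
    amp_mv = (baseline - trace.y) * 25.4 / (cfg.dpi * cfg.gain)
    col_times = np.arange(trace.columns) * 25.4 / (cfg.dpi * cfg.paper_speed)
    duration = col_times[-1] if trace.columns > 1 else 0.0
    n_out = max(int(np.floor(duration * target_rate)) + 1, 1)
    t_out = np.arange(n_out) / target_rate
    samples = np.interp(t_out, col_times, amp_mv)
    return Signal(samples, target_rate)


def digitize(
    image: RasterImage,
    cfg: ChartRenderConfig = ChartRenderConfig(),
    grid_lower: Sequence[int] = (120, 120, 120),
    grid_upper: Sequence[int] = (255, 255, 255),
    darkness_threshold: int = 128,
    min_area: Optional[int] = None,
    shrink_iterations: int = 2,
    target_rate: float = 300.0,
    region: Optional[Tuple[int, int, int, int]] = None,
) -> Signal:
    """Full chart-to-signal pipeline with the default stage ordering."""
    if region is not None:
        image = crop(image, region)
    cleaned = remove_grid(image, grid_lower, grid_upper)
    mask = binarize(cleaned, darkness_threshold)
    mask = despeckle(mask, min_area)
    mask = shrink(mask, shrink_iterations)
    spans = vertical_scan(mask)
    if not spans.records:
        raise ValueError("no trace pixels found after preprocessing")
    trace = interpolate_gaps(spans_to_trace(spans))
    return trace_to_signal(trace, cfg, target_rate)
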