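"""Stroke geometry and manifestation analysis of scanned handwriting pages.

A scanned page is binarized (Otsu after affine luminosity/contrast
adjustment), segmented into 8-connected ink components ("strokes"),
ordered into reading order (row bands, then left to right), and analysed
for the Parkinsonian writing manifestations:

* binary flags — micrographia, progressive micrographia, baseline drift,
  irregular spacing — via empirical thresholds on stroke height/width
  relative to page size (all thresholds are config keys surfaced in the
  output metadata, since no canonical values exist);
* series-valued attributes — slant angle (Hough segments against the
  moving-average centroid baseline), height uniformity, and per-stroke
  tremor residual — which feed lag-correlation imaging.

Strokes here are connected components: a paper scan carries no pen
timeline, so reading order is the only recoverable ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import probabilistic_hough_line

from .features import FeatureSeries, ValidationError, moving_average

__all__ = [
    "PageImage",
    "BinaryPage",
    "Stroke",
    "StrokeSet",
    "BaselineTrack",
    "ManifestationFlags",
    "HandwritingConfig",
    "load_and_binarize",
    "binarize_page",
    "extract_strokes",
    "compute_baseline",
    "slant_angles",
    "size_flags",
    "uniformity_series",
    "tremor_series_writing",
    "extract_writing_series",
]


@dataclass
class PageImage:
    """Grayscale scan: 2-D intensity grid + resolution in dots per inch."""

    pixels: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("page must be a 2-D grayscale grid")
        if self.dpi <= 0:
            raise ValidationError("dpi must be > 0")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryPage:
    """Boolean ink mask (True = ink) at the source resolution."""

    mask: np.ndarray
    dpi: float

    @property
    def height_px(self) -> int:
        return self.mask.shape[0]

    @property
    def width_px(self) -> int:
        return self.mask.shape[1]


@dataclass
class Stroke:
    """One connected ink component with its geometry summary."""

    id: int
    bbox: tuple  # (min_row, min_col, max_row, max_col), half-open
    centroid: tuple  # (row, col)
    area_px: int
    line_index: int = -1
    curvature: float = np.nan  # mean |turning angle| along the skeleton path, rad

    @property
    def height_px(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def width_px(self) -> int:
        return self.bbox[3] - self.bbox[1]


@dataclass
class StrokeSet:
    strokes: list
    labels: np.ndarray  # labelled component image (0 = background)
    dpi: float

    def __len__(self) -> int:
        return len(self.strokes)

    def heights(self) -> np.ndarray:
        return np.array([s.height_px for s in self.strokes], dtype=float)


@dataclass
class BaselineTrack:
    """Smoothed centroid vertical position along reading order, per text line."""

    per_line: list  # list of (stroke_ids, centroid_x, baseline_y) arrays per line
    window: int


@dataclass
class ManifestationFlags:
    micrographia: bool
    progressive_micrographia: bool
    baseline_drift: bool
    spacing: bool
    thresholds: dict = field(default_factory=dict)
    defined: bool = True


@dataclass
class HandwritingConfig:
    """Empirical thresholds and analysis parameters (defaults per field)."""

    min_blob_px: int = 9
    baseline_window: int = 9
    horiz_exclusion_deg: float = 20.0
    hough_threshold: int = 10
    hough_line_gap: int = 3
    min_len_rel_height: float = 0.5  # min Hough length = this x median stroke height
    tremor_smooth_window: int = 7
    theta_micrographia: float = 0.009  # median height / page height (~2.7 mm on A4)
    theta_progressive: float = 0.25  # first-to-last-third relative height decline
    theta_spacing_cv: float = 0.9  # CV of inter-stroke horizontal gaps
    theta_baseline: float = 1.5  # peak-to-peak baseline excursion / median height
    hough_seed: int = 12345


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize_page(
    page: PageImage,
    luminosity_adjust: float = 0.0,
    contrast_adjust: float = 1.0,
    cfg: HandwritingConfig | None = None,
) -> BinaryPage:
    """Affine intensity adjustment, Otsu threshold, ink = minority darker class.

    Otsu's threshold is invariant to affine intensity shifts, so a uniformly
    brighter or darker scan of the same page yields the same mask.  If the
    darker class covers the majority of the page (inverted-polarity scan),
    polarity is flipped so ink remains the minority class.  Components
    smaller than ``min_blob_px`` are removed as specks.
    """
    cfg = cfg or HandwritingConfig()
    img = page.pixels.astype(float)
    img = contrast_adjust * (img - img.mean()) + img.mean() + luminosity_adjust
    if np.ptp(img) == 0:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        thr = threshold_otsu(img)
        mask = img < thr
        if mask.mean() > 0.5:
            mask = ~mask
        mask = morphology.remove_small_objects(mask, max_size=cfg.min_blob_px - 1)
    return BinaryPage(mask, page.dpi)


def load_and_binarize(
    path,
    luminosity_adjust: float = 0.0,
    contrast_adjust: float = 1.0,
    dpi: float | None = None,
    cfg: HandwritingConfig | None = None,
) -> BinaryPage:
    """Open a JPEG/PNG scan and binarize it.

    Resolution comes from the file's dpi metadata unless overridden; a scan
    without either raises a validation error.
    """
    with Image.open(path) as im:
        meta_dpi = im.info.get("dpi")
        gray = np.asarray(im.convert("L"), dtype=float)
    if dpi is None:
        if not meta_dpi or not meta_dpi[0]:
            raise ValidationError(f"{path}: no dpi metadata; pass an explicit dpi")
        dpi = float(meta_dpi[0])
    return binarize_page(PageImage(gray, dpi), luminosity_adjust, contrast_adjust, cfg)


# ---------------------------------------------------------------------------
# strokes and reading order
# ---------------------------------------------------------------------------


def _order_skeleton_path(coords: np.ndarray) -> np.ndarray:
    """Order skeleton pixels by tracing the longest 8-connected path.

    Two breadth-first sweeps find the skeleton's diameter (farthest pixel
    from an arbitrary start, then farthest from that), which handles curved
    glyphs where a principal-axis projection would fold the path back on
    itself.  Side branches are dropped.
    """
    n = coords.shape[0]
    if n < 3:
        return coords
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    adj = [[] for _ in range(n)]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((int(r) + dr, int(c) + dc))
                if j is not None:
                    adj[i].append(j)

    def bfs(start):
        parent = np.full(n, -1)
        seen = np.zeros(n, dtype=bool)
        seen[start] = True
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        parent[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, parent

    a, _ = bfs(0)
    b, parent = bfs(a)
    path = [b]
    while parent[path[-1]] != -1:
        path.append(int(parent[path[-1]]))
    return coords[np.array(path[::-1])]


def _stroke_curvature(crop: np.ndarray) -> float:
    skel = morphology.skeletonize(crop)
    coords = np.column_stack(np.nonzero(skel)).astype(float)
    if coords.shape[0] < 5:
        return 0.0
    path = _order_skeleton_path(coords)
    d = np.diff(path, axis=0)
    ang = np.arctan2(d[:, 0], d[:, 1])
    turn = np.diff(np.unwrap(ang))
    return float(np.mean(np.abs(turn)))


def _cluster_lines(strokes: list) -> None:
    """Assign line indices by splitting the sorted centroid rows at large gaps."""
    if not strokes:
        return
    med_h = float(np.median([s.height_px for s in strokes]))
    ys = np.array([s.centroid[0] for s in strokes])
    order = np.argsort(ys, kind="stable")
    gap = 1.2 * max(med_h, 1.0)
    line = 0
    prev_y = ys[order[0]]
    for idx in order:
        if ys[idx] - prev_y > gap:
            line += 1
        strokes[idx].line_index = line
        prev_y = ys[idx]


def extract_strokes(page: BinaryPage, compute_curvature: bool = True) -> StrokeSet:
    """8-connected components in reading order (row bands, then left->right)."""
    labels = measure.label(page.mask, connectivity=2)
    props = measure.regionprops(labels)
    strokes = []
    for p in props:
        strokes.append(
            Stroke(
                id=p.label,
                bbox=tuple(p.bbox),
                centroid=tuple(p.centroid),
                area_px=int(p.area),
            )
        )
    _cluster_lines(strokes)
    strokes.sort(key=lambda s: (s.line_index, s.centroid[1]))
    if compute_curvature:
        for s in strokes:
            r0, c0, r1, c1 = s.bbox
            crop = labels[r0:r1, c0:c1] == s.id
            s.curvature = _stroke_curvature(crop)
    return StrokeSet(strokes, labels, page.dpi)


def compute_baseline(
    strokes: StrokeSet, window: int | None = None, cfg: HandwritingConfig | None = None
) -> BaselineTrack:
    """Moving-average filter over stroke centroid rows, per text line.

    The centered window shrinks at line edges, so a linear centroid ramp is
    reproduced exactly at interior points and high-frequency wobble is
    attenuated.
    """
    cfg = cfg or HandwritingConfig()
    window = cfg.baseline_window if window is None else window
    if len(strokes) < 1:
        raise ValidationError("need at least one stroke for a baseline")
    per_line = []
    lines = sorted({s.line_index for s in strokes.strokes})
    for li in lines:
        members = [s for s in strokes.strokes if s.line_index == li]
        ids = np.array([s.id for s in members])
        xs = np.array([s.centroid[1] for s in members])
        ys = np.array([s.centroid[0] for s in members])
        per_line.append((ids, xs, moving_average(ys, window)))
    return BaselineTrack(per_line, window)


# ---------------------------------------------------------------------------
# slant
# ---------------------------------------------------------------------------


def _line_direction_deg(xs: np.ndarray, ys: np.ndarray) -> float:
    """Baseline direction (degrees from image-horizontal) by least squares."""
    if xs.size < 2 or np.ptp(xs) == 0:
        return 0.0
    slope = np.polyfit(xs, ys, 1)[0]
    return float(np.degrees(np.arctan(slope)))


def slant_angles(
    page: BinaryPage,
    baseline: BaselineTrack,
    strokes: StrokeSet | None = None,
    min_len_px: float | None = None,
    horiz_excl_deg: float | None = None,
    cfg: HandwritingConfig | None = None,
) -> FeatureSeries:
    """Signed stroke slant per qualifying Hough segment (degrees).

    Probabilistic Hough segments on the ink mask are filtered: segments
    shorter than ``min_len_px`` (default half the median stroke height) or
    within ``horiz_excl_deg`` of the local baseline direction are excluded.
    The reported angle is measured from the baseline *normal* (0 deg =
    upright stroke, positive = leaning right), in reading order.
    """
    cfg = cfg or HandwritingConfig()
    horiz_excl = cfg.horiz_exclusion_deg if horiz_excl_deg is None else horiz_excl_deg
    if strokes is None:
        strokes = extract_strokes(page, compute_curvature=False)
    if len(strokes) == 0:
        return FeatureSeries("slant_angle_deg", np.empty(0), "deg")
    med_h = float(np.median(strokes.heights()))
    if min_len_px is None:
        min_len_px = cfg.min_len_rel_height * med_h
    rng = np.random.default_rng(cfg.hough_seed)
    segments = probabilistic_hough_line(
        page.mask,
        threshold=cfg.hough_threshold,
        line_length=max(3, int(round(min_len_px))),
        line_gap=cfg.hough_line_gap,
        rng=rng,
    )
    line_dirs = {}
    line_ys = {}
    for li, (_ids, xs, ys) in enumerate(baseline.per_line):
        line_dirs[li] = _line_direction_deg(xs, ys)
        line_ys[li] = float(np.mean(ys))
    if not line_ys:
        return FeatureSeries("slant_angle_deg", np.empty(0), "deg")

    entries = []
    for (x0, y0), (x1, y1) in segments:
        dx, dy = x1 - x0, y1 - y0
        length = np.hypot(dx, dy)
        if length < min_len_px:
            continue
        mid_y = 0.5 * (y0 + y1)
        mid_x = 0.5 * (x0 + x1)
        li = min(line_ys, key=lambda k: abs(line_ys[k] - mid_y))
        base_dir = line_dirs[li]
        # segment direction from horizontal, folded into (-90, 90]
        seg_dir = np.degrees(np.arctan2(dy, dx))
        rel = seg_dir - base_dir
        while rel <= -90:
            rel += 180
        while rel > 90:
            rel -= 180
        if abs(rel) < horiz_excl:  # near the baseline direction -> not a stroke
            continue
        # angle from the baseline normal, signed: positive = leaning right.
        # image rows grow downward, so an upright stroke has rel = -90 or +90.
        angle_from_normal = 90 - abs(rel)
        sign = -np.sign(rel) if rel != 0 else 1.0
        entries.append((li, mid_x, sign * angle_from_normal))
    entries.sort(key=lambda t: (t[0], t[1]))
    values = np.array([a for (_, _, a) in entries])
    fs = FeatureSeries("slant_angle_deg", values, "deg")
    fs.meta["n_segments"] = int(values.size)
    return fs


# ---------------------------------------------------------------------------
# flags and series
# ---------------------------------------------------------------------------


def _per_line_median_heights(strokes: StrokeSet) -> np.ndarray:
    lines = sorted({s.line_index for s in strokes.strokes})
    return np.array(
        [
            np.median([s.height_px for s in strokes.strokes if s.line_index == li])
            for li in lines
        ],
        dtype=float,
    )


def size_flags(
    strokes: StrokeSet,
    page: BinaryPage,
    baseline: BaselineTrack | None = None,
    cfg: HandwritingConfig | None = None,
) -> ManifestationFlags:
    """Binary manifestation flags from empirical thresholds.

    micrographia: median stroke height / page height < theta_m.
    progressive micrographia: per-line median height declines from the
    first to the last third of lines by more than theta_p (relative).
    spacing: coefficient of variation of within-line inter-stroke
    horizontal gaps > theta_s.
    baseline drift: peak-to-peak baseline excursion within a line >
    theta_b x median stroke height.
    """
    cfg = cfg or HandwritingConfig()
    thresholds = {
        "theta_micrographia": cfg.theta_micrographia,
        "theta_progressive": cfg.theta_progressive,
        "theta_spacing_cv": cfg.theta_spacing_cv,
        "theta_baseline": cfg.theta_baseline,
    }
    if len(strokes) < 3:
        return ManifestationFlags(False, False, False, False, thresholds, defined=False)
    heights = strokes.heights()
    med_h = float(np.median(heights))
    micro = med_h / page.height_px < cfg.theta_micrographia

    line_med = _per_line_median_heights(strokes)
    n_lines = line_med.size
    third = max(1, n_lines // 3)
    first, last = np.median(line_med[:third]), np.median(line_med[-third:])
    progressive = bool(first > 0 and (first - last) / first > cfg.theta_progressive)

    gaps = []
    lines = sorted({s.line_index for s in strokes.strokes})
    for li in lines:
        members = sorted(
            (s for s in strokes.strokes if s.line_index == li), key=lambda s: s.bbox[1]
        )
        for a, b in zip(members[:-1], members[1:]):
            gaps.append(max(0.0, b.bbox[1] - a.bbox[3]))
    gaps = np.array(gaps)
    spacing = bool(gaps.size >= 2 and gaps.mean() > 0 and gaps.std() / gaps.mean() > cfg.theta_spacing_cv)

    if baseline is None:
        baseline = compute_baseline(strokes, cfg=cfg)
    drift = False
    for _ids, _xs, ys in baseline.per_line:
        if ys.size >= 2 and np.ptp(ys) > cfg.theta_baseline * med_h:
            drift = True
            break
    return ManifestationFlags(bool(micro), progressive, drift, spacing, thresholds)


def uniformity_series(strokes: StrokeSet) -> FeatureSeries:
    """Stroke heights normalized by the page median, in reading order."""
    heights = strokes.heights()
    if heights.size == 0:
        return FeatureSeries("uniformity", np.empty(0), "")
    med = float(np.median(heights))
    return FeatureSeries("uniformity", heights / med if med > 0 else heights, "")


def tremor_series_writing(
    strokes: StrokeSet, smooth_window: int | None = None, cfg: HandwritingConfig | None = None
) -> FeatureSeries:
    """Per-stroke RMS tremor residual (px) around the smoothed skeleton path.

    Each stroke's skeleton is ordered along its principal axis; the RMS of
    the perpendicular coordinate around its moving-average-smoothed version
    measures high-frequency path oscillation.  One value per stroke, in
    reading order.
    """
    cfg = cfg or HandwritingConfig()
    window = cfg.tremor_smooth_window if smooth_window is None else window_check(smooth_window)
    out = []
    for s in strokes.strokes:
        r0, c0, r1, c1 = s.bbox
        crop = strokes.labels[r0:r1, c0:c1] == s.id
        skel = morphology.skeletonize(crop)
        coords = np.column_stack(np.nonzero(skel)).astype(float)
        if coords.shape[0] < window + 2:
            out.append(0.0)
            continue
        path = _order_skeleton_path(coords)
        smooth_r = moving_average(path[:, 0], window)
        smooth_c = moving_average(path[:, 1], window)
        resid2 = (path[:, 0] - smooth_r) ** 2 + (path[:, 1] - smooth_c) ** 2
        out.append(float(np.sqrt(np.mean(resid2))))
    return FeatureSeries("writing_tremor_px", np.array(out), "px")


def window_check(w: int) -> int:
    if w < 1:
        raise ValidationError("smoothing window must be >= 1")
    return w


def extract_writing_series(page: BinaryPage, cfg: HandwritingConfig | None = None) -> dict:
    """Full handwriting front end: flags + the three imaging series.

    Returns ``{"flags": ManifestationFlags, "angle": ..., "uniformity":
    ..., "tremor": ...}`` with series in reading order, imaging-ready.
    """
    cfg = cfg or HandwritingConfig()
    strokes = extract_strokes(page, compute_curvature=False)
    if len(strokes) == 0:
        raise ValidationError("empty page: no strokes found")
    baseline = compute_baseline(strokes, cfg=cfg)
    flags = size_flags(strokes, page, baseline, cfg)
    return {
        "flags": flags,
        "angle": slant_angles(page, baseline, strokes, cfg=cfg),
        "uniformity": uniformity_series(strokes),
        "tremor": tremor_series_writing(strokes, cfg=cfg),
    }
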