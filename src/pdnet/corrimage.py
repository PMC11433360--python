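"""Lag-shifted signal spaces, Pearson correlation matrices, and their images.

A feature series is expanded into a *signal space* of 50 forward-lagged
copies (step 1 frame, truncated to common support — no wraparound, which
would fabricate periodicity).  The 50x50 matrix of pairwise Pearson
correlations is the core representation classified downstream: its texture
encodes the temporal organization of the feature (smooth prosodic
modulation -> high off-diagonal correlation, cycle-to-cycle perturbation
-> rapid decay with lag, periodic tremor -> banding at the tremor lag).

Matrices serialize as plain 50x50 CSV; images map correlation 0 to blue
(0,0,255) and 1 to yellow (255,255,0) by a linear RGB ramp (negative
values are clipped for display only; the CSV retains signs).  Composite
"SoC-style" images tile several blocks into one canvas with region areas
proportional to significance weights (guillotine layout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSeries, ValidationError

__all__ = [
    "SignalSpace",
    "CorrelationMatrix",
    "CompositeBlock",
    "CompositeLayout",
    "build_signal_space",
    "correlation_matrix",
    "series_to_matrix",
    "matrix_to_csv",
    "csv_to_matrix",
    "value_to_rgb",
    "matrix_to_image",
    "compose_soc",
    "composite_to_image",
    "combined_manifestation_sets",
    "required_series_length",
]

N_SHIFTS_DEFAULT = 50
MIN_SUPPORT_DEFAULT = 50


@dataclass
class SignalSpace:
    """Stack of lag-shifted copies of a series, truncated to common support."""

    instances: np.ndarray  # (n_shifts, support)
    shift_step: int
    source_name: str

    @property
    def n_shifts(self) -> int:
        return self.instances.shape[0]


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal Pearson matrix of a signal space."""

    values: np.ndarray
    feature_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-9:
            raise ValidationError("correlation matrix must be symmetric")
        if np.max(np.abs(np.diag(v) - 1.0)) > 1e-9:
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.min(v) < -1 - 1e-9 or np.max(v) > 1 + 1e-9:
            raise ValidationError("correlation entries must lie in [-1, 1]")
        self.values = v


def required_series_length(
    n_shifts: int = N_SHIFTS_DEFAULT,
    shift_step: int = 1,
    min_support: int = MIN_SUPPORT_DEFAULT,
) -> int:
    """Minimum series length for a valid signal space."""
    return (n_shifts - 1) * shift_step + min_support


def build_signal_space(
    series: FeatureSeries,
    n_shifts: int = N_SHIFTS_DEFAULT,
    shift_step: int = 1,
    min_support: int = MIN_SUPPORT_DEFAULT,
) -> SignalSpace:
    """Expand a series into n_shifts forward-lagged copies.

    Instance k is ``series[k*step : k*step + L]`` with common support
    ``L = len - (n_shifts - 1) * step``; the series must be long enough
    that ``L >= min_support``.
    """
    x = np.asarray(series.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError(
            f"{series.name}: drop sentinel (NaN) values before building a signal space"
        )
    need = required_series_length(n_shifts, shift_step, min_support)
    if x.size < need:
        raise ValidationError(
            f"{series.name}: series of length {x.size} too short for "
            f"{n_shifts} shifts of step {shift_step}; need >= {need}"
        )
    support = x.size - (n_shifts - 1) * shift_step
    inst = np.stack([x[k * shift_step : k * shift_step + support] for k in range(n_shifts)])
    return SignalSpace(inst, shift_step, series.name)


def correlation_matrix(space: SignalSpace) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the shifted instances.

    Zero-variance instances are defined to correlate 0 with everything
    (diagonal stays 1), so a constant series yields the identity pattern
    rather than NaNs.
    """
    inst = space.instances
    sd = inst.std(axis=1)
    ok = sd > 0
    m = np.zeros((space.n_shifts, space.n_shifts))
    if ok.sum() >= 2:
        sub = np.corrcoef(inst[ok])
        m[np.ix_(ok, ok)] = sub
    elif ok.sum() == 1:
        m[np.where(ok)[0][0], np.where(ok)[0][0]] = 1.0
    np.fill_diagonal(m, 1.0)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(m, space.source_name)


def series_to_matrix(
    series: FeatureSeries,
    n_shifts: int = N_SHIFTS_DEFAULT,
    shift_step: int = 1,
    min_support: int = MIN_SUPPORT_DEFAULT,
) -> CorrelationMatrix:
    """Convenience: signal space + correlation matrix in one call."""
    return correlation_matrix(build_signal_space(series, n_shifts, shift_step, min_support))


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def matrix_to_csv(m: CorrelationMatrix, path) -> None:
    """Write the matrix as bare comma-separated decimals, full precision."""
    np.savetxt(path, m.values, delimiter=",", fmt="%.17g")


def csv_to_matrix(path, feature_name: str = "") -> CorrelationMatrix:
    """Read a matrix CSV, validating that every row has the same width."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if rows and len(parts) != len(rows[0]):
                raise ValidationError(
                    f"{path}: row {ln + 1} has {len(parts)} columns, expected {len(rows[0])}"
                )
            rows.append([float(p) for p in parts])
    return CorrelationMatrix(np.array(rows), feature_name)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_BLUE = np.array([0, 0, 255], dtype=float)
_YELLOW = np.array([255, 255, 0], dtype=float)


def value_to_rgb(values: np.ndarray) -> np.ndarray:
    """Linear blue->yellow ramp on [0,1] (values clipped), round-half-up."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    rgb = v[..., None] * _YELLOW + (1.0 - v[..., None]) * _BLUE
    return np.floor(rgb + 0.5).astype(np.uint8)


def matrix_to_image(m: CorrelationMatrix, cell_px: int = 1) -> np.ndarray:
    """Render a matrix as an RGB array, cell_px x cell_px pixels per cell."""
    rgb = value_to_rgb(m.values)
    if cell_px > 1:
        rgb = np.repeat(np.repeat(rgb, cell_px, axis=0), cell_px, axis=1)
    return rgb


# ---------------------------------------------------------------------------
# SoC-style composites
# ---------------------------------------------------------------------------


@dataclass
class CompositeBlock:
    """One member of a composite: a matrix, a binary flag, or a sub-composite.

    ``content`` is a CorrelationMatrix, a bool (flag panel: yellow present /
    blue absent), or a 2-D float array in [0,1] (pre-rendered values of a
    nested composite).
    """

    name: str
    content: object
    weight: float

    def value_array(self) -> np.ndarray:
        if isinstance(self.content, CorrelationMatrix):
            return np.clip(self.content.values, 0.0, 1.0)
        if isinstance(self.content, (bool, np.bool_)):
            return np.full((50, 50), 1.0 if self.content else 0.0)
        arr = np.asarray(self.content, dtype=float)
        if arr.ndim != 2:
            raise ValidationError(f"block {self.name}: content must be 2-D")
        return np.clip(arr, 0.0, 1.0)


@dataclass
class CompositeLayout:
    """Rectangular regions assigned to named blocks on a canvas."""

    canvas_hw: tuple
    regions: list = field(default_factory=list)  # (name, weight, top, left, h, w)

    def to_json(self) -> str:
        return json.dumps(
            {
                "canvas": list(self.canvas_hw),
                "regions": [
                    {"name": n, "weight": w, "top": t, "left": l, "height": h, "width": wd}
                    for (n, w, t, l, h, wd) in self.regions
                ],
            },
            indent=2,
        )


def _nearest_resample(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    rows = np.floor((np.arange(h) + 0.5) * arr.shape[0] / h).astype(int)
    cols = np.floor((np.arange(w) + 0.5) * arr.shape[1] / w).astype(int)
    return arr[np.ix_(rows, cols)]


def _guillotine(blocks, top, left, h, w, layout):
    if len(blocks) == 1:
        layout.regions.append((blocks[0].name, blocks[0].weight, top, left, h, w))
        return
    total = sum(b.weight for b in blocks)
    frac = blocks[0].weight / total
    if w >= h:  # split along the longer axis; vertical cut
        cut = int(round(w * frac))
        cut = min(max(cut, 1), w - len(blocks) + 1)
        layout.regions.append((blocks[0].name, blocks[0].weight, top, left, h, cut))
        _guillotine(blocks[1:], top, left + cut, h, w - cut, layout)
    else:
        cut = int(round(h * frac))
        cut = min(max(cut, 1), h - len(blocks) + 1)
        layout.regions.append((blocks[0].name, blocks[0].weight, top, left, cut, w))
        _guillotine(blocks[1:], top + cut, left, h - cut, w, layout)


def compose_soc(blocks, canvas_px: int = 200):
    """Tile blocks into one value canvas, areas proportional to weights.

    Blocks are ordered by descending significance weight (ties broken by
    name, so permuting the input cannot change the layout).  The canvas is
    recursively guillotine-split: each block takes a strip across the
    current region's longer axis whose area matches its weight share within
    rounding; the last block absorbs the remainder, so regions tile the
    canvas exactly.

    Returns ``(values, layout)`` where ``values`` is a (canvas_px,
    canvas_px) float array in [0,1].
    """
    blocks = list(blocks)
    if not blocks:
        raise ValidationError("composite needs at least one block")
    for b in blocks:
        if b.weight <= 0:
            raise ValidationError(f"block {b.name}: weight must be > 0")
    blocks = sorted(blocks, key=lambda b: (-b.weight, b.name))
    layout = CompositeLayout((canvas_px, canvas_px))
    _guillotine(blocks, 0, 0, canvas_px, canvas_px, layout)
    canvas = np.zeros((canvas_px, canvas_px))
    by_name = {b.name: b for b in blocks}
    for name, _wt, t, l, h, w in layout.regions:
        canvas[t : t + h, l : l + w] = _nearest_resample(by_name[name].value_array(), h, w)
    return canvas, layout


def composite_to_image(values: np.ndarray) -> np.ndarray:
    """Render a composite value canvas with the blue->yellow ramp."""
    return value_to_rgb(values)


def composite_to_csv(blocks, path, layout: CompositeLayout | None = None) -> None:
    """Combined CSV: member value arrays concatenated block-row-wise.

    Each member contributes its rows (50 per matrix) in significance
    order; a JSON sidecar (``<path>.layout.json``) records the layout when
    given.
    """
    blocks = sorted(blocks, key=lambda b: (-b.weight, b.name))
    arrs = [b.value_array() for b in blocks]
    width = max(a.shape[1] for a in arrs)
    rows = np.vstack([_nearest_resample(a, a.shape[0], width) for a in arrs])
    np.savetxt(path, rows, delimiter=",", fmt="%.17g")
    if layout is not None:
        with open(str(path) + ".layout.json", "w") as fh:
            fh.write(layout.to_json())


# ---------------------------------------------------------------------------
# combined-manifestation recipes
# ---------------------------------------------------------------------------


def _rank_weights(names):
    n = len(names)
    return {name: float(n - i) for i, name in enumerate(names)}


def combined_manifestation_sets() -> dict:
    """Named recipes for the composite images, in significance order.

    Weights are rank-proportional (w_i proportional to n-i+1) over the
    declared significance order.  Members may be matrix-valued
    manifestations, binary flags (rendered as solid panels), or other
    composites (rendered then embedded).
    """
    recipes = {
        "evenness": {
            "members": ["micrographia", "uniformity", "tremor"],
            "kinds": {"micrographia": "flag", "uniformity": "matrix", "tremor": "matrix"},
        },
        "legibility": {
            "members": ["micrographia", "spacing", "tremor", "evenness"],
            "kinds": {
                "micrographia": "flag",
                "spacing": "flag",
                "tremor": "matrix",
                "evenness": "composite",
            },
        },
        "writing_combined": {
            "members": ["appearance", "legibility", "progressive_micrographia", "tremor"],
            "kinds": {
                "appearance": "composite",
                "legibility": "composite",
                "progressive_micrographia": "flag",
                "tremor": "matrix",
            },
        },
        "appearance": {
            "members": ["angle", "uniformity"],
            "kinds": {"angle": "matrix", "uniformity": "matrix"},
        },
        "speech_combined": {
            "members": [
                "monoloudness",
                "monopitch",
                "articulation",
                "tremor",
                "nasality",
                "breaks",
            ],
            "kinds": {
                k: "matrix"
                for k in (
                    "monoloudness",
                    "monopitch",
                    "articulation",
                    "tremor",
                    "nasality",
                    "breaks",
                )
            },
        },
    }
    for r in recipes.values():
        r["weights"] = _rank_weights(r["members"])
    return recipes


def build_recipe_blocks(recipe_name: str, providers: dict) -> list:
    """Materialize a recipe's blocks from ``providers``.

    ``providers`` maps member names to a CorrelationMatrix, a bool flag, or
    (for nested composites) is consulted recursively.  Returns the list of
    CompositeBlocks ready for :func:`compose_soc`.
    """
    recipes = combined_manifestation_sets()
    if recipe_name not in recipes:
        raise ValidationError(f"unknown recipe {recipe_name!r}")
    recipe = recipes[recipe_name]
    blocks = []
    for member in recipe["members"]:
        kind = recipe["kinds"][member]
        if kind == "composite":
            sub_blocks = build_recipe_blocks(member, providers)
            values, _ = compose_soc(sub_blocks, canvas_px=100)
            content: object = values
        else:
            if member not in providers:
                raise ValidationError(f"recipe {recipe_name}: missing provider {member!r}")
            content = providers[member]
            if kind == "flag":
                content = bool(content)
        blocks.append(CompositeBlock(member, content, recipe["weights"][member]))
    return blocks
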