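"""Seeded synthetic cohorts: voices and handwriting pages with ground truth.

Since no clinical recordings ship with this package, every stage is
exercised against synthetic subjects whose Parkinsonian manifestations
are injected with exact, recoverable ground truth:

* **speech** — source–filter synthesis: a glottal pulse train with
  per-period frequency perturbation (jitter) and amplitude perturbation
  (shimmer), slow f0 and intensity modulation (their standard deviations
  control monopitch / monoloudness), a two-resonator vocal tract whose
  f1/f2 targets span a configurable fraction of a schematic vowel
  triangle (articulatory decay), an additive nasal-murmur resonance, and
  silence insertions (involuntary breaks);
* **writing** — parametric pseudo-letter glyphs (slanted staves and arcs)
  rendered along text lines with controllable height schedule
  (micrographia, progressive micrographia), per-stroke height variation
  (non-uniformity), sinusoidal path wobble (tremor), slant statistics,
  gap dispersion (spacing) and sinusoidal baseline drift.

Because the downstream representation is the *Pearson* lag-correlation
matrix — invariant to level and scale — each manifestation is expressed
as a change in the temporal organization of its feature series (slow
modulation, quasi-periodic tremor oscillation, or loss of structure),
not merely in its mean or variance.

Class-conditional presence probabilities default to the published
per-manifestation cohort proportions (e.g. 75 % of patients with
non-uniform writing, 65 % with monoloudness, none of the controls for
most manifestations), so a default cohort statistically mirrors the
reference dataset's label structure.  All randomness flows from a single
seed; identical seeds give byte-identical waveforms, pages and manifests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import corrimage
from .features import FeatureSeries, ValidationError
from .handwriting import HandwritingConfig, PageImage, binarize_page, extract_writing_series
from .speech import SpeechConfig, Waveform, extract_manifestation_series

__all__ = [
    "SpeechProfile",
    "PageProfile",
    "CohortSpec",
    "synth_speech",
    "synth_page",
    "make_cohort",
    "generate_cohort_images",
    "SPEECH_LABEL_THRESHOLDS",
    "WRITING_LABEL_THRESHOLDS",
]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class SpeechProfile:
    """Generative parameters of one synthetic voice."""

    f0_mean: float = 140.0  # Hz
    f0_sd: float = 18.0  # Hz of slow prosodic modulation; low -> monopitch
    f0_mod_hz: float = 2.5  # prosodic inflection rate; hypokinetic speech is slower
    intensity_sd: float = 4.0  # dB of slow loudness modulation; low -> monoloudness
    intensity_mod_hz: float = 2.5  # loudness inflection rate
    artic_block_s: float = 0.15  # vowel-target dwell time; bradykinetic speech dwells longer
    jitter_pct: float = 0.4  # target local jitter (%)
    shimmer_pct: float = 1.2  # target local shimmer (%)
    formant_range_scale: float = 0.95  # fraction of the vowel triangle spanned
    nasal_band_gain: float = 0.1  # nasal resonance weight; high -> hypernasality
    break_rate: float = 4.0  # involuntary pauses per minute
    tremor_hz: float = 5.0  # phonatory tremor modulation rate
    tremor_depth_pct: float = 0.0  # f0 modulation depth at tremor_hz (% of f0)
    noise_floor_db: float = -50.0  # additive recording noise re. speech peak
    seed: int = 0

    def __post_init__(self) -> None:
        if not (60 <= self.f0_mean <= 400):
            raise ValidationError("f0_mean must lie in [60, 400] Hz")
        for name in ("f0_sd", "intensity_sd", "jitter_pct", "shimmer_pct",
                     "nasal_band_gain", "break_rate", "tremor_depth_pct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class PageProfile:
    """Generative parameters of one synthetic handwriting page."""

    base_height_mm: float = 6.0  # stroke height; small -> micrographia
    height_decay_pct: float = 4.0  # first-to-last-line shrinkage (progressive)
    nonuniformity_pct: float = 3.0  # per-stroke height variation (slow + white)
    tremor_amp_px: float = 0.25  # sinusoidal path wobble amplitude (px at page dpi)
    tremor_freq: float = 3.0  # wobble cycles per stroke
    slant_deg_mean: float = 0.0
    slant_deg_sd: float = 1.5
    gap_cv: float = 0.3  # coefficient of variation of inter-stroke gaps
    baseline_drift_px: float = 4.0  # peak-to-peak within-line drift (px)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_height_mm", "height_decay_pct", "nonuniformity_pct",
                     "tremor_amp_px", "tremor_freq", "slant_deg_sd", "gap_cv",
                     "baseline_drift_px"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.base_height_mm > 297.0:
            raise ValidationError("base_height_mm exceeds the page height")


# ground-truth label thresholds (midway between the affected and normal
# parameter regimes; surfaced so tests can assert against them)
SPEECH_LABEL_THRESHOLDS = {
    "monoloudness": ("intensity_sd", "<", 2.0),
    "monopitch": ("f0_sd", "<", 8.0),
    "articulation": ("formant_range_scale", "<", 0.6),
    "nasality": ("nasal_band_gain", ">", 0.6),
    "breaks": ("break_rate", ">", 8.0),
}

WRITING_LABEL_THRESHOLDS = {
    "micrographia": ("base_height_mm", "<", 2.7),
    "spacing": ("gap_cv", ">", 0.9),
    "uniformity": ("nonuniformity_pct", ">", 8.0),
    "angle": ("slant_deg_sd", ">", 3.5),
}


def speech_labels(p: SpeechProfile) -> dict:
    labels = {}
    for manif, (attr, op, thr) in SPEECH_LABEL_THRESHOLDS.items():
        v = getattr(p, attr)
        labels[manif] = bool(v < thr) if op == "<" else bool(v > thr)
    labels["tremor"] = bool(p.jitter_pct > 1.2 or p.shimmer_pct > 3.5)
    return labels


def writing_labels(p: PageProfile, dpi: float) -> dict:
    labels = {}
    for manif, (attr, op, thr) in WRITING_LABEL_THRESHOLDS.items():
        v = getattr(p, attr)
        labels[manif] = bool(v < thr) if op == "<" else bool(v > thr)
    h_px = p.base_height_mm / 25.4 * dpi
    labels["progressive_micrographia"] = bool(_intended_decline(p) > 0.25)
    labels["baseline"] = bool(p.baseline_drift_px > 1.5 * h_px)
    labels["tremor"] = bool(p.tremor_amp_px > 0.1 / 25.4 * dpi)  # > 0.1 mm
    return labels


def _intended_decline(p: PageProfile, n_lines: int = 11) -> float:
    """Relative first-to-last-third decline implied by the height schedule."""
    pos = np.arange(n_lines) / max(n_lines - 1, 1)
    h = 1.0 - p.height_decay_pct / 100.0 * pos
    third = max(1, n_lines // 3)
    first, last = np.median(h[:third]), np.median(h[-third:])
    return float((first - last) / first)


# ---------------------------------------------------------------------------
# speech synthesis
# ---------------------------------------------------------------------------

#: Schematic vowel triangle in the (f1, f2) plane, Hz.
VOWEL_TRIANGLE = np.array([[300.0, 800.0], [800.0, 1200.0], [400.0, 2400.0]])

# The mean |eps_i - eps_(i-1)| of i.i.d. standard normals is 2/sqrt(pi), so a
# per-period sd of target/1.1284 yields the requested *local* perturbation.
_LOCAL_FACTOR = 2.0 / np.sqrt(np.pi)


def _smooth_modulation(rng, duration_s, rate, sd, ctrl_hz=2.0):
    """Slow random modulation: linear interpolation of N(0, sd) control points."""
    n = int(duration_s * rate)
    n_ctrl = max(3, int(duration_s * ctrl_hz) + 1)
    ctrl = rng.normal(0.0, sd, n_ctrl)
    t = np.linspace(0, n_ctrl - 1, n)
    return np.interp(t, np.arange(n_ctrl), ctrl)


def _resonator_sos(f_hz, bw_hz, rate):
    r = np.exp(-np.pi * bw_hz / rate)
    theta = 2 * np.pi * f_hz / rate
    # unity gain at the resonance frequency
    b0 = (1 - r) * np.sqrt(1 - 2 * r * np.cos(2 * theta) + r * r)
    return np.array([b0, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r])


def synth_speech(profile: SpeechProfile, duration_s: float, rate: int = 44100):
    """Synthesize a voice recording; returns (Waveform, ground-truth labels).

    Source-filter synthesis as described in the module docstring.  The
    recording starts and ends with ~0.35 s of silence (as a real take
    would), which also supplies the denoiser's noise estimate.
    """
    if duration_s < 2.0:
        raise ValidationError("duration must be >= 2 s")
    if rate <= 0:
        raise ValidationError("rate must be > 0")
    rng = np.random.default_rng(profile.seed)
    lead_s = 0.35
    n_breaks = int(round(profile.break_rate * duration_s / 60.0))
    break_durs = rng.uniform(0.30, 0.40, n_breaks)
    speech_s = duration_s - 2 * lead_s - float(np.sum(break_durs))
    if speech_s < 1.0:
        raise ValidationError("duration too short for the requested break rate")
    n_speech = int(speech_s * rate)

    # slow f0 / intensity modulation + phonatory tremor
    f0_mod = _smooth_modulation(rng, speech_s, rate, profile.f0_sd, profile.f0_mod_hz)
    t_axis = np.arange(n_speech) / rate
    tremor = (
        profile.tremor_depth_pct / 100.0 * profile.f0_mean
        * np.sin(2 * np.pi * profile.tremor_hz * t_axis + rng.uniform(0, 2 * np.pi))
    )
    f0_traj = np.clip(profile.f0_mean + f0_mod + tremor, 60.0, 400.0)
    env_db = _smooth_modulation(
        rng, speech_s, rate, profile.intensity_sd, profile.intensity_mod_hz
    )
    env = 10.0 ** (env_db / 20.0)

    # glottal pulse train with jitter & shimmer (fractional-sample impulses)
    sigma_j = profile.jitter_pct / 100.0 / _LOCAL_FACTOR
    sigma_s = profile.shimmer_pct / 100.0 / _LOCAL_FACTOR
    excitation = np.zeros(n_speech)
    t = 0.0
    while True:
        idx = int(t)
        if idx >= n_speech - 1:
            break
        frac = t - idx
        amp = 1.0 + sigma_s * rng.standard_normal()
        excitation[idx] += amp * (1 - frac)
        excitation[idx + 1] += amp * frac
        period = rate / f0_traj[idx] * (1.0 + sigma_j * rng.standard_normal())
        t += max(period, rate / 500.0)

    # vocal tract: f1/f2 piecewise-constant targets over ~150 ms blocks,
    # drawn from the scaled vowel triangle; nasal branch in parallel
    centroid = VOWEL_TRIANGLE.mean(axis=0)
    block = int(profile.artic_block_s * rate)
    voice = np.zeros(n_speech)
    zi1 = zi2 = None
    for start in range(0, n_speech, block):
        stop = min(start + block, n_speech)
        w = rng.dirichlet(np.ones(3))
        target = centroid + profile.formant_range_scale * (w @ VOWEL_TRIANGLE - centroid)
        sos1 = _resonator_sos(target[0], 120.0, rate)[None, :]
        sos2 = _resonator_sos(target[1], 150.0, rate)[None, :]
        if zi1 is None:
            zi1 = np.zeros((1, 2))
            zi2 = np.zeros((1, 2))
        y, zi1 = sps.sosfilt(sos1, excitation[start:stop], zi=zi1)
        y, zi2 = sps.sosfilt(sos2, y, zi=zi2)
        voice[start:stop] = y
    if profile.nasal_band_gain > 0:
        sos_n = _resonator_sos(280.0, 100.0, rate)[None, :]
        nasal = sps.sosfilt(sos_n, excitation)
        voice = voice + profile.nasal_band_gain * nasal
    voice *= env

    # assemble: lead silence + speech with silence insertions + tail silence
    fade = int(0.01 * rate)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))
    pieces = [np.zeros(int(lead_s * rate))]
    if n_breaks:
        cuts = ((np.arange(1, n_breaks + 1) / (n_breaks + 1))
                + rng.uniform(-0.03, 0.03, n_breaks))
        cut_idx = np.sort((cuts * n_speech).astype(int))
        prev = 0
        for k, ci in enumerate(cut_idx):
            seg = voice[prev:ci].copy()
            if seg.size > 2 * fade:
                seg[:fade] *= ramp
                seg[-fade:] *= ramp[::-1]
            pieces.append(seg)
            pieces.append(np.zeros(int(break_durs[k] * rate)))
            prev = ci
        tail = voice[prev:].copy()
        if tail.size > 2 * fade:
            tail[:fade] *= ramp
            tail[-fade:] *= ramp[::-1]
        pieces.append(tail)
    else:
        pieces.append(voice)
    pieces.append(np.zeros(int(lead_s * rate)))
    x = np.concatenate(pieces)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.5 * x / peak
    noise = 0.5 * 10 ** (profile.noise_floor_db / 20.0)
    x = x + rng.normal(0.0, noise, x.size)
    return Waveform(x, rate), speech_labels(profile)


# ---------------------------------------------------------------------------
# handwriting synthesis
# ---------------------------------------------------------------------------

A4_MM = (210.0, 297.0)


def _stamp_path(canvas, ys, xs, radius):
    """Stamp a disk of the given radius at every path point (ink = True)."""
    h, w = canvas.shape
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = dy**2 + dx**2 <= radius**2
    offs = np.column_stack(np.nonzero(disk)) - r
    pts = np.column_stack([np.round(ys).astype(int), np.round(xs).astype(int)])
    pix = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    ok = (pix[:, 0] >= 0) & (pix[:, 0] < h) & (pix[:, 1] >= 0) & (pix[:, 1] < w)
    pix = pix[ok]
    canvas[pix[:, 0], pix[:, 1]] = True


def _slow_series(rng, n, period):
    """Unit-amplitude slow oscillation with random phase, length n."""
    phase = rng.uniform(0, 2 * np.pi)
    return np.sin(2 * np.pi * np.arange(n) / period + phase)


def synth_page(
    profile: PageProfile,
    n_lines: int = 11,
    strokes_per_line: int = 25,
    dpi: float = 600.0,
):
    """Render a synthetic handwriting page; returns (PageImage, labels, truth).

    Pseudo-letter glyphs (slanted staves and arcs, ~65 %/35 %) are drawn
    along ``n_lines`` text lines on an A4 canvas.  Stroke heights follow a
    per-line schedule decaying by ``height_decay_pct`` across the page with
    per-stroke variation of ``nonuniformity_pct`` (half slow oscillation,
    half white); the pen path carries a perpendicular sinusoidal wobble of
    amplitude ``tremor_amp_px`` whose amplitude itself waxes and wanes
    across strokes.  ``truth`` records the per-stroke intended heights,
    slants, and gaps for recovery tests.
    """
    rng = np.random.default_rng(profile.seed)
    W = int(round(A4_MM[0] / 25.4 * dpi))
    H = int(round(A4_MM[1] / 25.4 * dpi))
    h0 = profile.base_height_mm / 25.4 * dpi
    if h0 < 4:
        raise ValidationError("base height below 4 px at this dpi; raise dpi")
    margin_x = int(0.07 * W)
    margin_top = int(0.08 * H)
    usable_w = W - 2 * margin_x
    pitch = (H - margin_top - int(0.05 * H)) / n_lines
    if h0 > 0.75 * pitch:
        raise ValidationError("stroke height exceeds the line pitch; fewer/larger lines")
    thickness = max(2.0, dpi / 100.0)

    mask = np.zeros((H, W), dtype=bool)
    truth = {"heights": [], "slants": [], "gaps": [], "line": []}
    uni_slow_period = 9.0
    tremor_mod_period = 17.0
    stroke_counter = 0
    for li in range(n_lines):
        base_y = margin_top + (li + 0.8) * pitch
        h_line = h0 * (1.0 - profile.height_decay_pct / 100.0 * li / max(n_lines - 1, 1))
        slant_slow = _slow_series(rng, strokes_per_line, 11.0)
        uni_slow = _slow_series(rng, strokes_per_line, uni_slow_period)
        drift_phase = rng.uniform(0, 2 * np.pi)
        x = float(margin_x + rng.uniform(0, 0.3) * h_line)
        mean_gap = 0.55 * h_line
        for j in range(strokes_per_line):
            if x > margin_x + usable_w - 1.2 * h_line:
                break
            u = profile.nonuniformity_pct / 100.0
            h = h_line * (1.0 + u * (0.8 * uni_slow[j] + 0.6 * rng.standard_normal()))
            h = max(h, 4.0)
            slant = (profile.slant_deg_mean
                     + profile.slant_deg_sd * (0.8 * slant_slow[j] + 0.6 * rng.standard_normal()))
            drift = 0.5 * profile.baseline_drift_px * np.sin(
                2 * np.pi * 1.5 * (x - margin_x) / usable_w + drift_phase
            )
            y0 = base_y + drift
            n_pts = max(int(2 * h), 8)
            s = np.linspace(0.0, 1.0, n_pts)
            # tremor amplitude waxes/wanes slowly across consecutive strokes
            amp = profile.tremor_amp_px * (
                1.0 + 0.5 * np.sin(2 * np.pi * stroke_counter / tremor_mod_period)
            )
            wobble = amp * np.sin(2 * np.pi * profile.tremor_freq * s + rng.uniform(0, 2 * np.pi))
            if rng.random() < 0.65:  # stave
                dy, dx = -h, h * np.tan(np.radians(slant))
                norm = np.hypot(dy, dx)
                perp = (dx / norm, -dy / norm)  # unit normal to the stave
                ys = y0 + s * dy + wobble * perp[0]
                xs = x + s * dx + wobble * perp[1]
                width = abs(dx) + thickness
            else:  # arc ('c'-like open curve), full stroke height
                r_arc = 0.45 * h
                ang = np.pi * (0.25 + 1.5 * s)
                cx = x + r_arc
                cy = y0 - r_arc
                ys = cy + r_arc * np.sin(ang) + wobble * np.cos(ang)
                xs = cx + r_arc * np.cos(ang) + wobble * np.sin(ang)
                width = 2 * r_arc + thickness
            _stamp_path(mask, ys, xs, thickness / 2.0)
            truth["heights"].append(h)
            truth["slants"].append(slant)
            truth["line"].append(li)
            gap = (mean_gap if profile.gap_cv <= 0 else
                   rng.gamma(1.0 / profile.gap_cv**2, mean_gap * profile.gap_cv**2))
            truth["gaps"].append(gap)
            x += width + gap
            stroke_counter += 1

    pixels = np.where(mask, 25.0, 235.0)
    page = PageImage(pixels.astype(np.uint8), dpi)
    return page, writing_labels(profile, dpi), truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Class-conditional per-manifestation presence probabilities; the patient
#: column mirrors the reference cohort's reported proportions.
DEFAULT_PRESENCE = {
    "case": {
        "speech": {
            "monoloudness": 0.65,
            "monopitch": 0.65,
            "articulation": 0.35,
            "tremor": 0.55,
            "breaks": 0.65,
            "nasality": 0.40,
        },
        "writing": {
            "micrographia": 0.20,
            "progressive_micrographia": 0.35,
            "baseline": 0.55,
            "spacing": 0.10,
            "angle": 0.55,
            "uniformity": 0.75,
            "tremor": 0.45,
        },
    },
    "control": {
        "speech": {
            "monoloudness": 0.0,
            "monopitch": 0.0,
            "articulation": 0.0,
            "tremor": 0.10,
            "breaks": 0.0,
            "nasality": 0.05,
        },
        "writing": {
            "micrographia": 0.0,
            "progressive_micrographia": 0.0,
            "baseline": 0.0,
            "spacing": 0.0,
            "angle": 0.0,
            "uniformity": 0.0,
            "tremor": 0.0,
        },
    },
}

# (present value, absent value) per generative parameter.  Affected prosody
# and articulation are both flatter (smaller sd / range) and slower (lower
# modulation rate, longer dwell): the lag-correlation representation is
# scale-invariant, so the timescale change is what it actually images.
_SPEECH_PARAMS = {
    "monoloudness": {"intensity_sd": (0.7, 4.0), "intensity_mod_hz": (0.6, 2.5)},
    "monopitch": {"f0_sd": (2.5, 18.0), "f0_mod_hz": (0.6, 2.5)},
    "tremor": {"jitter_pct": (2.5, 0.4), "shimmer_pct": (7.0, 1.2),
               "tremor_depth_pct": (6.0, 0.0)},
    "articulation": {"formant_range_scale": (0.35, 0.95), "artic_block_s": (0.45, 0.15)},
    "nasality": {"nasal_band_gain": (1.5, 0.1)},
    "breaks": {"break_rate": (12.0, 4.0)},
}

_WRITING_PARAMS = {
    "micrographia": {"base_height_mm": (2.0, 6.0)},
    "progressive_micrographia": {"height_decay_pct": (40.0, 4.0)},
    "spacing": {"gap_cv": (1.3, 0.3)},
    "uniformity": {"nonuniformity_pct": (18.0, 3.0)},
    "angle": {"slant_deg_sd": (6.0, 1.5)},
    # baseline drift and tremor amplitude are resolved in px below
}


@dataclass
class CohortSpec:
    """Synthetic cohort layout and acquisition parameters."""

    n_cases: int = 20
    n_controls: int = 10
    presence: dict = field(default_factory=lambda: DEFAULT_PRESENCE)
    speech_duration_s: float = 20.0
    speech_rate: int = 44100
    page_dpi: float = 300.0
    n_lines: int = 11
    strokes_per_line: int = 25
    n_chunks: int = 3  # correlation images per subject per manifestation
    canvas_px: int = 64  # composite canvas edge (CNN input size)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        for cls in self.presence.values():
            for group in cls.values():
                for p in group.values():
                    if not (0.0 <= p <= 1.0):
                        raise ValidationError("presence probabilities must be in [0,1]")


def _sample_speech_profile(rng, presence: dict) -> SpeechProfile:
    kw = {"f0_mean": float(rng.uniform(110, 220)), "seed": int(rng.integers(2**31))}
    for manif, params in _SPEECH_PARAMS.items():
        present = presence.get(manif, False)
        for attr, (on, off) in params.items():
            base = on if present else off
            kw[attr] = float(base * rng.lognormal(0.0, 0.10))
    return SpeechProfile(**kw)


def _sample_page_profile(rng, presence: dict, dpi: float) -> PageProfile:
    kw = {"seed": int(rng.integers(2**31)),
          "slant_deg_mean": float(rng.normal(0, 2.0))}
    for manif, params in _WRITING_PARAMS.items():
        present = presence.get(manif, False)
        for attr, (on, off) in params.items():
            base = on if present else off
            kw[attr] = float(base * rng.lognormal(0.0, 0.08))
    if presence.get("angle", False):
        kw["slant_deg_mean"] = float(rng.choice([-1, 1]) * rng.normal(10.0, 1.5))
    h_px = kw["base_height_mm"] / 25.4 * dpi
    drift_rel = 2.2 if presence.get("baseline", False) else 0.06
    kw["baseline_drift_px"] = float(drift_rel * h_px * rng.lognormal(0.0, 0.08))
    amp_mm = 0.19 if presence.get("tremor", False) else 0.02
    kw["tremor_amp_px"] = float(amp_mm / 25.4 * dpi * rng.lognormal(0.0, 0.08))
    kw["tremor_freq"] = float(h_px / 8.0)  # wobble wavelength ~ 8 px along the stroke
    return PageProfile(**kw)


def _chunk_series(series: FeatureSeries, n_chunks: int):
    """Evenly spaced (possibly overlapping) windows, each imaging-ready."""
    need = corrimage.required_series_length()
    x = series.values
    if x.size < need:
        raise ValidationError(
            f"{series.name}: length {x.size} < {need}, cannot build a signal space"
        )
    if n_chunks == 1:
        return [FeatureSeries(series.name, x, series.units)]
    starts = [int(round(c * (x.size - need) / (n_chunks - 1))) for c in range(n_chunks)]
    return [FeatureSeries(series.name, x[s : s + need], series.units) for s in starts]


def subject_speech_matrices(w: Waveform, cfg: SpeechConfig, n_chunks: int) -> dict:
    """Six per-manifestation matrices per chunk: {manif: [CorrelationMatrix, ...]}."""
    series = extract_manifestation_series(w, cfg)
    out = {}
    for manif, s in series.items():
        chunks = _chunk_series(s, n_chunks)
        out[manif] = [corrimage.series_to_matrix(c) for c in chunks]
    return out


def subject_writing_artifacts(page: PageImage, hw_cfg: HandwritingConfig, n_chunks: int):
    """Writing matrices per chunk + the recovered flags."""
    binary = binarize_page(page, cfg=hw_cfg)
    res = extract_writing_series(binary, hw_cfg)
    matrices = {}
    for manif in ("angle", "uniformity", "tremor"):
        chunks = _chunk_series(res[manif], n_chunks)
        matrices[manif] = [corrimage.series_to_matrix(c) for c in chunks]
    return matrices, res["flags"]


def _speech_combined_image(matrices: dict, chunk: int, canvas_px: int) -> np.ndarray:
    providers = {m: matrices[m][min(chunk, len(matrices[m]) - 1)] for m in matrices}
    blocks = corrimage.build_recipe_blocks("speech_combined", providers)
    values, _ = corrimage.compose_soc(blocks, canvas_px=canvas_px)
    return corrimage.composite_to_image(values)

def _writing_combined_image(matrices: dict, flags, chunk: int, canvas_px: int) -> np.ndarray:
    providers = {
        "angle": matrices["angle"][min(chunk, len(matrices["angle"]) - 1)],
        "uniformity": matrices["uniformity"][min(chunk, len(matrices["uniformity"]) - 1)],
        "tremor": matrices["tremor"][min(chunk, len(matrices["tremor"]) - 1)],
        "micrographia": flags.micrographia,
        "spacing": flags.spacing,
        "progressive_micrographia": flags.progressive_micrographia,
    }
    blocks = corrimage.build_recipe_blocks("writing_combined", providers)
    values, _ = corrimage.compose_soc(blocks, canvas_px=canvas_px)
    return corrimage.composite_to_image(values)


def generate_cohort_images(spec: CohortSpec, keep_raw: bool = False):
    """Synthesize the cohort and run both pipelines end to end, in memory.

    Returns a dict with:

    * ``manifest``: DataFrame (path, subject, manifestation, label, split="")
      — one row per correlation image, labels from generator ground truth
      (combined tasks are labelled by disease class);
    * ``images``: {path: uint8 RGB array};
    * ``subjects``: per-subject records (class, ground-truth labels,
      recovered flags, profiles);
    * optionally ``raw``: waveforms and pages (``keep_raw=True``).
    """
    ss = np.random.SeedSequence(spec.seed)
    # transition context widened so every subject's break series is
    # imaging-ready; jitter blocks shortened so 4-7 Hz phonatory tremor
    # modulation survives the within-block averaging
    speech_cfg = SpeechConfig(
        transition_context_frames=10, jitter_block_periods=12, jitter_block_hop=2
    )
    hw_cfg = HandwritingConfig()
    rows = []
    images = {}
    subjects = []
    raw = {}
    classes = [("case", i) for i in range(spec.n_cases)] + [
        ("control", i) for i in range(spec.n_controls)
    ]
    child_seeds = ss.spawn(len(classes))
    for (cls, idx), child in zip(classes, child_seeds):
        sid = f"{cls}{idx:02d}"
        rng = np.random.default_rng(child)
        pres_s = {
            m: bool(rng.random() < p)
            for m, p in spec.presence[cls]["speech"].items()
        }
        pres_w = {
            m: bool(rng.random() < p)
            for m, p in spec.presence[cls]["writing"].items()
        }
        sp = _sample_speech_profile(rng, pres_s)
        pp = _sample_page_profile(rng, pres_w, spec.page_dpi)
        wav, s_truth = synth_speech(sp, spec.speech_duration_s, spec.speech_rate)
        page, w_truth, _ = synth_page(pp, spec.n_lines, spec.strokes_per_line, spec.page_dpi)
        s_mats = subject_speech_matrices(wav, speech_cfg, spec.n_chunks)
        w_mats, w_flags = subject_writing_artifacts(page, hw_cfg, spec.n_chunks)
        is_case = int(cls == "case")

        for manif, mats in s_mats.items():
            for c, m in enumerate(mats):
                path = f"{sid}/speech_{manif}_{c}.png"
                images[path] = corrimage.matrix_to_image(m)
                rows.append((path, sid, manif, int(s_truth[manif]), ""))
        for manif, mats in w_mats.items():
            for c, m in enumerate(mats):
                path = f"{sid}/writing_{manif}_{c}.png"
                images[path] = corrimage.matrix_to_image(m)
                rows.append((path, sid, f"writing_{manif}", int(w_truth[manif]), ""))
        for c in range(spec.n_chunks):
            path = f"{sid}/speech_combined_{c}.png"
            images[path] = _speech_combined_image(s_mats, c, spec.canvas_px)
            rows.append((path, sid, "speech_combined", is_case, ""))
            path = f"{sid}/writing_combined_{c}.png"
            images[path] = _writing_combined_image(w_mats, w_flags, c, spec.canvas_px)
            rows.append((path, sid, "writing_combined", is_case, ""))

        subjects.append(
            {
                "subject": sid,
                "class": cls,
                "speech_truth": s_truth,
                "writing_truth": w_truth,
                "recovered_flags": {
                    "micrographia": w_flags.micrographia,
                    "progressive_micrographia": w_flags.progressive_micrographia,
                    "baseline": w_flags.baseline_drift,
                    "spacing": w_flags.spacing,
                },
                "speech_profile": dataclasses.asdict(sp),
                "page_profile": dataclasses.asdict(pp),
            }
        )
        if keep_raw:
            raw[sid] = {"waveform": wav, "page": page}

    manifest = pd.DataFrame(
        rows, columns=["path", "subject", "manifestation", "label", "split"]
    )
    out = {"manifest": manifest, "images": images, "subjects": subjects}
    if keep_raw:
        out["raw"] = raw
    return out


def make_cohort(spec: CohortSpec, out_dir, force: bool = False) -> "pd.DataFrame":
    """Full cohort to disk: WAVs, pages, correlation images, manifest, report."""
    import os

    from PIL import Image

    from .speech import save_audio

    out_dir = str(out_dir)
    if os.path.exists(out_dir) and os.listdir(out_dir) and not force:
        raise ValidationError(f"output dir {out_dir} is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    result = generate_cohort_images(spec, keep_raw=True)
    for sid, r in result["raw"].items():
        os.makedirs(os.path.join(out_dir, sid), exist_ok=True)
        save_audio(os.path.join(out_dir, sid, "speech.wav"), r["waveform"])
        Image.fromarray(r["page"].pixels).save(
            os.path.join(out_dir, sid, "page.png"),
            dpi=(r["page"].dpi, r["page"].dpi),
        )
    for path, arr in result["images"].items():
        full = os.path.join(out_dir, path)
        os.makedirs(os.path.dirname(full), exist_ok=True)
        Image.fromarray(arr).save(full)
    manifest = result["manifest"]
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)

    presence_report = {}
    for modality, key in (("speech", "speech_truth"), ("writing", "writing_truth")):
        cases = [s for s in result["subjects"] if s["class"] == "case"]
        rates = {}
        if cases:
            for m in cases[0][key]:
                rates[m] = float(np.mean([s[key][m] for s in cases]))
        presence_report[modality] = rates
    report = {
        "seed": spec.seed,
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "case_presence_rates": presence_report,
        "reference_case_rates": DEFAULT_PRESENCE["case"],
    }
    with open(os.path.join(out_dir, "generation_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return manifest
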