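"""Acoustic feature extraction from running speech.

The pipeline turns a mono recording of read text into the six
per-manifestation feature series used for lag-correlation imaging:

====================  =============================================
manifestation          series (units)
====================  =============================================
monoloudness           squared energy / Teager–Kaiser energy (–)
monopitch              fundamental frequency f0 (Hz), phonatory
                       frequency range (Hz), zero-crossing rate (–)
phonation tremor       local jitter (%) and local shimmer (%)
articulatory decay     first two formants f1, f2 (Hz)
hypernasality          nasal-band power ratio (–)
involuntary breaks     pitch + HNR trajectories at speech/silence
                       transitions (Hz, dB, concatenated)
====================  =============================================

Processing order follows the classical front end for hypokinetic
dysarthria analysis: Wiener noise reduction, energy-based voice activity
detection, 50 ms frames with 50 % overlap, then per-frame estimators.
All estimators are amplitude-scale invariant where the underlying
quantity is (VAD, pitch, jitter, ZCR, nasality), and frames without a
defensible estimate carry NaN sentinels (see :mod:`pdnet.features`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz

from .features import FeatureSeries, ValidationError

__all__ = [
    "Waveform",
    "FrameSeries",
    "VoicedSegmentation",
    "TransitionFeatureSet",
    "SpeechConfig",
    "load_audio",
    "save_audio",
    "wiener_denoise",
    "detect_voice_activity",
    "frame_signal",
    "loudness_series",
    "pitch_series",
    "phonatory_frequency_range",
    "zero_crossing_series",
    "tremor_series",
    "articulation_series",
    "nasality_series",
    "voice_break_features",
    "extract_manifestation_series",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Waveform:
    """Mono sampled audio: amplitude samples (nominally in [-1, 1]) + rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValidationError("sampling rate must be > 0")
        if self.samples.size < 1:
            raise ValidationError("waveform must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class FrameSeries:
    """Fixed-length overlapping windows cut from a waveform."""

    frames: np.ndarray  # (n_frames, win_samples)
    win_samples: int
    hop_samples: int
    rate: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class VoicedSegmentation:
    """Half-open [start, end) sample intervals labelled speech; rest is silence."""

    segments: list
    n_samples: int
    rate: int

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.segments:
            if not (0 <= s < e <= self.n_samples):
                raise ValidationError(f"segment ({s},{e}) outside signal bounds")
            if s < prev_end:
                raise ValidationError("segments overlap or are unsorted")
            prev_end = e

    def voiced_samples(self, x: np.ndarray) -> np.ndarray:
        """Concatenate the speech-labelled samples in temporal order."""
        if not self.segments:
            return np.empty(0)
        return np.concatenate([x[s:e] for s, e in self.segments])


@dataclass
class TransitionFeatureSet:
    """Per-transition pitch and HNR trajectories around speech/silence boundaries."""

    records: list  # of dicts: transition_type, boundary_sample, pitch_hz, hnr_db


@dataclass
class SpeechConfig:
    """Tunable parameters of the speech front end (defaults documented per field)."""

    win_ms: float = 50.0  # analysis window
    overlap: float = 0.5
    # Wiener denoise
    noise_lead_ms: float = 250.0  # leading non-speech portion for the noise PSD
    noise_oversubtraction: float = 2.0
    # VAD
    vad_frame_ms: float = 25.0
    vad_threshold_rel: float = 0.05  # fraction of the 95th-percentile frame energy
    vad_min_segment_ms: float = 50.0
    # pitch
    fmin_hz: float = 60.0
    fmax_hz: float = 400.0
    voicing_threshold: float = 0.45
    # rolling blocks
    jitter_block_periods: int = 30
    jitter_block_hop: int = 5
    range_block_frames: int = 20
    transition_context_frames: int = 5
    # articulation
    lpc_order: int | None = None  # default 2 + round(analysis_rate / 1000)
    formant_max_bandwidth_hz: float = 400.0
    formant_min_hz: float = 90.0
    formant_target_rate: float = 11025.0
    formant_min_prediction_gain: float = 4.0  # skip frames LP models poorly
    # nasality
    nasal_band_hz: tuple = (200.0, 500.0)
    nasal_total_hz: tuple = (0.0, 4000.0)


# ---------------------------------------------------------------------------
# I/O and conditioning
# ---------------------------------------------------------------------------


def load_audio(path) -> Waveform:
    """Read a WAV file (PCM 16/24/32-bit or float) as a mono Waveform.

    Multi-channel files are down-mixed by channel averaging; integer PCM is
    scaled to [-1, 1] by the type's full-scale value.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable/corrupt container
        raise IOError(f"could not read audio file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise ValidationError(f"{path}: zero-length audio")
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return Waveform(data, int(rate))


def save_audio(path, w: Waveform) -> None:
    """Write a Waveform as 32-bit float WAV (lossless for our purposes)."""
    wavfile.write(path, w.rate, w.samples.astype(np.float32))


def _stft_window(win: int) -> np.ndarray:
    # periodic Hann: 50 %-overlapped copies sum exactly to 1
    return sps.get_window("hann", win, fftbins=True)


def wiener_denoise(w: Waveform, noise_profile=None, cfg: SpeechConfig | None = None) -> Waveform:
    """Frequency-domain Wiener filtering with overlap-add.

    Per analysis frame the gain ``H(f) = S(f) / (S(f) + N(f))`` is applied,
    with the clean-speech PSD estimated by noise oversubtraction
    ``S(f) = max(P(f) - alpha * N(f), 0)`` from the frame periodogram
    ``P``.  ``noise_profile`` may be a per-bin noise PSD array, a Waveform
    of pure noise, or None, in which case the leading non-speech portion
    of the input (``noise_lead_ms``) supplies the estimate.  A zero noise
    PSD makes the filter the identity.
    """
    cfg = cfg or SpeechConfig()
    win = int(round(cfg.win_ms / 1000.0 * w.rate))
    win += win % 2  # even length: periodic-Hann 50% overlap-add sums to exactly 1
    if win < 2:
        raise ValidationError("signal rate too low for the analysis window")
    if w.samples.size < win:
        raise ValidationError("signal shorter than one analysis frame")
    hop = win // 2
    window = _stft_window(win)
    nbins = win // 2 + 1

    if noise_profile is None:
        lead = int(round(cfg.noise_lead_ms / 1000.0 * w.rate))
        lead = max(lead, win)
        noise_profile = Waveform(w.samples[:lead], w.rate)
    if isinstance(noise_profile, Waveform):
        seg = noise_profile.samples
        if seg.size < win:
            seg = np.pad(seg, (0, win - seg.size))
        starts = range(0, seg.size - win + 1, hop)
        psd = np.mean(
            [np.abs(np.fft.rfft(seg[s : s + win] * window)) ** 2 for s in starts],
            axis=0,
        )
    else:
        psd = np.asarray(noise_profile, dtype=float).ravel()
        if psd.size != nbins:
            raise ValidationError(
                f"noise PSD must have {nbins} bins for a {win}-sample window"
            )
    alpha = cfg.noise_oversubtraction

    n = w.samples.size
    x = np.pad(w.samples, (win, win))
    out = np.zeros_like(x)
    for start in range(0, x.size - win + 1, hop):
        frame = x[start : start + win] * window
        spec = np.fft.rfft(frame)
        p = np.abs(spec) ** 2
        s_est = np.maximum(p - alpha * psd, 0.0)
        denom = s_est + psd
        gain = np.where(denom > 0, s_est / np.where(denom > 0, denom, 1.0), 1.0)
        out[start : start + win] += np.fft.irfft(spec * gain, n=win)
    return Waveform(out[win : win + n], w.rate)


def detect_voice_activity(
    w: Waveform,
    frame_ms: float | None = None,
    energy_threshold_rel: float | None = None,
    cfg: SpeechConfig | None = None,
) -> VoicedSegmentation:
    """Energy-based speech/silence segmentation.

    Non-overlapping frames whose short-time energy exceeds
    ``energy_threshold_rel`` times the 95th-percentile frame energy are
    labelled speech; adjacent speech frames merge and segments shorter
    than ``vad_min_segment_ms`` are dropped.  The relative threshold makes
    the segmentation invariant to amplitude scaling.
    """
    cfg = cfg or SpeechConfig()
    frame_ms = cfg.vad_frame_ms if frame_ms is None else frame_ms
    thr_rel = cfg.vad_threshold_rel if energy_threshold_rel is None else energy_threshold_rel
    if frame_ms <= 0:
        raise ValidationError("frame_ms must be > 0")
    if not (0 < thr_rel < 1):
        raise ValidationError("energy_threshold_rel must be in (0, 1)")

    flen = max(1, int(round(frame_ms / 1000.0 * w.rate)))
    n_frames = w.samples.size // flen
    if n_frames == 0:
        return VoicedSegmentation([], w.samples.size, w.rate)
    x = w.samples[: n_frames * flen].reshape(n_frames, flen)
    energy = np.mean(x**2, axis=1)
    scale = np.percentile(energy, 95)
    if scale <= 0:
        return VoicedSegmentation([], w.samples.size, w.rate)
    speech = energy > thr_rel * scale

    segments = []
    min_len = int(round(cfg.vad_min_segment_ms / 1000.0 * w.rate))
    start = None
    for i, flag in enumerate(np.append(speech, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            s, e = start * flen, i * flen
            if e == n_frames * flen:
                e = w.samples.size  # extend last frame block to signal end
            if e - s >= min_len:
                segments.append((s, e))
            start = None
    return VoicedSegmentation(segments, w.samples.size, w.rate)


def frame_signal(w: Waveform, win_ms: float = 50.0, overlap: float = 0.5) -> FrameSeries:
    """Cut a waveform into fixed windows; trailing remainder is dropped.

    Frame count is ``floor((N - win) / hop) + 1`` with ``win =
    round(win_ms/1000 * rate)`` and ``hop = floor(win * (1 - overlap))``.
    """
    win = int(round(win_ms / 1000.0 * w.rate))
    hop = int(np.floor(win * (1.0 - overlap)))
    if hop < 1:
        raise ValidationError("overlap too large: hop would be zero")
    if w.samples.size < win:
        raise ValidationError(
            f"signal of {w.samples.size} samples is shorter than one {win}-sample window"
        )
    n_frames = (w.samples.size - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameSeries(w.samples[idx], win, hop, w.rate)


# ---------------------------------------------------------------------------
# per-frame estimators
# ---------------------------------------------------------------------------


def loudness_series(fs: FrameSeries):
    """Mean squared energy and mean Teager–Kaiser energy per frame.

    TKE of sample n is ``psi[n] = x[n]^2 - x[n-1] * x[n+1]``, averaged over
    the frame interior; for a sinusoid A*cos(Omega*n) its mean is
    A^2 * sin^2(Omega), for a constant it vanishes.
    """
    if fs.n_frames < 1:
        raise ValidationError("need at least one frame")
    if fs.win_samples < 3:
        raise ValidationError("Teager-Kaiser energy needs frames of length >= 3")
    x = fs.frames
    sq = np.mean(x**2, axis=1)
    psi = x[:, 1:-1] ** 2 - x[:, :-2] * x[:, 2:]
    tke = np.mean(psi, axis=1)
    return (
        FeatureSeries("squared_energy", sq, ""),
        FeatureSeries("tk_energy", tke, ""),
    )


def _autocorr(frame: np.ndarray) -> np.ndarray:
    """Biased autocorrelation via FFT (taper with lag breaks octave ties)."""
    n = frame.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frame, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    return r


def _frame_f0(frame: np.ndarray, rate: int, fmin: float, fmax: float, vthr: float):
    """(f0_hz, voiced?, unbiased normalized peak) for one frame.

    The lag search uses the biased autocorrelation (its taper with lag
    breaks octave ties toward the shorter period); the reported peak value
    is bias-corrected by N/(N-k), so a perfectly periodic frame scores ~1
    regardless of the lag.
    """
    x = frame - frame.mean()
    r = _autocorr(x)
    if r[0] <= 0:
        return np.nan, False, 0.0
    lo = int(np.floor(rate / fmax))
    hi = int(np.ceil(rate / fmin))
    hi = min(hi, x.size - 2)
    if lo < 1 or lo >= hi:
        return np.nan, False, 0.0
    band = r[lo : hi + 1]
    k = int(np.argmax(band)) + lo
    peak = min(r[k] / r[0] * x.size / (x.size - k), 1.0)
    if peak < vthr:
        return np.nan, False, peak
    # parabolic interpolation around the lag peak
    if 0 < k < r.size - 1:
        denom = r[k - 1] - 2 * r[k] + r[k + 1]
        delta = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return rate / (k + delta), True, peak


def pitch_series(
    fs: FrameSeries,
    fmin: float | None = None,
    fmax: float | None = None,
    cfg: SpeechConfig | None = None,
) -> FeatureSeries:
    """Per-frame f0 (Hz) via the normalized-autocorrelation peak.

    Lags are searched in ``[rate/fmax, rate/fmin]``; a frame is voiced when
    the normalized peak reaches the voicing threshold, otherwise it carries
    the NaN sentinel (excluded from downstream statistics).
    """
    cfg = cfg or SpeechConfig()
    fmin = cfg.fmin_hz if fmin is None else fmin
    fmax = cfg.fmax_hz if fmax is None else fmax
    if fmin >= fmax:
        raise ValidationError("fmin must be < fmax")
    if fs.win_samples < 2 * fs.rate / fmin:
        raise ValidationError("window too short to hold two periods at fmin")
    out = np.full(fs.n_frames, np.nan)
    for i in range(fs.n_frames):
        f0, voiced, _ = _frame_f0(fs.frames[i], fs.rate, fmin, fmax, cfg.voicing_threshold)
        if voiced:
            out[i] = f0
    return FeatureSeries("pitch", out, "Hz")


def phonatory_frequency_range(
    pitch: FeatureSeries, block_frames: int | None = None, cfg: SpeechConfig | None = None
):
    """Robust f0 range: p95 - p5 of voiced frames, plus a rolling-block series."""
    cfg = cfg or SpeechConfig()
    block = cfg.range_block_frames if block_frames is None else block_frames
    voiced = pitch.valid_values()
    if voiced.size == 0:
        return np.nan, FeatureSeries("phonatory_range", np.empty(0), "Hz")
    total = float(np.percentile(voiced, 95) - np.percentile(voiced, 5))
    if voiced.size <= block:
        rolling = np.array([np.ptp(voiced) if voiced.size > 1 else 0.0])
    else:
        windows = np.lib.stride_tricks.sliding_window_view(voiced, block)
        rolling = np.percentile(windows, 95, axis=1) - np.percentile(windows, 5, axis=1)
    return total, FeatureSeries("phonatory_range", rolling, "Hz")


def zero_crossing_series(fs: FrameSeries) -> FeatureSeries:
    """Sign changes per sample interval in each frame (dimensionless)."""
    s = np.sign(fs.frames)
    s[s == 0] = 1  # zeros adopt positive sign: no spurious double-crossings
    crossings = np.sum(s[:, 1:] != s[:, :-1], axis=1)
    return FeatureSeries("zcr", crossings / (fs.win_samples - 1), "")


# ---------------------------------------------------------------------------
# glottal-cycle perturbation (jitter / shimmer)
# ---------------------------------------------------------------------------


def _refine_peak(x: np.ndarray, k: int):
    """Parabolic vertex (position, amplitude) around sample peak k."""
    if 0 < k < x.size - 1:
        a, b, c = x[k - 1], x[k], x[k + 1]
        denom = a - 2 * b + c
        if denom != 0:
            d = float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
            return k + d, b - 0.25 * (a - c) * d
    return float(k), float(x[k])


def _period_marks(x: np.ndarray, rate: int, f0: float):
    """Glottal epoch times (samples, sub-sample) and amplitudes by peak picking."""
    dist = max(2, int(0.7 * rate / f0))
    if x.size < 2 * dist:
        return np.empty(0), np.empty(0)
    peaks, _ = sps.find_peaks(x, distance=dist, height=0.2 * np.max(np.abs(x)))
    t = np.empty(peaks.size)
    a = np.empty(peaks.size)
    for j, p in enumerate(peaks):
        t[j], a[j] = _refine_peak(x, int(p))
    return t, a


def tremor_series(
    w: Waveform, seg: VoicedSegmentation, cfg: SpeechConfig | None = None
):
    """Local jitter (%) and local shimmer (%) over sliding blocks of periods.

    Glottal epochs are located by autocorrelation-guided peak picking in
    each voiced segment.  Per block of ``jitter_block_periods`` periods:
    ``jitter = 100 * mean|T(i) - T(i-1)| / mean T`` and analogously for the
    peak amplitudes.  Blocks with fewer than 3 periods are skipped.
    """
    cfg = cfg or SpeechConfig()
    jit_blocks: list = []
    shim_blocks: list = []
    for s, e in seg.segments:
        x = w.samples[s:e]
        if x.size < int(0.1 * w.rate):
            continue
        try:
            fseg = frame_signal(Waveform(x, w.rate), cfg.win_ms, cfg.overlap)
        except ValidationError:
            continue
        p = pitch_series(fseg, cfg=cfg)
        voiced_f0 = p.valid_values()
        if voiced_f0.size:
            f0 = float(np.median(voiced_f0))
        else:
            # irregular phonation can defeat the autocorrelation voicing
            # decision (e.g. strongly alternating periods); fall back to a
            # coarse pulse-rate estimate so period marks can still be found
            coarse, _ = sps.find_peaks(
                x, distance=max(2, int(w.rate / cfg.fmax_hz)),
                height=0.3 * np.max(np.abs(x)),
            )
            if coarse.size < 3:
                continue
            f0 = float(np.clip((coarse.size - 1) * w.rate / np.ptp(coarse),
                               cfg.fmin_hz, cfg.fmax_hz))
        t, a = _period_marks(x, w.rate, f0)
        if t.size < 3:
            continue
        periods = np.diff(t)
        amps = a[1:]
        ok = (periods > 0.55 * w.rate / f0) & (periods < 1.8 * w.rate / f0)
        periods, amps = periods[ok], amps[ok]
        block, hop = cfg.jitter_block_periods, cfg.jitter_block_hop
        if periods.size < 3:
            continue
        if periods.size <= block:
            starts = [0]
            block_eff = periods.size
        else:
            starts = list(range(0, periods.size - block + 1, hop))
            block_eff = block
        for st in starts:
            pt = periods[st : st + block_eff]
            am = amps[st : st + block_eff]
            jit_blocks.append(100.0 * np.mean(np.abs(np.diff(pt))) / np.mean(pt))
            shim_blocks.append(100.0 * np.mean(np.abs(np.diff(am))) / np.mean(np.abs(am)))
    return (
        FeatureSeries("jitter_local_pct", np.array(jit_blocks), "%"),
        FeatureSeries("shimmer_local_pct", np.array(shim_blocks), "%"),
    )


# ---------------------------------------------------------------------------
# articulation (formants), nasality, voice breaks
# ---------------------------------------------------------------------------


def _lpc(frame: np.ndarray, order: int):
    """LP coefficients [1, a1..ap] and the model's prediction gain.

    The gain (signal energy over residual energy) separates resonant
    speech-like frames, which linear prediction models well, from noise
    frames, which it does not.
    """
    r = _autocorr(frame)[: order + 1]
    if r[0] <= 0:
        return None, 0.0
    r = r / r[0]
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return None, 0.0
    coeffs = np.concatenate(([1.0], a))
    if not np.all(np.isfinite(coeffs)):
        return None, 0.0
    err = float(coeffs @ r)  # normalized residual energy
    gain = 1.0 / err if err > 1e-12 else np.inf
    return coeffs, gain


def articulation_series(
    fs: FrameSeries, lpc_order: int | None = None, cfg: SpeechConfig | None = None
):
    """First two formants per frame by LPC root solving.

    Frames are decimated to ~11 kHz (formant band) before fitting; roots
    with bandwidth < 400 Hz above 90 Hz qualify as resonances and the two
    lowest are reported as f1, f2.  Unstable or silent frames carry NaN.
    """
    cfg = cfg or SpeechConfig()
    q = max(1, int(round(fs.rate / cfg.formant_target_rate)))
    eff_rate = fs.rate / q
    order = lpc_order if lpc_order is not None else cfg.lpc_order
    if order is None:
        order = 2 + int(round(eff_rate / 1000.0))
    f1 = np.full(fs.n_frames, np.nan)
    f2 = np.full(fs.n_frames, np.nan)
    energy_floor = 1e-10 * max(np.max(fs.frames**2), 1e-30)
    for i in range(fs.n_frames):
        frame = fs.frames[i]
        if np.mean(frame**2) <= energy_floor:
            continue
        if q > 1:
            frame = sps.resample_poly(frame, 1, q)
        frame = np.append(frame[0], frame[1:] - 0.97 * frame[:-1])  # pre-emphasis
        frame = frame * np.hamming(frame.size)
        a, gain = _lpc(frame, order)
        if a is None or gain < cfg.formant_min_prediction_gain:
            continue
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        if roots.size == 0:
            continue
        freqs = np.angle(roots) * eff_rate / (2 * np.pi)
        mags = np.abs(roots)
        with np.errstate(divide="ignore"):
            bws = -eff_rate / np.pi * np.log(np.where(mags > 0, mags, 1e-12))
        keep = (bws < cfg.formant_max_bandwidth_hz) & (freqs > cfg.formant_min_hz)
        if keep.sum() < 2:
            # strong nasal coupling or high f0 can merge/broaden a formant;
            # retry with a relaxed bandwidth cap before skipping the frame
            keep = (bws < 1.5 * cfg.formant_max_bandwidth_hz) & (freqs > cfg.formant_min_hz)
        cand = np.sort(freqs[keep])
        if cand.size >= 1:
            f1[i] = cand[0]
        if cand.size >= 2:
            f2[i] = cand[1]
    return (
        FeatureSeries("f1_hz", f1, "Hz"),
        FeatureSeries("f2_hz", f2, "Hz"),
    )


def nasality_series(fs: FrameSeries, cfg: SpeechConfig | None = None) -> FeatureSeries:
    """Nasal-murmur band power over total power per frame.

    Ratio of the power in ``nasal_band_hz`` (default 200-500 Hz) to the
    power in ``nasal_total_hz`` (default 0-4 kHz) of the Hann-windowed
    magnitude-squared spectrum.  Zero-energy frames report 0.
    """
    cfg = cfg or SpeechConfig()
    win = np.hanning(fs.win_samples)
    spec = np.abs(np.fft.rfft(fs.frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(fs.win_samples, 1.0 / fs.rate)
    lo, hi = cfg.nasal_band_hz
    tlo, thi = cfg.nasal_total_hz
    band = spec[:, (freqs >= lo) & (freqs <= hi)].sum(axis=1)
    total = spec[:, (freqs >= tlo) & (freqs <= thi)].sum(axis=1)
    ratio = np.where(total > 0, band / np.where(total > 0, total, 1.0), 0.0)
    return FeatureSeries("nasality", ratio, "")


def _frame_hnr(frame: np.ndarray, rate: int, cfg: SpeechConfig) -> float:
    """Harmonics-to-noise ratio (dB) from the normalized autocorrelation peak."""
    _, _, peak = _frame_f0(frame, rate, cfg.fmin_hz, cfg.fmax_hz, vthr=0.0)
    peak = float(np.clip(peak, 1e-6, 1 - 1e-6))
    return 10.0 * np.log10(peak / (1.0 - peak))


def voice_break_features(
    w: Waveform, seg: VoicedSegmentation, cfg: SpeechConfig | None = None
):
    """Pitch and HNR trajectories around every speech/silence boundary.

    Every segment start contributes a silence-to-speech transition and every
    segment end a speech-to-silence transition.  Around each boundary a
    context of ``transition_context_frames`` frames per side is analysed;
    per transition the pitch trajectory (Hz, NaN when unvoiced) and the HNR
    trajectory (dB) are concatenated, and all transitions concatenate in
    temporal order into one flattened series for imaging.
    """
    cfg = cfg or SpeechConfig()
    if not seg.segments:
        return TransitionFeatureSet([]), FeatureSeries("voice_breaks", np.empty(0), "")
    win = int(round(cfg.win_ms / 1000.0 * w.rate))
    hop = int(np.floor(win * (1.0 - cfg.overlap)))
    ctx = cfg.transition_context_frames

    boundaries = []
    for s, e in seg.segments:
        boundaries.append(("silence_to_speech", s))
        boundaries.append(("speech_to_silence", e))
    boundaries.sort(key=lambda t: t[1])

    records = []
    flat: list = []
    for ttype, b in boundaries:
        lo = max(0, b - ctx * hop - win // 2)
        hi = min(w.samples.size, b + ctx * hop + win // 2 + win)
        chunk = w.samples[lo:hi]
        if chunk.size < win:
            continue
        fseg = frame_signal(Waveform(chunk, w.rate), cfg.win_ms, cfg.overlap)
        pitch = np.full(fseg.n_frames, np.nan)
        hnr = np.empty(fseg.n_frames)
        for i in range(fseg.n_frames):
            f0, voiced, _ = _frame_f0(
                fseg.frames[i], w.rate, cfg.fmin_hz, cfg.fmax_hz, cfg.voicing_threshold
            )
            if voiced:
                pitch[i] = f0
            hnr[i] = _frame_hnr(fseg.frames[i], w.rate, cfg)
        records.append(
            {
                "transition_type": ttype,
                "boundary_sample": int(b),
                "pitch_hz": pitch,
                "hnr_db": hnr,
            }
        )
        flat.extend(pitch.tolist())
        flat.extend(hnr.tolist())
    series = FeatureSeries("voice_breaks", np.array(flat), "")
    series.meta["units_note"] = "per transition: pitch trajectory (Hz) then HNR trajectory (dB)"
    return TransitionFeatureSet(records), series


# ---------------------------------------------------------------------------
# full front end
# ---------------------------------------------------------------------------


def extract_manifestation_series(w: Waveform, cfg: SpeechConfig | None = None) -> dict:
    """Run the complete speech front end and return the six canonical series.

    Returns a dict keyed by manifestation: ``monoloudness`` (squared
    energy), ``monopitch`` (voiced f0), ``articulation`` (f2),
    ``tremor`` (local jitter), ``nasality`` (voiced nasal-band ratio) and
    ``breaks`` (flattened transition trajectories).  Sentinel (NaN) frames
    are dropped so every series is imaging-ready.
    """
    cfg = cfg or SpeechConfig()
    clean = wiener_denoise(w, cfg=cfg)
    seg = detect_voice_activity(clean, cfg=cfg)
    voiced = seg.voiced_samples(clean.samples)
    if voiced.size < int(cfg.win_ms / 1000.0 * w.rate):
        raise ValidationError("no usable voiced speech detected")
    vf = frame_signal(Waveform(voiced, w.rate), cfg.win_ms, cfg.overlap)

    sq, _ = loudness_series(vf)
    pitch = pitch_series(vf, cfg=cfg)
    jitter, _shimmer = tremor_series(clean, seg, cfg)
    _f1, f2 = articulation_series(vf, cfg=cfg)
    nas = nasality_series(vf, cfg=cfg)
    nas_voiced = FeatureSeries("nasality", nas.values[pitch.valid_mask], nas.units)
    _trans, breaks = voice_break_features(clean, seg, cfg)
    return {
        "monoloudness": sq,
        "monopitch": pitch.dropna(),
        "articulation": f2.dropna(),
        "tremor": jitter,
        "nasality": nas_voiced,
        "breaks": breaks.dropna(),
    }
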