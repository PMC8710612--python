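"""Acoustic and prosodic feature extraction from a single speech response.

The chain is: energy-based voice activity detection -> per-frame analysis
restricted to voiced speech -> response-level summaries.  Acoustic features
are the first two formants (LPC root finding) and the per-coefficient
variances of the first-order delta of MFCC coefficients 1-14.  Prosodic
features are the dispersion of the frame-level fundamental frequency
(pitch variation) and the total internal pause duration.

All frame-level aggregations use population (ddof=0) variance / standard
deviation; this convention is fixed package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.signal

VOICE = "voice"
SILENCE = "silence"

#: default analysis rate (Hz); inputs are resampled here before analysis
ANALYSIS_RATE = 16000


@dataclass(frozen=True)
class AudioResponse:
    """Mono PCM samples for one question response.

    samples are dimensionless amplitudes in [-1, 1]; rate in Hz.
    """

    samples: np.ndarray
    rate: int
    question_id: int = 1

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("audio must be single-channel")
        if self.samples.size == 0:
            raise ValueError("empty audio")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class Segmentation:
    """Ordered voice/silence intervals tiling [0, duration].

    intervals: list of (start_s, end_s, label); adjacent labels differ.
    """

    intervals: tuple

    def __post_init__(self):
        iv = tuple((float(a), float(b), str(lab)) for a, b, lab in self.intervals)
        object.__setattr__(self, "intervals", iv)
        prev_end, prev_lab = 0.0, None
        for a, b, lab in iv:
            if lab not in (VOICE, SILENCE):
                raise ValueError(f"bad label {lab!r}")
            if not a < b:
                raise ValueError("interval must have start < end")
            if abs(a - prev_end) > 1e-9:
                raise ValueError("intervals must tile without gap or overlap")
            if lab == prev_lab:
                raise ValueError("adjacent intervals must alternate labels")
            prev_end, prev_lab = b, lab

    @property
    def duration(self) -> float:
        return self.intervals[-1][1]

    def voice_intervals(self):
        return [(a, b) for a, b, lab in self.intervals if lab == VOICE]

    def silence_intervals(self):
        return [(a, b) for a, b, lab in self.intervals if lab == SILENCE]


@dataclass(frozen=True)
class AcousticSummary:
    """Response-level acoustic summary: F1, F2 (Hz) and 14 delta-MFCC variances."""

    f1_hz: float
    f2_hz: float
    dmfcc_var: np.ndarray  # indexed by coefficient 1..14

    def __post_init__(self):
        v = np.asarray(self.dmfcc_var, dtype=np.float64)
        object.__setattr__(self, "dmfcc_var", v)
        if v.shape != (14,):
            raise ValueError("exactly 14 delta-MFCC variances required")
        if np.any(v < 0):
            raise ValueError("variances must be non-negative")
        if np.isfinite(self.f1_hz) and np.isfinite(self.f2_hz) and not self.f1_hz < self.f2_hz:
            raise ValueError("F1 must lie below F2")


@dataclass(frozen=True)
class ProsodySummary:
    pitch_variation_hz: float
    pause_duration_s: float


# ---------------------------------------------------------------------------
# voice activity detection


def _frame_rms(x: np.ndarray, frame_len: int) -> np.ndarray:
    """RMS of consecutive non-overlapping frames (last partial frame kept)."""
    n_full = x.size // frame_len
    out = []
    if n_full:
        mat = x[: n_full * frame_len].reshape(n_full, frame_len)
        out.append(np.sqrt(np.mean(mat**2, axis=1)))
    rem = x[n_full * frame_len:]
    if rem.size:
        out.append(np.array([np.sqrt(np.mean(rem**2))]))
    return np.concatenate(out)


def detect_voice_activity(
    audio: AudioResponse,
    frame_s: float = 0.025,
    energy_floor_db: float = -30.0,
    min_seg_s: float = 0.2,
) -> Segmentation:
    """Split a response into voice and silence segments by frame energy.

    A frame is voice iff its RMS energy in dB exceeds the loudest frame's
    RMS plus ``energy_floor_db`` (a negative offset).  Label runs shorter
    than ``min_seg_s`` are absorbed into the surrounding label so the
    segmentation does not flicker at phone rate.
    """
    if frame_s <= 0:
        raise ValueError("frame_s must be positive")
    if min_seg_s < frame_s:
        raise ValueError("min_seg_s must be >= frame_s")
    x = audio.samples
    frame_len = int(round(frame_s * audio.rate))
    if frame_len > x.size:
        raise ValueError("frame longer than audio")
    rms = _frame_rms(x, frame_len)
    peak = rms.max()
    if peak == 0.0:
        raise ValueError("no signal: audio is all zeros")
    with np.errstate(divide="ignore"):
        rms_db = 20.0 * np.log10(rms / peak)
    voiced = rms_db > energy_floor_db

    # frame boundaries in seconds; last frame may be shorter
    n = voiced.size
    bounds = np.minimum(np.arange(n + 1) * frame_len / audio.rate, audio.duration)

    # run-length encode, then absorb short runs in two passes: first bridge
    # sub-minimum silences into voice, then drop sub-minimum voice bursts
    def encode(flags):
        runs = []  # [label, start_idx, end_idx) over frames
        for i, v in enumerate(flags):
            if runs and runs[-1][0] == v:
                runs[-1][2] = i + 1
            else:
                runs.append([bool(v), i, i + 1])
        return runs

    def absorb(runs, target_label):
        out = []
        for r in runs:
            if (r[0] is target_label and len(runs) > 1
                    and bounds[r[2]] - bounds[r[1]] < min_seg_s):
                r = [not target_label, r[1], r[2]]
            if out and out[-1][0] == r[0]:
                out[-1][2] = r[2]
            else:
                out.append(r)
        return out

    runs = absorb(encode(voiced), False)
    runs = absorb(runs, True)

    intervals = [
        (bounds[a], bounds[b], VOICE if lab else SILENCE) for lab, a, b in runs
    ]
    return Segmentation(tuple(intervals))


# ---------------------------------------------------------------------------
# framing helpers


def _voiced_frame_starts(
    n_samples: int, rate: int, frame_len: int, hop_len: int, segmentation: Segmentation
) -> np.ndarray:
    """Start indices of frames lying fully inside voice segments."""
    starts = np.arange(0, n_samples - frame_len + 1, hop_len)
    keep = np.zeros(starts.size, dtype=bool)
    for a, b in segmentation.voice_intervals():
        lo, hi = a * rate, b * rate
        keep |= (starts >= lo - 0.5) & (starts + frame_len <= hi + 0.5)
    return starts[keep]


# ---------------------------------------------------------------------------
# MFCC


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mel: int, n_fft: int, rate: int, f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mel, n_fft//2 + 1)."""
    if f_hi is None:
        f_hi = rate / 2.0
    mel_pts = np.linspace(hz_to_mel(f_lo), hz_to_mel(f_hi), n_mel + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((n_mel, bin_freqs.size))
    for k in range(n_mel):
        left, center, right = hz_pts[k], hz_pts[k + 1], hz_pts[k + 2]
        up = (bin_freqs - left) / (center - left)
        down = (right - bin_freqs) / (right - center)
        fb[k] = np.maximum(0.0, np.minimum(up, down))
    return fb


def compute_mfcc(
    audio: AudioResponse,
    segmentation: Segmentation,
    n_coeff: int = 14,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    n_mel: int = 26,
    n_fft: int = 512,
    include_c0: bool = False,
) -> np.ndarray:
    """MFCC matrix (voiced frames x n_coeff).

    Each row is the DCT-II (orthonormal) of the log mel-filterbank energies
    of one Hann-windowed frame.  By default the 0th (energy) coefficient is
    dropped and coefficients 1..n_coeff are returned; ``include_c0`` switches
    to coefficients 0..n_coeff-1.
    """
    rate = audio.rate
    frame_len = int(round(frame_s * rate))
    hop_len = int(round(hop_s * rate))
    starts = _voiced_frame_starts(audio.samples.size, rate, frame_len, hop_len, segmentation)
    if starts.size == 0:
        raise ValueError("no voiced speech")
    window = np.hanning(frame_len)
    fb = mel_filterbank(n_mel, n_fft, rate)
    frames = audio.samples[starts[:, None] + np.arange(frame_len)] * window
    spec = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    energies = spec @ fb.T
    log_e = np.log(np.maximum(energies, 1e-12))
    cepstra = scipy.fft.dct(log_e, type=2, norm="ortho", axis=1)
    if include_c0:
        return cepstra[:, :n_coeff]
    return cepstra[:, 1 : n_coeff + 1]


def delta_coefficients(mfcc: np.ndarray, half_window: int = 2) -> np.ndarray:
    """First-order delta by local linear regression over +/- half_window frames.

    delta_t = sum_d d*(c_{t+d} - c_{t-d}) / (2 * sum_d d^2), edges replicated.
    """
    mfcc = np.asarray(mfcc, dtype=np.float64)
    if mfcc.ndim == 1:
        mfcc = mfcc[:, None]
    n = mfcc.shape[0]
    if n < 2 * half_window + 1:
        raise ValueError("too few frames for delta window")
    padded = np.concatenate(
        [np.repeat(mfcc[:1], half_window, axis=0), mfcc, np.repeat(mfcc[-1:], half_window, axis=0)]
    )
    denom = 2.0 * sum(d * d for d in range(1, half_window + 1))
    out = np.zeros_like(mfcc)
    for d in range(1, half_window + 1):
        out += d * (padded[half_window + d : half_window + d + n] - padded[half_window - d : half_window - d + n])
    return out / denom


def dmfcc_variances(delta: np.ndarray) -> np.ndarray:
    """Population variance of each delta-coefficient track across frames."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.ndim == 1:
        delta = delta[:, None]
    if delta.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    return np.var(delta, axis=0, ddof=0)


# ---------------------------------------------------------------------------
# fundamental frequency


def estimate_f0_track(
    audio: AudioResponse,
    segmentation: Segmentation,
    f0_min: float = 60.0,
    f0_max: float = 400.0,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.6,
):
    """Per-frame F0 by the normalized-autocorrelation peak in the lag band.

    Returns (f0_hz, voiced_flag) arrays over frames fully inside voice
    segments.  A frame is voiced when its normalized autocorrelation peak
    exceeds ``voicing_threshold``.
    """
    if not f0_min < f0_max:
        raise ValueError("f0_min must be below f0_max")
    rate = audio.rate
    lag_min = int(np.floor(rate / f0_max))
    lag_max = int(np.ceil(rate / f0_min))
    frame_len = int(round(frame_s * rate))
    hop_len = int(round(hop_s * rate))
    if lag_max >= frame_len or lag_min < 1:
        raise ValueError("F0 band empty at this rate / frame length")
    starts = _voiced_frame_starts(audio.samples.size, rate, frame_len, hop_len, segmentation)
    if starts.size == 0:
        raise ValueError("no voiced speech")
    f0 = np.zeros(starts.size)
    voiced = np.zeros(starts.size, dtype=bool)
    x = audio.samples
    lags = np.arange(lag_min, lag_max + 1)
    for i, s in enumerate(starts):
        frame = x[s : s + frame_len]
        frame = frame - frame.mean()
        ac = scipy.signal.correlate(frame, frame, mode="full")[frame_len - 1 :]
        e0 = ac[0]
        if e0 <= 0:
            continue
        cum = np.cumsum(frame**2)
        tails = cum[-1] - cum[lags - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = ac[lags] / np.sqrt(e0 * tails)
        r = np.where(np.isfinite(r), r, -1.0)
        best_r = r.max()
        if best_r > voicing_threshold:
            # subharmonics of a periodic frame peak nearly as high as the
            # true period; among local maxima within tolerance of the global
            # peak, take the smallest lag
            interior = np.zeros(r.size, dtype=bool)
            interior[1:-1] = (r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])
            interior[np.argmax(r)] = True
            cand = np.nonzero(interior & (r >= best_r - 0.05))[0]
            lag = lags[cand[0]]
            f0[i] = rate / lag
            voiced[i] = True
    return f0, voiced


def pitch_variation(f0_track) -> float:
    """Population SD of F0 over voiced frames (Hz)."""
    f0, voiced = f0_track
    vals = np.asarray(f0)[np.asarray(voiced, dtype=bool)]
    if vals.size < 2:
        raise ValueError("need at least 2 voiced frames")
    return float(np.std(vals, ddof=0))


def pause_duration(segmentation: Segmentation) -> float:
    """Total duration of silences strictly between the first and last voice
    interval; leading and trailing silence do not count as pauses."""
    voice = segmentation.voice_intervals()
    if not voice:
        raise ValueError("no voice interval in segmentation")
    first_v, last_v = voice[0][0], voice[-1][1]
    total = 0.0
    for a, b in segmentation.silence_intervals():
        if a >= first_v and b <= last_v:
            total += b - a
    return total


# ---------------------------------------------------------------------------
# formants (LPC)


def levinson_durbin(r: np.ndarray, order: int) -> np.ndarray:
    """Solve the LPC autocorrelation normal equations by Levinson-Durbin.

    Returns prediction coefficients a[1..order] such that
    x_t ~ sum_k a_k x_{t-k}; they satisfy R a = r[1:order+1] with R the
    Toeplitz autocorrelation matrix.
    """
    a = np.zeros(order)
    e = r[0]
    if e <= 0:
        raise ValueError("non-positive frame energy")
    for i in range(order):
        acc = r[i + 1] - np.dot(a[:i], r[i:0:-1])
        k = acc / e
        a_new = a.copy()
        a_new[i] = k
        a_new[:i] = a[:i] - k * a[i - 1 :: -1][: i]
        a = a_new
        e *= 1.0 - k * k
        if e <= 0:
            break
    return a


def _lpc_formant_candidates(frame: np.ndarray, rate: int, order: int):
    """Formant (frequency, bandwidth) candidates from LPC polynomial roots."""
    r = scipy.signal.correlate(frame, frame, mode="full")[frame.size - 1 :][: order + 1]
    if r[0] <= 0:
        return []
    a = levinson_durbin(r, order)
    poly = np.concatenate([[1.0], -a])
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 1e-6]
    freqs = np.angle(roots) * rate / (2.0 * np.pi)
    with np.errstate(divide="ignore"):
        bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * rate / np.pi
    cands = [(f, bw) for f, bw in zip(freqs, bws) if 90.0 <= f <= 4000.0 and bw < 400.0]
    cands.sort()
    return cands


def estimate_formants(
    audio: AudioResponse,
    segmentation: Segmentation,
    lpc_order: int | None = None,
    frame_s: float = 0.030,
    hop_s: float = 0.010,
    preemphasis: float = 0.5,
):
    """Response-level (F1, F2) in Hz.

    Per voiced frame: pre-emphasized, Hamming-windowed LPC fit by the
    autocorrelation method; polynomial roots in the upper half plane are
    converted to (frequency, bandwidth) pairs, gated to 90-4000 Hz and
    bandwidth < 400 Hz, and sorted ascending.  The response value is the
    median over frames that produced at least two surviving candidates.
    """
    rate = audio.rate
    if lpc_order is None:
        lpc_order = 2 + rate // 1000
    if lpc_order < 4:
        raise ValueError("lpc_order must be >= 4")
    frame_len = int(round(frame_s * rate))
    hop_len = int(round(hop_s * rate))
    x = np.append(audio.samples[0], audio.samples[1:] - preemphasis * audio.samples[:-1])
    starts = _voiced_frame_starts(x.size, rate, frame_len, hop_len, segmentation)
    if starts.size == 0:
        raise ValueError("no voiced speech")
    window = np.hamming(frame_len)
    f1s, f2s = [], []
    for s in starts:
        cands = _lpc_formant_candidates(x[s : s + frame_len] * window, rate, lpc_order)
        if len(cands) >= 2:
            f1s.append(cands[0][0])
            f2s.append(cands[1][0])
    if not f1s:
        raise ValueError("formants unresolved")
    return float(np.median(f1s)), float(np.median(f2s))


# ---------------------------------------------------------------------------
# response-level composition


def summarize_response_acoustics(
    audio: AudioResponse,
    segmentation: Segmentation,
    n_coeff: int = 14,
    delta_half_window: int = 2,
    **mfcc_kwargs,
) -> AcousticSummary:
    """Compose MFCC -> delta -> variances and LPC formants into one summary."""
    mfcc = compute_mfcc(audio, segmentation, n_coeff=n_coeff, **mfcc_kwargs)
    delta = delta_coefficients(mfcc, half_window=delta_half_window)
    variances = dmfcc_variances(delta)
    f1, f2 = estimate_formants(audio, segmentation)
    return AcousticSummary(f1_hz=f1, f2_hz=f2, dmfcc_var=variances)


def summarize_response_prosody(
    audio: AudioResponse,
    segmentation: Segmentation,
    f0_min: float = 60.0,
    f0_max: float = 400.0,
) -> ProsodySummary:
    track = estimate_f0_track(audio, segmentation, f0_min=f0_min, f0_max=f0_max)
    return ProsodySummary(
        pitch_variation_hz=pitch_variation(track),
        pause_duration_s=pause_duration(segmentation),
    )
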