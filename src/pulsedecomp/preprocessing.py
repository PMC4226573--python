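"""Raw two-channel record → ten consecutive ectopic-free pulse episodes.

The pretreatment chain mirrors standard pulse-wave practice: remove slow
baseline wander (0–0.05 Hz) from both channels, locate ECG R-peaks as beat
anchors, find the pulse foot (beat onset) that follows each R-peak on the
pressure channel, exclude ectopic beats by an RR-interval deviation rule,
and select the earliest run of ``k`` consecutive clean beats as episodes.

Conventions: 0-based sample indices throughout; an episode is the half-open
sample range [foot_i, foot_{i+1}).

The R-peak detector is a band-pass + adaptive-threshold local-maximum
detector with a refractory period — a functional stand-in for wavelet-based
detectors, adequate because R-peaks serve only as timing anchors.  The foot
detector uses the intersecting-tangent construction: the tangent at the
point of maximal upslope intersected with the horizontal line through the
preceding minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DetectionError, InputError, SelectionError


@dataclass(frozen=True)
class RawRecord:
    """Synchronized ECG and radial-pressure traces with their sampling rate."""

    ecg: np.ndarray
    rapw: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "ecg", np.asarray(self.ecg, dtype=float))
        object.__setattr__(self, "rapw", np.asarray(self.rapw, dtype=float))
        if len(self.ecg) != len(self.rapw):
            raise InputError("ECG and RAPW channels must have equal length")
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)


@dataclass(frozen=True)
class BeatAnnotations:
    """Per-beat landmarks: R-peak and foot sample indices plus ectopic flags."""

    r_peaks: np.ndarray
    feet: np.ndarray
    ectopic_mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "r_peaks", np.asarray(self.r_peaks, dtype=int))
        object.__setattr__(self, "feet", np.asarray(self.feet, dtype=int))
        object.__setattr__(self, "ectopic_mask", np.asarray(self.ectopic_mask, dtype=bool))


def remove_baseline(signal: np.ndarray, fs: float, cutoff: float = 0.05) -> np.ndarray:
    """Remove slow baseline wander (the 0–``cutoff`` Hz band).

    Zero-phase (forward–backward) 4th-order Butterworth high-pass, so beat
    morphology is not phase-distorted.  For good attenuation the record
    should span several wander periods (length >= 10 * fs / cutoff samples
    recommended).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise InputError("empty signal")
    if fs <= 0:
        raise InputError("sampling rate must be positive")
    sos = sps.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    # pad with ~2 filter time constants to suppress edge transients
    padlen = int(min(len(signal) - 1, round(2.0 * fs / cutoff)))
    return sps.sosfiltfilt(sos, signal, padlen=padlen)


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    band: tuple[float, float] = (5.0, 30.0),
    threshold_frac: float = 0.3,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """Locate one R-peak per beat on the ECG channel.

    The signal is band-passed to ``band`` Hz, squared and smoothed into an
    energy envelope; candidate beats are envelope peaks above
    ``threshold_frac`` of the maximum envelope, separated by the refractory
    period.  Each candidate is then refined to the local ECG maximum within
    ±50 ms.  Scale-invariant because the threshold is relative.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < int(fs):
        raise InputError("ECG too short for R-peak detection")
    if not np.any(ecg != 0):
        raise DetectionError("flat ECG: no R-peaks detectable")

    nyq = fs / 2.0
    hi = min(band[1], 0.9 * nyq)
    sos = sps.butter(2, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    energy = sps.sosfiltfilt(sos, ecg) ** 2
    win = max(1, int(round(0.10 * fs)))
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")

    height = threshold_frac * float(np.max(envelope))
    if height <= 0:
        raise DetectionError("flat ECG: no R-peaks detectable")
    locs, _ = sps.find_peaks(envelope, height=height, distance=max(1, int(round(refractory_s * fs))))
    if len(locs) < 2:
        raise DetectionError(f"found {len(locs)} candidate beats; need at least 2")

    half = int(round(0.05 * fs))
    peaks = []
    for loc in locs:
        a, b = max(0, loc - half), min(len(ecg), loc + half + 1)
        peaks.append(a + int(np.argmax(ecg[a:b])))
    peaks = np.unique(peaks)
    return peaks.astype(int)


def _hinge_breakpoint(seg: np.ndarray) -> int | None:
    """Breakpoint of a continuous-trend + onset model fit to one window.

    Least-squares fit of ``y = a + b·n + J·1[n>k] + g·(n-k)+`` for each
    candidate breakpoint k: a linear pre-onset trend plus a rising edge that
    may start with a sharp offset.  Returns the first post-break sample (the
    onset), or None when the window is too short.
    """
    m = len(seg)
    if m < 15:
        return None
    n = np.arange(m, dtype=float)
    ones = np.ones_like(n)
    best_k, best_sse = None, np.inf
    for k in range(5, m - 5):
        x = np.column_stack([ones, n, (n > k).astype(float), np.maximum(0.0, n - k)])
        beta, res, *_ = np.linalg.lstsq(x, seg, rcond=None)
        sse = float(res[0]) if len(res) else float(np.sum((seg - x @ beta) ** 2))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return None if best_k is None else best_k + 1


def detect_pulse_feet(
    rapw: np.ndarray, fs: float, r_peaks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the pulse foot (beat onset) following each R-peak.

    Three passes per record:

    1. *Coarse:* within the window from each R-peak to the next, find the
       maximal-upslope point on a lightly smoothed copy and intersect its
       tangent with the horizontal line through the preceding minimum
       (intersecting-tangent construction) to bracket the onset.
    2. *Rising-edge fit:* around that bracket, fit a continuous two-segment
       model — linear diastolic trend plus a rising edge with optional sharp
       onset — by least squares; the fitted breakpoint is the foot.  Run
       twice, re-centering the window on the first estimate.
    3. *Transit-time consistency:* the foot-to-R-peak interval is
       physiologically stable within a recording, so feet deviating from the
       record median offset are re-fit in a narrow window and, failing that,
       snapped to the consensus offset.

    Returns ``(feet, ok)`` aligned to ``r_peaks``; a window with no rising
    edge yields ``ok[i] = False`` and sentinel foot ``-1`` (beat dropped).
    Invariant to constant offsets of ``rapw``.
    """
    rapw = np.asarray(rapw, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) == 0:
        raise InputError("no R-peaks supplied")
    median_rr = float(np.median(np.diff(r_peaks))) if len(r_peaks) > 1 else 1.0 * fs

    win = max(1, int(round(0.015 * fs)))
    smooth = np.convolve(rapw, np.ones(win) / win, mode="same")
    deriv = np.gradient(smooth)

    feet = np.full(len(r_peaks), -1, dtype=int)
    ok = np.zeros(len(r_peaks), dtype=bool)

    for i, r in enumerate(r_peaks):
        end = r_peaks[i + 1] if i + 1 < len(r_peaks) else min(len(rapw), int(r + 1.2 * median_rr))
        a, b = int(r), int(end)
        if b - a < 5:
            continue
        window_deriv = deriv[a:b]
        if np.max(window_deriv) <= 0:
            continue  # no rising edge in this window
        up = a + int(np.argmax(window_deriv))
        # preceding minimum between the R-peak and the max-upslope point
        mn = a + int(np.argmin(smooth[a : up + 1]))
        slope = deriv[up]
        if slope <= 0:
            feet[i], ok[i] = mn, True
            continue
        x = up - (smooth[up] - smooth[mn]) / slope
        tangent_pt = int(round(np.clip(x, a, b - 1)))

        lo, hi = max(a, tangent_pt - int(0.15 * median_rr)), min(b, tangent_pt + 40)
        k = _hinge_breakpoint(rapw[lo:hi])
        if k is None:
            feet[i], ok[i] = mn, True
            continue
        foot = lo + k
        lo2, hi2 = max(a, foot - int(0.12 * median_rr)), min(b, foot + 30)
        k2 = _hinge_breakpoint(rapw[lo2:hi2])
        if k2 is not None:
            foot = lo2 + k2
        feet[i], ok[i] = foot, True

    if ok.sum() >= 3:
        med = int(round(np.median(feet[ok] - r_peaks[ok])))
        for i, r in enumerate(r_peaks):
            if not ok[i] or abs(feet[i] - (r + med)) <= 5:
                continue
            lo, hi = max(0, r + med - 22), min(len(rapw), r + med + 23)
            k = _hinge_breakpoint(rapw[lo:hi])
            if k is not None:
                feet[i] = lo + k
            if abs(feet[i] - (r + med)) > 5:
                feet[i] = r + med
    if not np.any(ok):
        raise DetectionError("no pulse feet detected in any beat window")
    return feet, ok


def exclude_ectopic(
    r_peaks: np.ndarray, fs: float, threshold: float = 0.20, window: int = 7
) -> np.ndarray:
    """Flag beats with anomalous timing.

    An RR interval deviating more than ``threshold`` (fraction) from the
    running median RR (centered window of ``window`` intervals) is anomalous;
    both beats bounding it are flagged.  Returns a boolean mask per beat.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if len(r_peaks) < 3:
        raise InputError("need at least 3 beats for ectopic screening")
    rr = np.diff(r_peaks)
    mask = np.zeros(len(r_peaks), dtype=bool)
    half = window // 2
    for j in range(len(rr)):
        a, b = max(0, j - half), min(len(rr), j + half + 1)
        med = float(np.median(rr[a:b]))
        if med > 0 and abs(rr[j] - med) > threshold * med:
            mask[j] = True
            mask[j + 1] = True
    return mask


def segment_and_select(
    rapw: np.ndarray, feet: np.ndarray, mask: np.ndarray, k: int = 10
) -> list[np.ndarray]:
    """Extract the earliest run of ``k`` consecutive clean beat episodes.

    Episode ``i`` is the half-open sample range [feet[i], feet[i+1]); it is
    clean when neither bounding beat is flagged.  Raises
    :class:`SelectionError` (carrying the longest clean run found) when no
    run of ``k`` clean episodes exists.
    """
    rapw = np.asarray(rapw, dtype=float)
    feet = np.asarray(feet, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    if len(feet) != len(mask):
        raise InputError("feet and mask must be aligned")
    n_episodes = len(feet) - 1
    clean = np.array([not (mask[i] or mask[i + 1]) for i in range(n_episodes)], dtype=bool)

    run_start, run_len, longest = None, 0, 0
    for i in range(n_episodes):
        if clean[i]:
            if run_len == 0:
                run_start = i
            run_len += 1
            longest = max(longest, run_len)
            if run_len == k:
                start = run_start
                return [rapw[feet[j] : feet[j + 1]].copy() for j in range(start, start + k)]
        else:
            run_len = 0
    raise SelectionError(
        f"no run of {k} consecutive clean beats (longest clean run: {longest})",
        longest_clean_run=longest,
    )


def annotate(record: RawRecord) -> BeatAnnotations:
    """Run detectors end-to-end on a (baseline-removed) record.

    Beats whose foot detection failed are folded into the ectopic mask so
    that episode selection skips them.
    """
    r_peaks = detect_r_peaks(record.ecg, record.fs)
    feet, ok = detect_pulse_feet(record.rapw, record.fs, r_peaks)
    mask = exclude_ectopic(r_peaks, record.fs)
    mask = mask | ~ok
    return BeatAnnotations(r_peaks=r_peaks, feet=feet, ectopic_mask=mask)
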