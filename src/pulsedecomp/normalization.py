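"""Canonical pulse-episode normalization.

Each segmented beat episode is mapped to a fixed representation ``S(n)`` with
exactly 1000 samples and amplitudes spanning [0, 1]: width normalization
resamples the episode onto 1000 uniformly spaced points by interpolation
(linear by default), then amplitude normalization applies the min–max map
``(x - min) / (max - min)``.  Both steps are affine-invariant in amplitude
and preserve the episode's endpoints in time.

Conventions: 0-based sample indices; an episode is the half-open sample
range [foot_i, foot_{i+1}) of the raw recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

TARGET_LENGTH = 1000


@dataclass(frozen=True)
class NormalizedPulse:
    """A width- and amplitude-normalized beat episode.

    ``samples`` has min 0 and max 1 (length 1000 when produced by
    :func:`normalize_episode`); ``source_len`` and ``source_range`` record the
    original episode length and amplitude range so the raw scale is
    recoverable.
    """

    samples: np.ndarray
    source_len: int
    source_range: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    def __len__(self) -> int:
        return len(self.samples)


def width_normalize(episode: np.ndarray, length: int = TARGET_LENGTH, kind: str = "linear") -> np.ndarray:
    """Resample an episode onto ``length`` uniformly spaced points.

    The output grid spans the episode exactly, so the first and last input
    samples are preserved.  ``kind`` selects linear (default) or cubic
    interpolation.
    """
    episode = np.asarray(episode, dtype=float)
    if episode.ndim != 1 or len(episode) < 3:
        raise InputError(f"episode must be 1-D with at least 3 samples, got shape {episode.shape}")
    src = np.arange(len(episode), dtype=float)
    dst = np.linspace(0.0, len(episode) - 1.0, length)
    if kind == "linear":
        return np.interp(dst, src, episode)
    if kind == "cubic":
        from scipy.interpolate import CubicSpline

        return CubicSpline(src, episode)(dst)
    raise InputError(f"unknown interpolation kind {kind!r}")


def amplitude_normalize(episode: np.ndarray) -> NormalizedPulse:
    """Min–max scale an episode to the amplitude range [0, 1]."""
    episode = np.asarray(episode, dtype=float)
    if episode.size == 0:
        raise InputError("empty episode")
    lo, hi = float(np.min(episode)), float(np.max(episode))
    if hi <= lo:
        raise InputError("constant episode has degenerate amplitude range")
    return NormalizedPulse(
        samples=(episode - lo) / (hi - lo),
        source_len=len(episode),
        source_range=(lo, hi),
    )


def normalize_episode(episode: np.ndarray, length: int = TARGET_LENGTH, kind: str = "linear") -> NormalizedPulse:
    """Width-normalize then amplitude-normalize one raw beat episode."""
    episode = np.asarray(episode, dtype=float)
    widened = width_normalize(episode, length=length, kind=kind)
    lo, hi = float(np.min(episode)), float(np.max(episode))
    pulse = amplitude_normalize(widened)
    return NormalizedPulse(samples=pulse.samples, source_len=len(episode), source_range=(lo, hi))
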