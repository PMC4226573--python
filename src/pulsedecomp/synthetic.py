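"""Synthetic signals and cohorts with the structure the analysis assumes.

Two levels of simulation:

* **Beat level** — each pulse is the sum of three positive Gaussians (the
  same model the fitting stage assumes) plus slow sinusoidal baseline wander
  (< 0.05 Hz) and additive white noise.  A pulse train concatenates per-beat
  episodes whose widths follow a jittered RR series, with an ECG-like spike
  channel whose R-peaks precede each pulse foot by a fixed transit delay.
  The ECG is a timing template, not physiological morphology.

* **Cohort level** — per-subject evaluation indices drawn independently per
  (sex × SBP-category) cell from normal distributions with configurable
  means/SDs and cell sizes, defaulting to the composition of a 190-subject
  study cohort (105 men, 85 women in four SBP categories).

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .gaussfit import GaussianTriplet, model_curve
from .preprocessing import RawRecord

#: Interval between the ECG R-peak and the radial pulse foot (s): pulse
#: transit from heart to wrist, a fixed plumbing delay in the simulator.
R_TO_FOOT_DELAY_S = 0.20


@dataclass(frozen=True)
class PulseGroundTruth:
    """True sub-wave parameters and noise model of one synthetic beat shape.

    ``h``/``w``/``c`` are the heights, half-width scales and peak positions
    of the three Gaussians on the canonical 1000-sample beat axis.
    """

    h: tuple[float, float, float] = (0.73, 0.67, 0.30)
    # wide third sub-wave keeps a definite diastolic decay to the beat's end,
    # so the next pulse foot is a well-defined onset minimum
    w: tuple[float, float, float] = (55.0, 85.0, 200.0)
    c: tuple[float, float, float] = (136.0, 260.0, 450.0)
    noise_sd: float = 0.0
    baseline_amp: float = 0.0
    baseline_freq: float = 0.02  # Hz, must stay below the 0.05 Hz removal band

    def __post_init__(self):
        self.triplet()  # validates h, w, c
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0 < self.baseline_freq < 0.05):
            raise ParameterError("baseline wander frequency must lie in (0, 0.05) Hz")

    def triplet(self) -> GaussianTriplet:
        return GaussianTriplet(h=self.h, w=self.w, c=self.c)


@dataclass(frozen=True)
class TrainSpec:
    """Layout of a synthetic pulse train."""

    n_beats: int = 15
    fs: float = 1000.0
    mean_rr: float = 0.9
    rr_jitter_sd: float = 0.02
    ectopic_beat_indices: tuple[int, ...] = ()
    shape_jitter_sd: float = 0.0  # relative SD applied to h, w, c per beat
    seed: int = 0

    def __post_init__(self):
        if self.n_beats < 1:
            raise ParameterError("n_beats must be >= 1")
        if self.fs <= 0 or self.mean_rr <= 0:
            raise ParameterError("fs and mean_rr must be positive")
        if self.rr_jitter_sd < 0 or self.shape_jitter_sd < 0:
            raise ParameterError("jitter SDs must be >= 0")


@dataclass(frozen=True)
class SyntheticTrain:
    """A generated record plus its ground-truth annotations."""

    record: RawRecord
    r_peaks: np.ndarray
    feet: np.ndarray
    rr_s: np.ndarray
    beat_params: tuple[GaussianTriplet, ...] = ()


def generate_pulse_episode(gt: PulseGroundTruth, length: int = 1000, seed: int = 0) -> np.ndarray:
    """One beat episode: the three-Gaussian curve on samples 1..length plus noise."""
    if length < 3:
        raise ParameterError("length must be >= 3")
    curve = model_curve(gt.triplet(), n_samples=length)
    if gt.noise_sd > 0:
        rng = np.random.default_rng(seed)
        curve = curve + rng.normal(0.0, gt.noise_sd, size=length)
    return curve


def _scaled_params(gt: GaussianTriplet, beat_len: int) -> GaussianTriplet:
    """Rescale canonical-axis parameters to a beat of ``beat_len`` samples."""
    s = beat_len / 1000.0
    return GaussianTriplet(
        h=gt.h,
        w=tuple(max(1e-6, w * s) for w in gt.w),
        c=tuple(min(999.0, max(1.001, c * s)) for c in gt.c),
    )


def generate_pulse_train(gt: PulseGroundTruth, spec: TrainSpec) -> SyntheticTrain:
    """Synthesize a synchronized ECG + RAPW record with known landmarks.

    Beat intervals are ``mean_rr`` plus Gaussian jitter; beats listed in
    ``ectopic_beat_indices`` have their interval shortened by 40%.  Each
    beat's episode is the ground-truth curve rescaled to its own duration;
    the ECG channel carries a narrow spike ``R_TO_FOOT_DELAY_S`` before each
    pulse foot.  Baseline wander and white noise are added to the pressure
    channel.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rr = spec.mean_rr + rng.normal(0.0, spec.rr_jitter_sd, size=spec.n_beats)
    rr = np.clip(rr, 0.3 * spec.mean_rr, None)
    for idx in spec.ectopic_beat_indices:
        if not (0 <= idx < spec.n_beats):
            raise ParameterError(f"ectopic beat index {idx} out of range")
        rr[idx] *= 0.6

    fs = spec.fs
    lead_in = int(round(0.5 * fs))  # room for the first R-peak before the first foot
    beat_lens = np.maximum(3, np.round(rr * fs).astype(int))
    feet = lead_in + np.concatenate([[0], np.cumsum(beat_lens[:-1])])
    total = lead_in + int(np.sum(beat_lens)) + int(round(0.3 * fs))

    rapw = np.zeros(total)
    base_triplet = gt.triplet()
    beat_params = []
    for i in range(spec.n_beats):
        triplet = base_triplet
        if spec.shape_jitter_sd > 0:
            jit = lambda v: tuple(
                float(x * (1.0 + rng.normal(0.0, spec.shape_jitter_sd))) for x in v
            )
            c = tuple(sorted(jit(base_triplet.c)))
            triplet = GaussianTriplet(h=jit(base_triplet.h), w=jit(base_triplet.w), c=c)
        scaled = _scaled_params(triplet, beat_lens[i])
        episode = model_curve(scaled, n_samples=beat_lens[i])
        rapw[feet[i] : feet[i] + beat_lens[i]] = episode
        beat_params.append(triplet)

    t = np.arange(total) / fs
    if gt.baseline_amp != 0.0:
        rapw = rapw + gt.baseline_amp * np.sin(2 * np.pi * gt.baseline_freq * t)
    if gt.noise_sd > 0:
        rapw = rapw + rng.normal(0.0, gt.noise_sd, size=total)

    delay = int(round(R_TO_FOOT_DELAY_S * fs))
    r_peaks = feet - delay
    ecg = np.zeros(total)
    spike_half = int(round(0.01 * fs))
    spike_grid = np.arange(-spike_half, spike_half + 1)
    spike = np.exp(-(spike_grid**2) / (2.0 * (0.004 * fs) ** 2))
    for r in r_peaks:
        a, b = r - spike_half, r + spike_half + 1
        ecg[max(0, a) : b] += spike[max(0, a) - a :]

    record = RawRecord(ecg=ecg, rapw=rapw, fs=fs)
    return SyntheticTrain(
        record=record,
        r_peaks=r_peaks.astype(int),
        feet=feet.astype(int),
        rr_s=rr,
        beat_params=tuple(beat_params),
    )


# ---------------------------------------------------------------------------
# Cohort-level generation

SEX_LEVELS = ("men", "women")
SBP_CATEGORIES = ("<=110", "111-120", "121-130", ">=131")
#: Integer SBP range consistent with each category label (mmHg).
SBP_CATEGORY_RANGES = {
    "<=110": (90, 110),
    "111-120": (111, 120),
    "121-130": (121, 130),
    ">=131": (131, 160),
}
INDEX_COLUMNS = ("C1", "C2", "C_ref_forw", "H1", "H2", "H_ref_forw")


@dataclass(frozen=True)
class CohortCell:
    """One (sex × SBP-category) cell: size and per-variable mean/SD."""

    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("cell size must be >= 1")
        for k, sd in self.sds.items():
            if sd < 0:
                raise ParameterError(f"negative SD for {k}")


@dataclass(frozen=True)
class CohortSpec:
    """Map from (sex, sbp_category) to a :class:`CohortCell`, plus a seed."""

    cells: dict[tuple[str, str], CohortCell]
    seed: int = 0

    def __post_init__(self):
        for sex, cat in self.cells:
            if sex not in SEX_LEVELS or cat not in SBP_CATEGORIES:
                raise ParameterError(f"unknown cell label ({sex}, {cat})")


def _table_cells() -> dict[tuple[str, str], CohortCell]:
    """Default cohort parameterization: a 190-subject sex × SBP-category layout."""
    n = {"men": (22, 29, 33, 21), "women": (17, 25, 25, 18)}
    stats = {
        "SBP": {
            "men": ((104, 3), (115, 4), (126, 3), (135, 5)),
            "women": ((104, 4), (116, 3), (125, 3), (134, 3)),
        },
        "DBP": {
            "men": ((67, 8), (73, 7), (77, 6), (82, 7)),
            "women": ((66, 6), (72, 8), (75, 7), (80, 6)),
        },
        "C1": {
            "men": ((136, 11), (135, 12), (140, 11), (138, 12)),
            "women": ((142, 9), (135, 11), (137, 11), (134, 10)),
        },
        "C2": {
            "men": ((260, 16), (251, 12), (246, 13), (233, 14)),
            "women": ((265, 15), (256, 14), (248, 15), (235, 15)),
        },
        "C_ref_forw": {
            "men": ((124, 16), (116, 17), (106, 11), (95, 12)),
            "women": ((123, 15), (121, 18), (111, 17), (101, 15)),
        },
        "H1": {
            "men": ((0.73, 0.11), (0.70, 0.12), (0.66, 0.12), (0.61, 0.13)),
            "women": ((0.71, 0.12), (0.70, 0.12), (0.67, 0.13), (0.62, 0.10)),
        },
        "H2": {
            "men": ((0.67, 0.10), (0.71, 0.09), (0.73, 0.11), (0.77, 0.10)),
            "women": ((0.67, 0.11), (0.70, 0.11), (0.72, 0.09), (0.75, 0.11)),
        },
        "H_ref_forw": {
            "men": ((92, 16), (101, 17), (111, 18), (126, 20)),
            "women": ((94, 17), (100, 17), (107, 19), (121, 19)),
        },
    }
    cells = {}
    for sex in SEX_LEVELS:
        for j, cat in enumerate(SBP_CATEGORIES):
            means = {var: float(stats[var][sex][j][0]) for var in stats}
            sds = {var: float(stats[var][sex][j][1]) for var in stats}
            cells[(sex, cat)] = CohortCell(n=n[sex][j], means=means, sds=sds)
    return cells


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The reference 190-subject cohort parameterization."""
    return CohortSpec(cells=_table_cells(), seed=seed)


def null_cohort_spec(seed: int = 0) -> CohortSpec:
    """Same layout and cell sizes, but every cell identically distributed.

    Useful for type-I-error calibration of the ANOVA stage: under this
    cohort no factor has a true effect on any variable.
    """
    cells = _table_cells()
    pooled_means = {
        var: float(np.mean([c.means[var] for c in cells.values()]))
        for var in next(iter(cells.values())).means
    }
    pooled_sds = {
        var: float(np.mean([c.sds[var] for c in cells.values()]))
        for var in next(iter(cells.values())).sds
    }
    null_cells = {
        key: CohortCell(n=c.n, means=dict(pooled_means), sds=dict(pooled_sds))
        for key, c in cells.items()
    }
    return CohortSpec(cells=null_cells, seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-subject index values cell by cell.

    Each variable is drawn independently from a normal distribution with the
    cell's mean/SD.  Returns a tidy table with one row per subject:
    subject_id, sex, sbp_category, then one column per variable.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for (sex, cat), cell in spec.cells.items():
        for _ in range(cell.n):
            row = {"subject_id": f"S{sid:04d}", "sex": sex, "sbp_category": cat}
            for var, mu in cell.means.items():
                row[var] = mu + cell.sds[var] * rng.standard_normal()
            rows.append(row)
            sid += 1
    df = pd.DataFrame(rows)
    df["sex"] = pd.Categorical(df["sex"], categories=list(SEX_LEVELS))
    df["sbp_category"] = pd.Categorical(
        df["sbp_category"], categories=list(SBP_CATEGORIES), ordered=True
    )
    return df


# ---------------------------------------------------------------------------
# Waveform-level cohort (for end-to-end pipeline tests at reduced n)


@dataclass(frozen=True)
class WaveformSubject:
    """Ground truth for one simulated subject's recording."""

    subject_id: str
    sex: str
    sbp_category: str
    sbp: float
    dbp: float
    gt: PulseGroundTruth
    train: TrainSpec


def generate_waveform_cohort(
    n_subjects: int,
    seed: int = 0,
    n_beats: int = 14,
    noise_sd: float = 0.005,
    spec: CohortSpec | None = None,
) -> list[tuple[WaveformSubject, SyntheticTrain]]:
    """Simulate full recordings for a small cohort.

    Subjects are allocated round-robin over the (sex × category) cells of
    ``spec`` (default: the reference cohort).  Each subject's Gaussian
    ground truth is drawn from the cell distributions of C1/C2/H1/H2, with a
    late third sub-wave; the recording is a pulse train of ``n_beats``.
    Intended for end-to-end tests at reduced n — the index-level generator
    is the primary cohort source.
    """
    if spec is None:
        spec = default_cohort_spec(seed=seed)
    rng = np.random.default_rng(seed)
    keys = list(spec.cells.keys())
    out = []
    for i in range(n_subjects):
        sex, cat = keys[i % len(keys)]
        cell = spec.cells[(sex, cat)]
        draw = lambda var: cell.means[var] + cell.sds[var] * rng.standard_normal()
        c1 = float(np.clip(draw("C1"), 60, 220))
        c2 = float(np.clip(draw("C2"), c1 + 40, 600))
        c3 = float(np.clip(c2 + rng.normal(190, 20), c2 + 60, 900))
        h1 = float(np.clip(draw("H1"), 0.2, 1.0))
        h2 = float(np.clip(draw("H2"), 0.2, 1.0))
        h3 = float(np.clip(rng.normal(0.30, 0.04), 0.1, 0.6))
        gt = PulseGroundTruth(
            h=(h1, h2, h3),
            w=(55.0, 85.0, 200.0),
            c=(c1, c2, c3),
            noise_sd=noise_sd,
            baseline_amp=0.05,
        )
        lo, hi = SBP_CATEGORY_RANGES[cat]
        sbp = float(np.clip(np.floor(draw("SBP") + 0.5), lo, hi))
        dbp = float(np.clip(np.floor(draw("DBP") + 0.5), 40, sbp - 10))
        train = TrainSpec(
            n_beats=n_beats,
            mean_rr=float(rng.uniform(0.8, 1.0)),
            rr_jitter_sd=0.01,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subject = WaveformSubject(
            subject_id=f"S{i:04d}", sex=sex, sbp_category=cat, sbp=sbp, dbp=dbp, gt=gt, train=train
        )
        out.append((subject, generate_pulse_train(gt, train)))
    return out
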