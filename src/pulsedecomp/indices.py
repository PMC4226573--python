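"""Per-subject wave-reflection indices and blood-pressure summaries.

The first fitted Gaussian is read as the forward pressure component and the
second as the main reflected component.  Per subject, the base quantities
C1, C2 (peak positions, normalized-beat samples) and H1, H2 (peak heights)
are averaged over the selected episodes; two derived indices follow from the
averages:

* ``C_ref_forw = C2 - C1`` — timing of the reflection relative to the
  forward wave, in samples on the 1000-sample normalized beat axis;
* ``H_ref_forw = 100 * H2 / H1`` — reflection amplitude relative to the
  forward wave, in percent (ratio of averaged heights, not the average of
  per-episode ratios).

Blood-pressure summaries use the classic formulas MAP = DBP + (SBP - DBP)/3
and PP = SBP - DBP, with SBP/DBP the mean of two auscultatory readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InputError
from .gaussfit import FitResult


@dataclass(frozen=True)
class SubjectIndices:
    """Episode-averaged evaluation indices for one subject."""

    C1: float
    C2: float
    H1: float
    H2: float
    C_ref_forw: float
    H_ref_forw: float
    n_episodes: int


@dataclass(frozen=True)
class PressureSummary:
    """Summary blood pressures (mmHg)."""

    SBP: float
    DBP: float
    MAP: float
    PP: float


def compute_indices(fits: Sequence[FitResult | None]) -> SubjectIndices:
    """Average the first/second-Gaussian features over episodes.

    ``None`` entries (failed episode fits) are skipped.  Derived indices are
    computed from the averaged base quantities.
    """
    usable = [f for f in fits if f is not None]
    if not usable:
        raise InputError("no usable fits to average")
    n = len(usable)
    c1 = sum(f.params.c[0] for f in usable) / n
    c2 = sum(f.params.c[1] for f in usable) / n
    h1 = sum(f.params.h[0] for f in usable) / n
    h2 = sum(f.params.h[1] for f in usable) / n
    return SubjectIndices(
        C1=c1,
        C2=c2,
        H1=h1,
        H2=h2,
        C_ref_forw=c2 - c1,
        H_ref_forw=100.0 * h2 / h1,
        n_episodes=n,
    )


def compute_pressures(
    sbp_readings: Sequence[float], dbp_readings: Sequence[float]
) -> PressureSummary:
    """Combine paired auscultatory readings into SBP/DBP/MAP/PP.

    Readings are taken at the start and end of the recording; each SBP
    reading must exceed its paired DBP reading.
    """
    if len(sbp_readings) != len(dbp_readings) or len(sbp_readings) == 0:
        raise InputError("need equally many (>= 1) SBP and DBP readings")
    for s, d in zip(sbp_readings, dbp_readings):
        if s <= d:
            raise InputError(f"SBP reading {s} must exceed paired DBP reading {d}")
    sbp = sum(sbp_readings) / len(sbp_readings)
    dbp = sum(dbp_readings) / len(dbp_readings)
    return PressureSummary(SBP=sbp, DBP=dbp, MAP=dbp + (sbp - dbp) / 3.0, PP=sbp - dbp)
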