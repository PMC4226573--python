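"""CSV/JSON readers and writers tying the pipeline stages together.

Formats (all plain text):

* raw record — two-column CSV ``ecg,rapw`` with a JSON sidecar holding the
  sampling rate and any ground-truth annotations;
* beat annotations — CSV ``beat_index,r_peak,foot,ectopic_flag``;
* episodes — long CSV ``episode_id,sample_idx,value`` (episodes have
  variable length before width normalization);
* normalized episodes — wide CSV, one row per episode with 1000 sample
  columns;
* fit results — CSV ``episode_id,H1..H3,W1..W3,C1..C3,sse,rmse,converged``;
* cohort / index tables — tidy CSV, one row per subject.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .gaussfit import FitResult, GaussianTriplet, model_curve
from .normalization import NormalizedPulse
from .preprocessing import BeatAnnotations, RawRecord
from .synthetic import SBP_CATEGORIES, SEX_LEVELS


def write_record(record: RawRecord, path: str | Path, extra: dict | None = None) -> Path:
    path = Path(path)
    pd.DataFrame({"ecg": record.ecg, "rapw": record.rapw}).to_csv(path, index=False)
    sidecar = {"fs": record.fs}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, default=_jsonable))
    return path


def read_record(path: str | Path, fs: float | None = None) -> RawRecord:
    path = Path(path)
    if not path.exists():
        raise InputError(f"record file not found: {path}")
    df = pd.read_csv(path)
    if not {"ecg", "rapw"} <= set(df.columns):
        raise InputError(f"{path} lacks 'ecg'/'rapw' columns")
    if fs is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise InputError(f"no sampling rate given and no sidecar at {sidecar}")
        fs = float(json.loads(sidecar.read_text())["fs"])
    return RawRecord(ecg=df["ecg"].to_numpy(), rapw=df["rapw"].to_numpy(), fs=fs)


def write_annotations(ann: BeatAnnotations, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "beat_index": np.arange(len(ann.r_peaks)),
            "r_peak": ann.r_peaks,
            "foot": ann.feet,
            "ectopic_flag": ann.ectopic_mask.astype(int),
        }
    ).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> BeatAnnotations:
    df = pd.read_csv(path)
    return BeatAnnotations(
        r_peaks=df["r_peak"].to_numpy(),
        feet=df["foot"].to_numpy(),
        ectopic_mask=df["ectopic_flag"].to_numpy().astype(bool),
    )


def write_episodes(episodes: Sequence[np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"episode_id": i, "sample_idx": np.arange(len(ep)), "value": np.asarray(ep)}
        )
        for i, ep in enumerate(episodes)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_episodes(path: str | Path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    return [
        g.sort_values("sample_idx")["value"].to_numpy()
        for _, g in df.groupby("episode_id", sort=True)
    ]


def write_normalized(pulses: Sequence[NormalizedPulse], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for i, p in enumerate(pulses):
        row = {"episode_id": i, "source_len": p.source_len}
        row.update({f"s{j:04d}": v for j, v in enumerate(p.samples)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_normalized(path: str | Path) -> list[NormalizedPulse]:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    cols.sort()
    out = []
    for _, row in df.iterrows():
        samples = row[cols].to_numpy(dtype=float)
        out.append(
            NormalizedPulse(
                samples=samples,
                source_len=int(row["source_len"]),
                source_range=(float(samples.min()), float(samples.max())),
            )
        )
    return out


def fits_to_frame(fits: Sequence[FitResult | None]) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fits):
        if f is None:
            continue
        h, w, c = f.params.h, f.params.w, f.params.c
        rows.append(
            {
                "episode_id": i,
                "H1": h[0], "H2": h[1], "H3": h[2],
                "W1": w[0], "W2": w[1], "W3": w[2],
                "C1": c[0], "C2": c[1], "C3": c[2],
                "sse": f.objective_value,
                "rmse": f.rmse,
                "converged": int(f.converged),
            }
        )
    return pd.DataFrame(rows)


def write_fits(fits: Sequence[FitResult | None], path: str | Path) -> Path:
    path = Path(path)
    fits_to_frame(fits).to_csv(path, index=False)
    return path


def read_fits(path: str | Path) -> list[FitResult]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        params = GaussianTriplet(
            h=(r["H1"], r["H2"], r["H3"]),
            w=(r["W1"], r["W2"], r["W3"]),
            c=(r["C1"], r["C2"], r["C3"]),
        )
        curve = model_curve(params)
        out.append(
            FitResult(
                params=params,
                objective_value=float(r["sse"]),
                fitted_curve=curve,
                n_evaluations=0,
                converged=bool(r["converged"]),
                rmse=float(r["rmse"]),
            )
        )
    return out


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    if "sex" in df.columns:
        df["sex"] = pd.Categorical(df["sex"], categories=list(SEX_LEVELS))
    if "sbp_category" in df.columns:
        df["sbp_category"] = pd.Categorical(
            df["sbp_category"], categories=list(SBP_CATEGORIES), ordered=True
        )
    return df


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_jsonable))
    return path
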