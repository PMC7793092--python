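"""CSV record formats, run configuration, and output plumbing.

A cohort lives in one directory:

* ``epochs.csv`` — columns ``subject, epoch, t_start_s, activity_count,
  spo2_coverage_s, psg_stage`` (stage NA when unscored); epoch 0 starts at
  t = 0 and timestamps are half-open ``[t, t+30)``.
* ``rr.csv`` — columns ``subject, beat_time_s, rr_ms``; each row is the
  interval terminated by that beat.
* ``meta.json`` — per-subject lights-off seconds and seeds, plus the hash
  of the configuration that produced the cohort.

Malformed rows are reported with their line numbers; reading back a written
cohort reproduces it field-by-field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import EpochGrid, RRSeries, SubjectRecord
from .stages import EPOCH_LEN_S, STAGES5, StageSequence

EPOCH_COLUMNS = ["subject", "epoch", "t_start_s", "activity_count", "spo2_coverage_s", "psg_stage"]
RR_COLUMNS = ["subject", "beat_time_s", "rr_ms"]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_cohort(records: list[SubjectRecord], outdir, config: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ep_frames, rr_frames, meta = [], [], {"subjects": {}}
    for rec in records:
        g = rec.grid
        stages = (
            [str(s) for s in g.stages.labels] if g.stages is not None else ["NA"] * g.n_epochs
        )
        ep_frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject,
                    "epoch": np.arange(g.n_epochs),
                    "t_start_s": g.t_start,
                    "activity_count": g.activity,
                    "spo2_coverage_s": g.spo2_coverage,
                    "psg_stage": stages,
                }
            )
        )
        rr_frames.append(
            pd.DataFrame(
                {"subject": rec.subject, "beat_time_s": rec.rr.beat_times, "rr_ms": rec.rr.intervals}
            )
        )
        meta["subjects"][rec.subject] = {"lights_off_s": rec.lights_off_s, **rec.meta}
    if config is not None:
        meta["config"] = config
        meta["config_hash"] = config_hash(config)
    pd.concat(ep_frames).to_csv(outdir / "epochs.csv", index=False)
    pd.concat(rr_frames).to_csv(outdir / "rr.csv", index=False)
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1, default=str))


def _fail_rows(mask: np.ndarray, offset: int, message: str):
    if np.any(mask):
        # +2: header line plus 1-based numbering
        lines = (np.nonzero(mask)[0] + offset + 2).tolist()[:10]
        raise ValueError(f"{message} (line(s) {lines})")


def read_cohort(indir) -> list[SubjectRecord]:
    """Read a cohort directory back into :class:`SubjectRecord` objects."""
    indir = Path(indir)
    epochs = pd.read_csv(indir / "epochs.csv")
    rr = pd.read_csv(indir / "rr.csv")
    for col in EPOCH_COLUMNS:
        if col not in epochs.columns:
            raise ValueError(f"epochs.csv missing required column {col!r}")
    for col in RR_COLUMNS:
        if col not in rr.columns:
            raise ValueError(f"rr.csv missing required column {col!r}")
    meta_path = indir / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {"subjects": {}}
    records = []
    for subject, ep in epochs.groupby("subject", sort=False):
        off = int(ep.index[0])
        _fail_rows(ep["activity_count"].to_numpy() < 0, off, f"negative activity count for {subject}")
        _fail_rows(
            (ep["spo2_coverage_s"].to_numpy() < 0) | (ep["spo2_coverage_s"].to_numpy() > EPOCH_LEN_S),
            off, f"SpO2 coverage outside [0, 30] s for {subject}",
        )
        expected_t = ep["epoch"].to_numpy() * EPOCH_LEN_S
        _fail_rows(
            np.abs(ep["t_start_s"].to_numpy() - expected_t) > 1e-6,
            off, f"epoch timestamps off the 30-s grid for {subject}",
        )
        stage_vals = ep["psg_stage"].astype(str).to_numpy()
        stages = None
        if not np.all(stage_vals == "NA"):
            bad = ~np.isin(stage_vals, STAGES5)
            _fail_rows(bad, off, f"unknown stage label for {subject}")
            stages = StageSequence(stage_vals.astype(object))
        sub_rr = rr[rr["subject"] == subject]
        if sub_rr.empty:
            raise ValueError(f"no RR rows for subject {subject}")
        bt = sub_rr["beat_time_s"].to_numpy(dtype=float)
        off_rr = int(sub_rr.index[0])
        _fail_rows(np.concatenate([[False], np.diff(bt) <= 0]), off_rr,
                   f"non-monotone beat times for {subject}")
        _fail_rows(sub_rr["rr_ms"].to_numpy(dtype=float) <= 0, off_rr,
                   f"non-positive RR interval for {subject}")
        n_epochs = len(ep)
        if bt[0] > n_epochs * EPOCH_LEN_S:
            raise ValueError(f"epochs/RR time-base mismatch for {subject}")
        grid = EpochGrid(
            activity=ep["activity_count"].to_numpy(dtype=float),
            spo2_coverage=ep["spo2_coverage_s"].to_numpy(dtype=float),
            stages=stages,
        )
        sub_meta = dict(meta.get("subjects", {}).get(subject, {}))
        lights_off = float(sub_meta.pop("lights_off_s", 0.0))
        records.append(
            SubjectRecord(
                subject=str(subject),
                grid=grid,
                rr=RRSeries(bt, sub_rr["rr_ms"].to_numpy(dtype=float)),
                lights_off_s=lights_off,
                meta=sub_meta,
            )
        )
    return records


def write_features(features: pd.DataFrame, subject: str, path) -> None:
    """Features CSV: epoch index plus the 17 named metric columns."""
    out = features.reset_index()
    out.insert(0, "subject", subject)
    out.to_csv(path, index=False)


def write_parameters(rows: list[dict], path) -> None:
    """Parameters CSV, one row per subject per scorer."""
    cols = ["subject", "scorer", "SPT", "TST", "SE", "SOL", "WASO", "REM", "NREM"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def write_predictions(pred: dict[str, np.ndarray], path) -> None:
    """Predicted hypnograms CSV: subject, epoch, stage."""
    frames = [
        pd.DataFrame({"subject": s, "epoch": np.arange(len(lab)), "stage": lab})
        for s, lab in pred.items()
    ]
    pd.concat(frames).to_csv(path, index=False)


def read_predictions(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        str(s): g.sort_values("epoch")["stage"].to_numpy(dtype=object)
        for s, g in df.groupby("subject", sort=False)
    }
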