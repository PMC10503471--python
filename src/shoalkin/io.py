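"""Readers, writers, metadata and configuration for the shoaling pipeline.

All on-disk formats are plain delimited text with a one-line header:

* midline file: ``trial_id, fish_id, frame, time_s, point_index, x_mm, y_mm``
  (point_index 0..n-1 head -> tail);
* trajectory file: ``trial_id, fish_id, time_s, x_mm, y_mm``;
* oxygen file: ``trial_id, time_s, phase, o2_mg_per_l, temp_c``;
* trial metadata: one row per shoal with recorded temperature as a
  "mean ± sd" string;
* truth manifest and run manifest: JSON.

Trial identifiers for per-speed recordings are ``<shoal_id>@<speed>``.
Coordinates are stored in mm; BL normalization happens at computation time,
never at storage time.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .kinematics import MidlineSequence
from .respirometry import OxygenTrace
from .shoal import ShoalTrajectory

__all__ = [
    "TrialMetadata",
    "PipelineConfig",
    "MetadataError",
    "load_metadata",
    "write_metadata",
    "parse_mean_sd",
    "trial_id",
    "split_trial_id",
    "write_midlines",
    "read_midlines",
    "write_trajectories",
    "read_trajectories",
    "write_oxygen",
    "read_oxygen",
    "write_truth",
    "read_truth",
    "write_manifest",
    "verify_manifest",
    "write_study_bundle",
    "read_study_bundle",
    "load_config",
]

STAGES = ("larva", "juvenile", "adult")


class MetadataError(ValueError):
    """Metadata file fails validation; the message names the offending row."""


# ---------------------------------------------------------------------------
# trial metadata
# ---------------------------------------------------------------------------

@dataclass
class TrialMetadata:
    """One shoal's design-level information."""

    shoal_id: str
    stage: str
    treatment_temp_c: float
    recorded_temp_mean_c: float
    recorded_temp_sd_c: float
    n_fish: int
    body_length_mm: float
    speeds_bl_s: tuple[float, ...]
    mass_g: float | None = None


_MEAN_SD_RE = re.compile(
    r"^\s*([-+]?\d+(?:\.\d+)?)\s*(?:±|\+/-|\+-)\s*(\d+(?:\.\d+)?)\s*$"
)


def parse_mean_sd(text: str) -> tuple[float, float]:
    """Parse a ``"32.0 ± 0.7"`` style string into (mean, sd)."""
    s = str(text).strip()
    m = _MEAN_SD_RE.match(s)
    if m:
        return float(m.group(1)), float(m.group(2))
    try:
        return float(s), 0.0
    except ValueError:
        raise MetadataError(f"cannot parse mean ± sd value {text!r}") from None


REQUIRED_META_COLUMNS = (
    "shoal_id",
    "stage",
    "treatment_temp_c",
    "recorded_temp_c",
    "n_fish",
    "body_length_mm",
    "speeds_bl_s",
)


def load_metadata(path) -> list[TrialMetadata]:
    """Load and validate the trial metadata table.

    Rows whose recorded temperature field is '–' (an absent shoal) are
    dropped, not zero-filled.  Unknown stage labels or missing columns raise
    a :class:`MetadataError` naming the row.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty and df.columns.size == 0:
        raise MetadataError(
            "empty metadata file; required columns: " + ", ".join(REQUIRED_META_COLUMNS)
        )
    missing = set(REQUIRED_META_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(
            "metadata lacks required columns: " + ", ".join(sorted(missing))
        )
    records: list[TrialMetadata] = []
    seen = set()
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        rec_temp = str(row["recorded_temp_c"]).strip()
        if rec_temp in ("–", "-", "", "nan"):
            continue  # shoal absent from the study
        stage = str(row["stage"]).strip()
        if stage not in STAGES:
            raise MetadataError(f"row {rowno}: unknown stage label {stage!r}")
        shoal_id = str(row["shoal_id"]).strip()
        if not shoal_id or shoal_id == "nan":
            raise MetadataError(f"row {rowno}: missing shoal_id")
        if shoal_id in seen:
            raise MetadataError(f"row {rowno}: duplicate shoal_id {shoal_id!r}")
        seen.add(shoal_id)
        try:
            mean, sd = parse_mean_sd(rec_temp)
            speeds = tuple(
                float(v) for v in str(row["speeds_bl_s"]).split(";") if v.strip()
            )
            mass = row.get("mass_g")
            mass_val = (
                float(mass) if mass is not None and str(mass) not in ("", "nan") else None
            )
            records.append(
                TrialMetadata(
                    shoal_id=shoal_id,
                    stage=stage,
                    treatment_temp_c=float(row["treatment_temp_c"]),
                    recorded_temp_mean_c=mean,
                    recorded_temp_sd_c=sd,
                    n_fish=int(float(row["n_fish"])),
                    body_length_mm=float(row["body_length_mm"]),
                    speeds_bl_s=speeds,
                    mass_g=mass_val,
                )
            )
        except MetadataError:
            raise
        except (TypeError, ValueError) as exc:
            raise MetadataError(f"row {rowno}: {exc}") from exc
    return records


def write_metadata(records, path) -> None:
    rows = []
    for r in records:
        if isinstance(r, TrialMetadata):
            rows.append(
                {
                    "shoal_id": r.shoal_id,
                    "stage": r.stage,
                    "treatment_temp_c": r.treatment_temp_c,
                    "recorded_temp_c": f"{r.recorded_temp_mean_c:.1f} ± {r.recorded_temp_sd_c:.1f}",
                    "n_fish": r.n_fish,
                    "body_length_mm": r.body_length_mm,
                    "mass_g": r.mass_g if r.mass_g is not None else "",
                    "speeds_bl_s": ";".join(str(v) for v in r.speeds_bl_s),
                }
            )
        else:
            rows.append(dict(r))
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trial ids
# ---------------------------------------------------------------------------

def trial_id(shoal_id: str, speed: float) -> str:
    return f"{shoal_id}@{speed}"


def split_trial_id(tid: str) -> tuple[str, float]:
    shoal, _, speed = tid.rpartition("@")
    if not shoal:
        raise ValueError(f"trial id {tid!r} is not of the form shoal@speed")
    return shoal, float(speed)


# ---------------------------------------------------------------------------
# midlines
# ---------------------------------------------------------------------------

def write_midlines(seqs: Mapping[str, Mapping[str, MidlineSequence]], path) -> None:
    """Write trials of midline sequences to one flat delimited file."""
    parts = []
    for tid, per_fish in seqs.items():
        for fid, seq in per_fish.items():
            nf, npt = seq.coords.shape[:2]
            parts.append(
                pd.DataFrame(
                    {
                        "trial_id": np.repeat(tid, nf * npt),
                        "fish_id": np.repeat(fid, nf * npt),
                        "frame": np.repeat(np.arange(nf), npt),
                        "time_s": np.repeat(seq.times, npt),
                        "point_index": np.tile(np.arange(npt), nf),
                        "x_mm": seq.coords[:, :, 0].ravel(),
                        "y_mm": seq.coords[:, :, 1].ravel(),
                    }
                )
            )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_midlines(
    path, body_lengths_mm, frame_rate: float | None = None
) -> dict[str, dict[str, MidlineSequence]]:
    """Read a midline file back into sequences.

    ``body_lengths_mm`` is a scalar or a mapping keyed by trial id (or by
    the shoal part of the trial id).  Frame rate is inferred from the time
    stamps when not given.
    """
    df = pd.read_csv(path)
    out: dict[str, dict[str, MidlineSequence]] = {}
    for (tid, fid), grp in df.groupby(["trial_id", "fish_id"], sort=False):
        grp = grp.sort_values(["frame", "point_index"])
        frames = grp["frame"].unique()
        npt = grp["point_index"].nunique()
        coords = grp[["x_mm", "y_mm"]].to_numpy().reshape(len(frames), npt, 2)
        times = grp.drop_duplicates("frame")["time_s"].to_numpy()
        fr = frame_rate or 1.0 / float(np.median(np.diff(times)))
        if np.isscalar(body_lengths_mm):
            bl = float(body_lengths_mm)
        else:
            key = tid if tid in body_lengths_mm else split_trial_id(tid)[0]
            bl = float(body_lengths_mm[key])
        out.setdefault(tid, {})[fid] = MidlineSequence(
            fish_id=str(fid), times=times, coords=coords, body_length_mm=bl, frame_rate=fr
        )
    return out


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectories(trajs: Mapping[str, ShoalTrajectory], path) -> None:
    parts = []
    for tid, traj in trajs.items():
        nf = traj.times.size
        for i in range(traj.n_fish):
            parts.append(
                pd.DataFrame(
                    {
                        "trial_id": np.repeat(tid, nf),
                        "fish_id": np.repeat(f"f{i + 1}", nf),
                        "time_s": traj.times,
                        "x_mm": traj.positions[:, i, 0],
                        "y_mm": traj.positions[:, i, 1],
                    }
                )
            )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path, body_lengths_mm) -> dict[str, ShoalTrajectory]:
    df = pd.read_csv(path)
    out: dict[str, ShoalTrajectory] = {}
    for tid, grp in df.groupby("trial_id", sort=False):
        fish = sorted(grp["fish_id"].unique())
        times = np.sort(grp["time_s"].unique())
        pos = np.empty((times.size, len(fish), 2))
        for j, fid in enumerate(fish):
            sub = grp[grp["fish_id"] == fid].sort_values("time_s")
            pos[:, j, 0] = sub["x_mm"].to_numpy()
            pos[:, j, 1] = sub["y_mm"].to_numpy()
        if np.isscalar(body_lengths_mm):
            bl = float(body_lengths_mm)
        else:
            key = tid if tid in body_lengths_mm else split_trial_id(tid)[0]
            bl = float(body_lengths_mm[key])
        out[tid] = ShoalTrajectory(
            times=times, positions=pos, body_lengths_mm=np.full(len(fish), bl)
        )
    return out


# ---------------------------------------------------------------------------
# oxygen traces
# ---------------------------------------------------------------------------

def write_oxygen(traces: Mapping[str, OxygenTrace], path) -> None:
    parts = []
    for tid, tr in traces.items():
        parts.append(
            pd.DataFrame(
                {
                    "trial_id": tid,
                    "time_s": tr.times_s,
                    "phase": tr.phase,
                    "o2_mg_per_l": tr.o2_mg_per_l,
                    "temp_c": tr.temperature_c,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_oxygen(path) -> dict[str, OxygenTrace]:
    df = pd.read_csv(path)
    out = {}
    for tid, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("time_s")
        out[tid] = OxygenTrace(
            times_s=grp["time_s"].to_numpy(),
            o2_mg_per_l=grp["o2_mg_per_l"].to_numpy(),
            phase=grp["phase"].to_numpy(dtype=object),
            temperature_c=float(grp["temp_c"].iloc[0]),
            shoal_id=str(tid),
        )
    return out


# ---------------------------------------------------------------------------
# truth and run manifests
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True, default=_jsonable))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, extra: dict | None = None, name: str = "run_manifest.json") -> Path:
    """Write a manifest listing every output file with its content hash."""
    outdir = Path(outdir)
    files = {}
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != name:
            files[p.name] = sha256_of(p)
    manifest = {"files": files}
    if extra:
        manifest.update(extra)
    path = outdir / name
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=_jsonable))
    return path


def verify_manifest(outdir, name: str = "run_manifest.json") -> bool:
    outdir = Path(outdir)
    manifest = json.loads((outdir / name).read_text())
    return all(
        sha256_of(outdir / fname) == digest for fname, digest in manifest["files"].items()
    )


# ---------------------------------------------------------------------------
# study bundles
# ---------------------------------------------------------------------------

def write_study_bundle(bundle, outdir) -> None:
    """Write a synthetic study bundle as raw-data files plus manifests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.metadata.to_csv(outdir / "metadata.csv", index=False)
    write_midlines(
        {trial_id(sid, sp): seqs for (sid, sp), seqs in bundle.midlines.items()},
        outdir / "midlines.csv",
    )
    write_trajectories(
        {trial_id(sid, sp): tr for (sid, sp), tr in bundle.trajectories.items()},
        outdir / "trajectories.csv",
    )
    write_oxygen(bundle.oxygen, outdir / "oxygen.csv")
    write_truth(bundle.truth, outdir / "truth.json")


def read_study_bundle(indir):
    """Read a written study bundle back into memory."""
    from .synthetic import StudyBundle  # deferred to avoid an import cycle

    indir = Path(indir)
    meta_records = load_metadata(indir / "metadata.csv")
    meta_df = pd.read_csv(indir / "metadata.csv")
    bls = {r.shoal_id: r.body_length_mm for r in meta_records}
    midlines = {
        split_trial_id(tid): seqs
        for tid, seqs in read_midlines(indir / "midlines.csv", bls).items()
    }
    trajectories = {
        split_trial_id(tid): tr
        for tid, tr in read_trajectories(indir / "trajectories.csv", bls).items()
    }
    oxygen = read_oxygen(indir / "oxygen.csv")
    for tid, tr in oxygen.items():
        rec = next((r for r in meta_records if r.shoal_id == tid), None)
        if rec is not None:
            tr.stage = rec.stage
    truth_path = indir / "truth.json"
    truth = read_truth(truth_path) if truth_path.exists() else {}
    return StudyBundle(
        metadata=meta_df,
        midlines=midlines,
        trajectories=trajectories,
        oxygen=oxygen,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults equal the module defaults."""

    mode: str = "synthetic"  # or "provided"
    input_dir: str | None = None
    output_dir: str = "shoalkin_run"
    seed: int = 0
    design: str = "default"  # synthetic mode: "default" or "zero_effect"
    write_raw: bool = False
    min_cycles: int = 1
    sample_hz: float = 10.0
    hysteresis_bl: float = 0.05
    rest_window_min: float = 30.0
    peak_window_min: float = 3.0
    m_permutations: int = 4999
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration; absent keys take their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
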