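"""One-command pipeline: simulate -> kinematics -> shoal -> respo -> stats.

``run_pipeline`` executes the whole analysis and writes tidy per-shoal
metric tables, a per-stage Q10 table, a permutation-ANOVA results table,
plain-text summary lines for the headline ontogeny/warming contrasts, and a
run manifest with content hashes so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from . import kinematics as kin
from . import respirometry as resp
from . import shoal as shoalmod
from . import synthetic
from .io import PipelineConfig
from .permstats import FactorialDataset, permutation_anova, within_speed_sweep

__all__ = [
    "kinematics_table",
    "shoal_table",
    "metabolic_table",
    "stats_tables",
    "analyze_study",
    "run_pipeline",
]

log = logging.getLogger(__name__)

KINEMATIC_VARS = [
    "tbf_hz",
    "head_amp_bl",
    "tail_amp_bl",
    "head_tail_ratio",
    "wave_speed_bl_s",
    "wavelength_bl",
    "max_curvature_per_bl",
]
SHOAL_VARS = ["mean_sep_bl", "switch_rate_per_s"]


def _meta_lookup(metadata: pd.DataFrame) -> dict[str, dict]:
    out = {}
    for _, row in metadata.iterrows():
        mean, sd = skio.parse_mean_sd(row["recorded_temp_c"])
        out[str(row["shoal_id"])] = {
            "stage": row["stage"],
            "treatment_temp_c": float(row["treatment_temp_c"]),
            "recorded_temp_c": mean,
        }
    return out


def kinematics_table(bundle, min_cycles: int = 1) -> pd.DataFrame:
    """One row of averaged kinematics per (shoal, speed).

    Each fish's sequences are analyzed independently; fish without at least
    ``min_cycles`` complete tail-beat cycles are excluded with a logged
    count, and the remaining fish are averaged to a single shoal record.
    """
    meta = _meta_lookup(bundle.metadata)
    rows = []
    n_excluded = 0
    for (shoal_id, speed), per_fish in sorted(bundle.midlines.items()):
        records = {}
        for fid, seqs in per_fish.items():
            seq_list = seqs if isinstance(seqs, (list, tuple)) else [seqs]
            recs = []
            for seq in seq_list:
                r = kin.analyze_sequence(seq)
                if r is None or r.n_cycles_used < min_cycles:
                    n_excluded += 1
                    continue
                recs.append(r)
            if recs:
                records[fid] = recs
        if not records:
            log.warning("no usable fish for shoal %s at %s BL/s", shoal_id, speed)
            continue
        summary, counts = kin.summarize_shoal(records)
        row = {"shoal_id": shoal_id, "speed_bl_s": speed, **meta[shoal_id]}
        row.update(summary.as_dict())
        row["n_fish_used"] = counts["tbf_hz"]
        rows.append(row)
    if n_excluded:
        log.warning("excluded %d fish sequences with no complete cycle", n_excluded)
    return pd.DataFrame(rows)


def shoal_table(bundle, sample_hz: float = 10.0, hysteresis_bl: float = 0.05) -> pd.DataFrame:
    """Mean separation and switch rate per (shoal, speed)."""
    meta = _meta_lookup(bundle.metadata)
    rows = []
    for (shoal_id, speed), traj in sorted(bundle.trajectories.items()):
        rows.append(
            {
                "shoal_id": shoal_id,
                "speed_bl_s": speed,
                **meta[shoal_id],
                "mean_sep_bl": shoalmod.mean_separation_distance(traj),
                "switch_rate_per_s": shoalmod.position_switch_rate(
                    traj, sample_hz=sample_hz, hysteresis_bl=hysteresis_bl
                ),
                "duration_s": float(traj.times[-1] - traj.times[0]),
                "n_frames": int(traj.times.size),
            }
        )
    return pd.DataFrame(rows)


def metabolic_table(
    bundle, rest_window_min: float = 30.0, peak_window_min: float = 3.0
) -> pd.DataFrame:
    """Resting, peak and factorial MO2 per shoal."""
    meta = _meta_lookup(bundle.metadata)
    rows = []
    for shoal_id, trace in sorted(bundle.oxygen.items()):
        rec = resp.analyze_trace(trace, rest_window_min, peak_window_min)
        rows.append(
            {
                "shoal_id": shoal_id,
                **meta[shoal_id],
                "mo2_rest": rec.mo2_rest,
                "mo2_peak": rec.mo2_peak,
                "factorial_mo2": rec.factorial_mo2,
                "rest_r2": rec.rest_fit.r_squared if rec.rest_fit else np.nan,
                "peak_r2": rec.peak_fit.r_squared if rec.peak_fit else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["temperature_c"] = df["treatment_temp_c"]
    return df


def stats_tables(
    kin_df: pd.DataFrame,
    shoal_df: pd.DataFrame,
    metab_df: pd.DataFrame,
    m_permutations: int = 4999,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """All study-level hypothesis tests.

    * Kinematic and behavioral variables: two-way (stage x temperature)
      permutation ANOVA within each speed.
    * Factorial MO2: two-way permutation ANOVA across stages x temperature.
    * Resting and peak MO2: one-way permutation ANOVA between temperatures
      within each stage (rates are not mass-adjusted, so stages are never
      compared directly on raw rates).
    """
    merged = pd.merge(
        kin_df,
        shoal_df[["shoal_id", "speed_bl_s"] + SHOAL_VARS],
        on=["shoal_id", "speed_bl_s"],
        how="outer",
    )
    sweep = within_speed_sweep(
        merged,
        [v for v in KINEMATIC_VARS + SHOAL_VARS if v in merged.columns],
        m_permutations=m_permutations,
        seed=seed,
        alpha=alpha,
    )
    rows = []
    ds = FactorialDataset(
        y=metab_df["factorial_mo2"].to_numpy(),
        a=metab_df["stage"].to_numpy(),
        b=metab_df["treatment_temp_c"].to_numpy(),
    )
    res = permutation_anova(ds, "two_way_interaction", m_permutations, seed=seed + 1)
    for term, tr in res.terms.items():
        rows.append(
            {
                "variable": "factorial_mo2",
                "stage": "all",
                "term": term,
                "F": tr.f,
                "df": tr.df,
                "p_perm": tr.p,
                "m": res.m_permutations,
                "significant": bool(tr.p is not None and tr.p <= alpha),
            }
        )
    for i, (stage, grp) in enumerate(metab_df.groupby("stage", sort=False)):
        for var in ("mo2_rest", "mo2_peak"):
            ds = FactorialDataset(y=grp[var].to_numpy(), a=grp["treatment_temp_c"].to_numpy())
            res = permutation_anova(ds, "one_way", m_permutations, seed=seed + 100 + i)
            tr = res.terms["A"]
            rows.append(
                {
                    "variable": var,
                    "stage": stage,
                    "term": "temperature",
                    "F": tr.f,
                    "df": tr.df,
                    "p_perm": tr.p,
                    "m": res.m_permutations,
                    "significant": bool(tr.p is not None and tr.p <= alpha),
                }
            )
    return {"within_speed": sweep, "metabolic": pd.DataFrame(rows)}


def _summary_lines(
    kin_df: pd.DataFrame,
    shoal_df: pd.DataFrame,
    q10_df: pd.DataFrame,
    stats: dict[str, pd.DataFrame],
) -> list[str]:
    lines = []
    order = [s for s in ("larva", "juvenile", "adult") if s in set(shoal_df["stage"])]

    def stage_means(df, var):
        return {s: df[df["stage"] == s][var].mean() for s in order}

    sep = stage_means(shoal_df, "mean_sep_bl")
    sep_txt = " > ".join(f"{s} {sep[s]:.2f}" for s in order)
    dec = all(sep[a] > sep[b] for a, b in zip(order, order[1:]))
    lines.append(
        f"mean separation distance (BL) by stage: {sep_txt}"
        + (" [decreasing with ontogeny]" if dec else "")
    )
    tbf = stage_means(kin_df, "tbf_hz")
    tbf_txt = " > ".join(f"{s} {tbf[s]:.1f}" for s in order)
    dec = all(tbf[a] > tbf[b] for a, b in zip(order, order[1:]))
    lines.append(
        f"tail-beat frequency (Hz) by stage: {tbf_txt}"
        + (" [decreasing with ontogeny]" if dec else "")
    )
    sweep = stats["within_speed"]
    for var in ("mean_sep_bl", "tbf_hz"):
        sig = sweep[(sweep["variable"] == var) & (sweep["term"] == "A")]
        if len(sig):
            frac = sig["significant"].mean()
            lines.append(
                f"stage effect on {var}: significant at {int(frac * len(sig))}/{len(sig)} speeds"
            )
    for _, row in q10_df.iterrows():
        lines.append(
            f"Q10 {row['rate_type']} {row['stage']}: {row['q10']:.2f} "
            f"(K1={row['k1']:.3f}, K2={row['k2']:.3f})"
        )
    rest_q10 = {r["stage"]: r["q10"] for _, r in q10_df[q10_df["rate_type"] == "rest"].iterrows()}
    if "juvenile" in rest_q10 and rest_q10["juvenile"] > 2 * max(
        v for s, v in rest_q10.items() if s != "juvenile"
    ):
        lines.append("juvenile resting Q10 strongly elevated relative to larvae and adults")
    return lines


def analyze_study(bundle, config: PipelineConfig) -> dict:
    """Run every analysis stage on an in-memory study bundle."""
    log.info("kinematics: %d (shoal, speed) trials", len(bundle.midlines))
    kin_df = kinematics_table(bundle, min_cycles=config.min_cycles)
    log.info("shoal metrics: %d trajectories", len(bundle.trajectories))
    shoal_df = shoal_table(bundle, config.sample_hz, config.hysteresis_bl)
    log.info("respirometry: %d traces", len(bundle.oxygen))
    metab_df = metabolic_table(bundle, config.rest_window_min, config.peak_window_min)
    q10_df = resp.stage_q10_table(
        metab_df.rename(columns={"recorded_temp_c": "recorded_temp_c"})
    )
    stats = stats_tables(
        kin_df, shoal_df, metab_df, config.m_permutations, config.seed, config.alpha
    )
    summary = _summary_lines(kin_df, shoal_df, q10_df, stats)
    return {
        "kinematics": kin_df,
        "shoal_metrics": shoal_df,
        "metabolic_rates": metab_df,
        "q10": q10_df,
        "stats_within_speed": stats["within_speed"],
        "stats_metabolic": stats["metabolic"],
        "summary": summary,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline and write the run directory.

    Synthetic mode generates the study bundle from the named design;
    provided-data mode reads raw-data files from ``input_dir`` (aborting
    cleanly, with no partial outputs, when the directory lacks them).
    Returns the output directory path.  Deterministic given the seed.
    """
    outdir = Path(config.output_dir)
    if config.mode == "synthetic":
        design = (
            synthetic.zero_effect_design()
            if config.design == "zero_effect"
            else synthetic.default_study_design()
        )
        bundle = synthetic.generate_study(design, seed=config.seed)
    elif config.mode == "provided":
        if config.input_dir is None:
            raise ValueError("provided mode requires input_dir")
        indir = Path(config.input_dir)
        required = ["metadata.csv", "midlines.csv", "trajectories.csv", "oxygen.csv"]
        missing = [f for f in required if not (indir / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"input directory {indir} lacks required files: {missing}"
            )
        bundle = skio.read_study_bundle(indir)
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")

    results = analyze_study(bundle, config)

    outdir.mkdir(parents=True, exist_ok=True)
    for name in (
        "kinematics",
        "shoal_metrics",
        "metabolic_rates",
        "q10",
        "stats_within_speed",
        "stats_metabolic",
    ):
        results[name].to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "summary.txt").write_text("\n".join(results["summary"]) + "\n")
    if config.mode == "synthetic":
        skio.write_truth(bundle.truth, outdir / "truth.json")
        if config.write_raw:
            skio.write_study_bundle(bundle, outdir / "raw")
    skio.write_manifest(outdir, extra={"config": asdict(config)})
    return outdir
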