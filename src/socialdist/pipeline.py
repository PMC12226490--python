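"""End-to-end cohort analysis: sessions in, comparison report out.

Given a cohort of 2-mouse sessions (DeepLabCut CSVs with metadata
sidecars, or a simulation block), the pipeline runs likelihood filtering,
calibration, centroid kinematics, epoch-wise social distance, head/body/
tail symmetry, annotation QC and morphometry per session, then compares
the two groups with the pooled-null bootstrap test and reports
correlations of social distance with age and body size.

Statistical units follow the study design: the cage/session for social
distance and symmetry, the individual animal-video for locomotion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_qc, body_regions, kinematics, morphometry, resampling_stats
from .synthetic_data import SimConfig, simulate_session
from .trajectory_io import (
    ArenaCalibration,
    SessionMeta,
    apply_p_cutoff,
    read_dlc_csv,
    read_session_meta,
    to_mm,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "p_cutoff": 0.6,
    "epoch_length_s": 30.0,
    "bin_minutes": 20.0,
    "age_split_months": 3.5,
    "part_subset": "all",
    "n_boot": 10_000,
    "seed": 0,
}


@dataclass
class CohortReport:
    """Structured results of one cohort run."""

    session_table: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    time_binned: pd.DataFrame
    config: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.session_table.to_csv(out / "sessions.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.time_binned.to_csv(out / "time_binned.csv", index=False)
        (out / "config.json").write_text(json.dumps(self.config, indent=2, default=str))
        return out


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    cfg = {**DEFAULTS, **config}
    if not 0.0 <= cfg["p_cutoff"] <= 1.0:
        raise ValueError("config.p_cutoff must lie in [0, 1]")
    if "simulate" not in cfg and "sessions" not in cfg:
        raise ValueError("config must contain a 'simulate' block or a 'sessions' list")
    return cfg


def _gather_sessions(cfg: dict):
    """Yield (track_px, meta, area_mm2_per_animal) for every session."""
    out = []
    if "simulate" in cfg:
        sim = cfg["simulate"]
        rng = np.random.default_rng(cfg["seed"])
        for group_key, n_key in (("group_a", "n_pairs_a"), ("group_b", "n_pairs_b")):
            params = dict(sim.get(group_key, {}))
            strain = params.pop("strain", "BTBR" if group_key == "group_a" else "CBA")
            n_pairs = int(sim[n_key])
            for i in range(n_pairs):
                scfg = SimConfig(seed=int(rng.integers(0, 2**31 - 1)), **params)
                meta = SessionMeta(
                    session_id=f"{strain}-{i:03d}",
                    strain=strain,
                    sex="M" if i % 2 == 0 else "F",
                    age_months=float(np.round(rng.uniform(2.0, 8.0), 1)),
                )
                track, _truth = simulate_session(scfg, meta=meta)
                # Body-size stand-in: tapered-ellipse outline scaled off the
                # configured body length with mild per-animal variation.
                areas = []
                for _a in range(2):
                    scale = float(rng.normal(1.0, 0.05))
                    poly = morphometry.mouse_polygon(
                        length_px=scfg.body_length / scfg.mm_per_pixel * scale,
                        width_px=0.42 * scfg.body_length / scfg.mm_per_pixel * scale,
                    )
                    areas.append(morphometry.polygon_area(poly, track.calibration))
                out.append((track, meta, areas))
    else:
        missing = [s["csv"] for s in cfg["sessions"] if not Path(s["csv"]).exists()]
        missing += [s["meta"] for s in cfg["sessions"] if not Path(s["meta"]).exists()]
        if missing:
            raise FileNotFoundError(f"missing session files: {missing}")
        for s in cfg["sessions"]:
            meta, calibration = read_session_meta(s["meta"])
            track = read_dlc_csv(s["csv"], meta, calibration)
            areas = [np.nan, np.nan]
            if "polygons" in s:
                polys = morphometry.read_polygon_csv(s["polygons"], calibration)
                by_id = {p.animal_id: p.area_mm2 for p in polys}
                areas = [by_id.get(a, np.nan) for a in meta.animal_ids]
            out.append((track, meta, areas))
    return out


def _analyze_session(track_px, meta, areas, cfg: dict) -> tuple[dict, pd.DataFrame]:
    """Per-session metrics row plus its time-binned distance table."""
    filtered = to_mm(apply_p_cutoff(track_px, cfg["p_cutoff"]))
    c1, c2 = kinematics.compute_centroids(filtered, part_subset=cfg["part_subset"])
    epochs = kinematics.social_distance_epochs(
        c1, c2, epoch_length_s=cfg["epoch_length_s"], session_id=meta.session_id
    )
    loco = [kinematics.locomotion_rate(c) for c in (c1, c2)]
    regions = body_regions.reduce_to_hbt(filtered)
    hbt = body_regions.hbt_matrix(
        regions[:, 0], regions[:, 1], session_id=meta.session_id
    )
    dist = kinematics.frame_distances(c1, c2)
    qc = annotation_qc.rejection_vs_distance(filtered, dist)

    row = {
        "session_id": meta.session_id,
        "strain": meta.strain,
        "sex": meta.sex,
        "age_months": meta.age_months,
        "grand_mean_mm": epochs.grand_mean_mm,
        "grand_median_mm": epochs.grand_median_mm,
        "n_epochs": epochs.n_epochs,
        "loco_rate_1_mm_s": loco[0].rate_mm_s,
        "loco_rate_2_mm_s": loco[1].rate_mm_s,
        "symmetry_ratio": hbt.symmetry_ratio,
        "mean_rejected_per_frame": qc.mean_rejected_per_frame,
        "area_1_mm2": areas[0],
        "area_2_mm2": areas[1],
    }
    binned = kinematics.time_binned_distance(epochs, bin_minutes=cfg["bin_minutes"])
    binned.insert(0, "session_id", meta.session_id)
    binned.insert(1, "strain", meta.strain)
    return row, binned


def _compare(name, a, b, seed, n_boot, n_comparisons=None) -> dict | None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        logger.warning("comparison %s skipped: group too small (%d vs %d)", name, a.size, b.size)
        return None
    res = resampling_stats.bootstrap_t_test(
        a, b, n_boot=n_boot, seed=seed, n_comparisons=n_comparisons
    )
    sa = resampling_stats.group_summary(a, "A")
    sb = resampling_stats.group_summary(b, "B")
    return {
        "comparison": name,
        "mean_A": sa.mean,
        "sem_A": sa.sem,
        "mean_B": sb.mean,
        "sem_B": sb.sem,
        "delta_mu": res.delta_mu_observed,
        "p_value": res.p_value,
        "p_adjusted": res.p_adjusted,
        "n_A": res.n_A,
        "n_B": res.n_B,
        "n_boot": res.n_boot,
        "seed": res.seed,
    }


def age_sex_grouping(
    session_table: pd.DataFrame,
    split_months: float = 3.5,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Age-split and sex comparisons of grand mean social distance.

    Within each strain and pooled across strains, compares sessions
    younger-or-equal vs older than ``split_months`` (ties go to the
    younger group) and males vs females, each with the pooled-null
    bootstrap test.  Empty groups skip the comparison with a warning.
    """
    rows = []
    strains = list(dict.fromkeys(session_table["strain"])) + ["all"]
    for i, strain in enumerate(strains):
        sub = session_table if strain == "all" else session_table[session_table["strain"] == strain]
        young = sub.loc[sub["age_months"] <= split_months, "grand_mean_mm"]
        old = sub.loc[sub["age_months"] > split_months, "grand_mean_mm"]
        row = _compare(
            f"age<= {split_months} vs > ({strain})", young, old, seed + 100 + i, n_boot
        )
        if row:
            rows.append(row)
        males = sub.loc[sub["sex"] == "M", "grand_mean_mm"]
        females = sub.loc[sub["sex"] == "F", "grand_mean_mm"]
        row = _compare(f"male vs female ({strain})", males, females, seed + 200 + i, n_boot)
        if row:
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: str | Path | dict) -> CohortReport:
    """Run the full cohort analysis described by a YAML config or dict.

    Deterministic under the configured seed: rerunning with identical
    inputs reproduces the report bit for bit.
    """
    cfg = _load_config(config)
    sessions = _gather_sessions(cfg)

    rows, binned_tables = [], []
    for track, meta, areas in sessions:
        row, binned = _analyze_session(track, meta, areas, cfg)
        rows.append(row)
        binned_tables.append(binned)
    table = pd.DataFrame(rows)
    time_binned = pd.concat(binned_tables, ignore_index=True)

    strains = list(dict.fromkeys(table["strain"]))
    comparisons = []
    if len(strains) == 2:
        ga = table[table["strain"] == strains[0]]
        gb = table[table["strain"] == strains[1]]
        seed = int(cfg["seed"])
        n_boot = int(cfg["n_boot"])
        comparisons.append(
            _compare("grand_mean_distance", ga["grand_mean_mm"], gb["grand_mean_mm"], seed + 1, n_boot)
        )
        comparisons.append(
            _compare("grand_median_distance", ga["grand_median_mm"], gb["grand_median_mm"], seed + 2, n_boot)
        )
        loco_a = pd.concat([ga["loco_rate_1_mm_s"], ga["loco_rate_2_mm_s"]])
        loco_b = pd.concat([gb["loco_rate_1_mm_s"], gb["loco_rate_2_mm_s"]])
        comparisons.append(
            _compare("locomotion_rate", loco_a, loco_b, seed + 3, n_boot, n_comparisons=1)
        )
        comparisons.append(
            _compare("symmetry_ratio", ga["symmetry_ratio"], gb["symmetry_ratio"], seed + 4, n_boot)
        )
        comparisons.append(
            _compare(
                "mean_rejected_labels",
                ga["mean_rejected_per_frame"],
                gb["mean_rejected_per_frame"],
                seed + 5,
                n_boot,
            )
        )
        for b in sorted(time_binned["bin"].unique()):
            tb = time_binned[time_binned["bin"] == b]
            comparisons.append(
                _compare(
                    f"time_bin_{int(b)}_mean_distance",
                    tb.loc[tb["strain"] == strains[0], "mean_mm"],
                    tb.loc[tb["strain"] == strains[1], "mean_mm"],
                    seed + 10 + int(b),
                    n_boot,
                )
            )
        comparisons = [c for c in comparisons if c]
        age_sex = age_sex_grouping(
            table, split_months=float(cfg["age_split_months"]), n_boot=n_boot, seed=seed
        )
        comparisons.extend(age_sex.to_dict("records"))

    corr_rows = []
    for strain in strains + (["all"] if len(strains) > 1 else []):
        sub = table if strain == "all" else table[table["strain"] == strain]
        for xcol, label in (("age_months", "age_vs_distance"),):
            if sub[xcol].nunique() >= 3:
                r, p, slope, intercept = resampling_stats.pearson_with_fit(
                    sub[xcol], sub["grand_mean_mm"]
                )
                corr_rows.append(
                    {"correlation": label, "group": strain, "r": r, "p": p,
                     "slope": slope, "intercept": intercept, "n": len(sub)}
                )
        # Size vs distance: one point per animal (two per session).
        size = pd.concat([sub["area_1_mm2"], sub["area_2_mm2"]])
        dist2 = pd.concat([sub["grand_mean_mm"], sub["grand_mean_mm"]])
        ok = size.notna()
        if ok.sum() >= 3 and size[ok].nunique() >= 2:
            r, p, slope, intercept = resampling_stats.pearson_with_fit(size[ok], dist2[ok])
            corr_rows.append(
                {"correlation": "size_vs_distance", "group": strain, "r": r, "p": p,
                 "slope": slope, "intercept": intercept, "n": int(ok.sum())}
            )

    report = CohortReport(
        session_table=table,
        comparisons=pd.DataFrame(comparisons),
        correlations=pd.DataFrame(corr_rows),
        time_binned=time_binned,
        config=cfg,
    )
    if cfg.get("output_dir"):
        report.write(cfg["output_dir"])
    return report
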