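"""End-to-end analysis pipeline.

Stages: obtain a staged-profile dataset (simulated, or read from the
profile-point CSV + metadata JSON dialect), process profiles into closed
outlines, run elliptical Fourier analysis with size normalization, build
the shared PCA shape space, and run the statistical battery — permutation
tests of among-potter shape variation at the pre-formed and final stages
(pooled and per community), the growth-curve model comparison chain on
exterior surface area, and the Stage mixed model on shape-space
distances.  Every stage writes its tidy output file so each reported
number is traceable; rerunning with the same configuration reproduces
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .efa import EllipticalFourierAnalysis
from .morphometrics import coefficient_of_variation, trial_size_table
from .outline import Profile, mirror_to_outline, resample_profile, smooth_profile
from .shape_space import ShapeSpacePCA, stage_distances
from .stats import (
    fit_growth_model,
    likelihood_ratio_test,
    pearson_ci,
    permanova,
    stage_lmm,
)
from .synthetic import (
    StudyDataset,
    Trial,
    TrialStage,
    default_study_config,
    simulate_study,
    write_dataset,
)

logger = logging.getLogger("vesselmorph")

__all__ = ["PipelineConfig", "run_pipeline", "read_outlines", "write_report"]

REQUIRED_CSV_COLUMNS = ["trial_id", "stage_index", "time_s", "point_index", "x_cm", "y_cm"]


class SchemaError(ValueError):
    """Input file does not match the documented CSV/JSON dialect."""


@dataclass
class PipelineConfig:
    """Validated, fully serializable configuration of one pipeline run."""

    # input: either a synthetic study (default) or CSV+JSON paths
    input_csv: str | None = None
    input_json: str | None = None
    seed: int = 0
    n_trials_per_type: int = 5
    profile_points: int = 256
    # processing
    n_points: int = 256
    smooth_cutoff: float | None = 0.15
    # EFA
    n_harmonics: int = 20
    norm_method: str = "semi_major"
    # shape space / stats
    n_components: int = 3
    n_permutations: int = 9999
    n_time_bins: int = 20
    output_dir: str = "vesselmorph_out"

    def __post_init__(self) -> None:
        if (self.input_csv is None) != (self.input_json is None):
            raise ValueError("input_csv and input_json must be given together")
        if self.n_points < 16 or self.n_harmonics < 1 or self.n_components < 1:
            raise ValueError("invalid processing/EFA/shape-space sizes")
        if self.smooth_cutoff is not None and not (0 < self.smooth_cutoff < 1):
            raise ValueError("smooth_cutoff must lie in (0, 1) or be null")
        if self.n_permutations < 1 or self.n_time_bins < 2:
            raise ValueError("invalid stats options")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError(f"config file {path} must hold a mapping")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# dataset IO


def read_outlines(csv_path, json_path) -> StudyDataset:
    """Read a staged-profile dataset from the CSV + metadata JSON dialect.

    Validates the schema and the trial invariants (strictly increasing
    stage times, nonempty trials), naming the offending trial on failure.
    """
    # keep_default_na: potter/trial labels like "NA" must stay strings
    df = pd.read_csv(csv_path, keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{csv_path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{csv_path}: empty trial set")
    df[["stage_index", "point_index"]] = df[["stage_index", "point_index"]].astype(int)
    df[["time_s", "x_cm", "y_cm"]] = df[["time_s", "x_cm", "y_cm"]].astype(float)
    with open(json_path) as fh:
        meta = json.load(fh)
    info = {t["trial_id"]: t for t in meta.get("trials", [])}
    trials = []
    for trial_id, tdf in df.groupby("trial_id", sort=True):
        ti = info.get(trial_id, {})
        stages = []
        for stage_index, sdf in tdf.groupby("stage_index", sort=True):
            sdf = sdf.sort_values("point_index")
            times = sdf["time_s"].unique()
            if len(times) != 1:
                raise SchemaError(
                    f"trial {trial_id} stage {stage_index}: inconsistent time_s"
                )
            stages.append(
                TrialStage(
                    gesture_index=int(stage_index),
                    time_s=float(times[0]),
                    profile=Profile(
                        x=sdf["x_cm"].to_numpy(), y=sdf["y_cm"].to_numpy()
                    ),
                )
            )
        try:
            trials.append(
                Trial(
                    trial_id=str(trial_id),
                    potter_id=str(ti.get("potter_id", str(trial_id).split("-")[0])),
                    community=str(ti.get("community", "NA")),
                    vessel_type=str(ti.get("vessel_type", "vessel")),
                    stages=tuple(stages),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"trial {trial_id}: {exc}") from exc
    cfg = default_study_config(seed=int(meta.get("seed") or 0))
    return StudyDataset(trials=tuple(trials), config=cfg,
                        provenance={"seed": meta.get("seed"),
                                    "generator_version": meta.get("generator_version")})


# --------------------------------------------------------------------------
# pipeline stages


def _process_trials(ds: StudyDataset, cfg: PipelineConfig):
    """Resample, smooth and mirror every stage profile into an outline."""
    outlines = {}
    for tr in ds.trials:
        for st in tr.stages:
            try:
                p = resample_profile(st.profile, n_points=cfg.n_points)
                if cfg.smooth_cutoff is not None:
                    p = smooth_profile(p, cutoff=cfg.smooth_cutoff)
                outlines[(tr.trial_id, st.gesture_index)] = mirror_to_outline(p)
            except ValueError as exc:
                raise type(exc)(
                    f"processing failed for trial {tr.trial_id} "
                    f"stage {st.gesture_index}: {exc}"
                ) from exc
    return outlines


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the analysis report (also written to
    ``output_dir`` along with every intermediate table)."""
    t0 = time.perf_counter()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: dataset -------------------------------------------------
    if config.input_csv is not None:
        ds = read_outlines(config.input_csv, config.input_json)
        logger.info("read %d trials from %s", len(ds.trials), config.input_csv)
    else:
        study = default_study_config(
            seed=config.seed,
            n_trials_per_type=config.n_trials_per_type,
            profile_points=config.profile_points,
        )
        ds = simulate_study(study)
        logger.info("simulated %d trials (seed=%d)", len(ds.trials), config.seed)
    if not ds.trials:
        raise SchemaError("empty trial set")
    write_dataset(ds, outdir / "dataset.csv", outdir / "metadata.json")

    # --- stage 2: processing + size metrics -------------------------------
    outlines = _process_trials(ds, config)
    sizes = trial_size_table(ds.trials, n_bins=config.n_time_bins)
    sizes.to_csv(outdir / "sizes.csv", index=False, float_format="%.10g")
    logger.info("processed %d outlines", len(outlines))

    # --- stage 3: EFA -----------------------------------------------------
    efa = EllipticalFourierAnalysis(
        n_harmonics=config.n_harmonics, normalize=True,
        norm_method=config.norm_method,
    ).fit(None)
    keys = sorted(outlines)
    coeffs = efa.transform([outlines[k] for k in keys])
    coeff_df = pd.DataFrame(coeffs, columns=efa.get_feature_names_out())
    coeff_df.insert(0, "stage_index", [k[1] for k in keys])
    coeff_df.insert(0, "trial_id", [k[0] for k in keys])
    coeff_df.to_csv(outdir / "coefficients.csv", index=False, float_format="%.10g")

    # --- stage 4: shared shape space --------------------------------------
    space = ShapeSpacePCA(n_components=config.n_components).fit(coeffs)
    scores = space.transform(coeffs)
    score_df = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(config.n_components)]
    )
    score_df.insert(0, "stage_index", coeff_df["stage_index"])
    score_df.insert(0, "trial_id", coeff_df["trial_id"])
    score_df.to_csv(outdir / "scores.csv", index=False, float_format="%.10g")
    logger.info("shape space: first %d PCs explain %.1f%%", config.n_components,
                100 * space.explained_variance_ratio_[: config.n_components].sum())

    trial_info = {t.trial_id: t for t in ds.trials}
    report: dict = {
        "provenance": {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_trials": len(ds.trials),
            "n_outlines": int(coeffs.shape[0]),
        },
        "shape_space": {
            "explained_variance_ratio": [
                float(v) for v in space.explained_variance_ratio_[:10]
            ],
            "captured_by_retained": float(
                space.explained_variance_ratio_[: config.n_components].sum()
            ),
        },
        "types": {},
    }

    # --- stage 5: per-type statistics -------------------------------------
    rng_master = np.random.default_rng(np.random.SeedSequence((config.seed, 0xABCD)))
    all_dist = []
    vessel_types = sorted({t.vessel_type for t in ds.trials})
    for vtype in vessel_types:
        tids = [t.trial_id for t in ds.trials if t.vessel_type == vtype]
        potter_of = {tid: trial_info[tid].potter_id for tid in tids}
        comm_of = {tid: trial_info[tid].community for tid in tids}

        # dimension summary at final stage
        final_sizes = (
            sizes[sizes["trial_id"].isin(tids)]
            .sort_values(["trial_id", "stage_index"])
            .groupby("trial_id")
            .tail(1)
        )
        dims = {}
        for potter, pdf in final_sizes.groupby("potter_id"):
            dims[potter] = {
                m: {
                    "mean": float(pdf[m].mean()),
                    "cv": coefficient_of_variation(pdf[m]) if len(pdf) > 1 else None,
                }
                for m in ("height_cm", "max_diameter_cm", "esa_cm2")
            }

        # permutation tests at the two stages, pooled and per community
        stage_rows = {}
        for stage_name, pick_last in (("pre_formed", False), ("final", True)):
            mask = []
            for tid in tids:
                smax = max(s.gesture_index for s in trial_info[tid].stages)
                mask.append((tid, smax if pick_last else 0))
            idx = [keys.index(k) for k in mask]
            stage_rows[stage_name] = (np.asarray(idx), mask)

        perm_section = {}
        communities = sorted({comm_of[tid] for tid in tids})
        for stage_name, (idx, mask) in stage_rows.items():
            feats = coeffs[idx]
            labels = np.array([potter_of[tid] for tid, _ in mask])
            comms = np.array([comm_of[tid] for tid, _ in mask])
            sect = {}
            seed_p = int(rng_master.integers(2**31))
            sect["pooled"] = asdict(
                permanova(feats, labels, n_permutations=config.n_permutations,
                          seed=seed_p)
            )
            for c in communities:
                m = comms == c
                if len(np.unique(labels[m])) >= 2:
                    seed_c = int(rng_master.integers(2**31))
                    sect[c] = asdict(
                        permanova(feats[m], labels[m],
                                  n_permutations=config.n_permutations, seed=seed_c)
                    )
            perm_section[stage_name] = sect

        # growth-model chain on ESA over time bins
        tsizes = sizes[sizes["trial_id"].isin(tids)]
        chain = {}
        lrt = {}
        try:
            m_none = fit_growth_model(tsizes, random_effects="none")
            m_int = fit_growth_model(tsizes, random_effects="intercept")
            m_slope = fit_growth_model(tsizes, random_effects="slopes")
            chain = {
                "none": {"loglik": m_none.loglik_, "n_params": m_none.n_params_},
                "intercept": {"loglik": m_int.loglik_, "n_params": m_int.n_params_},
                "slopes": {"loglik": m_slope.loglik_, "n_params": m_slope.n_params_},
            }
            lrt["intercept_vs_none"] = asdict(likelihood_ratio_test(m_none, m_int))
            lrt["slopes_vs_intercept"] = asdict(likelihood_ratio_test(m_int, m_slope))
            if len(set(comm_of.values())) == 2:
                m_comm = fit_growth_model(tsizes, random_effects="slopes",
                                          community=True)
                chain["slopes+community"] = {
                    "loglik": m_comm.loglik_, "n_params": m_comm.n_params_,
                }
                lrt["community_vs_slopes"] = asdict(
                    likelihood_ratio_test(m_slope, m_comm)
                )
        except ValueError as exc:
            chain = {"error": str(exc)}

        # stage distances + Stage LMM, pooled and per community
        dist_frames = []
        for stage_name, (idx, mask) in stage_rows.items():
            sc = scores[idx]
            tid_arr = [tid for tid, _ in mask]
            pooled = stage_distances(sc, tid_arr, ["pooled"] * len(tid_arr),
                                     stage_label=stage_name)
            by_comm = stage_distances(
                sc, tid_arr, [comm_of[t] for t in tid_arr], stage_label=stage_name
            )
            dist_frames.extend([pooled, by_comm])
        dists = pd.concat(dist_frames, ignore_index=True)
        dists["potter_id"] = dists["trial_id"].map(potter_of)
        dists["vessel_type"] = vtype
        all_dist.append(dists)

        lmm_section = {}
        for group in ["pooled"] + communities:
            sub = dists[dists["group"] == group]
            if sub.empty or sub["potter_id"].nunique() < 2:
                continue
            res = stage_lmm(sub)
            lmm_section[group] = {
                "stage_estimate": res.stage_estimate,
                "F": res.F,
                "df": [res.df_num, res.df_den],
                "p_value": res.p_value,
                "potter_intercept_sd": res.potter_intercept_sd,
                "stratum_sds": {str(k): v for k, v in res.stratum_sds.items()},
                "mean_distance_pre_formed": float(
                    sub[sub["stage"] == "pre_formed"]["distance"].mean()
                ),
                "mean_distance_final": float(
                    sub[sub["stage"] == "final"]["distance"].mean()
                ),
            }

        # size ~ effort correlations over trials
        per_trial = final_sizes.set_index("trial_id")
        durations = np.array([trial_info[t].duration_s for t in per_trial.index])
        gestures = np.array([trial_info[t].n_gestures for t in per_trial.index])
        esa = per_trial["esa_cm2"].to_numpy()
        correlations = {}
        for name, v in (("duration_s", durations), ("n_gestures", gestures)):
            if np.std(v) > 0:
                r, p, lo, hi = pearson_ci(esa, v)
                correlations[f"esa_vs_{name}"] = {
                    "r": r, "p_value": p, "ci95": [lo, hi], "n": int(len(esa)),
                }

        report["types"][vtype] = {
            "dimensions": dims,
            "permutation_tests": perm_section,
            "growth_model": {"chain": chain, "lrt": lrt},
            "stage_lmm": lmm_section,
            "size_correlations": correlations,
        }

    pd.concat(all_dist, ignore_index=True).to_csv(
        outdir / "distances.csv", index=False, float_format="%.10g"
    )
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    write_report(report, outdir)
    return report


def write_report(report: dict, outdir) -> None:
    """Write the JSON report and a short human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
    lines = ["vesselmorph analysis report", "=" * 27, ""]
    ss = report.get("shape_space", {})
    if ss:
        evr = ss["explained_variance_ratio"][:3]
        lines.append(
            "Shape space: PC1-3 explain "
            + ", ".join(f"{100 * v:.1f}%" for v in evr)
            + f" (total {100 * ss['captured_by_retained']:.1f}%)"
        )
    for vtype, sec in report.get("types", {}).items():
        lines.append(f"\n[{vtype}]")
        for stage in ("pre_formed", "final"):
            pooled = sec["permutation_tests"][stage]["pooled"]
            lines.append(
                f"  {stage:>10} shape: R2(potter) = {pooled['r_squared_among']:.2f}, "
                f"pseudo-F = {pooled['pseudo_F']:.2f}, p = {pooled['p_value']:.4g}"
            )
        for grp, lm in sec["stage_lmm"].items():
            lines.append(
                f"  stage LMM [{grp}]: F(1,{lm['df'][1]}) = {lm['F']:.2f}, "
                f"p = {lm['p_value']:.3g}; mean distance "
                f"{lm['mean_distance_pre_formed']:.3f} -> "
                f"{lm['mean_distance_final']:.3f}"
            )
        lrt = sec["growth_model"].get("lrt", {})
        for name, t in lrt.items():
            lines.append(
                f"  growth LRT {name}: chi2({t['df']}) = {t['chi_square']:.2f}, "
                f"p = {t['p_value']:.3g}"
            )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
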