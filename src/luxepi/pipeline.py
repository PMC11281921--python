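"""End-to-end orchestration: synthesize -> process light -> simulate pacemaker
-> derive exposures -> fit Cox models -> report.

Each stage reads and writes plain CSV artifacts in the run directory so any
step can be audited or re-run in isolation; a single config seed fans out to
per-participant substreams, making serial and re-run results identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circadian as circ
from . import exposures as expo
from . import light as lp
from . import survival as surv
from . import synthetic as syn

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown run-configuration key."""


_DEFAULT_CONFIG = {
    "seed": 0,
    "paths": {"out_dir": "run"},
    "synthetic": {
        "n_participants": 200,
        "days": 7,
        "epoch_seconds": 60,
        "night_dark_fraction": 0.6,
        "nonwear_gap_rate": 0.5,
        "n_snps": 100,
    },
    "light": {"min_days": 3, "min_bin_coverage": 1, "window_mode": "fixed"},
    "circadian": {"enabled": True, "dt": 1.0 / 60.0, "max_weeks": 10, "tol_h": 0.1, "params": {}},
    "grouping": {"cutpoints": [0, 50, 70, 90, 100]},
    # demo-scale outcome defaults: the rate is inflated so every exposure
    # level carries events at the default n; cohort-scale experiments set
    # study-realistic rates (~0.003/person-year) explicitly
    "outcome": {
        "baseline_rate": 0.05,
        "follow_up_years": 8.0,
        "censor_mortality_rate": 0.0,
        "true_night_hr": {"50-70%": 1.29, "70-90%": 1.39, "90-100%": 1.53},
    },
    "models": [
        {"tier": 1, "predictors": ["night_group", "day_group"]},
        {"tier": 2, "predictors": ["night_group", "day_group"]},
        {"tier": 3, "predictors": ["night_group", "day_group"]},
    ],
}


def _merge_validate(defaults, user, path=""):
    if not isinstance(user, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            # leaf dicts with free-form keys (model params, HR maps)
            if isinstance(dval, dict) and key not in ("params", "true_night_hr"):
                out[key] = _merge_validate(dval, uval, f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(f'{path}{k}' for k in unknown)}")
    return out


def load_config(source=None) -> dict:
    """Build a validated run config from a YAML path / dict / None (defaults).

    Unknown keys raise :class:`ConfigError` before any stage runs.
    """
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge_validate(_DEFAULT_CONFIG, user)
    if "models" in user and user["models"] is not None:
        cfg["models"] = user["models"]
    return cfg


def _light_cfg(cfg) -> syn.LightGenConfig:
    s = cfg["synthetic"]
    return syn.LightGenConfig(
        n_participants=s["n_participants"],
        days=s["days"],
        epoch_seconds=s["epoch_seconds"],
        night_dark_fraction=s["night_dark_fraction"],
        nonwear_gap_rate=s["nonwear_gap_rate"],
        seed=cfg["seed"],
    )


def stage_simulate(cfg: dict, out: Path) -> None:
    """Write synthetic light recordings and PRS inputs."""
    out.joinpath("light").mkdir(parents=True, exist_ok=True)
    lcfg = _light_cfg(cfg)
    for i in range(lcfg.n_participants):
        rec = syn.generate_light_recording(lcfg, i)
        lp.write_light_csv(rec, out / "light" / f"{rec.participant_id}.csv")
    weights, dosages = syn.generate_prs_inputs(
        lcfg.n_participants, cfg["synthetic"]["n_snps"], seed=cfg["seed"]
    )
    weights.to_csv(out / "prs_weights.csv", index=False)
    dosages.to_csv(out / "prs_dosages.csv")
    logger.info("simulated %d light recordings", lcfg.n_participants)


def _load_recordings(out: Path) -> list:
    files = sorted(out.joinpath("light").glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no light CSVs under {out/'light'}")
    recs = []
    for f in files:
        rec = lp.read_light_csv(f)
        if rec.participant_id == "unknown":
            rec.participant_id = f.stem
        recs.append(rec)
    return recs


def stage_process_light(cfg: dict, out: Path) -> pd.DataFrame:
    """Mask non-wear, bin to 48 half-hour bins, derive windows, summarize."""
    recs = _load_recordings(out)
    profiles = [lp.bin_half_hour(lp.mask_nonwear(r)) for r in recs]
    qc = [
        lp.qc_participant(
            p, cfg["light"]["min_days"], cfg["light"]["min_bin_coverage"]
        )
        for p in profiles
    ]
    if cfg["light"]["window_mode"] == "factor":
        matrix = np.stack([p.bin_means for p in profiles])
        windows = lp.derive_windows(matrix)
    elif cfg["light"]["window_mode"] == "fixed":
        windows = lp.ExposureWindows()
    else:
        raise ConfigError(f"unknown window_mode {cfg['light']['window_mode']!r}")
    rows = []
    for p, ok in zip(profiles, qc):
        s = lp.summarize_exposure(p, windows)
        rows.append(
            {
                "participant_id": s.participant_id,
                "day_lux": s.day_lux,
                "night_lux": s.night_lux,
                "qc_pass": bool(ok and s.qc_pass),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "exposures.csv", index=False)
    prof = pd.DataFrame(
        np.stack([p.bin_means for p in profiles]),
        columns=[f"bin{k:02d}" for k in range(lp.N_BINS)],
    )
    prof.insert(0, "participant_id", [p.participant_id for p in profiles])
    prof.to_csv(out / "profiles.csv", index=False)
    logger.info("processed light for %d participants (%d QC pass)", len(df), int(df.qc_pass.sum()))
    return df


def stage_circadian(cfg: dict, out: Path) -> pd.DataFrame:
    """Simulate the pacemaker on each weekly recording and summarize."""
    recs = _load_recordings(out)
    params = circ.CircadianParams(**cfg["circadian"]["params"])
    summaries = circ.simulate_cohort(
        recs,
        params,
        max_weeks=cfg["circadian"]["max_weeks"],
        tol_h=cfg["circadian"]["tol_h"],
        dt=cfg["circadian"]["dt"],
    )
    df = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in summaries],
            "mean_phase": [s.mean_phase for s in summaries],
            "phase_sd": [s.phase_sd for s in summaries],
            "amp_mean": [s.amp_mean for s in summaries],
            "amp_min": [s.amp_min for s in summaries],
            "amp_max": [s.amp_max for s in summaries],
        }
    )
    df.to_csv(out / "circadian.csv", index=False)
    return df


def stage_derive(cfg: dict, out: Path) -> pd.DataFrame:
    """Derive analysis variables, simulate outcomes, assemble the cohort table."""
    exposures = pd.read_csv(out / "exposures.csv")
    cutpoints = tuple(cfg["grouping"]["cutpoints"])
    usable = exposures[exposures["qc_pass"]].reset_index(drop=True)
    night = expo.percentile_groups(usable["night_lux"].to_numpy(), cutpoints)
    day = expo.percentile_groups(usable["day_lux"].to_numpy(), cutpoints)
    usable = usable.assign(night_group=night.assignment, day_group=day.assignment)

    circ_path = out / "circadian.csv"
    circ_df = None
    if cfg["circadian"]["enabled"] and circ_path.exists():
        circ_df = pd.read_csv(circ_path)
        pq = expo.phase_quintiles(circ_df["mean_phase"].to_numpy())
        circ_df["phase_quintile"] = pq.assignment
        for col in ("amp_mean", "amp_min", "amp_max", "phase_sd"):
            try:
                circ_df[f"{col}_z"] = expo.zscore(circ_df[col].to_numpy())
            except ValueError:
                circ_df[f"{col}_z"] = 0.0  # degenerate (e.g. identical schedules)

    prs_df = None
    wpath, dpath = out / "prs_weights.csv", out / "prs_dosages.csv"
    if wpath.exists() and dpath.exists():
        weights = pd.read_csv(wpath)
        dosages = pd.read_csv(dpath, index_col="participant_id")
        res = expo.score_and_bin_prs(dosages, weights)
        prs_df = pd.DataFrame(
            {
                "participant_id": res.scores.index,
                "prs": res.scores.to_numpy(),
                "prs_quartile": res.quartile_assignment.to_numpy(),
            }
        )

    # Outcomes are simulated from the derived night-light group so that the
    # configured hazard ratios are the ground truth of the whole pipeline.
    ocfg = cfg["outcome"]
    rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 2**22]))
    covs = syn._simulate_covariates(rng, len(usable))
    covs.insert(0, "participant_id", usable["participant_id"].to_numpy())
    covs["prevalent"] = False
    lhr = np.array(
        [np.log(ocfg["true_night_hr"].get(g, 1.0)) for g in usable["night_group"]]
    )
    time, status = syn.simulate_survival(
        lhr,
        ocfg["baseline_rate"],
        ocfg["follow_up_years"],
        rng,
        ocfg["censor_mortality_rate"],
    )
    outcomes = pd.DataFrame(
        {"participant_id": usable["participant_id"], "time": time, "status": status}
    )

    cohort = surv.build_cohort_table(
        usable, circ_df, prs_df, covariates=covs, outcomes=outcomes
    )
    cohort.to_csv(out / "cohort.csv", index=False)
    logger.info("cohort table: %d participants, %d events", len(cohort), int(cohort["status"].sum()))
    return cohort


def stage_fit(cfg: dict, out: Path) -> list:
    """Fit every configured model tier on the cohort table."""
    path = out / "cohort.csv"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the derive stage (or run-all) first"
        )
    cohort = pd.read_csv(path)
    fits = []
    for m in cfg["models"]:
        referents = dict(m.get("referents", {}))
        if "phase_quintile" in m["predictors"]:
            referents.setdefault("phase_quintile", "40-60%")
        spec = surv.ModelSpec(
            predictors=list(m["predictors"]),
            tier=int(m.get("tier", 1)),
            referents=referents,
        )
        fits.append(surv.fit_cox(cohort, spec))
    surv.hazard_tables_to_csv(fits, out / "hazards.csv")
    return fits


def stage_report(cfg: dict, out: Path, fits=None) -> str:
    if fits is None:
        fits = stage_fit(cfg, out)
    cohort = pd.read_csv(out / "cohort.csv")
    rate = surv.incidence_rate(int(cohort["status"].sum()), float(cohort["time"].sum()))
    text = (
        f"Cohort: {len(cohort)} participants, {int(cohort['status'].sum())} events, "
        f"{cohort['time'].sum():.0f} person-years ({rate} cases per 1000 person-years)\n\n"
        + surv.render_hazard_report(fits)
    )
    (out / "report.txt").write_text(text)
    try:
        surv.plot_cumulative_incidence(cohort, "night_group", out / "cumulative_incidence.png")
    except Exception as exc:  # plotting is best-effort
        logger.warning("cumulative-incidence plot failed: %s", exc)
    return text


_STAGES = {
    "simulate": stage_simulate,
    "process-light": stage_process_light,
    "circadian": stage_circadian,
    "derive": stage_derive,
    "fit": stage_fit,
}


def run_pipeline(config=None, out_dir=None) -> dict:
    """Execute all stages in order; returns the artifact bundle.

    Stage failures abort with the failing stage named.
    """
    cfg = load_config(config)
    out = Path(out_dir if out_dir is not None else cfg["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"out_dir": out}
    order = ["simulate", "process-light"]
    if cfg["circadian"]["enabled"]:
        order.append("circadian")
    order += ["derive", "fit"]
    for name in order:
        try:
            artifacts[name] = _STAGES[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    artifacts["report"] = stage_report(cfg, out, fits=artifacts["fit"])
    return artifacts
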