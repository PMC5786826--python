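"""End-to-end orchestration: simulate/load → clean → ISC → SSVEP → spectrum → stats.

`run_pipeline` consumes a config dictionary (usually parsed from YAML by the
CLI), runs every stage, and writes tidy CSV/JSON/HDF5 outputs into the
result directory:

- ``isc_per_subject.csv`` — C1..CK and summed ISC per subject, condition and
  model fit group,
- ``ssvep_power.csv`` — per-subject 25 Hz band power and trials retained,
- ``spectrum.csv`` — per-subject total power and log-log eigenspectrum slope,
- ``group_stats.json`` — age correlations with FDR flags, two-way ANOVAs,
  Tukey comparisons, residual-ISC tests, topography similarities,
- ``models.h5`` — CorrCA projections/forward models per condition and group,
- ``run_log.txt`` — parameters, seeds and versions.

Component models can be fitted on all subjects or within age / sex /
age-and-sex subgroups (``fit_groups``), since group comparisons are cleaner
when each group's components are optimized on that group alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .corrca import CorrCA, IscResult, subject_isc, topography_similarity
from .io_core import (
    CohortError,
    Recording,
    ValidationError,
    build_cohort,
    load_role_table,
    load_subject_table,
    read_recording,
)
from .preprocess import preprocess_recording
from .rpca import clean_recording
from .simulate import OCCIPITAL, SimConfig, simulate_cohort, simulate_flicker_trials
from .spectrum import subject_spectrum
from .ssvep import subject_band_power
from .stats import (
    correlate_with_age,
    median_split,
    residualize_isc,
    tukey_hsd,
    two_way_anova,
)

log = logging.getLogger("eegisc")

CONTROL_CONDITIONS = {"Rest", "Flash"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1f s", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: dict, output_dir: str | Path) -> Path:
    """Run every configured stage and write results under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run_log.txt")
    log.info("eegisc %s", __version__)
    log.info("config: %s", json.dumps(config, default=str))

    conditions = list(config.get("conditions") or [])
    recordings, sim_cfg = _acquire(config, conditions, out)
    if not conditions:
        raise ValidationError("config lists no conditions")

    pp_cfg = config.get("preprocess", {})
    rp_cfg = config.get("rpca", {})
    cleaned = _clean_stage(recordings, pp_cfg, rp_cfg)

    cohorts = _cohort_stage(cleaned, conditions)
    meta = _meta_table(cleaned)

    cc_cfg = config.get("corrca", {})
    fit_groups = config.get("fit_groups", ["all", "age", "sex", "age_sex"])
    stats_cfg = config.get("stats", {})
    meta = median_split(meta, fixed_boundary=stats_cfg.get("fixed_boundary"))
    isc_table, models = _isc_stage(cohorts, meta, cc_cfg, fit_groups)
    isc_table.to_csv(out / "isc_per_subject.csv", index=False)
    _write_models(models, out / "models.h5")

    ssvep_cfg = config.get("ssvep", {})
    ssvep_table = _ssvep_stage(sim_cfg, ssvep_cfg, config)
    if ssvep_table is not None:
        ssvep_table.to_csv(out / "ssvep_power.csv", index=False)

    spec_table = _spectrum_stage(cohorts)
    spec_table.to_csv(out / "spectrum.csv", index=False)

    results = _stats_stage(
        isc_table, ssvep_table, spec_table, meta, models, stats_cfg
    )
    with open(out / "group_stats.json", "w") as f:
        json.dump(results, f, indent=2, default=float)
    log.info("pipeline complete: %s", out)
    return out


def _setup_logging(path: Path) -> None:
    log.setLevel(logging.INFO)
    for h in list(log.handlers):
        log.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(fh)
    log.addHandler(sh)


@_stage("acquire")
def _acquire(config: dict, conditions: list, out: Path):
    """Simulate a cohort or load recordings from disk."""
    if "simulation" in config:
        sim = dict(config["simulation"])
        sim.setdefault("seed", int(config.get("seed", 0)))
        cfg = SimConfig(**{k: v for k, v in sim.items() if k != "conditions"})
        if not conditions:
            conditions.extend(sim.get("conditions", ["Wimpy", "Rest"]))
        recordings: list[Recording] = []
        truth_summary = {}
        for cond in conditions:
            recs, truth = simulate_cohort(cfg, cond)
            recordings.extend(recs)
            truth_summary[cond] = {
                "gains": list(map(float, truth["gains"])),
                "ages": list(map(float, truth["ages"])),
                "sexes": truth["sexes"],
                "n_spikes": [len(s) for s in truth["spikes"]],
            }
        with open(out / "ground_truth.json", "w") as f:
            json.dump(truth_summary, f, indent=2)
        return recordings, cfg
    if "recordings" in config:
        block = config["recordings"]
        roles = load_role_table(block["roles_csv"])
        meta = load_subject_table(block["meta_csv"])
        recordings = [read_recording(p, roles, meta) for p in block["paths"]]
        if not conditions:
            conditions.extend(sorted({r.condition for r in recordings}))
        return recordings, None
    raise ValidationError("config needs a 'simulation' or 'recordings' block")


@_stage("preprocess+rpca")
def _clean_stage(recordings, pp_cfg: dict, rp_cfg: dict):
    notch = tuple(pp_cfg.get("notch", (59.0, 61.0)))
    cleaned = []
    for rec in recordings:
        r = preprocess_recording(
            rec,
            fs_target=pp_cfg.get("fs_target", 125.0),
            hp_hz=pp_cfg.get("hp_hz", 1.0),
            notch=notch,
            order=pp_cfg.get("butter_order", 4),
        )
        if rp_cfg.get("enabled", True):
            r = clean_recording(
                r,
                lam=rp_cfg.get("lambda"),
                tol=float(rp_cfg.get("tol", 1e-7)),
                max_iter=int(rp_cfg.get("max_iter", 500)),
            )
        cleaned.append(r)
    return cleaned


@_stage("cohort")
def _cohort_stage(recordings, conditions):
    return {c: build_cohort(recordings, c) for c in conditions}


def _meta_table(recordings) -> pd.DataFrame:
    rows = {}
    for r in recordings:
        rows[r.subject_id] = {"subject_id": r.subject_id, "age": r.age, "sex": r.sex}
    return pd.DataFrame(rows.values()).reset_index(drop=True)


def _group_assignments(meta: pd.DataFrame, scheme: str) -> dict[str, list[str]]:
    if scheme == "all":
        return {"all": list(meta["subject_id"])}
    if scheme == "age":
        return {
            g: list(meta.loc[meta["age_group"] == g, "subject_id"])
            for g in ("young", "old")
        }
    if scheme == "sex":
        return {
            g: list(meta.loc[meta["sex"] == g, "subject_id"])
            for g in ("male", "female")
        }
    if scheme == "age_sex":
        return {
            f"{a}_{s}": list(
                meta.loc[
                    (meta["age_group"] == a) & (meta["sex"] == s), "subject_id"
                ]
            )
            for a in ("young", "old")
            for s in ("male", "female")
        }
    raise ValidationError(f"unknown fit group scheme {scheme!r}")


@_stage("corrca")
def _isc_stage(cohorts, meta, cc_cfg: dict, fit_groups):
    """Fit CorrCA per condition within each configured subject grouping."""
    k = int(cc_cfg.get("n_components", 3))
    rank_tol = float(cc_cfg.get("rank_tol", 1e-9))
    rows = []
    models: dict[tuple[str, str], CorrCA] = {}
    for cond, cohort in cohorts.items():
        for scheme in fit_groups:
            for gname, subjects in _group_assignments(meta, scheme).items():
                idx = [cohort.subjects.index(s) for s in subjects
                       if s in cohort.subjects]
                if len(idx) < 2:
                    log.warning(
                        "skipping group %s/%s for %s: fewer than 2 subjects",
                        scheme, gname, cond,
                    )
                    continue
                sub = cohort.tensor[idx]
                model = CorrCA(n_components=k, rank_tol=rank_tol).fit(sub)
                model.fit_group_ = [cohort.subjects[i] for i in idx]
                models[(cond, f"{scheme}:{gname}")] = model
                res: IscResult = subject_isc(sub, model)
                for j, sid in enumerate(model.fit_group_):
                    row = {
                        "subject_id": sid,
                        "condition": cond,
                        "model_group": f"{scheme}:{gname}",
                        "isc": res.isc[j],
                    }
                    for i in range(res.per_subject_components.shape[1]):
                        row[f"C{i + 1}"] = res.per_subject_components[j, i]
                    rows.append(row)
    return pd.DataFrame(rows), models


def _write_models(models, path: Path) -> None:
    with h5py.File(path, "w") as f:
        for (cond, group), model in models.items():
            g = f.create_group(f"{cond}/{group.replace(':', '_')}")
            g.create_dataset("projections", data=model.projections_)
            g.create_dataset("forward", data=model.forward_)
            g.create_dataset("eigenvalues", data=model.eigenvalues_)
            g.attrs["fit_group"] = ",".join(model.fit_group_)
            g.attrs["rank_used"] = model.rank_used_


@_stage("ssvep")
def _ssvep_stage(sim_cfg, ssvep_cfg: dict, config: dict):
    if sim_cfg is None:
        return None  # flicker trials come only from the simulator here
    electrodes = list(ssvep_cfg.get("electrodes", OCCIPITAL))
    trial_sets, _truth = simulate_flicker_trials(
        sim_cfg, n_trials=int(ssvep_cfg.get("n_trials", 128))
    )
    rows = []
    for sid, ts in trial_sets.items():
        power, n_used = subject_band_power(
            ts,
            f0=float(ssvep_cfg.get("f0", 25.0)),
            bw=float(ssvep_cfg.get("bw", 0.5)),
            electrodes=electrodes,
            z=float(ssvep_cfg.get("reject_z", 3.0)),
            onset_ms=float(ssvep_cfg.get("onset_ms", 200.0)),
        )
        rows.append(
            {"subject_id": sid, "n_trials_used": n_used, "band_power": power}
        )
    return pd.DataFrame(rows)


@_stage("spectrum")
def _spectrum_stage(cohorts):
    rows = []
    for cond, cohort in cohorts.items():
        for j, sid in enumerate(cohort.subjects):
            fit = subject_spectrum(cohort.tensor[j])
            rows.append(
                {
                    "subject_id": sid,
                    "condition": cond,
                    "total_power": fit.total_power,
                    "slope": fit.slope,
                    "n_used": fit.n_used,
                }
            )
    return pd.DataFrame(rows)


@_stage("stats")
def _stats_stage(isc_table, ssvep_table, spec_table, meta, models, stats_cfg):
    """Group statistics mirroring the study's result procedures."""
    q = float(stats_cfg.get("fdr_q", 0.05))
    results: dict = {}
    meta_idx = meta.set_index("subject_id")

    stimuli = sorted(
        c for c in isc_table["condition"].unique() if c not in CONTROL_CONDITIONS
    )
    all_rows = isc_table[isc_table["model_group"] == "all:all"].merge(
        meta, on="subject_id"
    )

    # per-stimulus age correlation, BH-corrected across the stimulus family
    fam_conditions = stimuli + [
        c for c in ("Flash",) if c in set(isc_table["condition"])
    ]
    pvals = {}
    for cond in fam_conditions:
        sub = all_rows[all_rows["condition"] == cond]
        res = correlate_with_age(sub["isc"].to_numpy(), sub["age"].to_numpy())
        pvals[cond] = res
    family = [pvals[c].p for c in fam_conditions]
    results["age_correlation"] = {}
    for cond in fam_conditions:
        res = correlate_with_age(
            all_rows.loc[all_rows["condition"] == cond, "isc"].to_numpy(),
            all_rows.loc[all_rows["condition"] == cond, "age"].to_numpy(),
            fdr_q=q,
            family=family,
        )
        results["age_correlation"][cond] = {
            "r": res.r, "p": res.p, "n": res.n, "fdr_significant": res.fdr_significant,
        }
    if "Rest" in set(isc_table["condition"]):
        sub = all_rows[all_rows["condition"] == "Rest"]
        res = correlate_with_age(sub["isc"].to_numpy(), sub["age"].to_numpy())
        results["age_correlation"]["Rest"] = {"r": res.r, "p": res.p, "n": res.n}
        results["rest_mean_isc"] = float(sub["isc"].mean())

    # stimulus one-way structure: Tukey pairwise comparisons between stimuli
    stim_rows = all_rows[all_rows["condition"].isin(fam_conditions)]
    if len(fam_conditions) >= 2:
        tk = tukey_hsd(
            stim_rows["isc"].to_numpy(), list(stim_rows["condition"]), alpha=0.05
        )
        results["stimulus_tukey"] = tk.to_dict(orient="records")

    # median-split and sex two-way ANOVAs (group-specific components)
    for scheme, factor in (("age", "age_group"), ("sex", "sex")):
        grp_rows = isc_table[
            isc_table["model_group"].str.startswith(f"{scheme}:")
        ].merge(meta, on="subject_id")
        grp_rows = grp_rows[grp_rows["condition"].isin(fam_conditions)]
        if grp_rows.empty or grp_rows["condition"].nunique() < 2:
            continue
        results[f"anova_{scheme}_stimulus"] = two_way_anova(
            grp_rows["isc"].to_numpy(),
            list(grp_rows[factor]),
            list(grp_rows["condition"]),
        )

    # age x sex groups, ISC averaged over narrative stimuli
    as_rows = isc_table[isc_table["model_group"].str.startswith("age_sex:")].merge(
        meta, on="subject_id"
    )
    as_rows = as_rows[as_rows["condition"].isin(stimuli)]
    mean_isc = None
    if not as_rows.empty:
        mean_isc = as_rows.groupby("subject_id")["isc"].mean()
        sub_meta = meta_idx.loc[mean_isc.index]
        if sub_meta["age_group"].nunique() == 2 and sub_meta["sex"].nunique() == 2:
            results["anova_age_sex"] = two_way_anova(
                mean_isc.to_numpy(),
                list(sub_meta["age_group"]),
                list(sub_meta["sex"]),
            )

    # SSVEP: age relation and residualized ISC
    if ssvep_table is not None and mean_isc is not None:
        power = ssvep_table.set_index("subject_id")["band_power"]
        ages = meta_idx.loc[power.index, "age"]
        res = correlate_with_age(power.to_numpy(), ages.to_numpy())
        results["ssvep_age_correlation"] = {"r": res.r, "p": res.p, "n": res.n}
        shared = mean_isc.index.intersection(power.index)
        if len(shared) >= 3:
            r_iscssvep = correlate_with_age(
                mean_isc.loc[shared].to_numpy(), power.loc[shared].to_numpy()
            )
            results["isc_vs_ssvep"] = {"r": r_iscssvep.r, "p": r_iscssvep.p}
            resid = residualize_isc(mean_isc.loc[shared], power.loc[shared])
            sub_meta = meta_idx.loc[shared]
            if sub_meta["age_group"].nunique() == 2 and sub_meta["sex"].nunique() == 2:
                results["anova_residual_isc"] = two_way_anova(
                    resid, list(sub_meta["age_group"]), list(sub_meta["sex"])
                )

    # forward-model topography similarity across age/sex group models
    results["topography_similarity"] = _topography_block(models, stimuli)

    # eigenspectrum power and slope group effects
    spec_rows = spec_table.merge(meta, on="subject_id")
    spec_stim = spec_rows[~spec_rows["condition"].isin({"Rest"})]
    if spec_stim["condition"].nunique() >= 2:
        for measure in ("total_power", "slope"):
            for factor in ("age_group", "sex"):
                results[f"anova_{measure}_{factor}"] = two_way_anova(
                    spec_stim[measure].to_numpy(),
                    list(spec_stim[factor]),
                    list(spec_stim["condition"]),
                )
    return results


def _topography_block(models, stimuli):
    """Min pairwise |cosine| per component across age/sex group models."""
    block = {}
    for cond in stimuli:
        group_models = [
            m for (c, g), m in models.items()
            if c == cond and g.startswith("age_sex:")
        ]
        if len(group_models) < 2:
            continue
        k = min(m.forward_.shape[1] for m in group_models)
        mins = np.ones(k)
        for i, ma in enumerate(group_models):
            for mb in group_models[i + 1:]:
                sim = topography_similarity(ma, mb)[:k]
                mins = np.minimum(mins, sim)
        block[cond] = {f"C{i + 1}": float(mins[i]) for i in range(k)}
    return block
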