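"""End-to-end orchestration: synthesis -> behavior -> spectra -> ITPC -> coupling.

One YAML-configurable entry point, :func:`run_full_pipeline`, simulates a
cohort with per-subject effect strengths shared between the behavioral
forward model (hazard gains) and the EEG generator (von Mises concentration),
then runs every analysis stage and writes TSV/JSON outputs plus a run
manifest (config hash, seeds, versions, per-stage outputs).  Identical
config + seed yields identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import brain_behavior as bb
from . import eeg_itpc as itpc_mod
from . import switch_spectra as spec_mod
from . import synthgen as sg

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a stage's validation fails; names the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


def default_config() -> dict:
    return {
        "study": {"n_subjects": 8, "blocks_per_session": 4,
                  "block_duration": 180.0},
        "dynamics": {"dominance_shape": 3.5, "dominance_mean": 2.5,
                     "hazard_gain_mismatch": 2.0, "hazard_gain_match": 0.5,
                     "modulation_freq_mismatch": 3.5,
                     "modulation_freq_match": 8.0,
                     "modulation_depth": 0.9},
        "heterogeneity": {"effect_min": 0.3, "effect_max": 1.0},
        "report_accuracy": 0.9,
        "eeg": {"montage": "standard", "kappa_35": 6.0, "kappa_8": 6.0,
                "match_ratio": 0.25, "noise_sd": 0.3,
                "region_35": ["FT8", "C6"], "region_8": ["P6", "PO8"]},
        "spectra": {"n_surrogates": 5000, "p_first": 0.005, "p_cluster": 0.05},
        "itpc": {"n_resamples": 100, "n_perm": 2000, "p_first": 0.05,
                 "max_dist_cm": 3.5, "freqs": [3.5, 8.0]},
        "psi": {"window_congruent": [1.0, 4.0], "window_switch": [2.0, 4.0]},
    }


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key)
               .generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# stage: synthetic cohort
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: dict, seed: int) -> dict:
    """Simulate traces, schedules, reports and per-subject effect strengths.

    Each subject carries a scalar effect in [effect_min, effect_max] that
    scales both the hazard-gain departure from 1 (behavior) and, later, the
    von Mises concentration of the phase-locked EEG components -- the shared
    cause behind the brain-behavior correlation.
    """
    study = sg.StudyConfig(seed=seed, **cfg["study"])
    base_dyn = sg.RivalryDynamics(**cfg["dynamics"])
    het = cfg["heterogeneity"]
    subjects = []
    for s in range(study.n_subjects):
        rng = sg.child_rng(seed, s)
        effect = float(rng.uniform(het["effect_min"], het["effect_max"]))
        dyn = sg.RivalryDynamics(**cfg["dynamics"])
        dyn.hazard_gain_mismatch = 1.0 + effect * (base_dyn.hazard_gain_mismatch - 1.0)
        dyn.hazard_gain_match = 1.0 - effect * (1.0 - base_dyn.hazard_gain_match)
        sessions = {}
        for sess_i, attended in enumerate((True, False)):
            schedules, traces = [], []
            for b in range(study.blocks_per_session):
                sched = sg.generate_cue_schedule(
                    study, block_index=b, attended=attended,
                    rng_seed=_child_seed(seed, s, sess_i, b, 0))
                trace = sg.simulate_rivalry_block(
                    sched, dyn, study, rng_seed=_child_seed(seed, s, sess_i, b, 1))
                schedules.append(sched)
                traces.append(trace)
            sessions["attended" if attended else "ignored"] = {
                "schedules": schedules, "traces": traces}
        reports = sg.simulate_attention_reports(
            sessions["attended"]["traces"], sessions["attended"]["schedules"],
            cfg["report_accuracy"], rng_seed=_child_seed(seed, s, 7))
        subjects.append({"id": s, "effect": effect, "dynamics": dyn,
                         "sessions": sessions, "reports": reports})
    return {"study": study, "subjects": subjects}


# ---------------------------------------------------------------------------
# stage: behavior
# ---------------------------------------------------------------------------

def behavioral_stage(cohort: dict, cfg: dict) -> dict:
    """Epoch trials, build six-condition time-courses, PSI and summaries."""
    all_trials = []
    for subj in cohort["subjects"]:
        for sess in subj["sessions"].values():
            for b, (trace, sched) in enumerate(zip(sess["traces"],
                                                   sess["schedules"])):
                all_trials.extend(bhv.epoch_trials(trace, sched,
                                                   subject_id=subj["id"],
                                                   block=b))
    subject_ids = sorted({t.subject_id for t in all_trials})

    def per_subject_matrix(trials, reference):
        tc = bhv.congruent_probability_timecourse(trials, reference)
        if tc.subject_ids != subject_ids:
            raise PipelineStageError(
                "behavior", "unequal subject sets across conditions")
        return tc

    by_cond = {}
    for cond in bhv.SIX_CONDITIONS:
        own = [t for t in all_trials if t.condition_label == cond]
        if not own:
            raise PipelineStageError("behavior", f"no trials in {cond}")
        by_cond[cond] = per_subject_matrix(own, "congruent")
    times = by_cond["attended_low"].times
    mats = {k: v.per_subject for k, v in by_cond.items()}
    stats_table = bhv.per_bin_condition_test(mats)

    psi_cong = bhv.compute_psi(mats, times, target="attended_low",
                               window=tuple(cfg["psi"]["window_congruent"]))

    # congruence-split switch probabilities (attended-low vs the others)
    psi_split, switch_times = {}, {}
    for split in (bhv.MISMATCHED, bhv.MATCHED):
        split_mats = {}
        for cond in bhv.SIX_CONDITIONS:
            own = [t for t in all_trials
                   if t.condition_label == cond and t.congruence == split]
            if not own:
                raise PipelineStageError("behavior",
                                         f"no {split} trials in {cond}")
            split_mats[cond] = per_subject_matrix(own, "switched").per_subject
        psi_split[split] = bhv.compute_psi(
            split_mats, times, target="attended_low",
            window=tuple(cfg["psi"]["window_switch"]))
        switch_times[split] = [
            bhv.first_switch_times([t for t in all_trials
                                    if t.subject_id == sid
                                    and t.condition_label == "attended_low"
                                    and t.congruence == split])
            for sid in subject_ids]
    switch_times["visual_only"] = [
        bhv.first_switch_times([t for t in all_trials
                                if t.subject_id == sid
                                and t.condition_label == "visual_only_attend"])
        for sid in subject_ids]

    att_idx = np.array([bhv.attention_index(s["reports"]["reported"],
                                            s["reports"]["actual"])
                        for s in cohort["subjects"]])
    counts = {split: [t.size for t in switch_times[split]]
              for split in switch_times}
    return {"trials": all_trials, "subject_ids": subject_ids, "times": times,
            "timecourses": mats, "stats_table": stats_table,
            "psi_congruent": psi_cong, "psi_mismatched": psi_split[bhv.MISMATCHED],
            "psi_matched": psi_split[bhv.MATCHED],
            "attention_index": att_idx, "switch_times": switch_times,
            "switch_counts": counts}


# ---------------------------------------------------------------------------
# stage: switch spectra
# ---------------------------------------------------------------------------

def spectra_stage(behavior_out: dict, cfg: dict, seed: int) -> dict:
    out = {}
    sp = cfg["spectra"]
    for i, cond in enumerate(("mismatched", "matched", "visual_only")):
        times = behavior_out["switch_times"][cond]
        tc, spec, null, clusters = spec_mod.analyze_switch_spectrum(
            times, n_surrogates=sp["n_surrogates"],
            seed=_child_seed(seed, 100 + i),
            p_first=sp["p_first"], p_cluster=sp["p_cluster"])
        out[cond] = {"timecourse": tc, "spectrum": spec, "null": null,
                     "clusters": clusters}
    return out


# ---------------------------------------------------------------------------
# stage: EEG ITPC
# ---------------------------------------------------------------------------

EEG_CONDITIONS = ("mismatched", "matched", "attended_high",
                  "ignored_low", "ignored_high")


def eeg_stage(cohort: dict, behavior_out: dict, cfg: dict, seed: int) -> dict:
    ecfg = cfg["eeg"]
    if ecfg["montage"] == "standard":
        montage = sg.standard_montage()
    else:
        p = Path(ecfg["montage"])
        if not p.exists():
            raise PipelineStageError("eeg_itpc", f"montage file not found: {p}")
        montage = sg.Montage.from_json(p)
    n_ch = len(montage.ch_names)
    r35 = [montage.index(c) for c in ecfg["region_35"]]
    r8 = [montage.index(c) for c in ecfg["region_8"]]

    def kappa_for(effect: float, locked: bool) -> np.ndarray:
        k = np.zeros((2, n_ch))
        if locked:
            k[0, r35] = ecfg["kappa_35"] * effect
            k[1, r8] = ecfg["kappa_8"] * effect
        return k

    epochs_by_cond = {c: [] for c in EEG_CONDITIONS}
    for si, subj in enumerate(cohort["subjects"]):
        sid = subj["id"]
        n_mis = max(behavior_out["switch_counts"]["mismatched"][si], 2)
        n_mat = max(behavior_out["switch_counts"]["matched"][si], 2)
        n_other = max((n_mis + n_mat) // 2, 2)
        for cond, n_tr, scale in (
                ("mismatched", n_mis, 1.0),
                ("matched", n_mat, ecfg["match_ratio"]),
                ("attended_high", n_other, 0.0),
                ("ignored_low", n_other, 0.0),
                ("ignored_high", n_other, 0.0)):
            truth = sg.EEGGroundTruth(
                kappa=kappa_for(subj["effect"] * scale, scale > 0),
                noise_sd=ecfg["noise_sd"])
            epochs_by_cond[cond].append(sg.simulate_eeg_epochs(
                n_tr, truth, montage,
                rng_seed=_child_seed(seed, 200, si,
                                     EEG_CONDITIONS.index(cond)),
                subject_id=sid, condition=cond))

    scfg = itpc_mod.SpectralConfig(
        frequencies_of_interest=tuple(cfg["itpc"]["freqs"]))
    maps = itpc_mod.equalized_evoked_itpc(
        epochs_by_cond, scfg, n_resamples=cfg["itpc"]["n_resamples"],
        seed=_child_seed(seed, 201))
    clusters = {}
    for fi, f in enumerate(scfg.frequencies_of_interest):
        clusters[f] = itpc_mod.spatial_cluster_test(
            maps["mismatched"].evoked[:, :, fi],
            maps["matched"].evoked[:, :, fi], montage,
            n_perm=cfg["itpc"]["n_perm"], p_first=cfg["itpc"]["p_first"],
            max_dist_cm=cfg["itpc"]["max_dist_cm"],
            seed=_child_seed(seed, 202, fi))
    return {"montage": montage, "maps": maps, "clusters": clusters,
            "regions": {3.5: r35, 8.0: r8}, "config": scfg}


# ---------------------------------------------------------------------------
# stage: brain-behavior coupling
# ---------------------------------------------------------------------------

def brain_behavior_stage(behavior_out: dict, eeg_out: dict, cfg: dict) -> dict:
    maps = eeg_out["maps"]
    freqs = list(maps["mismatched"].freqs)
    out = {}
    for f, psi_key in ((3.5, "psi_mismatched"), (3.5, "psi_matched"),
                       (8.0, "psi_mismatched"), (8.0, "psi_matched")):
        fi = freqs.index(f)
        sig = [c for c in eeg_out["clusters"].get(f, []) if c.significant]
        region = (sig[0].member_indices if sig
                  else np.asarray(eeg_out["regions"][f], int))
        target = "mismatched" if psi_key == "psi_mismatched" else "matched"
        evoked = {c: maps[c].evoked[:, :, fi] for c in maps}
        others = [c for c in EEG_CONDITIONS
                  if c not in ("mismatched", "matched")]
        nitpc = bb.normalized_itpc(evoked, target=target, region=region,
                                   others=others)
        res = bb.correlate(nitpc, behavior_out[psi_key])
        out[(f, target)] = {"nitpc": nitpc, "psi": behavior_out[psi_key],
                            "region": region, "result": res}
    return out


# ---------------------------------------------------------------------------
# full run + outputs
# ---------------------------------------------------------------------------

def run_full_pipeline(cfg: dict | None = None, seed: int = 0,
                      out_dir: str | Path | None = None) -> dict:
    """Execute every stage; optionally write the results bundle to disk."""
    cfg = cfg or default_config()
    t0 = time.time()
    try:
        cohort = simulate_cohort(cfg, seed)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineStageError("synthgen", str(e)) from e
    behavior_out = behavioral_stage(cohort, cfg)
    spectra_out = spectra_stage(behavior_out, cfg, seed)
    eeg_out = eeg_stage(cohort, behavior_out, cfg, seed)
    coupling = brain_behavior_stage(behavior_out, eeg_out, cfg)

    bundle = {"config": cfg, "seed": seed, "cohort": cohort,
              "behavior": behavior_out, "spectra": spectra_out,
              "eeg": eeg_out, "brain_behavior": coupling,
              "elapsed_s": time.time() - t0}
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg, seed = bundle["config"], bundle["seed"]
    b = bundle["behavior"]

    summary = pd.DataFrame({
        "subject": b["subject_ids"],
        "psi_congruent": b["psi_congruent"],
        "psi_mismatched": b["psi_mismatched"],
        "psi_matched": b["psi_matched"],
        "attention_index": b["attention_index"]})
    summary.to_csv(out / "subject_summary.tsv", sep="\t", index=False)
    b["stats_table"].to_csv(out / "per_bin_stats.tsv", sep="\t", index=False)

    for cond, res in bundle["spectra"].items():
        spec_mod.write_spectrum_tsv(res["spectrum"],
                                    out / f"spectrum_{cond}.tsv")
        spec_mod.write_clusters_json(res["clusters"],
                                     out / f"clusters_{cond}.json")

    maps = bundle["eeg"]["maps"]
    itpc_mod.write_itpc_tsv(maps["mismatched"], out / "itpc_mismatched.tsv")
    itpc_mod.write_itpc_tsv(maps["matched"], out / "itpc_matched.tsv")
    for f, cl in bundle["eeg"]["clusters"].items():
        itpc_mod.write_spatial_clusters_json(
            cl, out / f"spatial_clusters_{f}hz.json")

    rows = []
    for (f, cond), rec in bundle["brain_behavior"].items():
        r = rec["result"]
        rows.append({"freq_hz": f, "condition": cond,
                     "r": r.r, "p": r.p, "df": r.df, "n": r.n})
    pd.DataFrame(rows).to_csv(out / "brain_behavior.tsv", sep="\t", index=False)

    manifest = {"config_hash": config_hash(cfg), "seed": seed,
                "version": _package_version(),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "elapsed_s": bundle["elapsed_s"],
                "outputs": sorted(p.name for p in out.iterdir())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _package_version() -> str:
    from . import __version__
    return __version__
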