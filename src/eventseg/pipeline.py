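"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

A :class:`RunConfig` fully determines a run: the master seed spawns one
independent substream per participant and stage, so two runs with the same
config produce byte-identical tables. Stages write tidy CSV/JSON tables
under the output directory plus a run manifest recording the config, seeds,
and package version.

Default problem sizes are scaled for a laptop-class single-CPU run (a few
simulated participants, a few hundred parsing trials, 250 Hz); the full
paradigm sizes (1,400 exposure + 1,200 parsing trials, 1,000 Hz) are plain
config overrides.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__, behavior as bh, erp, montage
from . import graph_sequences as gs
from . import multivariate as mv
from . import pattern_similarity as ps
from . import preprocessing as pp
from . import synthetic as syn

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_participants: int = 4
    exposure_trials: int = 300
    parsing_trials: int = 450
    spec: syn.GenerativeSpec = None  # type: ignore[assignment]
    outdir: str = "results"
    pooled_pca: bool = False          # fit-once PCA inside cross-validation
    do_filter: bool = True
    do_ica: bool = False
    ica_components: int = 20
    freqs_n: int = 30
    freq_min: float = 4.0
    freq_max: float = 100.0
    tfr_decim: int = 4
    stages: list[str] = ["simulate", "preprocess", "analyze", "report"]

    def model_post_init(self, __context):
        if self.spec is None:
            self.spec = syn.GenerativeSpec()

    def freqs(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.freq_min), np.log10(self.freq_max), self.freqs_n
        )


def validate_config(raw: dict) -> list[str]:
    """Return diagnostics (empty when the config is valid)."""
    try:
        RunConfig(**raw)
    except ValidationError as err:
        return [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
    return []


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _participant_seed(master: int, participant: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(participant, stage))


def simulate_participant(config: RunConfig, p: int) -> dict:
    """Sequences, behavior, posttest, and the parsing-phase EEG recording."""
    spec = config.spec
    rng = lambda stage: np.random.default_rng(_participant_seed(config.seed, p, stage))
    graph = gs.build_graph(seed=int(rng(0).integers(2**31)))
    exposure = gs.build_exposure_sequence(
        graph, n_trials=config.exposure_trials, seed=rng(1)
    )
    parsing = gs.build_parsing_sequence(
        graph, n_trials=config.parsing_trials, seed=rng(2)
    )
    out = {
        "participant": p,
        "graph": graph,
        "exposure": exposure,
        "parsing": parsing,
        "exposure_behavior": syn.simulate_behavior(exposure, spec, rng(3)),
        "parsing_behavior": syn.simulate_behavior(parsing, spec, rng(4)),
        "posttest": syn.simulate_posttest(gs.build_posttest(graph, rng(5)), spec, rng(6)),
        "session": syn.simulate_session(parsing, spec, rng(7), graph=graph),
    }
    return out


def preprocess_participant(config: RunConfig, sim: dict) -> dict:
    """Filter, (optionally) remove ocular components, epoch, reject, decompose."""
    sess: syn.SimulatedSession = sim["session"]
    data = sess.data
    if config.do_filter:
        # at sampling rates below 450 Hz the 200 Hz low-pass is inherent
        h_freq = 200.0 if sess.sfreq > 450.0 else None
        data = pp.filter_continuous(data, sess.sfreq, h_freq=h_freq)
    if config.do_ica:
        data, _ = pp.remove_ocular_components(
            data, sess.ch_names, montage.EOG_CHANNELS,
            n_components=config.ica_components, seed=config.seed + sim["participant"],
        )
    scalp = montage.scalp_channels(config.spec.montage_name)
    epochs = pp.epoch_and_baseline(
        data, sess.sfreq, sess.onsets, sess.ch_names, metadata=sess.trials
    )
    # analyses use scalp channels only
    scalp_ix = [epochs.ch_names.index(c) for c in scalp]
    epochs.data = epochs.data[:, scalp_ix, :]
    epochs.ch_names = scalp
    pp.reject_artifacts(epochs)
    retained = epochs.retained()
    power_tr = pp.spectral_power(
        retained, freqs=config.freqs(), decim=config.tfr_decim
    )
    z_tr = pp.zscore_features(power_tr)
    avg = pp.SpectralPower(
        power=power_tr.power.astype(np.float64).mean(axis=3),
        freqs=power_tr.freqs, ch_names=power_tr.ch_names,
        metadata=power_tr.metadata,
    )
    z_avg = pp.zscore_features(avg)
    return {"epochs": epochs, "retained": retained, "z_time": z_tr, "z_avg": z_avg}


def analyze_participant(config: RunConfig, sim: dict, prep: dict) -> dict:
    """All within-participant analyses; returns a nested result dict."""
    rng = np.random.default_rng(
        _participant_seed(config.seed, sim["participant"], 8)
    )
    res: dict = {"participant": sim["participant"]}
    graph = sim["graph"]
    retained: pp.EpochArray = prep["retained"]
    z_avg: pp.SpectralPower = prep["z_avg"]
    z_time: pp.SpectralPower = prep["z_time"]

    # --- behavior ---
    res["rotation"] = bh.rotation_summary(sim["exposure_behavior"])
    res["parsing"] = bh.parsing_summary(sim["parsing_behavior"])
    res["posttest_pct"] = bh.posttest_score(sim["posttest"])

    # --- ERP ---
    res["p300"] = erp.condition_means(retained).to_dict()
    res["early_window"] = erp.condition_means(
        retained, window=erp.EARLY_WINDOW
    ).to_dict()

    # --- PCA topography ---
    X, feat_index = pp.features_matrix(z_avg)
    space, scores = mv.pca_select(X, seed=rng, feature_index=feat_index)
    res["n_components"] = space.n_components
    res["pcspace"] = space
    res["pc_scores"] = scores

    # --- novel vs learned classification ---
    labels = z_avg.metadata["transition_label"].to_numpy()
    mask = np.isin(labels, [gs.NOVEL, gs.LEARNED])
    try:
        dec = mv.classify_conditions(
            X[mask], labels[mask], pooled_pca=config.pooled_pca, seed=rng
        )
        res["auc_novel_learned"] = dec.auc
        # importance from a decoder fit on the full (PCA-reduced) data
        sp2, sc2 = mv.pca_select(X[mask], seed=rng, feature_index=feat_index)
        clf = mv._fit_logistic(sc2, (labels[mask] == gs.NOVEL).astype(int), 1.0)
        imp = mv.haufe_importance(sc2, clf.coef_, space=sp2,
                                  n_channels=len(z_avg.ch_names))
        res["importance"] = mv.aggregate_importance(
            imp.channel_frequency, z_avg.ch_names, z_avg.freqs
        )
        pz = erp.window_amplitude(retained)
        uni = mv.univariate_classifier(pz.to_numpy()[mask], labels[mask], seed=rng)
        res["auc_pz"] = uni.auc
    except ValueError as err:
        logger.info("participant %s: classification skipped (%s)",
                    sim["participant"], err)
        res["auc_novel_learned"] = np.nan
        res["auc_pz"] = np.nan

    # --- predictive decoding ---
    pred = mv.predictive_decode(z_time, graph)
    res["predictive"] = pred
    res["predictive_auc"] = pred.whole_epoch_auc
    res["predictive_windows"] = pred.window_auc
    res["early_late"] = mv.early_late_split(pred.trial_table)
    pre = mv.predictive_decode(z_time, graph, test_on="preboundary")
    res["preboundary_auc"] = pre.whole_epoch_auc

    # --- pattern similarity ---
    pairs = ps.find_pairs(
        retained.metadata, sim["parsing_behavior"], graph
    )
    if len(pairs):
        sim_table = ps.pair_similarity(scores, pairs)
        res["similarity"] = ps.condition_summary(sim_table).to_dict()
    else:
        res["similarity"] = {}
    res["boundary_item"] = ps.boundary_item_similarity(
        scores, retained.metadata, graph, seed=rng
    )
    return res


def group_report(config: RunConfig, participants: list[dict]) -> dict:
    """Aggregate participant results into the group-level summary."""
    report: dict = {"n_participants": len(participants)}

    parse = pd.DataFrame(
        [
            {r["condition"]: r["parse_pct"] for _, r in p["parsing"].iterrows()}
            for p in participants
        ]
    )
    report["parse_pct_mean"] = parse.mean().to_dict()
    rts = pd.DataFrame(
        [
            {r["condition"]: r["rt_ms"] for _, r in p["parsing"].iterrows()}
            for p in participants
        ]
    )
    report["parse_rt_mean"] = rts.mean().to_dict()
    report["posttest_mean_pct"] = float(
        np.mean([p["posttest_pct"] for p in participants])
    )

    p300 = pd.DataFrame([p["p300"] for p in participants])
    report["p300_mean"] = p300.mean().to_dict()
    # sphericity corrections need at least 3 complete participants
    if len(p300.dropna()) >= 3 and p300.shape[1] == 3:
        report["p300_anova"] = [
            r.as_row() for r in erp.condition_contrasts(p300)
        ]

    aucs = [p["auc_novel_learned"] for p in participants]
    report["auc_novel_learned_mean"] = float(np.nanmean(aucs))
    report["auc_pz_mean"] = float(np.nanmean([p["auc_pz"] for p in participants]))
    report["predictive_auc_mean"] = float(
        np.nanmean([p["predictive_auc"] for p in participants])
    )
    report["preboundary_auc_mean"] = float(
        np.nanmean([p["preboundary_auc"] for p in participants])
    )
    el = pd.DataFrame([p["early_late"] for p in participants])
    report["early_auc_mean"] = float(el["early"].mean())
    report["late_auc_mean"] = float(el["late"].mean())

    simdf = pd.DataFrame([p["similarity"] for p in participants])
    report["similarity_mean_z"] = simdf.mean().to_dict()
    bi = pd.DataFrame([p["boundary_item"] for p in participants])
    report["boundary_item_mean_z"] = bi.mean().to_dict()

    win = np.vstack(
        [p["predictive_windows"] for p in participants]
    )
    if len(win) >= 2:
        sig = mv.window_significance(win)
        report["predictive_significant_windows"] = sig["significant"].sum().item()
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    known = {"simulate", "preprocess", "analyze", "report"}
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    if "simulate" not in stages:
        raise ValueError("downstream stages need 'simulate'; nothing to do")
    sims = [simulate_participant(config, p) for p in range(config.n_participants)]
    for sim in sims:
        gs.write_events_tsv(sim["parsing"], out / f"sub-{sim['participant']:02d}_events.tsv")

    if "preprocess" not in stages:
        if "analyze" in stages:
            raise ValueError("'analyze' requires the 'preprocess' stage")
        return {"manifest": manifest}

    results = []
    for sim in sims:
        prep = preprocess_participant(config, sim)
        if "analyze" in stages:
            results.append(analyze_participant(config, sim, prep))

    if "analyze" not in stages:
        return {"manifest": manifest}

    report = group_report(config, results)
    if "report" in stages:
        (out / "summary.json").write_text(
            json.dumps(_to_jsonable(report), indent=1, sort_keys=True)
        )
        win_rows = []
        for p in results:
            for start, auc in zip(
                p["predictive"].window_starts, p["predictive_windows"]
            ):
                win_rows.append(
                    {"participant": p["participant"],
                     "window_start_s": float(start), "auc": float(auc)}
                )
        pd.DataFrame(win_rows).to_csv(out / "predictive_windows.csv", index=False)
        rows = []
        for p in results:
            rows.append(
                {
                    "participant": p["participant"],
                    "posttest_pct": p["posttest_pct"],
                    "auc_novel_learned": p["auc_novel_learned"],
                    "auc_pz": p["auc_pz"],
                    "predictive_auc": p["predictive_auc"],
                    "preboundary_auc": p["preboundary_auc"],
                    "early_auc": p["early_late"].get("early"),
                    "late_auc": p["early_late"].get("late"),
                    "n_components": p["n_components"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "participants.csv", index=False)
    return {"manifest": manifest, "participants": results, "report": report}


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj
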