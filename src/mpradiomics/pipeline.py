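"""Config-driven pipeline orchestration.

A YAML config names either real inputs (NIfTI volumes + atlases + a
participant table) or a synthesis block, plus the stages to run and a seed.
Artifacts are plain TSV/JSON files in the output directory; a run log
records the seed and a hash of the config, and the whole run is a pure
function of (inputs, config, seed).

Stages: ``extract``, ``select``, ``classify``, ``roc``, ``correlate``,
``longitudinal``.  Later stages read the artifacts of earlier ones and fail
with a clear error when an upstream artifact is missing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .classify import ModelSpec, combined_score, evaluate_all, roc_auc, suvr_correlation
from .core import FeatureKey, FeatureMatrix
from .extract import assemble_feature_matrix, modality_feature_block
from .selection import (
    BRANCHES, SelectionConfig, SelectionTally, StabilityResult,
    adjust_covariates, stability_run, stable_overlap,
)
from .simulate import EffectSpec, synth_atlas, synth_feature_cohort, synth_longitudinal, synth_subject_volumes
from .survival import PairedSeries, paired_change_test, survival_records_from_split, km_logrank

log = logging.getLogger(__name__)

KNOWN_STAGES = ("extract", "select", "classify", "roc", "correlate", "longitudinal")

_MODEL_SPECS = {
    "svm_rbf": dict(family="svm", kernel="rbf"),
    "svm_linear": dict(family="svm", kernel="linear"),
    "svm_sigmoid": dict(family="svm", kernel="sigmoid"),
    "rf": dict(family="rf"),
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires {path.name}, produced by the '{produced_by}' stage"
        )
    return path


def _effect_spec(cfg: dict, seed: int) -> EffectSpec:
    keys = (
        "n_cases", "n_controls", "n_planted", "effect_size_d", "signal_family",
        "feature_noise_corr", "block_size", "suvr_link",
    )
    return EffectSpec(seed=seed, **{k: cfg[k] for k in keys if k in cfg})


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run the configured stages; returns the artifact directory."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {KNOWN_STAGES}")

    for stage in stages:
        log.info("stage: %s", stage)
        globals()[f"_stage_{stage}"](config, out, seed)

    (out / "run_log.json").write_text(
        json.dumps({"seed": seed, "config_hash": _config_hash(config), "stages": stages}, indent=2)
        + "\n"
    )
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_extract(config: dict, out: Path, seed: int) -> None:
    syn = config.get("synthesis")
    if syn is None:
        raise ValueError("extract without a synthesis block requires input paths (not configured)")
    tier = syn.get("tier", "features")
    if tier == "features":
        cohort = synth_feature_cohort(int(syn.get("n_features", 2000)), _effect_spec(syn, seed))
        mio.persist_feature_matrix(cohort.features, out / "features.tsv")
        mio.write_subject_table(cohort.records, out / "subjects.tsv")
        (out / "planted_keys.tsv").write_text(
            "".join(k.canonical() + "\n" for k in cohort.planted_keys)
        )
    elif tier == "image":
        shape = tuple(syn.get("shape", (48, 48, 48)))
        n_sub = int(syn.get("n_subjects", 4))
        spec = _effect_spec(syn, seed)
        cortical = synth_atlas(syn.get("n_regions", 116), shape, seed=seed, kind="cortical_atlas")
        tracts = synth_atlas(syn.get("n_tracts", 50), shape, seed=seed + 1, kind="tract_atlas")
        per_subject = {}
        for i in range(n_sub):
            group = i % 2
            vols = synth_subject_volumes(cortical, tracts, group, spec, subject_seed=seed * 10_000 + i)
            per_subject[f"S{i:04d}"] = modality_feature_block(
                structural=vols["structural"], functional=vols["functional"],
                diffusion=vols["diffusion"], cortical_atlas=cortical, tract_atlas=tracts,
            )
        fm = assemble_feature_matrix(per_subject)
        mio.persist_feature_matrix(fm, out / "features.tsv")
    else:
        raise ValueError(f"unknown synthesis tier {tier!r}")


def _load_cohort(out: Path, stage: str):
    fm = mio.read_feature_matrix(_require(out / "features.tsv", stage, "extract"))
    records = mio.read_subject_table(_require(out / "subjects.tsv", stage, "extract"))
    by_id = {r.id: r for r in records}
    labels = np.array([by_id[s].group for s in fm.subjects])
    return fm, records, labels


def _stage_select(config: dict, out: Path, seed: int) -> None:
    fm, records, labels = _load_cohort(out, "select")
    sel_cfg = config.get("selection", {})
    adjusted = adjust_covariates(fm, records)
    by_id = {r.id: r for r in records}
    labels = np.array([by_id[s].group for s in adjusted.subjects])
    cfg = SelectionConfig(seed=seed, **{
        k: sel_cfg[k] for k in ("alpha", "corr_threshold", "top_k_fisher", "top_k_mrmr",
                                 "folds", "repetitions") if k in sel_cfg
    })
    result = stability_run(adjusted, labels, cfg)
    for b in BRANCHES:
        t = result.tallies[b]
        rows = sorted(t.counts.items(), key=lambda kv: (-kv[1], kv[0].sort_tuple()))
        with open(out / f"tally_{b}.tsv", "w") as fh:
            fh.write("feature\tcount\tmax_possible\n")
            for k, c in rows:
                fh.write(f"{k.canonical()}\t{c}\t{t.max_possible}\n")
    report = stable_overlap(result.tallies)
    with open(out / "stable_report.tsv", "w") as fh:
        fh.write("kind\tfeature\tmean_count\n")
        for k in report.stable:
            fh.write(f"stable\t{k.canonical()}\t{report.mean_counts[k]!r}\n")
        for k in report.stable_300:
            fh.write(f"stable_300\t{k.canonical()}\t{report.mean_counts[k]!r}\n")
        for b in BRANCHES:
            for k, c in report.high_frequency[b]:
                fh.write(f"high_frequency_{b}\t{k.canonical()}\t{c}\n")
    np.savetxt(out / "fold_assignments.tsv", result.fold_assignments, fmt="%d", delimiter="\t")
    with open(out / "run_selections.tsv", "w") as fh:
        fh.write("repetition\tfold\tbranch\tfeatures\n")
        for (rep, fold), sel in zip(result.run_folds, result.run_selections):
            for b in BRANCHES:
                keys = ";".join(result.keys[i].canonical() for i in sel[b])
                fh.write(f"{rep}\t{fold}\t{b}\t{keys}\n")
    (out / "adjusted_subjects.tsv").write_text("".join(s + "\n" for s in adjusted.subjects))
    mio.persist_feature_matrix(adjusted, out / "features_adjusted.tsv")


def _load_stability(out: Path, fm: FeatureMatrix, stage: str) -> StabilityResult:
    fold_assignments = np.loadtxt(
        _require(out / "fold_assignments.tsv", stage, "select"), dtype=int, delimiter="\t"
    )
    if fold_assignments.ndim == 1:
        fold_assignments = fold_assignments[None, :]
    df = pd.read_csv(
        _require(out / "run_selections.tsv", stage, "select"), sep="\t",
        keep_default_na=False,
    )
    idx = fm.key_index()
    run_map: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    for row in df.itertuples(index=False):
        cols = (
            np.array([idx[k] for k in row.features.split(";")], dtype=int)
            if row.features else np.array([], dtype=int)
        )
        run_map.setdefault((int(row.repetition), int(row.fold)), {})[row.branch] = cols
    run_folds = sorted(run_map)
    tallies = {}
    max_possible = len(run_folds)
    for b in BRANCHES:
        counts: dict[FeatureKey, int] = {}
        for rf in run_folds:
            for c in run_map[rf].get(b, []):
                counts[fm.keys[c]] = counts.get(fm.keys[c], 0) + 1
        tallies[b] = SelectionTally(branch=b, counts=counts, max_possible=max_possible)
    return StabilityResult(
        tallies=tallies,
        fold_assignments=fold_assignments,
        run_selections=[run_map[rf] for rf in run_folds],
        run_folds=run_folds,
        keys=list(fm.keys),
    )


def _stage_classify(config: dict, out: Path, seed: int) -> None:
    fm = mio.read_feature_matrix(_require(out / "features_adjusted.tsv", "classify", "select"))
    records = mio.read_subject_table(_require(out / "subjects.tsv", "classify", "extract"))
    by_id = {r.id: r for r in records}
    labels = np.array([by_id[s].group for s in fm.subjects])
    stability = _load_stability(out, fm, "classify")
    cls_cfg = config.get("classification", {})
    specs = [
        ModelSpec(seed=seed, **_MODEL_SPECS[name])
        for name in cls_cfg.get("models", ("svm_rbf", "rf"))
    ]
    table = evaluate_all(fm, labels, stability, specs, max_runs=cls_cfg.get("max_runs"))
    with open(out / "classifier_report.tsv", "w") as fh:
        fh.write("dataset\tbranch\tmodel\tmetric\tmean\tsd\tn\n")
        for (ds, branch, model), m in sorted(table.cells.items()):
            for name in ("accuracy", "sensitivity", "specificity"):
                if name + "_mean" in m:
                    fh.write(
                        f"{ds}\t{branch}\t{model}\t{name}\t{m[name + '_mean']!r}"
                        f"\t{m[name + '_sd']!r}\t{m[name + '_n']}\n"
                    )


def _stable_keys(out: Path, stage: str) -> list[FeatureKey]:
    path = _require(out / "stable_report.tsv", stage, "select")
    df = pd.read_csv(path, sep="\t")
    return [FeatureKey.parse(f) for f in df.loc[df["kind"] == "stable", "feature"]]


def _stage_roc(config: dict, out: Path, seed: int) -> None:
    fm, records, labels = _load_cohort(out, "roc")
    keys = _stable_keys(out, "roc")
    rows = []
    for k in keys:
        res = roc_auc(fm.column(k), labels)
        rows.append((k.canonical(), res["auc"], res["auc_oriented"], res["direction"]))
    if len(keys) >= 2:
        comb = combined_score(np.column_stack([fm.column(k) for k in keys]), labels)
        res = roc_auc(comb["score"], labels)
        rows.append(("combined", res["auc"], res["auc_oriented"], res["direction"]))
    with open(out / "roc_report.tsv", "w") as fh:
        fh.write("feature\tauc\tauc_oriented\tdirection\n")
        for name, auc, auc_o, d in rows:
            fh.write(f"{name}\t{auc!r}\t{auc_o!r}\t{d}\n")


def _stage_correlate(config: dict, out: Path, seed: int) -> None:
    fm, records, labels = _load_cohort(out, "correlate")
    keys = _stable_keys(out, "correlate")
    by_id = {r.id: r for r in records}
    suvr = np.array([np.nan if by_id[s].suvr is None else by_id[s].suvr for s in fm.subjects])
    cov = np.array([
        [by_id[s].age, by_id[s].sex, by_id[s].education,
         np.nan if by_id[s].moca is None else by_id[s].moca]
        for s in fm.subjects
    ])
    with open(out / "correlation_report.tsv", "w") as fh:
        fh.write("feature\tr\tp\tr_adjusted\tp_adjusted\tn\n")
        for k in keys:
            res = suvr_correlation(fm.column(k), suvr, cov)
            fh.write(
                f"{k.canonical()}\t{res['r']!r}\t{res['p']!r}"
                f"\t{res['r_adjusted']!r}\t{res['p_adjusted']!r}\t{res['n']}\n"
            )


def _stage_longitudinal(config: dict, out: Path, seed: int) -> None:
    lng = config.get("longitudinal", {})
    data = synth_longitudinal(
        n_subjects=int(lng.get("n_subjects", 37)),
        drift=float(lng.get("drift", -0.5)),
        hazard_model=lng.get("hazard_model", {"type": "loglinear", "beta": -0.7,
                                               "baseline_hazard": 1 / 48.0}),
        seed=seed,
    )
    key = data.drifted_key
    series = [
        PairedSeries(sid, float(b), float(f))
        for sid, b, f in zip(
            data.baseline.subjects, data.baseline.column(key), data.followup.column(key)
        )
    ]
    change = paired_change_test(series)
    recs = survival_records_from_split(
        data.baseline.subjects, data.times, data.events, data.baseline.column(key)
    )
    km = km_logrank(recs)
    n_high = sum(1 for r in recs if r.group == "high")
    with open(out / "longitudinal_report.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"paired_t\t{change['t']!r}\n")
        fh.write(f"paired_df\t{change['df']}\n")
        fh.write(f"paired_p\t{change['p']!r}\n")
        fh.write(f"mean_change\t{change['mean_change']!r}\n")
        fh.write(f"n_high\t{n_high}\n")
        fh.write(f"n_low\t{len(recs) - n_high}\n")
        fh.write(f"logrank_chi_square\t{km['chi_square']!r}\n")
        fh.write(f"logrank_p\t{km['p']!r}\n")
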