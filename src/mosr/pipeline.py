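"""End-to-end experiment orchestration.

Runs the study design over its dataset arms — clinical-only, CRF-only,
combined, CPET time-series (crf_ts) and the scalar-CRF restriction to the
time-series subset (crf_subset) — crossed with the model arms (MOSR,
reference classifiers, threshold clinical scores), under one reproducible
seed schedule: every stage seed is derived deterministically from the master
seed, and the report bundle carries a manifest (config, seeds, input hash)
from which every number is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, evaluation, synthetic
from .expressions import used_features
from .cpet import build_ts_feature_matrix
from .engine import EvolutionConfig, MOSRClassifier
from .evaluation import Partition, Preprocessor, repeated_test_evaluation
from .synthetic import GeneratorConfig, OUTCOME_COLUMN, generate_cohort

__all__ = ["ExperimentSpec", "run_experiment", "load_spec"]

DATASET_ARMS = ("clinical", "crf", "combined", "crf_ts", "crf_subset")
MODEL_ARMS = ("mosr", "lr", "dt", "rf", "lgbm", "xgb", "scores")


@dataclass
class ExperimentSpec:
    dataset_arms: tuple[str, ...] = ("clinical", "crf", "combined")
    model_arms: tuple[str, ...] = ("mosr", "lr")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    split_ratio: float = 0.8
    cv_folds: int = 10
    n_test_runs: int = 10
    test_fraction: float = 0.9
    ts_target_len: int = 100
    grids: dict | None = None
    compute_shap: bool = False
    shap_rows: int = 20
    master_seed: int = 0
    out_dir: str | None = None
    cohort_path: str | None = None      # optional user data instead of generator

    def __post_init__(self):
        unknown = set(self.dataset_arms) - set(DATASET_ARMS)
        if unknown:
            raise ValueError(f"unknown dataset arms {sorted(unknown)}")
        unknown = set(self.model_arms) - set(MODEL_ARMS)
        if unknown:
            raise ValueError(f"unknown model arms {sorted(unknown)}")
        if not self.dataset_arms or not self.model_arms:
            raise ValueError("need at least one dataset arm and one model arm")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _dataset_views(spec: ExperimentSpec, cohort: synthetic.Cohort) -> dict[str, pd.DataFrame]:
    views = {}
    table = cohort.table
    for arm in spec.dataset_arms:
        if arm == "clinical":
            X = cohort.features("clinical")
        elif arm == "crf":
            X = cohort.features("crf")
        elif arm == "combined":
            X = cohort.features()
        elif arm in ("crf_ts", "crf_subset"):
            pids = cohort.ts_patients
            if arm == "crf_subset":
                X = cohort.features("crf").loc[pids]
            else:
                waves = cohort.waveforms()
                X = build_ts_feature_matrix(waves, spec.ts_target_len)
                X = X.loc[pids]
        views[arm] = X
    return views


def _make_partitions(X: pd.DataFrame, y: np.ndarray, ratio: float, seed: int):
    idx_a, idx_b = evaluation.stratified_split(y, ratio, seed)
    train = Partition(X.iloc[idx_a], y[idx_a], role="train")
    test = Partition(X.iloc[idx_b], y[idx_b], role="test")
    return train, test


def _fit_mosr(spec, train: Partition, seed: int) -> MOSRClassifier:
    from dataclasses import replace
    cfg = replace(spec.evolution, seed=seed)
    clf = MOSRClassifier(cfg)
    clf.fit(train.X, train.y)
    return clf


def run_experiment(spec: ExperimentSpec):
    """Execute every dataset x model arm; returns the report bundle dict.

    When ``spec.out_dir`` is set, writes report.json, table2.csv,
    roc_points.csv, pr_points.csv, champion_formulas.txt and (optionally)
    shap_long.csv there.
    """
    t0 = time.time()
    if spec.cohort_path:
        table = pd.read_csv(spec.cohort_path, index_col=0)
        raise NotImplementedError(
            "external cohorts are supported through synthetic.Cohort "
            "construction; see docs")  # pragma: no cover
    cohort = generate_cohort(spec.generator)
    cohort_bytes = cohort.table.to_csv().encode()
    manifest = {
        "master_seed": spec.master_seed,
        "generator": asdict(spec.generator),
        "evolution": asdict(spec.evolution),
        "cohort_sha256": hashlib.sha256(cohort_bytes).hexdigest(),
        "stage_seeds": {},
        "stages": [],
    }
    views = _dataset_views(spec, cohort)
    y_all = pd.Series(cohort.outcome, index=cohort.table.index)

    results: dict[str, dict] = {}
    roc_rows, pr_rows, shap_rows, formulas = [], [], [], {}

    for dataset, X in views.items():
        y = y_all.loc[X.index].to_numpy()
        seed_split = stage_seed(spec.master_seed, f"split:{dataset}")
        manifest["stage_seeds"][f"split:{dataset}"] = seed_split
        train, test = _make_partitions(X, y, spec.split_ratio, seed_split)

        categorical = [c for c in X.columns
                       if cohort.categorical_mask.get(c, False)
                       and not np.issubdtype(X[c].dtype, np.floating)]
        binary = [c for c in X.columns if c not in categorical
                  and set(pd.unique(X[c])) <= {0, 1}]
        prep = Preprocessor(categorical=categorical, binary=binary).fit(train)
        Xtr = prep.transform(train)
        Xte = prep.transform(test)
        ptrain = Partition(Xtr, train.y, role="train")
        ptest = Partition(Xte, test.y, role="test")

        results[dataset] = {}
        for model in spec.model_arms:
            stage = f"{dataset}:{model}"
            seed_m = stage_seed(spec.master_seed, stage)
            manifest["stage_seeds"][stage] = seed_m
            t_stage = time.time()

            if model == "scores":
                results[dataset][model] = _score_arm(
                    spec, cohort, test, seed_m)
                manifest["stages"].append(
                    {"stage": stage, "seconds": round(time.time() - t_stage, 2)})
                continue

            if model == "mosr":
                clf = _fit_mosr(spec, ptrain, seed_m)
                formulas[dataset] = clf.formula_
                predict = clf.predict_proba
            else:
                factory = baselines.classifier_factory(model, seed=seed_m)
                grids = (spec.grids or baselines.DEFAULT_GRIDS)
                best, _ = evaluation.grid_search_cv(
                    factory, grids[model], ptrain, folds=spec.cv_folds,
                    seed=seed_m)
                est = factory(**best).fit(Xtr, ptrain.y.astype(int))
                predict = est.predict_proba
                clf = est

            report = repeated_test_evaluation(
                predict, ptest, n_runs=spec.n_test_runs,
                fraction=spec.test_fraction,
                seed=stage_seed(spec.master_seed, f"eval:{stage}"))
            results[dataset][model] = report.to_dict()

            probs = np.asarray(predict(ptest.X))
            if probs.ndim == 2:
                probs = probs[:, 1]
            from sklearn.metrics import roc_curve
            fpr, tpr, _ = roc_curve(ptest.y, probs)
            roc_rows.append(pd.DataFrame({
                "dataset": dataset, "model": model, "fpr": fpr, "tpr": tpr}))
            pr = evaluation.pr_curve(probs, ptest.y)
            pr["dataset"], pr["model"] = dataset, model
            pr_rows.append(pr)

            if spec.compute_shap and model == "mosr":
                from .attribution import shapley_values
                bg_idx, _ = evaluation.stratified_split(
                    ptrain.y, min(100 / len(ptrain.X), 0.5),
                    seed=stage_seed(spec.master_seed, f"shapbg:{stage}"))
                used = sorted(used_features(clf.champion_.tree))
                cols = used if used else list(Xtr.columns[:5])
                res = shapley_values(
                    lambda df: clf.predict_proba(
                        df.reindex(columns=Xtr.columns, fill_value=0.0))[:, 1],
                    Xte[cols].head(spec.shap_rows), Xtr[cols].head(100),
                    seed=stage_seed(spec.master_seed, f"shap:{stage}"))
                long = res.to_long_frame()
                long["dataset"] = dataset
                shap_rows.append(long)

            manifest["stages"].append(
                {"stage": stage, "seconds": round(time.time() - t_stage, 2)})

    bundle = {
        "manifest": manifest,
        "results": results,
        "champion_formulas": formulas,
        "wall_seconds": round(time.time() - t0, 2),
    }
    if spec.out_dir:
        _write_bundle(spec, bundle, roc_rows, pr_rows, shap_rows)
    return bundle


def _score_arm(spec, cohort, test: Partition, seed: int) -> dict:
    """Threshold clinical-score rules, evaluated on raw feature units."""
    out = {}
    raw = cohort.table.loc[test.X.index]
    for name, rule in baselines.CLINICAL_SCORE_RULES.items():
        feature = baselines.SCORE_FEATURES[name]
        if feature not in raw.columns:
            continue
        values = raw[feature]

        def predict(df, _v=values, _r=rule):
            return baselines.score_predict(_r, _v.loc[df.index]).astype(float)

        report = repeated_test_evaluation(
            predict, test, n_runs=spec.n_test_runs,
            fraction=spec.test_fraction, seed=seed)
        out[name] = report.to_dict()
    return out


def _write_bundle(spec, bundle, roc_rows, pr_rows, shap_rows):
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(bundle, indent=1, default=str))
    rows = []
    for dataset, models in bundle["results"].items():
        for model, rep in models.items():
            if model == "scores":
                for score, srep in rep.items():
                    rows.append(_table2_row(dataset, score, srep))
            else:
                rows.append(_table2_row(dataset, model, rep))
    pd.DataFrame(rows).to_csv(out / "table2.csv", index=False)
    if roc_rows:
        pd.concat(roc_rows, ignore_index=True).to_csv(
            out / "roc_points.csv", index=False)
    if pr_rows:
        pd.concat(pr_rows, ignore_index=True).to_csv(
            out / "pr_points.csv", index=False)
    if shap_rows:
        pd.concat(shap_rows, ignore_index=True).to_csv(
            out / "shap_long.csv", index=False)
    text = "\n".join(f"[{d}] {f}" for d, f in bundle["champion_formulas"].items())
    (out / "champion_formulas.txt").write_text(text + "\n")


def _table2_row(dataset, model, rep):
    row = {"dataset": dataset, "model": model}
    for metric in evaluation.METRICS:
        row[metric] = rep["mean"].get(metric)
        row[f"{metric}_ci"] = rep["ci_halfwidth"].get(metric)
    return row


def load_spec(path) -> ExperimentSpec:
    """Build an :class:`ExperimentSpec` from a YAML config file."""
    import yaml
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "generator" in raw:
        raw["generator"] = GeneratorConfig(**raw["generator"])
    if "evolution" in raw:
        ev = dict(raw["evolution"])
        if "init_depth" in ev:
            ev["init_depth"] = tuple(ev["init_depth"])
        raw["evolution"] = EvolutionConfig(**ev)
    for key in ("dataset_arms", "model_arms"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentSpec(**raw)
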