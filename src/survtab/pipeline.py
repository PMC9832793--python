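"""End-to-end orchestration: simulate/load -> impute -> nested CV ->
five models -> horizon evaluation -> cross-model comparison.

The experiment mirrors a five-model benchmarking design: two regularized
Cox procedures (elastic net; stability-selected features pooled by
Rubin's rules) and three Cox-loss neural networks (feedforward,
dense-block, tab-transformer), all trained and evaluated inside nested
cross-validation on each of the m imputed datasets, with min-max
normalization fitted on training rows only, IPCW concordance and
time-dependent metrics at fixed horizons, subject-level bootstrap CIs,
and a Tukey HSD comparison of Uno's C across models.

All randomness fans out from one master seed through named child
streams, so any stage can be replayed in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cox_models import (
    consensus_candidates,
    coxsf_finalize,
    fit_cox,
    fit_coxnet,
    stability_select,
    tune_coxnet,
)
from .datatypes import SurvivalDataset, child_rng, child_seed
from .deep_survival import (
    NetworkSpec,
    build_densenet,
    build_feedforward,
    build_tabtransformer,
    train_risk_model,
)
from .evaluation import (
    MetricResult,
    bootstrap_ci,
    compare_models,
    harrells_c,
    td_auc,
    td_confusion,
    unos_c,
    youden_cutoff,
)
from .imputation import choose_m, mice_impute, quickpred
from .preprocessing import apply_minmax, fit_minmax, prune_collinear
from .synthetic_data import make_elsa_like

__all__ = ["ExperimentConfig", "desk_config", "nested_splits", "Split",
           "run_experiment", "ExperimentResult"]

_ALL_MODELS = ("coxen", "coxsf", "feedforward", "densenet", "tabtransformer")


@dataclass
class ExperimentConfig:
    """Configuration of a full experiment run."""

    data_path: str | None = None
    preset: str | None = "elsa_like"
    preset_n: int = 5433
    models: tuple[str, ...] = _ALL_MODELS + ("random",)
    m: int | None = None                  # None: choose_m from observed missingness
    mice_iterations: int = 20
    quickpred_min_correlation: float = 0.1
    folds: int = 5
    repeats: int = 2
    split_limit: int | None = None        # evaluate only the first k splits
    horizons: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0)
    bootstrap_B: int = 100
    alpha_grid: tuple[float, ...] = (0.1, 0.5, 0.9)
    lambda_grid: tuple[float, ...] = (0.2, 0.1, 0.05, 0.02, 0.01, 0.005)
    tune_max_datasets: int = 2
    vif_threshold: float = 10.0
    consensus_fractions: tuple[float, ...] = (0.75, 0.9, 1.0)
    network: dict = field(default_factory=dict)       # per-architecture overrides
    uno_tau_quantile: float = 0.95
    td_max_cutoffs: int | None = 80
    bootstrap_td: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model roster is empty")
        unknown = set(self.models) - set(_ALL_MODELS) - {"random"}
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        hz = tuple(float(h) for h in self.horizons)
        if any(h <= 0 for h in hz) or list(hz) != sorted(hz):
            raise ValueError("horizons must be positive and sorted")
        self.horizons = hz

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("models", "horizons", "alpha_grid", "lambda_grid",
                    "consensus_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def desk_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale preset: the full five-model roster at reduced problem size.

    n = 2000 subjects, m = 5 imputations (5 chained-equation sweeps),
    two evaluated splits, networks trained for at most 100 epochs with
    mini-batch risk sets, 50 bootstrap replicates, three horizons.  Sized
    to exercise every stage of the design on a single CPU.
    """
    return ExperimentConfig(
        preset="elsa_like",
        preset_n=2000,
        m=5,
        mice_iterations=5,
        split_limit=2,
        horizons=(4.0, 8.0, 10.0),
        bootstrap_B=50,
        alpha_grid=(0.5, 0.9),
        lambda_grid=(0.1, 0.05, 0.02, 0.01),
        tune_max_datasets=1,
        network={
            "feedforward": {"epochs": 100, "learning_rate": 1e-3,
                            "batch_mode": "risk-set-batched", "batch_size": 512,
                            "gaussian_noise_std": 0.05},
            "densenet": {"epochs": 100, "learning_rate": 1e-3,
                         "batch_mode": "risk-set-batched", "batch_size": 512,
                         "gaussian_noise_std": 0.05},
            "tabtransformer": {"epochs": 16, "learning_rate": 3e-3,
                               "embed_dim": 8, "n_heads": 2,
                               "n_transformer_layers": 1, "dtype": "float32",
                               "batch_mode": "risk-set-batched",
                               "batch_size": 256, "dropout_rate": 0.1,
                               "gaussian_noise_std": 0.05},
        },
        bootstrap_td=False,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    """One train/test index pair; tuning code receives only ``train``."""

    split_id: int
    train: np.ndarray
    test: np.ndarray


def nested_splits(time: np.ndarray, event: np.ndarray, folds: int = 5,
                  repeats: int = 2, seed: int = 0) -> list[Split]:
    """Event-stratified repeated K-fold: repeats x folds (train, test) pairs.

    Each training set holds (folds-1)/folds of the rows; within a repeat
    the test sets partition the data.  Every fold contains events
    (stratified by the event indicator); fewer events than folds is an
    error.
    """
    from sklearn.model_selection import RepeatedStratifiedKFold

    event = np.asarray(event, dtype=int)
    if len(event) < folds:
        raise ValueError("fewer subjects than folds")
    if event.sum() < folds:
        raise ValueError(f"only {int(event.sum())} events: cannot stratify "
                         f"{folds} folds")
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=seed % (2**31 - 1))
    return [Split(split_id=i, train=tr, test=te)
            for i, (tr, te) in enumerate(rskf.split(np.zeros(len(event)), event))]


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    report: pd.DataFrame                  # tidy metric rows
    unos_table: pd.DataFrame              # models x (dataset, split) point values
    comparisons: pd.DataFrame             # Tukey table
    manifest: dict
    coxsf_summary: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report.csv", index=False)
        self.unos_table.to_csv(out / "unos_c.csv")
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        if self.coxsf_summary is not None:
            self.coxsf_summary.to_csv(out / "coxsf_model.csv")
        # record a digest of every written artifact so the manifest can be
        # checked against the files it references
        artifacts = {}
        for f in sorted(out.glob("*.csv")):
            artifacts[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
        self.manifest["artifacts"] = artifacts
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1,
                                                      default=str))


def _load_data(config: ExperimentConfig) -> SurvivalDataset:
    if config.data_path:
        return SurvivalDataset.from_csv(config.data_path)
    if config.preset == "elsa_like":
        return make_elsa_like(child_seed(config.seed, "data"), config.preset_n)
    raise ValueError("config must give data_path or preset='elsa_like'")


def _network_spec(arch: str, config: ExperimentConfig, seed: int) -> NetworkSpec:
    overrides = dict(config.network.get(arch, {}))
    return NetworkSpec(architecture=arch, seed=seed, **overrides)


def _fit_and_score(model: str, t_tr, d_tr, X_train: pd.DataFrame,
                   X_test: pd.DataFrame, t_te, d_te, meta, en_params,
                   coxsf_terms, config: ExperimentConfig, seed: int):
    """Train one roster member on the (normalized) train split.

    Returns (test scores, train scores); the train scores feed the
    Youden cutoff policy for the time-dependent confusion metrics.
    """
    Xtr = X_train.to_numpy(dtype=float)
    Xte = X_test.to_numpy(dtype=float)
    if model == "coxen":
        alpha, lam = en_params
        ds_norm = SurvivalDataset(t_tr, d_tr, X_train.reset_index(drop=True),
                                  list(meta))
        beta = fit_coxnet(ds_norm, alpha=alpha, lam=lam).to_numpy()
        return Xte @ beta, Xtr @ beta
    if model == "coxsf":
        ds_norm = SurvivalDataset(t_tr, d_tr, X_train.reset_index(drop=True),
                                  list(meta))
        fit = fit_cox(ds_norm, terms=coxsf_terms)
        return fit.predict(X_test), fit.predict(X_train)
    if model == "random":
        rng = child_rng(seed, "random-scores")
        return rng.standard_normal(len(Xte)), rng.standard_normal(len(Xtr))
    spec = _network_spec(model, config, seed)
    if model == "feedforward":
        net = build_feedforward(spec, Xtr.shape[1])
    elif model == "densenet":
        net = build_densenet(spec, Xtr.shape[1])
    else:
        net = build_tabtransformer(spec, list(meta))
    trained = train_risk_model(net, (Xtr, t_tr, d_tr), (Xte, t_te, d_te), spec)
    return trained.predict(Xte), trained.predict(Xtr)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline and return the evaluation report."""
    t_start = _time.time()
    timings: dict[str, float] = {}
    seed = config.seed

    def tick(stage: str, t0: float) -> float:
        timings[stage] = round(_time.time() - t0, 2)
        return _time.time()

    t0 = _time.time()
    dataset = _load_data(config)
    t0 = tick("data", t0)

    # ---- imputation (once, on the full predictor set) --------------------
    max_missing_pct = float(dataset.features.isna().mean().max() * 100)
    m = config.m if config.m is not None else choose_m(max_missing_pct)
    if dataset.features.isna().any().any():
        pm = quickpred(dataset, min_correlation=config.quickpred_min_correlation)
        stack = mice_impute(dataset, pm, m=m, iterations=config.mice_iterations,
                            seed=child_seed(seed, "mice"))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = mice_impute(dataset, quickpred(dataset), m=m, iterations=0,
                                seed=child_seed(seed, "mice"))
    t0 = tick("imputation", t0)

    # ---- multicollinearity pruning on the first completed dataset --------
    vif_report = prune_collinear(stack.datasets[0].features,
                                 threshold=config.vif_threshold)
    retained = vif_report.retained
    meta = [mt for mt in dataset.feature_meta if mt.name in retained]
    t0 = tick("vif", t0)

    # ---- nested CV splits ------------------------------------------------
    splits = nested_splits(dataset.time, dataset.event, config.folds,
                           config.repeats, child_seed(seed, "splits"))
    eval_splits = splits[: config.split_limit] if config.split_limit else splits

    # ---- elastic-net tuning on training rows only ------------------------
    en_params = None
    tuning = None
    if "coxen" in config.models or "coxsf" in config.models:
        tuning = tune_coxnet(stack, config.alpha_grid, config.lambda_grid,
                             folds=config.folds, repeats=1,
                             seed=child_seed(seed, "tune"), terms=retained,
                             row_idx=eval_splits[0].train,
                             max_datasets=config.tune_max_datasets)
        en_params = (tuning.alpha, tuning.lam)
    t0 = tick("tuning", t0)

    # ---- stability selection + pooled model (CoxSf) ----------------------
    coxsf_terms = None
    coxsf_summary = None
    if "coxsf" in config.models:
        profile = stability_select(stack, alpha=en_params[0], lam=en_params[1],
                                   n_splits=config.folds * config.repeats,
                                   seed=child_seed(seed, "stability"),
                                   terms=retained)
        thresholds = sorted({max(1, int(np.ceil(f * m)))
                             for f in config.consensus_fractions})
        cands = consensus_candidates(profile, thresholds)
        lists = []
        for t in sorted(cands, reverse=True):
            c = cands[t]
            if c and (not lists or set(c) != set(lists[-1])):
                lists.append(c)
        if not lists:
            # nothing passed anywhere: fall back to the most stable features
            top = profile.dataset_pass.sort_values(ascending=False).head(8)
            lists = [list(top.index)]
        if len(lists) >= 2:
            pooled, coxsf_terms, _comp = coxsf_finalize(
                stack, lists, row_idx=None)
        else:
            coxsf_terms = lists[0]
            from .cox_models import pool_cox_fits
            pooled = pool_cox_fits([fit_cox(d, terms=coxsf_terms) for d in stack])
        coxsf_summary = pooled.summary()
    t0 = tick("coxsf", t0)

    # ---- per (model, imputed dataset, split): fit, score, evaluate -------
    rows: list[dict] = []
    unos_points: dict[str, dict[tuple[int, int], float]] = {
        mdl: {} for mdl in config.models}
    for di, ds_imp in enumerate(stack):
        feats = ds_imp.features[retained]
        for sp in eval_splits:
            stats_ = fit_minmax(feats.iloc[sp.train], split_id=f"d{di}s{sp.split_id}")
            Xtr = apply_minmax(feats.iloc[sp.train], stats_)
            Xte = apply_minmax(feats.iloc[sp.test], stats_)
            t_te, d_te = dataset.time[sp.test], dataset.event[sp.test]
            t_tr, d_tr = dataset.time[sp.train], dataset.event[sp.train]
            tau = float(np.quantile(t_te, config.uno_tau_quantile))
            for mdl in config.models:
                mseed = child_seed(seed, "model", mdl, di, sp.split_id)
                scores, train_scores = _fit_and_score(
                    mdl, t_tr, d_tr, Xtr, Xte, t_te, d_te, meta, en_params,
                    coxsf_terms, config, mseed)
                rows.extend(_evaluate_scores(
                    mdl, di, sp, scores, t_te, d_te, train_scores, t_tr, d_tr,
                    tau, config, mseed))
                c_point = unos_c(scores, t_te, d_te, tau=tau)
                unos_points[mdl][(di, sp.split_id)] = c_point
    t0 = tick("models", t0)

    report = pd.DataFrame(rows)
    unos_table = pd.DataFrame(unos_points)
    unos_table.index = pd.MultiIndex.from_tuples(unos_table.index,
                                                 names=["dataset", "split"])
    comparisons = compare_models(unos_table[[m_ for m_ in config.models]])
    t0 = tick("evaluation", t0)

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "package_version": _pkg_version,
        "versions": _versions(),
        "n_subjects": dataset.n,
        "n_features": len(dataset.feature_names),
        "n_retained_features": len(retained),
        "vif_removed": [s[0] for s in vif_report.steps if s[2]],
        "max_missing_pct": max_missing_pct,
        "m": m,
        "en_alpha": None if en_params is None else en_params[0],
        "en_lambda": None if en_params is None else en_params[1],
        "coxsf_terms": coxsf_terms,
        "n_eval_splits": len(eval_splits),
        "timings_s": timings,
        "total_s": round(_time.time() - t_start, 2),
        "seed": seed,
    }
    return ExperimentResult(report=report, unos_table=unos_table,
                            comparisons=comparisons, manifest=manifest,
                            coxsf_summary=coxsf_summary)


def _evaluate_scores(mdl, di, sp, scores, t_te, d_te, train_scores, t_tr, d_tr,
                     tau, config, mseed) -> list[dict]:
    """Uno's C plus time-dependent metrics (with bootstrap CIs) on one split."""
    rows = []
    B = config.bootstrap_B

    def add(mr: MetricResult, extra=None):
        row = {"model": mdl, "dataset": di, "split": sp.split_id,
               "metric": mr.name, "horizon": mr.horizon, "value": mr.value,
               "ci_low": mr.ci_low, "ci_high": mr.ci_high}
        if extra:
            row.update(extra)
        rows.append(row)

    def uno_closure(idx):
        return unos_c(scores[idx], t_te[idx], d_te[idx], tau=tau)

    add(bootstrap_ci(uno_closure, len(scores), B=B,
                     seed=child_seed(mseed, "boot-uno"), name="unos_c"))
    rows.append({"model": mdl, "dataset": di, "split": sp.split_id,
                 "metric": "harrells_c", "horizon": None,
                 "value": harrells_c(scores, t_te, d_te),
                 "ci_low": np.nan, "ci_high": np.nan})
    for h in config.horizons:
        try:
            cutoff = None
            mc = config.td_max_cutoffs

            def auc_closure(idx):
                return td_auc(scores[idx], t_te[idx], d_te[idx], h,
                              max_cutoffs=mc)

            if config.bootstrap_td:
                add(bootstrap_ci(auc_closure, len(scores), B=B,
                                 seed=child_seed(mseed, "boot-auc", h),
                                 name="td_auc", horizon=h))
            else:
                add(MetricResult("td_auc", auc_closure(np.arange(len(scores))),
                                 np.nan, np.nan, horizon=h))
        except ValueError as err:
            rows.append({"model": mdl, "dataset": di, "split": sp.split_id,
                         "metric": "td_auc", "horizon": h, "value": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "note": str(err)})
            continue
        # cutoff chosen on the training split at the same horizon (Youden),
        # then applied to the test split
        try:
            cutoff = youden_cutoff(train_scores, t_tr, d_tr, h,
                                   max_cutoffs=config.td_max_cutoffs)
            conf = td_confusion(scores, t_te, d_te, h, cutoff)
        except ValueError as err:
            rows.append({"model": mdl, "dataset": di, "split": sp.split_id,
                         "metric": "td_confusion", "horizon": h,
                         "value": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "note": str(err)})
            continue
        for key in ("sensitivity", "specificity", "balanced_accuracy"):
            rows.append({"model": mdl, "dataset": di, "split": sp.split_id,
                         "metric": key, "horizon": h, "value": conf[key],
                         "ci_low": np.nan, "ci_high": np.nan,
                         "cutoff": conf["cutoff"]})
    return rows


def _versions() -> dict:
    import numpy, pandas, scipy, sklearn

    return {"numpy": numpy.__version__, "pandas": pandas.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__}
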