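"""End-to-end orchestration: DE filtering -> sparse CCA -> classifier -> metrics.

The three stages can be toggled independently, which yields the ablation
variants studied alongside the full model:

========  ======================  ============================
variant   optimizations           classifier
========  ======================  ============================
DSCCN1    none                    attention network
DSCCN2    DE only                 attention network
DSCCN3    SCCA only               attention network
DSCCN4    DE + SCCA               external plugin (e.g. boosted trees)
DSCCN5    DE + SCCA               network without attention
DSCCN     DE + SCCA               attention network
========  ======================  ============================

The DE stage compares the healthy and disease cohorts per omics; the
classifier is trained on the subtyped (disease) samples only.  These are in
general different sample sets, so the dataset format carries both a ``group``
and a ``subtype`` column, either of which may be missing for a sample.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .attention_net import AttentionNetClassifier, NetConfig
from .datasets import OmicsDataset, load_dataset
from .diff_expr import DifferentialExpressionSelector
from .evaluation import EvalReport, evaluate_predictions
from .scca import grid_search_gamma, select_top_features

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_dataset",
           "VARIANTS"]

logger = logging.getLogger("dsccn")

#: variant name -> (enable_de, enable_scca, classifier)
VARIANTS = {
    "DSCCN1": (False, False, "dnn"),
    "DSCCN2": (True, False, "dnn"),
    "DSCCN3": (False, True, "dnn"),
    "DSCCN4": (True, True, "plugin"),
    "DSCCN5": (True, True, "dnn_no_attention"),
    "DSCCN": (True, True, "dnn"),
}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a pipeline run."""

    enable_de: bool = True
    enable_scca: bool = True
    classifier: str = "dnn"  # dnn | dnn_no_attention | plugin
    plugin_factory: object = None
    # DE thresholds
    de_p_thresh: float = 0.01
    de_fc_low: float = 0.5
    de_fc_high: float = 1.0
    # SCCA
    gamma1_grid: tuple = (0.01, 0.1, 1.0)
    gamma2_grid: tuple = (0.01, 0.1, 1.0)
    m1: int = 200
    n1: int = 200
    scca_train_frac: float = 0.7
    scca_weight_mode: str = "reweighted"
    scca_max_iter: int = 50
    edges: object = None
    # classifier / evaluation
    net: NetConfig = field(default_factory=NetConfig)
    holdout_frac: float = 0.3
    seed: int = 0

    @classmethod
    def variant(cls, name: str, **overrides) -> "PipelineConfig":
        """Build the config of a named ablation variant."""
        try:
            de, scca, clf = VARIANTS[name]
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
            ) from None
        return cls(enable_de=de, enable_scca=scca, classifier=clf, **overrides)


@dataclass
class PipelineResult:
    report: EvalReport
    artifacts: dict
    manifest: dict


def _log_stage(name: str, t0: float, **info) -> dict:
    entry = {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info}
    logger.info("%s", json.dumps(entry))
    return entry


def run_pipeline(
    config: PipelineConfig, dataset: OmicsDataset, outdir=None
) -> PipelineResult:
    """Execute the enabled stages in order and evaluate on a held-out split."""
    artifacts: dict = {}
    manifest: dict = {"config": _config_dict(config), "stages": []}
    ds_cls = dataset.disease_view()
    if ds_cls.n_samples == 0:
        raise ValueError("dataset has no subtyped samples to classify")
    X_feat = ds_cls.X
    Y_feat = ds_cls.Y

    if config.enable_de:
        t0 = time.perf_counter()
        for omics, mat in (("x", X_feat), ("y", Y_feat)):
            case, ctrl = dataset.de_groups(omics)
            if len(ctrl) < 2:
                raise ValueError(
                    "DE stage needs a healthy cohort with at least 2 samples"
                )
            sel = DifferentialExpressionSelector(
                p_thresh=config.de_p_thresh,
                fc_low=config.de_fc_low,
                fc_high=config.de_fc_high,
            )
            full = pd.concat([case, ctrl])
            groups = ["disease"] * len(case) + ["healthy"] * len(ctrl)
            sel.fit(full, groups)
            if sel.support_mask_.sum() == 0:
                raise ValueError(
                    f"no features survive the DE filter on omics {omics!r}; "
                    "consider relaxing p_thresh / fold-change thresholds"
                )
            artifacts[f"de_{omics}"] = sel.result_
            if omics == "x":
                X_feat = sel.transform(X_feat)
            else:
                Y_feat = sel.transform(Y_feat)
        manifest["stages"].append(
            _log_stage("de", t0, n_x=X_feat.shape[1], n_y=Y_feat.shape[1])
        )

    if config.enable_scca:
        t0 = time.perf_counter()
        rng = np.random.default_rng(config.seed)
        n = X_feat.shape[0]
        perm = rng.permutation(n)
        n_train = max(int(round(config.scca_train_frac * n)), 2)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        g1, g2, est, gamma_results = grid_search_gamma(
            X_feat.values,
            Y_feat.values,
            config.gamma1_grid,
            config.gamma2_grid,
            train_idx,
            test_idx,
            edges=config.edges,
            weight_mode=config.scca_weight_mode,
            max_iter=config.scca_max_iter,
        )
        if est.degenerate_:
            raise ValueError(
                "SCCA returned an all-zero canonical weight vector "
                f"(gamma1={g1}, gamma2={g2}); objective history: "
                f"{est.objective_history_[-3:]}"
            )
        m1 = min(config.m1, X_feat.shape[1])
        n1 = min(config.n1, Y_feat.shape[1])
        selection = select_top_features(
            est.u_, est.v_, m1, n1, X_feat.values, Y_feat.values
        )
        artifacts["scca"] = {
            "estimator": est,
            "gamma1": g1,
            "gamma2": g2,
            "gamma_results": gamma_results,
            "selection": selection,
            "x_features": list(X_feat.columns[selection.idx_u]),
            "y_features": list(Y_feat.columns[selection.idx_v]),
        }
        X_feat = X_feat.iloc[:, selection.idx_u]
        Y_feat = Y_feat.iloc[:, selection.idx_v]
        manifest["stages"].append(
            _log_stage(
                "scca", t0, gamma1=g1, gamma2=g2,
                corr_train=est.corr_train_, m1=m1, n1=n1,
            )
        )

    t0 = time.perf_counter()
    y = ds_cls.subtype.astype(str).values
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=config.holdout_frac,
        stratify=y,
        random_state=config.seed % (2**32),
    )
    views_train = [X_feat.values[idx_train], Y_feat.values[idx_train]]
    views_test = [X_feat.values[idx_test], Y_feat.values[idx_test]]

    if config.classifier in ("dnn", "dnn_no_attention"):
        net_cfg = replace(
            config.net,
            attention=config.classifier == "dnn",
            n_classes=len(np.unique(y)),
            seed=config.seed,
        )
        model = AttentionNetClassifier(
            n_modules=net_cfg.n_modules,
            module_dim=net_cfg.module_dim,
            hidden_sizes=net_cfg.hidden_sizes,
            activation=net_cfg.activation,
            attention=net_cfg.attention,
            learning_rate=net_cfg.learning_rate,
            weight_decay=net_cfg.weight_decay,
            patience=net_cfg.patience,
            max_epochs=net_cfg.max_epochs,
            batch_size=net_cfg.batch_size,
            val_fraction=net_cfg.val_fraction,
            fusion=net_cfg.fusion,
            seed=config.seed,
        )
        model.fit(views_train, y[idx_train])
        y_pred = model.predict(views_test)
        proba = model.predict_proba(views_test)
    elif config.classifier == "plugin":
        if config.plugin_factory is None:
            raise ValueError(
                "classifier='plugin' requires a plugin_factory returning an "
                "object with fit/predict on concatenated feature matrices"
            )
        model = config.plugin_factory()
        Ztr = np.hstack(views_train)
        Zte = np.hstack(views_test)
        model.fit(Ztr, y[idx_train])
        y_pred = np.asarray(model.predict(Zte))
        proba = (
            model.predict_proba(Zte) if hasattr(model, "predict_proba") else None
        )
    else:
        raise ValueError(f"unknown classifier {config.classifier!r}")

    labels = sorted(np.unique(y))
    scores = None
    if proba is not None and len(labels) == 2:
        scores = np.asarray(proba)[:, 1]
    report = evaluate_predictions(y[idx_test], y_pred, labels=labels, scores=scores)
    artifacts["model"] = model
    artifacts["holdout"] = {"train_idx": idx_train, "test_idx": idx_test}
    manifest["stages"].append(
        _log_stage(
            "classify", t0, classifier=config.classifier,
            accuracy=report.accuracy, f1_macro=report.f1_macro,
        )
    )

    if outdir is not None:
        _write_artifacts(outdir, artifacts, manifest, report)
    return PipelineResult(report=report, artifacts=artifacts, manifest=manifest)


def _config_dict(config: PipelineConfig) -> dict:
    out = {}
    for k, v in vars(config).items():
        if isinstance(v, NetConfig):
            out[k] = vars(v).copy()
            out[k] = {kk: (list(vv) if isinstance(vv, tuple) else vv)
                      for kk, vv in vars(v).items()}
        elif isinstance(v, tuple):
            out[k] = list(v)
        elif callable(v):
            out[k] = getattr(v, "__name__", str(v))
        else:
            out[k] = v
    return out


def _write_artifacts(outdir, artifacts, manifest, report) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("de_x", "de_y"):
        if key in artifacts:
            artifacts[key].to_frame().to_csv(outdir / f"{key}.tsv", sep="\t",
                                             index=False)
    if "scca" in artifacts:
        sc = artifacts["scca"]
        est = sc["estimator"]
        pd.DataFrame(
            {"feature_id": sc["x_features"],
             "weight": est.u_[sc["selection"].idx_u]}
        ).to_csv(outdir / "scca_u_selected.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"feature_id": sc["y_features"],
             "weight": est.v_[sc["selection"].idx_v]}
        ).to_csv(outdir / "scca_v_selected.tsv", sep="\t", index=False)
    model = artifacts.get("model")
    if isinstance(model, AttentionNetClassifier):
        model.save(outdir / "model.npz")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
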