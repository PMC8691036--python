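"""Reproducible experiment protocols around the classifier.

Three protocols are provided, mirroring the robustness and ablation
analyses this kind of classifier is validated with:

* :func:`resampling_repeats` — retrain several times varying *only* the
  seed of the reference-set resampling and record the held-out accuracy
  spread (robustness of the similarity measurement to the choice of
  references);
* :func:`interval_resampling` — re-draw the reference sets every n epochs
  during training and track held-out accuracy per epoch;
* :func:`compare_with_baseline` — class-similarity network vs the plain
  CNN on the same features, for each dense-head variant (z2, z3, z2+z3).

All protocols fit the feature model and scaler once on the training data
and evaluate single models with the class-mean reference convention, so
differences between rows come only from the factor under study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline import predict_baseline, train_baseline
from .features import FeatureScaler, featurize_many, fit_feature_model
from .network import ClassSimilarityModel, NetworkConfig, train_model
from .sequence_io import SequenceRecord


@dataclass
class PreparedData:
    """Featurized, scaled training and evaluation matrices."""

    X: np.ndarray
    y: np.ndarray  # 1 = positive (lncRNA convention)
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    X_eval: np.ndarray
    y_eval: np.ndarray


def prepare(
    train_pos: Sequence[SequenceRecord],
    train_neg: Sequence[SequenceRecord],
    eval_records: Sequence[SequenceRecord],
    positive_label: str = "lncRNA",
) -> PreparedData:
    """Fit features on training data and scale both splits."""
    fm = fit_feature_model(train_mRNA=train_neg, train_lncRNA=train_pos)
    Fpos = featurize_many(train_pos, fm)
    Fneg = featurize_many(train_neg, fm)
    fm.scaler = FeatureScaler.fit(np.vstack([Fpos, Fneg]))
    Spos = fm.scaler.transform(Fpos)
    Sneg = fm.scaler.transform(Fneg)
    X = np.vstack([Spos, Sneg])
    y = np.concatenate([np.ones(len(Spos), int), np.zeros(len(Sneg), int)])
    X_eval = fm.scaler.transform(featurize_many(eval_records, fm))
    y_eval = np.array([1 if r.label == positive_label else 0 for r in eval_records])
    return PreparedData(X=X, y=y, mean_pos=Spos.mean(axis=0),
                        mean_neg=Sneg.mean(axis=0), X_eval=X_eval, y_eval=y_eval)


def _model_predictions(model: ClassSimilarityModel, data: PreparedData) -> np.ndarray:
    n = data.X_eval.shape[0]
    out = model.forward(
        data.X_eval,
        np.tile(data.mean_pos, (n, 1)),
        np.tile(data.mean_neg, (n, 1)),
        train=False,
    )
    if model.config.target_convention == "[1,0]":
        return (out[:, 0] >= out[:, 1]).astype(int)
    return (out[:, 1] >= out[:, 0]).astype(int)


def _scores_row(y_eval: np.ndarray, pred: np.ndarray) -> dict:
    pos, neg = y_eval == 1, y_eval == 0
    return {
        "acc": float(np.mean(pred == y_eval)),
        "acc_pos": float(np.mean(pred[pos] == 1)) if pos.any() else float("nan"),
        "acc_neg": float(np.mean(pred[neg] == 0)) if neg.any() else float("nan"),
    }


def resampling_repeats(
    data: PreparedData,
    config: NetworkConfig,
    n_repeats: int = 10,
    base_ref_seed: int = 0,
) -> pd.DataFrame:
    """Held-out accuracy of models differing only in reference resampling.

    Weight initialisation, dropout and batch shuffling stay on
    ``config.seed``; repeat r uses reference seed ``base_ref_seed + r``.
    """
    rows = []
    for r in range(n_repeats):
        model = train_model(data.X, data.y, config, seed=config.seed,
                            ref_seed=base_ref_seed + r)
        rows.append({"repeat": r, **_scores_row(data.y_eval, _model_predictions(model, data))})
    return pd.DataFrame(rows)


def interval_resampling(
    data: PreparedData,
    config: NetworkConfig,
    intervals: Sequence[int] = (5, 10, 15, 20),
) -> pd.DataFrame:
    """Accuracy per epoch when references are re-drawn every n epochs."""
    rows = []
    for n in intervals:
        cfg = replace(config, resample_every=int(n))

        def record(model, epoch, n=n):
            rows.append({
                "interval": n, "epoch": epoch,
                "acc": _scores_row(data.y_eval, _model_predictions(model, data))["acc"],
            })

        train_model(data.X, data.y, cfg, seed=cfg.seed, epoch_callback=record)
    return pd.DataFrame(rows)


def compare_with_baseline(
    data: PreparedData,
    config: NetworkConfig,
    variants: Sequence[str] = ("z2", "z3", "z2+z3"),
    n_runs: int = 5,
) -> pd.DataFrame:
    """Class-similarity network vs plain CNN per dense-head variant."""
    rows = []
    for variant in variants:
        cfg = replace(config, dense_variant=variant)
        for run in range(n_runs):
            seed = cfg.seed + run
            cs = train_model(data.X, data.y, cfg, seed=seed)
            rows.append({
                "model": "class_similarity", "variant": variant, "run": run,
                **_scores_row(data.y_eval, _model_predictions(cs, data)),
            })
            bl = train_baseline(data.X, data.y, cfg, seed=seed)
            rows.append({
                "model": "baseline_cnn", "variant": variant, "run": run,
                **_scores_row(data.y_eval, predict_baseline(bl, data.X_eval)),
            })
    return pd.DataFrame(rows)
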