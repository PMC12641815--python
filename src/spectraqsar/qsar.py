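"""Gradient-boosted QSAR models per property × descriptor kind.

Each property gets one train/validation/test split shared across every
descriptor kind, so per-compound comparisons are like-for-like.  Models are
XGBoost regressors with fixed, seeded hyperparameters; performance is
reported as RMSE and MAE over the pooled validation+test rows (the default
evaluation pool), together with per-compound absolute errors for map
overlays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from xgboost import XGBRegressor

from .descriptors import DESCRIPTOR_KINDS, DescriptorMatrix, build_matrix
from .spectra_io import Dataset

__all__ = [
    "SplitSpec",
    "Hyperparameters",
    "QSARModel",
    "PerformanceReport",
    "split_dataset",
    "train_qsar",
    "evaluate",
    "compare_descriptors",
    "error_overlay",
]


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    evaluation_pool: str = "valid_plus_test"  # or "test_only"

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all split fractions must be > 0")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.evaluation_pool not in ("valid_plus_test", "test_only"):
            raise ValueError(f"unknown evaluation pool {self.evaluation_pool!r}")


@dataclass(frozen=True)
class Hyperparameters:
    n_estimators: int = 300
    max_depth: int = 6
    learning_rate: float = 0.1
    subsample: float = 0.8
    seed: int = 0


@dataclass
class QSARModel:
    descriptor_kind: str
    property_name: str
    booster: XGBRegressor
    hyperparameters: Hyperparameters
    feature_names: list[str]
    train_ids: list[str]

    def predict(self, matrix: DescriptorMatrix, ids: Sequence[str]) -> np.ndarray:
        if matrix.feature_names != self.feature_names:
            raise ValueError("matrix feature schema differs from training schema")
        return self.booster.predict(matrix.rows_for(list(ids)))


@dataclass
class PerformanceReport:
    property_name: str
    descriptor_kind: str
    rmse: float
    mae: float
    per_compound: dict[str, tuple[float, float, float]]  # id -> (true, pred, |err|)
    n_train: int
    n_eval: int

    def r2(self) -> float:
        truth = np.array([t for t, _, _ in self.per_compound.values()])
        pred = np.array([p for _, p, _ in self.per_compound.values()])
        ss_res = float(((truth - pred) ** 2).sum())
        ss_tot = float(((truth - truth.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot


def _largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = sorted(
        range(len(fractions)), key=lambda i: exact[i] - sizes[i], reverse=True
    )
    for i in range(n - sum(sizes)):
        sizes[remainders[i % len(fractions)]] += 1
    return sizes


def split_dataset(
    dataset: Dataset, spec: SplitSpec, property_name: str | None = None
) -> tuple[list[str], list[str], list[str]]:
    """Seeded uniform-random partition with largest-remainder rounding.

    Only records carrying ``property_name`` participate when it is given.
    """
    ids = [
        r.compound_id
        for r in dataset
        if property_name is None or property_name in r.properties
    ]
    if not ids:
        raise ValueError("no eligible records to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_train, n_valid, n_test = _largest_remainder_sizes(len(ids), spec.fractions)
    if min(n_train, n_valid, n_test) == 0:
        raise ValueError(f"split of {len(ids)} records leaves an empty part")
    train = shuffled[:n_train]
    valid = shuffled[n_train : n_train + n_valid]
    test = shuffled[n_train + n_valid :]
    return train, valid, test


def labels_for(dataset: Dataset, property_name: str) -> dict[str, float]:
    return {
        r.compound_id: r.properties[property_name]
        for r in dataset
        if property_name in r.properties
    }


def train_qsar(
    matrix: DescriptorMatrix,
    labels: Mapping[str, float],
    train_ids: Sequence[str],
    property_name: str,
    hyperparameters: Hyperparameters | None = None,
) -> QSARModel:
    """Fit a seeded XGBoost regressor on the training rows.

    Analytical matrices are expected *unstandardized* — per-feature monotone
    rescaling does not change tree splits, so standardization is reserved
    for the embedding workflow.
    """
    hp = hyperparameters or Hyperparameters()
    train_ids = list(train_ids)
    if len(train_ids) < 20:
        raise ValueError("need at least 20 training rows")
    y = np.array([labels[i] for i in train_ids], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite training labels")
    X = matrix.rows_for(train_ids)
    booster = XGBRegressor(
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        learning_rate=hp.learning_rate,
        subsample=hp.subsample,
        random_state=hp.seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    booster.fit(X, y)
    return QSARModel(
        descriptor_kind=matrix.descriptor_kind,
        property_name=property_name,
        booster=booster,
        hyperparameters=hp,
        feature_names=list(matrix.feature_names),
        train_ids=train_ids,
    )


def evaluate(
    model: QSARModel,
    matrix: DescriptorMatrix,
    labels: Mapping[str, float],
    eval_ids: Sequence[str],
) -> PerformanceReport:
    """RMSE/MAE and per-compound absolute errors over the evaluation pool."""
    eval_ids = list(eval_ids)
    if not eval_ids:
        raise ValueError("empty evaluation pool")
    overlap = set(eval_ids) & set(model.train_ids)
    if overlap:
        raise ValueError(f"evaluation ids overlap training ids: {sorted(overlap)[:5]}")
    pred = model.predict(matrix, eval_ids)
    truth = np.array([labels[i] for i in eval_ids], dtype=float)
    err = truth - pred
    return PerformanceReport(
        property_name=model.property_name,
        descriptor_kind=model.descriptor_kind,
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        per_compound={
            i: (float(t), float(p), float(abs(t - p)))
            for i, t, p in zip(eval_ids, truth, pred)
        },
        n_train=len(model.train_ids),
        n_eval=len(eval_ids),
    )


def evaluation_pool(
    split: tuple[list[str], list[str], list[str]], spec: SplitSpec
) -> list[str]:
    _, valid, test = split
    return valid + test if spec.evaluation_pool == "valid_plus_test" else list(test)


def compare_descriptors(
    dataset: Dataset,
    properties: Sequence[str],
    kinds: Sequence[str] = DESCRIPTOR_KINDS,
    spec: SplitSpec | None = None,
    hyperparameters: Hyperparameters | None = None,
    return_reports: bool = False,
):
    """RMSE table (rows = properties, columns = descriptor kinds).

    One split per property, shared across kinds; splits are verified
    identical by id comparison before each fit.
    """
    spec = spec or SplitSpec()
    matrices = {kind: build_matrix(dataset, kind) for kind in kinds}
    table = pd.DataFrame(index=list(properties), columns=list(kinds), dtype=float)
    reports: dict[tuple[str, str], PerformanceReport] = {}
    for prop in properties:
        labels = labels_for(dataset, prop)
        split = split_dataset(dataset, spec, property_name=prop)
        pool = evaluation_pool(split, spec)
        reference_train = split[0]
        for kind in kinds:
            matrix = matrices[kind]
            # descriptor-specific drops (no SMILES / no RI) may shrink the
            # shared split; ordering and membership are otherwise identical
            available = set(matrix.compound_ids)
            train = [i for i in reference_train if i in available]
            eval_ids = [i for i in pool if i in available]
            model = train_qsar(matrix, labels, train, prop, hyperparameters)
            report = evaluate(model, matrix, labels, eval_ids)
            table.loc[prop, kind] = report.rmse
            reports[(prop, kind)] = report
    return (table, reports) if return_reports else table


def error_overlay(embedding: pd.DataFrame, report: PerformanceReport) -> pd.DataFrame:
    """Join map coordinates with per-compound absolute errors (Fig-3 style)."""
    rows = []
    for cid, (truth, pred, abs_err) in report.per_compound.items():
        if cid not in embedding.index:
            continue
        y1, y2 = embedding.loc[cid].iloc[0], embedding.loc[cid].iloc[1]
        rows.append(
            {
                "compound_id": cid,
                "y1": float(y1),
                "y2": float(y2),
                "absolute_error": abs_err,
            }
        )
    n_missing = len(report.per_compound) - len(rows)
    if n_missing:
        logging.getLogger(__name__).info(
            "error_overlay: %d evaluation ids missing from embedding", n_missing
        )
    return pd.DataFrame(rows)
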