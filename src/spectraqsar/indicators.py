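"""GC-EI-MS summary indicators and ordinary-least-squares benchmarks.

Six scalars summarize a binned spectrum: the intensity-weighted center of
m/z (``center_mz``), the m/z of the highest-intensity bin (``maxint_mz``,
ties broken toward the lowest m/z), the highest occupied m/z (``max_mz``),
the intensity-weighted standard deviation of m/z (``sd_mz``), the number of
nonzero bins (``bin_num``), and the retention index.  OLS models on single
indicators or on all six give interpretable baselines against which the
full-spectrum boosted model is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import AnalyticalDescriptor, bin_spectrum, build_analytical_matrix
from .qsar import Hyperparameters, SplitSpec, evaluate, evaluation_pool, split_dataset, train_qsar
from .spectra_io import Dataset

logger = logging.getLogger(__name__)

INDICATOR_NAMES = ("center_mz", "maxint_mz", "max_mz", "sd_mz", "bin_num", "ri")


@dataclass(frozen=True)
class IndicatorVector:
    center_mz: float
    maxint_mz: float
    max_mz: float
    sd_mz: float
    bin_num: int
    ri: float | None = None

    def __post_init__(self) -> None:
        if self.sd_mz < 0:
            raise ValueError("sd_mz must be >= 0")
        if self.maxint_mz > self.max_mz:
            raise ValueError("maxint_mz cannot exceed max_mz")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in INDICATOR_NAMES}


@dataclass
class RegressionReport:
    property_name: str
    variables: tuple[str, ...]
    coefficients: np.ndarray  # aligned with variables
    intercept: float
    rmse: float
    mae: float
    n_train: int
    n_eval: int


def compute_indicators(
    descriptor: AnalyticalDescriptor, weighted: bool = True
) -> IndicatorVector:
    """The six spectral summary statistics of a binned spectrum.

    ``weighted`` uses intensity weighting for center_mz/sd_mz (default);
    the unweighted variant treats every occupied bin equally.  All values
    are invariant to uniform intensity rescaling.
    """
    inten = descriptor.bin_intensities
    mz = descriptor.bin_mz
    nz = inten > 0
    if not np.any(nz):
        raise ValueError("all-zero spectrum")
    w = inten[nz] if weighted else np.ones(int(nz.sum()))
    w = w / w.sum()
    center = float(w @ mz[nz])
    sd = float(np.sqrt(w @ (mz[nz] - center) ** 2))
    maxint = float(mz[np.argmax(inten)])  # argmax -> lowest m/z on ties
    return IndicatorVector(
        center_mz=center,
        maxint_mz=maxint,
        max_mz=float(mz[nz][-1]),
        sd_mz=sd,
        bin_num=int(nz.sum()),
        ri=descriptor.ri,
    )


def indicator_table(
    dataset: Dataset, weighted: bool = True, base_peak_normalize: bool = True
) -> pd.DataFrame:
    """Per-compound indicator frame (indexed by compound_id)."""
    lo, hi = dataset.global_mz_range
    rows = {}
    for rec in dataset:
        desc = bin_spectrum(rec, lo, hi, base_peak_normalize=base_peak_normalize)
        rows[rec.compound_id] = compute_indicators(desc, weighted=weighted).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound_id"
    return df


def fit_ols(
    table: pd.DataFrame,
    variables: Sequence[str],
    labels: Mapping[str, float],
    train_ids: Sequence[str],
    eval_ids: Sequence[str],
    property_name: str = "",
) -> RegressionReport:
    """OLS via QR least squares, evaluated on the held-out pool.

    Rows missing any selected variable (e.g. RI absent) are dropped with a
    logged count.  A rank-deficient design raises, naming the collinear
    columns.
    """
    variables = tuple(variables)
    unknown = set(variables) - set(table.columns)
    if unknown:
        raise ValueError(f"unknown indicator variables {sorted(unknown)}")

    def design(ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
        sub = table.loc[list(ids), list(variables)]
        keep = sub.notna().all(axis=1)
        if (~keep).sum():
            logger.info(
                "fit_ols: dropped %d rows with missing %s", int((~keep).sum()), variables
            )
        kept_ids = [i for i, k in zip(ids, keep) if k]
        X = sub[keep].to_numpy(dtype=float)
        y = np.array([labels[i] for i in kept_ids], dtype=float)
        return np.hstack([np.ones((X.shape[0], 1)), X]), y, kept_ids

    X_train, y_train, kept_train = design(train_ids)
    if X_train.shape[0] <= len(variables) + 1:
        raise ValueError("too few training rows for the variable count")
    rank = np.linalg.matrix_rank(X_train)
    if rank < X_train.shape[1]:
        # name columns whose removal restores full column rank
        collinear = [
            variables[j - 1]
            for j in range(1, X_train.shape[1])
            if np.linalg.matrix_rank(np.delete(X_train, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X_train, y_train, rcond=None)

    X_eval, y_eval, _ = design(eval_ids)
    if X_eval.shape[0] == 0:
        raise ValueError("empty evaluation pool after missing-value drops")
    resid = y_eval - X_eval @ beta
    return RegressionReport(
        property_name=property_name,
        variables=variables,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        n_train=len(kept_train),
        n_eval=int(X_eval.shape[0]),
    )


def indicator_comparison(
    dataset: Dataset,
    properties: Sequence[str],
    spec: SplitSpec | None = None,
    single_variables: Sequence[str] = INDICATOR_NAMES,
    include_boosted: bool = True,
    hyperparameters: Hyperparameters | None = None,
) -> pd.DataFrame:
    """Table-2-style RMSE comparison.

    Columns: the full analytical boosted model, the without-RI boosted
    model, the all-six-variable OLS, and each single-variable OLS; rows are
    properties.  Splits are shared with the boosted models per property.
    """
    spec = spec or SplitSpec()
    table = indicator_table(dataset)
    columns = (
        (["detective_qsar", "detective_qsar_no_ri"] if include_boosted else [])
        + ["all_six"]
        + [f"ols_{v}" for v in single_variables]
    )
    out = pd.DataFrame(index=list(properties), columns=columns, dtype=float)
    if include_boosted:
        m_full = build_analytical_matrix(dataset, include_ri=True)
        m_nori = build_analytical_matrix(dataset, include_ri=False)
    for prop in properties:
        labels = {
            r.compound_id: r.properties[prop] for r in dataset if prop in r.properties
        }
        split = split_dataset(dataset, spec, property_name=prop)
        train, pool = split[0], evaluation_pool(split, spec)
        if include_boosted:
            for col, matrix in (
                ("detective_qsar", m_full),
                ("detective_qsar_no_ri", m_nori),
            ):
                avail = set(matrix.compound_ids)
                model = train_qsar(
                    matrix,
                    labels,
                    [i for i in train if i in avail],
                    prop,
                    hyperparameters,
                )
                report = evaluate(
                    model, matrix, labels, [i for i in pool if i in avail]
                )
                out.loc[prop, col] = report.rmse
        out.loc[prop, "all_six"] = fit_ols(
            table, INDICATOR_NAMES, labels, train, pool, prop
        ).rmse
        for var in single_variables:
            out.loc[prop, f"ols_{var}"] = fit_ols(
                table, (var,), labels, train, pool, prop
            ).rmse
    return out
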