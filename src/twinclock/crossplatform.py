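"""Signature transfer across microarray platforms and repeated k-fold evaluation.

A signature extracted on one platform carries its gene list — not its
coefficients — to a target dataset: probes are matched by gene symbol, and
when several target probes share a symbol the one with the highest average
expression is kept.  The transferred gene list is then re-tuned by fitting
ridge regression on the target platform and evaluated by repeated 10-fold
cross-validation (one Pearson R per repeat, computed on the pooled
out-of-fold predictions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UNKNOWN_SYMBOL, ExpressionMatrix, PipelineConfig, substream
from .signature import RidgeModel, Signature, _pearson, ridge_fit, ridge_predict

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Repeated k-fold cross-validation summary: one Pearson R per repeat."""

    r_values: np.ndarray
    folds: int
    repeats: int
    seed: int

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, float)
        if len(self.r_values) != self.repeats:
            raise ValueError("one R per repeat required")
        if ((self.r_values < -1 - 1e-12) | (self.r_values > 1 + 1e-12)).any():
            raise ValueError("correlation outside [-1, 1]")

    @property
    def mean(self) -> float:
        return float(self.r_values.mean())

    @property
    def sd(self) -> float:
        return float(self.r_values.std(ddof=1)) if len(self.r_values) > 1 else 0.0


def map_signature(signature: Signature, target: ExpressionMatrix) -> Signature:
    """Map a signature onto a different platform by gene symbol.

    For every signature symbol present in the target annotation, keep the
    target probe with the highest average expression across target samples
    (ties broken by probe id).  Symbols absent from the target are dropped
    with a logged list.  The returned reduced signature carries no fitted
    model — coefficients are re-tuned on the target platform.
    """
    means = target.values.mean(axis=1)
    by_symbol: dict[str, list[str]] = {}
    for probe, sym in target.annotation.items():
        if sym != UNKNOWN_SYMBOL:
            by_symbol.setdefault(sym, []).append(probe)
    probes: list[str] = []
    symbols: list[str] = []
    dropped: list[str] = []
    seen: set[str] = set()
    for sym in signature.symbols:
        if sym in seen:
            continue
        seen.add(sym)
        candidates = by_symbol.get(sym)
        if not candidates:
            dropped.append(sym)
            continue
        best = max(sorted(candidates), key=lambda p: (means[p], ))
        probes.append(best)
        symbols.append(sym)
    if dropped:
        log.info("map_signature: %d symbol(s) absent from target: %s", len(dropped), dropped[:20])
    if not probes:
        raise ValueError("no signature symbol is present on the target platform")
    log.info("map_signature: reduced signature size %d (from %d symbols)", len(probes), len(seen))
    return Signature(
        probes=probes,
        symbols=symbols,
        model=None,
        provenance={"mapped_from": list(signature.probes), "dropped_symbols": dropped},
    )


def _batch_columns(batch, samples) -> np.ndarray:
    labels = pd.Series(list(batch), index=samples) if not isinstance(batch, pd.Series) else batch
    dummies = pd.get_dummies(labels.loc[samples], drop_first=True, dtype=float)
    return dummies.to_numpy()


def _design(matrix: ExpressionMatrix, probes, samples, batch) -> np.ndarray:
    X = matrix.values.loc[list(probes), list(samples)].T.to_numpy(float)
    if batch is not None:
        X = np.hstack([X, _batch_columns(batch, list(samples))])
    return X


def _single_cv_r(X: np.ndarray, y: np.ndarray, k: float, folds: int, rng) -> float:
    """One random k-fold partition; Pearson R on pooled out-of-fold predictions."""
    n = len(y)
    perm = rng.permutation(n)
    assignments = np.array_split(perm, folds)
    preds = np.empty(n)
    for held in assignments:
        if len(held) < 1:
            raise ValueError("a fold has no samples")
        train = np.setdiff1d(perm, held)
        model = ridge_fit(X[train], y[train], k)
        preds[held] = ridge_predict(model, X[held])
    return _pearson(preds, y)


def repeated_kfold_cv(
    matrix: ExpressionMatrix,
    ages,
    probes,
    config: PipelineConfig,
    batch=None,
    repeats: int | None = None,
    folds: int | None = None,
) -> CVResult:
    """Repeated random k-fold cross-validation of a ridge age model.

    Every repeat draws a fresh random partition of the samples into
    ``folds`` folds, fits ridge (parameter ``config.ridge_k``) on all folds
    but one, pools the held-out predictions, and records one Pearson R
    between pooled predictions and true ages.  Optional ``batch`` labels are
    appended to the predictors as 0/1 indicator columns.
    """
    folds = config.cv_folds if folds is None else folds
    repeats = config.cv_repeats if repeats is None else repeats
    ages = pd.Series(ages) if not isinstance(ages, pd.Series) else ages
    samples = list(ages.index)
    probes = list(probes)
    missing = [p for p in probes if p not in matrix.values.index]
    if missing:
        raise KeyError(f"probe(s) not in matrix: {missing[:10]}")
    if folds > len(samples):
        raise ValueError(f"folds ({folds}) exceed sample count ({len(samples)})")
    X = _design(matrix, probes, samples, batch)
    y = ages.to_numpy(float)
    rng = substream(config.seed, 3)
    log.info("repeated_kfold_cv: %d repeats of %d-fold CV, seed %d", repeats, folds, config.seed)
    rs = np.array([_single_cv_r(X, y, config.ridge_k, folds, rng) for _ in range(repeats)])
    return CVResult(r_values=rs, folds=folds, repeats=repeats, seed=config.seed)


def fit_without_cv(
    matrix: ExpressionMatrix, ages, probes, config: PipelineConfig, batch=None
) -> float:
    """Resubstitution Pearson R: ridge fitted and evaluated on the full dataset.

    This is the optimistic no-cross-validation figure; prefer
    :func:`repeated_kfold_cv` for honest estimates.
    """
    ages = pd.Series(ages) if not isinstance(ages, pd.Series) else ages
    samples = list(ages.index)
    X = _design(matrix, list(probes), samples, batch)
    y = ages.to_numpy(float)
    model = ridge_fit(X, y, config.ridge_k)
    r = _pearson(ridge_predict(model, X), y)
    log.info("fit_without_cv: resubstitution R = %.4f (optimistic)", r)
    return r
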