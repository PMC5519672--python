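"""Empirical random-signature null model.

The significance yardstick for a candidate age signature: draw many probe
subsets of matched size uniformly at random, evaluate each exactly as the
candidate was evaluated (twin-split fit/validate, or one 10-fold CV per
draw for singleton cohorts), and rank the candidate's validation R against
the resulting empirical distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossplatform import _design, _single_cv_r
from .io import ExpressionMatrix, PipelineConfig, TwinCohort, substream
from .signature import _pearson, ridge_fit, ridge_predict

log = logging.getLogger(__name__)

PROTOCOLS = ("twin-split", "repeated-kfold")


@dataclass
class NullDistribution:
    """Empirical distribution of validation correlations for random signatures."""

    r_values: np.ndarray
    protocol: str
    seed: int
    size: int

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, float)
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if ((self.r_values < -1 - 1e-12) | (self.r_values > 1 + 1e-12)).any():
            raise ValueError("correlation outside [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.r_values)

    @property
    def mean(self) -> float:
        return float(self.r_values.mean())

    @property
    def sd(self) -> float:
        return float(self.r_values.std(ddof=1)) if self.n > 1 else 0.0


def random_signature_null(
    matrix: ExpressionMatrix,
    cohort_or_ages,
    size: int,
    n_iter: int,
    protocol: str,
    config: PipelineConfig,
    split: tuple[list[str], list[str]] | None = None,
    folds: int | None = None,
) -> NullDistribution:
    """Validation R distribution over ``n_iter`` random signatures of ``size`` probes.

    ``twin-split`` protocol (paired cohorts): each draw reuses the candidate
    signature's couple ``split``, fits ridge on the training half and records
    Pearson R on the validation half.  ``repeated-kfold`` protocol (singleton
    cohorts, ``cohort_or_ages`` = ages): each draw runs one random k-fold CV
    and records the pooled out-of-fold R.  Probe subsets are drawn uniformly
    without replacement within each draw; the whole run is seed-deterministic.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    probe_ids = np.asarray(matrix.probe_ids)
    if size > len(probe_ids):
        raise ValueError(f"signature size {size} exceeds probe count {len(probe_ids)}")
    if size < 1 or n_iter < 1:
        raise ValueError("size and n_iter must be >= 1")
    rng = substream(config.seed, 1 if protocol == "twin-split" else 2)
    log.info(
        "random_signature_null: %d draws of %d probes, protocol %s, seed %d",
        n_iter,
        size,
        protocol,
        config.seed,
    )

    rs = np.empty(n_iter)
    if protocol == "twin-split":
        if not isinstance(cohort_or_ages, TwinCohort):
            raise TypeError("twin-split protocol requires a TwinCohort")
        if split is None:
            raise ValueError("twin-split protocol requires the candidate's couple split")
        train, val = split
        ages = cohort_or_ages.ages
        y_train = ages[train].to_numpy(float)
        y_val = ages[val].to_numpy(float)
        train_block = matrix.values[train].to_numpy(float).T
        val_block = matrix.values[val].to_numpy(float).T
        index = {p: i for i, p in enumerate(probe_ids)}
        for i in range(n_iter):
            cols = rng.choice(len(probe_ids), size=size, replace=False)
            model = ridge_fit(train_block[:, cols], y_train, config.ridge_k)
            rs[i] = _pearson(ridge_predict(model, val_block[:, cols]), y_val)
    else:
        ages = pd.Series(cohort_or_ages)
        folds = config.cv_folds if folds is None else folds
        if folds > len(ages):
            raise ValueError("folds exceed sample count")
        X_full = matrix.values[list(ages.index)].to_numpy(float).T
        y = ages.to_numpy(float)
        for i in range(n_iter):
            cols = rng.choice(len(probe_ids), size=size, replace=False)
            rs[i] = _single_cv_r(X_full[:, cols], y, config.ridge_k, folds, rng)
    return NullDistribution(r_values=rs, protocol=protocol, seed=config.seed, size=size)


def percentile_rank(null: NullDistribution, observed_r: float) -> tuple[float, int]:
    """Rank an observed R against the null.

    Returns ``(percentile, count_outperforming)`` with the percentile
    defined as 100 x #{R_null < R_obs} / n and the outperforming count as
    #{R_null > R_obs} — strict inequalities, so ties count as neither.
    """
    if null.n == 0:
        raise ValueError("empty null distribution")
    below = int(np.sum(null.r_values < observed_r))
    above = int(np.sum(null.r_values > observed_r))
    return 100.0 * below / null.n, above


def compare_null_means(null: NullDistribution, candidate_r_values) -> dict:
    """Two-sample Student's t-test of candidate repeated-CV R values vs the null."""
    cand = np.asarray(candidate_r_values, float)
    if len(cand) < 2 or null.n < 2:
        raise ValueError("both samples need at least 2 values")
    if np.std(cand) == 0 and np.std(null.r_values) == 0:
        raise ValueError("zero variance in both samples; t-test undefined")
    t, p = stats.ttest_ind(cand, null.r_values)
    return {
        "t": float(t),
        "p": float(p),
        "candidate_mean": float(cand.mean()),
        "null_mean": null.mean,
    }
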