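"""Age-signature extraction by leave-one-couple-out selection and ridge regression.

The extraction procedure:

1. For every leave-one-couple-out fold, compute per-probe divergence on the
   remaining couples, z-score it, and keep probes at least
   ``z_threshold_signature`` SDs below the mean.
2. Split the couples once into two halves (one twin per half), fit a ridge
   regression of age on the selected probes using the training half, and
   validate on the other half.
3. The final signature is the intersection of all per-fold selections,
   minus probes without a gene-symbol annotation; a final ridge model is
   fitted on the training half restricted to those probes.

Ridge fits center and scale predictors to unit sample SD, solve the
penalized normal equations on the standardized scale with parameter k, and
back-transform coefficients to the original expression scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import delta_scores, select_low_divergence, zscore_delta
from .io import UNKNOWN_SYMBOL, ExpressionMatrix, PipelineConfig, TwinCohort, substream

log = logging.getLogger(__name__)


@dataclass
class RidgeModel:
    """Fitted ridge regression of age on expression.

    ``coefficients`` are on the original expression scale (years per log2
    unit); the standardization used during fitting is retained in ``center``
    and ``scale`` so predictions can be formed either way.
    """

    probes: list[str]
    coefficients: np.ndarray
    intercept: float
    k: float
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        self.center = np.asarray(self.center, float)
        self.scale = np.asarray(self.scale, float)
        if len(self.coefficients) != len(self.probes):
            raise ValueError("coefficient count must equal probe count")
        if not self.k >= 0 and not np.isnan(self.k):
            raise ValueError("ridge parameter k must be >= 0")

    @property
    def standardized_coefficients(self) -> np.ndarray:
        return self.coefficients * self.scale


@dataclass
class Signature:
    """Ordered probe list with symbols, fitted model and fold provenance."""

    probes: list[str]
    symbols: list[str]
    model: RidgeModel | None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.probes) != len(self.symbols):
            raise ValueError("probes and symbols must align")
        if UNKNOWN_SYMBOL in self.symbols:
            raise ValueError(f"signature must not contain {UNKNOWN_SYMBOL!r}-symbol probes")

    def __len__(self) -> int:
        return len(self.probes)


def ridge_fit(X, y, k: float, probes=None) -> RidgeModel:
    """Fit ridge regression of ``y`` (ages) on ``X`` (samples-by-probes).

    Predictors are centered and scaled to unit sample SD; on that scale the
    coefficients solve ``(Xs'Xs + kI) beta = Xs'(y - ybar)`` (an ordinary
    least-squares solve when k = 0), then are back-transformed to original
    units with the intercept restored.  Zero-variance predictors are dropped
    with a zero coefficient and a logged warning.
    """
    if isinstance(X, pd.DataFrame):
        if probes is None:
            probes = list(X.columns)
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, float)
        if probes is None:
            probes = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be samples-by-probes aligned with y")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(y).all():
        raise ValueError("ages must be finite")
    if k < 0:
        raise ValueError("ridge parameter k must be >= 0")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    # constant columns can carry a nonzero sd from float summation error
    keep = (X.max(axis=0) - X.min(axis=0)) > 0
    if not keep.all():
        log.warning("ridge_fit: dropping %d zero-variance predictor(s)", int((~keep).sum()))
    ybar = float(y.mean())
    yc = y - ybar
    coef = np.zeros(X.shape[1])
    if keep.any():
        Xs = (X[:, keep] - mu[keep]) / sd[keep]
        if k == 0:
            beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        else:
            m = Xs.shape[1]
            gram = Xs.T @ Xs + k * np.eye(m)
            beta = np.linalg.solve(gram, Xs.T @ yc)
        coef[keep] = beta / sd[keep]
    intercept = ybar - float(mu @ coef)
    scale = np.where(keep, sd, 1.0)
    return RidgeModel(
        probes=list(probes),
        coefficients=coef,
        intercept=intercept,
        k=float(k),
        center=mu,
        scale=scale,
    )


def ridge_predict(model: RidgeModel, X) -> np.ndarray:
    """Predicted ages: intercept + X @ coefficients."""
    if isinstance(X, pd.DataFrame):
        missing = [p for p in model.probes if p not in X.columns]
        if missing:
            raise KeyError(f"missing probe column(s): {missing[:10]}")
        X = X[model.probes].to_numpy(float)
    else:
        X = np.asarray(X, float)
        if X.shape[1] != len(model.probes):
            raise ValueError("X column count does not match model probe count")
    return model.intercept + X @ model.coefficients


def split_couples(cohort: TwinCohort, seed: int) -> tuple[list[str], list[str]]:
    """Randomly assign one member of every couple to each half (seed-deterministic)."""
    if not cohort.paired:
        raise ValueError("split_couples requires a paired cohort")
    rng = np.random.default_rng(seed)
    half_a: list[str] = []
    half_b: list[str] = []
    for cid, s1, s2 in cohort.iter_couples():
        if rng.integers(2) == 0:
            half_a.append(s1)
            half_b.append(s2)
        else:
            half_a.append(s2)
            half_b.append(s1)
    return half_a, half_b


def _pearson(a, b) -> float:
    return float(np.corrcoef(np.asarray(a, float), np.asarray(b, float))[0, 1])


def extract_signature(
    matrix: ExpressionMatrix, cohort: TwinCohort, config: PipelineConfig
) -> Signature:
    """Run the full leave-one-couple-out extraction and return the signature.

    One couple split is drawn per extraction run from ``config.seed``.  In
    each fold the left-out couple contributes to neither the divergence
    computation nor the ridge fit; a per-fold model on the fold's selected
    probes is retained in provenance together with its validation R.  The
    final signature is the intersection of all per-fold selections minus
    unknown-symbol probes, with a final ridge model fitted on the training
    half restricted to the signature.
    """
    if not cohort.paired:
        raise ValueError("extract_signature requires a paired cohort")
    if cohort.n_couples < 3:
        raise ValueError("need at least 3 couples")
    split_seed = int(substream(config.seed, 0).integers(2**31))
    half_a, half_b = split_couples(cohort, split_seed)
    in_a = set(half_a)

    ages = cohort.ages
    folds = []
    selections: list[set[str]] = []
    for cid in cohort.couple_ids:
        sub_cohort = cohort.drop_couples([cid])
        sub_matrix = matrix.subset_samples(sub_cohort.sample_ids)
        scored = zscore_delta(delta_scores(sub_matrix, sub_cohort))
        selected = select_low_divergence(scored, config.z_threshold_signature)
        probes = sorted(selected)
        left_out = set(cohort.couple_members(cid))
        train = [s for s in half_a if s not in left_out]
        val = [s for s in half_b if s not in left_out]
        fold_model = None
        fold_r = np.nan
        if probes:
            fold_model = ridge_fit(matrix.design(probes, train), ages[train], config.ridge_k)
            preds = ridge_predict(fold_model, matrix.design(probes, val))
            fold_r = _pearson(preds, ages[val])
        folds.append(
            {
                "couple_id": cid,
                "selected": frozenset(selected),
                "model": fold_model,
                "validation_r": fold_r,
            }
        )
        selections.append(selected)

    intersection = set.intersection(*selections)
    known = sorted(p for p in intersection if matrix.annotation[p] != UNKNOWN_SYMBOL)
    n_unknown = len(intersection) - len(known)
    if n_unknown:
        log.info("extract_signature: removed %d unknown-symbol probe(s)", n_unknown)
    if not known:
        raise ValueError(
            "empty signature: no annotated probe was selected in every fold; "
            "consider a laxer z threshold"
        )
    final_model = ridge_fit(matrix.design(known, half_a), ages[half_a], config.ridge_k)
    log.info(
        "extract_signature: %d-probe signature from %d folds (split seed %d)",
        len(known),
        len(folds),
        split_seed,
    )
    return Signature(
        probes=known,
        symbols=[matrix.annotation[p] for p in known],
        model=final_model,
        provenance={
            "split": (half_a, half_b),
            "split_seed": split_seed,
            "folds": folds,
            "config": config,
        },
    )


def evaluate_signature(
    signature: Signature,
    matrix: ExpressionMatrix,
    cohort: TwinCohort,
    split: tuple[list[str], list[str]] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pearson R between predicted and true age on the validation half.

    ``split`` defaults to the split recorded in the signature's provenance.
    Returns the correlation and a per-sample table of true and predicted
    ages (for plotting predicted-vs-true age).
    """
    if signature.model is None:
        raise ValueError("signature has no fitted model")
    if split is None:
        split = signature.provenance.get("split")
        if split is None:
            raise ValueError("no split supplied and none recorded in provenance")
    train, val = split
    if set(train) & set(val):
        raise ValueError("training and validation samples overlap")
    if len(val) < 3:
        raise ValueError("need at least 3 validation samples")
    preds = ridge_predict(signature.model, matrix.design(signature.probes, val))
    ages = cohort.ages[val]
    r = _pearson(preds, ages)
    table = pd.DataFrame({"age": ages.to_numpy(), "predicted_age": preds}, index=val)
    return r, table


def rank_signature_genes(signature: Signature) -> pd.DataFrame:
    """Genes ordered by decreasing |ridge coefficient|, ties by probe id.

    The coefficient sign is reported alongside: a positive coefficient marks
    expression rising with age, a negative one falling.
    """
    if signature.model is None:
        raise ValueError("signature has no fitted model")
    coef = dict(zip(signature.model.probes, signature.model.coefficients))
    rows = [
        {
            "probe_id": p,
            "gene_symbol": s,
            "coefficient": float(coef[p]),
            "direction": "up" if coef[p] > 0 else ("down" if coef[p] < 0 else "flat"),
        }
        for p, s in zip(signature.probes, signature.symbols)
    ]
    df = pd.DataFrame(rows)
    df["abs_coefficient"] = df["coefficient"].abs()
    df = df.sort_values(
        ["abs_coefficient", "probe_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.drop(columns="abs_coefficient")
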