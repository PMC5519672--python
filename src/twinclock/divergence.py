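"""Twin-divergence statistics.

Two views of within-couple expression divergence:

* a whole-array view — Pearson correlation R between the two members of each
  monozygotic couple, regressed on age to quantify how concordance erodes
  over the lifespan; and
* a per-probe view — the divergence score

      delta_i = <|g_i^1 - g_i^2|> / sigma_{g_i}

  the mean absolute within-couple difference of probe i over all couples,
  rescaled by the probe's standard deviation over all samples.  Low delta_i
  marks probes whose expression is genetically controlled and insensitive to
  environment — the raw material for an age signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, TwinCohort

log = logging.getLogger(__name__)


@dataclass
class CoupleTrendResult:
    """Per-couple whole-array concordance and its linear trend in age.

    ``couples`` has one row per couple (couple_id index; columns ``age``,
    ``r``); the fit is ordinary least squares of R on age with a classical
    t-based 95% confidence interval on the slope.
    """

    couples: pd.DataFrame
    slope: float
    intercept: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        r = self.couples["r"]
        if ((r < -1 - 1e-12) | (r > 1 + 1e-12)).any():
            raise ValueError("correlation outside [-1, 1]")
        if not self.ci_low <= self.slope <= self.ci_high:
            raise ValueError("slope outside its confidence interval")


@dataclass
class DivergenceResult:
    """Per-probe divergence scores.

    ``scores`` is indexed by probe id with columns ``delta`` (the raw score;
    NaN for zero-variance probes where it is undefined) and ``z`` (the
    z-scored delta over finite entries; NaN until :func:`zscore_delta`).
    """

    scores: pd.DataFrame

    @property
    def delta(self) -> pd.Series:
        return self.scores["delta"]

    @property
    def z(self) -> pd.Series:
        return self.scores["z"]


def couple_correlation_trend(matrix: ExpressionMatrix, cohort: TwinCohort) -> CoupleTrendResult:
    """Whole-array Pearson R per couple, fitted against couple age by OLS.

    Requires a paired cohort with at least 3 couples (for a CI).  A couple
    in which either member has a zero-variance profile has undefined R and
    is a hard error naming the couple.
    """
    if not cohort.paired:
        raise ValueError("couple_correlation_trend requires a paired cohort")
    if cohort.n_couples < 3:
        raise ValueError("need at least 3 couples to fit a slope with a CI")
    rows = []
    for cid, s1, s2 in cohort.iter_couples():
        x = matrix.values[s1].to_numpy(float)
        y = matrix.values[s2].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"couple {cid!r} has a zero-variance member profile; R undefined")
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((cid, cohort.couple_age(cid), r))
    couples = pd.DataFrame(rows, columns=["couple_id", "age", "r"]).set_index("couple_id")
    fit = stats.linregress(couples["age"], couples["r"])
    n = len(couples)
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * fit.stderr if np.isfinite(fit.stderr) else 0.0
    return CoupleTrendResult(
        couples=couples,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        ci_low=float(fit.slope - half),
        ci_high=float(fit.slope + half),
    )


def delta_scores(matrix: ExpressionMatrix, cohort: TwinCohort, ddof: int = 1) -> DivergenceResult:
    """Per-probe twin-divergence score delta_i.

    Numerator: unweighted mean over couples of |g_i^1 - g_i^2|.  Denominator:
    the probe's sample SD (``ddof=1`` by default) over all 2·n_couples
    values.  Probes with zero SD get NaN (score undefined) and are excluded
    from downstream z-scoring; their count is logged.
    """
    if not cohort.paired:
        raise ValueError("delta_scores requires a paired cohort")
    if cohort.n_couples < 2:
        raise ValueError("need at least 2 couples")
    first = [s1 for _, s1, _ in cohort.iter_couples()]
    second = [s2 for _, _, s2 in cohort.iter_couples()]
    a = matrix.values[first].to_numpy(float)
    b = matrix.values[second].to_numpy(float)
    numerator = np.abs(a - b).mean(axis=1)
    all_samples = first + second
    sigma = matrix.values[all_samples].std(axis=1, ddof=ddof).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(sigma > 0, numerator / sigma, np.nan)
    n_zero = int((sigma == 0).sum())
    if n_zero:
        log.info("delta_scores: %d zero-variance probe(s) set to NaN", n_zero)
    scores = pd.DataFrame({"delta": delta, "z": np.nan}, index=matrix.values.index)
    return DivergenceResult(scores)


def zscore_delta(result: DivergenceResult, ddof: int = 1) -> DivergenceResult:
    """Z-score the delta column over finite entries (mean 0, SD 1)."""
    delta = result.delta
    finite = delta[np.isfinite(delta)]
    if len(finite) < 2:
        raise ValueError("need at least 2 finite delta values to z-score")
    sd = finite.std(ddof=ddof)
    if sd == 0:
        raise ValueError("all delta values are equal; z-score undefined")
    z = (delta - finite.mean()) / sd
    scores = result.scores.copy()
    scores["z"] = z
    return DivergenceResult(scores)


def select_low_divergence(result: DivergenceResult, threshold: float) -> set[str]:
    """Probes at least ``threshold`` SDs below the mean divergence (z <= -threshold).

    Non-finite z-scores are never selected.  An empty selection returns an
    empty set with a warning rather than an error.
    """
    z = result.z
    mask = np.isfinite(z) & (z <= -threshold)
    selected = set(result.scores.index[mask])
    if not selected:
        log.warning("select_low_divergence: no probe passes z <= -%g", threshold)
    return selected


def group_difference_test(
    matrix: ExpressionMatrix,
    cohort: TwinCohort,
    probes,
    grouping: str = "sex",
) -> pd.DataFrame:
    """Two-sample t-test per probe between the two levels of ``grouping``.

    Used to check that signature expression does not differ between male and
    female samples.  Returns a DataFrame (probe index) with raw ``p`` and
    Benjamini-Hochberg adjusted ``p_adj`` across the probe set.
    """
    probes = list(probes)
    if grouping not in cohort.samples.columns:
        raise ValueError(f"cohort has no {grouping!r} column")
    labels = cohort.samples[grouping]
    levels = list(pd.unique(labels.dropna()))
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    g1 = list(labels.index[labels == levels[0]])
    g2 = list(labels.index[labels == levels[1]])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    sub = matrix.subset_probes(probes)
    a = sub.values[g1].to_numpy(float)
    b = sub.values[g2].to_numpy(float)
    tstat, p = stats.ttest_ind(a, b, axis=1)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"t": tstat, "p": p, "p_adj": p_adj}, index=probes)
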