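"""Synthetic twin-cohort generator with ground-truth labels.

Emulates the statistical structure the analysis assumes: paired monozygotic
twin samples spanning adult ages, with three probe classes —

* ``age_regulated``: a genuine linear age trend shared by both twins, plus a
  couple-shared genetic effect and individual noise (the signal probes);
* ``volatile``: no age trend, but individual noise whose SD grows with age,
  so within-couple discordance increases over the lifespan;
* ``stable``: neither trend nor growing noise.

All classes carry the couple-shared genetic effect, so within-couple
differences come from individual noise alone; relative to each probe's total
variance this orders the mean divergence score as
age_regulated < stable <= volatile.  Values are emitted directly on the
post-log (log2-like) scale, so preprocessing of synthetic data is optional.

Singleton validation cohorts on a "different platform" (partial gene-symbol
overlap, several probes per symbol, a platform-wide affine shift) and
planted-enrichment pathway annotations are generated from the same truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import PathwayAnnotation
from .io import UNKNOWN_SYMBOL, ExpressionMatrix, TwinCohort, substream

log = logging.getLogger(__name__)

CLASSES = ("age_regulated", "volatile", "stable")


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Defaults describe a realistic cohort: 27 couples aged 22-98 with
    expression on the log2 scale (baselines 6-12), couple-shared genetic
    effects of 0.5 SD, individual noise of 0.25 SD, age slopes of about
    0.037-0.063 log2 units/year on age-regulated probes, and volatile-probe
    discordance growing 1.5% per year of age.
    """

    n_couples: int = 27
    n_probes: int = 5000
    age_range: tuple[float, float] = (22.0, 98.0)
    frac_age_regulated: float = 0.05
    frac_volatile: float = 0.15
    slope_scale: float = 0.05
    genetic_sd: float = 0.5
    individual_sd: float = 0.25
    divergence_growth: float = 0.015
    seed: int = 0
    baseline_range: tuple[float, float] = (6.0, 12.0)
    frac_unknown: float = 0.02
    onset_age: float | None = None  # volatile growth starts here; default = age minimum
    ages: list[float] | None = None  # fixed couple-age list overriding the uniform draw

    def __post_init__(self) -> None:
        numeric = [
            self.n_couples, self.n_probes, *self.age_range, self.frac_age_regulated,
            self.frac_volatile, self.slope_scale, self.genetic_sd, self.individual_sd,
            self.divergence_growth, *self.baseline_range, self.frac_unknown,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("non-finite value in SyntheticConfig")
        if self.n_couples < 1 or self.n_probes < 1:
            raise ValueError("n_couples and n_probes must be >= 1")
        if not 0 <= self.frac_age_regulated <= 1 or not 0 <= self.frac_volatile <= 1:
            raise ValueError("class fractions must be in [0, 1]")
        if self.frac_age_regulated + self.frac_volatile > 1:
            raise ValueError("frac_age_regulated + frac_volatile must be <= 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        for name in ("genetic_sd", "individual_sd", "slope_scale", "divergence_growth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ages is not None and len(self.ages) != self.n_couples:
            raise ValueError("fixed age list length must equal n_couples")


@dataclass
class SyntheticTruth:
    """Ground truth: per-probe class label, true slope and noise parameters."""

    table: pd.DataFrame  # index probe_id; columns label, slope, noise_sd, symbol
    config: SyntheticConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not set(self.table["label"]).issubset(CLASSES):
            raise ValueError(f"labels must be among {CLASSES}")

    def probes_of(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def _noise_sd(config: SyntheticConfig, labels: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Per probe-by-sample noise SD; volatile probes grow linearly past onset."""
    onset = config.age_range[0] if config.onset_age is None else config.onset_age
    growth = 1.0 + config.divergence_growth * np.clip(ages - onset, 0.0, None)
    sd = np.full((len(labels), len(ages)), config.individual_sd)
    sd[labels == "volatile", :] *= growth[None, :]
    return sd


def generate_twin_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, TwinCohort, SyntheticTruth]:
    """Generate a paired twin cohort with ground-truth labels.

    Couple ages are uniform over ``config.age_range`` (or taken from the
    fixed list), shared by both members.  Deterministic given
    ``config.seed``: all randomness flows from that one seed through
    deterministic substreams.
    """
    rng_meta = substream(config.seed, 10)
    rng_probe = substream(config.seed, 11)
    rng_genetic = substream(config.seed, 12)
    rng_noise = substream(config.seed, 13)

    n_c, n_p = config.n_couples, config.n_probes
    couple_ids = [f"C{i + 1:02d}" for i in range(n_c)]
    if config.ages is not None:
        couple_ages = np.asarray(config.ages, float)
    else:
        couple_ages = rng_meta.uniform(*config.age_range, size=n_c)
    sexes = rng_meta.choice(["F", "M"], size=n_c)

    meta = []
    for cid, age, sex in zip(couple_ids, couple_ages, sexes):
        for member in (1, 2):
            meta.append((f"{cid}M{member}", cid, member, age, sex))
    samples = pd.DataFrame(
        meta, columns=["sample_id", "couple_id", "member", "age", "sex"]
    ).set_index("sample_id")
    cohort = TwinCohort(samples)
    sample_ages = samples["age"].to_numpy()

    probe_ids = [f"P{i:05d}" for i in range(n_p)]
    n_ar = round(config.frac_age_regulated * n_p)
    n_vol = round(config.frac_volatile * n_p)
    labels = np.array(
        ["age_regulated"] * n_ar + ["volatile"] * n_vol + ["stable"] * (n_p - n_ar - n_vol)
    )
    rng_probe.shuffle(labels)
    baselines = rng_probe.uniform(*config.baseline_range, size=n_p)
    slopes = np.zeros(n_p)
    ar_mask = labels == "age_regulated"
    signs = rng_probe.choice([-1.0, 1.0], size=int(ar_mask.sum()))
    slopes[ar_mask] = signs * config.slope_scale * rng_probe.uniform(0.75, 1.25, size=int(ar_mask.sum()))
    symbols = np.array([f"GENE{i:05d}" for i in range(n_p)], dtype=object)
    unknown = rng_probe.random(n_p) < config.frac_unknown
    symbols[unknown] = UNKNOWN_SYMBOL

    genetic = rng_genetic.normal(0.0, config.genetic_sd, size=(n_p, n_c))
    genetic_per_sample = np.repeat(genetic, 2, axis=1)  # members share the couple effect
    noise = rng_noise.normal(0.0, 1.0, size=(n_p, 2 * n_c)) * _noise_sd(
        config, labels, sample_ages
    )
    values = (
        baselines[:, None]
        + slopes[:, None] * sample_ages[None, :]
        + genetic_per_sample
        + noise
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples.index),
        pd.Series(symbols, index=probe_ids),
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "label": labels,
                "slope": slopes,
                "noise_sd": np.full(n_p, config.individual_sd),
                "symbol": symbols,
            },
            index=probe_ids,
        ),
        config=config,
    )
    log.info(
        "generate_twin_cohort: %d couples, %d probes (%d age-regulated, %d volatile), seed %d",
        n_c, n_p, n_ar, n_vol, config.seed,
    )
    return matrix, cohort, truth


def generate_singleton_cohort(
    config: SyntheticConfig,
    source_truth: SyntheticTruth,
    symbol_overlap: float,
    probes_per_symbol=1,
    seed: int = 0,
    n_samples: int = 30,
    platform_scale: float | None = None,
    platform_offset: float | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate an unpaired cohort on a "different platform".

    Only a ``symbol_overlap`` fraction of the source symbols is present, and
    symbols may be carried by several probes differing in baseline (to
    exercise the highest-average-expression mapping rule).  Each symbol
    keeps its true age slope from ``source_truth``.  A platform-wide affine
    shift is applied (drawn from the seed unless given explicitly; pass
    ``platform_scale=1, platform_offset=0`` to disable).
    """
    if not 0 <= symbol_overlap <= 1:
        raise ValueError("symbol_overlap must be in [0, 1]")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = substream(seed, 20)

    truth_known = source_truth.table[source_truth.table["symbol"] != UNKNOWN_SYMBOL]
    symbol_slope = truth_known.groupby("symbol")["slope"].first()
    all_symbols = sorted(symbol_slope.index)
    n_keep = round(symbol_overlap * len(all_symbols))
    kept = sorted(rng.choice(all_symbols, size=n_keep, replace=False))

    if platform_scale is None:
        platform_scale = float(rng.uniform(0.8, 1.2))
    if platform_offset is None:
        platform_offset = float(rng.uniform(-1.0, 1.0))

    probe_ids: list[str] = []
    probe_symbols: list[str] = []
    probe_slopes: list[float] = []
    for sym in kept:
        n_probes = _draw_probe_count(probes_per_symbol, rng)
        for j in range(n_probes):
            probe_ids.append(f"T{len(probe_ids):05d}")
            probe_symbols.append(sym)
            probe_slopes.append(float(symbol_slope[sym]))

    sample_ids = [f"V{i + 1:03d}" for i in range(n_samples)]
    ages = pd.Series(rng.uniform(*config.age_range, size=n_samples), index=sample_ids, name="age")
    baselines = rng.uniform(*config.baseline_range, size=len(probe_ids))
    noise = rng.normal(0.0, config.individual_sd, size=(len(probe_ids), n_samples))
    values = (
        baselines[:, None]
        + np.asarray(probe_slopes)[:, None] * ages.to_numpy()[None, :]
        + noise
    )
    values = platform_scale * values + platform_offset
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        pd.Series(probe_symbols, index=probe_ids),
    )
    log.info(
        "generate_singleton_cohort: %d samples, %d probes over %d symbols "
        "(overlap %.2f, affine %.3g x + %.3g)",
        n_samples, len(probe_ids), len(kept), symbol_overlap, platform_scale, platform_offset,
    )
    return matrix, ages


def _draw_probe_count(probes_per_symbol, rng) -> int:
    """``probes_per_symbol``: a fixed int, or a {count: probability} distribution."""
    if isinstance(probes_per_symbol, int):
        if probes_per_symbol < 1:
            raise ValueError("probes_per_symbol must be >= 1")
        return probes_per_symbol
    counts = np.array(sorted(probes_per_symbol), dtype=int)
    probs = np.array([probes_per_symbol[c] for c in counts], float)
    probs = probs / probs.sum()
    return int(rng.choice(counts, p=probs))


def generate_pathway_annotation(
    truth: SyntheticTruth,
    n_pathways: int,
    enriched_fraction: float,
    seed: int = 0,
    size_range: tuple[int, int] = (10, 50),
    enrich_bias: float = 0.8,
) -> PathwayAnnotation:
    """Pathway membership with a planted-enriched subset.

    ``enriched_fraction`` of the pathways draw ``enrich_bias`` of their
    members from age-regulated probes (the rest uniformly); all other
    pathways draw uniformly from every probe, so their enrichment p-values
    are null.  The planted pathway ids are recorded in
    ``PathwayAnnotation.enriched_truth``.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    if not 0 <= enriched_fraction <= 1:
        raise ValueError("enriched_fraction must be in [0, 1]")
    rng = substream(seed, 30)
    probes = np.asarray(truth.table.index)
    ar_probes = np.asarray(truth.probes_of("age_regulated"))
    n_enriched = round(enriched_fraction * n_pathways)
    ids = [f"path{i + 1:03d}" for i in range(n_pathways)]
    enriched_ids = set(rng.choice(ids, size=n_enriched, replace=False)) if n_enriched else set()

    pathways: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    for pid in ids:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(probes))
        if pid in enriched_ids and len(ar_probes) > 0:
            n_ar = min(round(enrich_bias * size), len(ar_probes))
            members = set(rng.choice(ar_probes, size=n_ar, replace=False))
            rest_pool = np.setdiff1d(probes, list(members))
            members |= set(rng.choice(rest_pool, size=size - n_ar, replace=False))
        else:
            members = set(rng.choice(probes, size=size, replace=False))
        pathways[pid] = frozenset(members)
        names[pid] = f"Synthetic pathway {pid}"
    log.info(
        "generate_pathway_annotation: %d pathways (%d planted enriched), seed %d",
        n_pathways, len(enriched_ids), seed,
    )
    return PathwayAnnotation(
        pathways=pathways, names=names, enriched_truth=frozenset(enriched_ids)
    )
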