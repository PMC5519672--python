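"""Pathway over-representation analysis of low-divergence probe sets.

One-sided hypergeometric over-representation (Fisher's exact upper tail) of
a selected probe set against an annotated background — the background being
the probes that carry at least one pathway annotation, not the whole array.
Counting is probe-level: a gene with several annotated probes counts once
per probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .divergence import DivergenceResult, select_low_divergence

log = logging.getLogger(__name__)


@dataclass
class PathwayAnnotation:
    """Pathway id -> member probe set, with display names.

    ``background`` is the union of all pathway members — every probe with at
    least one annotation.  ``enriched_truth`` optionally records which
    pathways a synthetic generator planted as enriched (ground truth for
    recovery tests; empty for real annotations).
    """

    pathways: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)
    enriched_truth: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.pathways = {pid: frozenset(m) for pid, m in self.pathways.items()}
        for pid in self.pathways:
            self.names.setdefault(pid, pid)

    @property
    def background(self) -> frozenset:
        return frozenset().union(*self.pathways.values()) if self.pathways else frozenset()

    def __len__(self) -> int:
        return len(self.pathways)


def enrich(selected, annotation: PathwayAnnotation) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in every pathway.

    For a pathway with ``n_annotated`` background members of which
    ``n_significant`` are selected, the p-value is the upper tail
    P(X >= n_significant) of a hypergeometric distribution with population =
    background size, successes = selected-in-background count and draws =
    ``n_annotated``.  Selected probes outside the background are dropped with
    a logged count.  Rows are sorted by p; ``q`` is the Benjamini-Hochberg
    adjusted p across all tested pathways, and ``ratio`` is
    100 x n_significant / n_annotated.
    """
    background = annotation.background
    if not background:
        raise ValueError("empty annotation background")
    selected = set(selected)
    in_bg = selected & background
    n_dropped = len(selected) - len(in_bg)
    if n_dropped:
        log.info("enrich: dropped %d selected probe(s) outside the background", n_dropped)
    N = len(background)
    K = len(in_bg)
    rows = []
    for pid, members in annotation.pathways.items():
        n_annotated = len(members)
        n_significant = len(members & in_bg)
        if n_annotated:
            p = float(stats.hypergeom.sf(n_significant - 1, N, K, n_annotated))
            ratio = 100.0 * n_significant / n_annotated
        else:
            p, ratio = 1.0, 0.0
        rows.append(
            {
                "pathway_id": pid,
                "name": annotation.names[pid],
                "n_annotated": n_annotated,
                "n_significant": n_significant,
                "ratio": ratio,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = q
    return table.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)


def selection_summary(
    result: DivergenceResult, annotation: PathwayAnnotation, threshold: float
) -> tuple[int, int, float]:
    """Count annotated probes passing z <= -threshold.

    Returns ``(n_selected_annotated, background_size, percentage)`` with the
    percentage rounded to one decimal (e.g. 420 of 3,978 -> 10.6).
    """
    background = annotation.background
    if not background:
        raise ValueError("empty annotation background")
    selected = select_low_divergence(result, threshold) & background
    pct = round(100.0 * len(selected) / len(background), 1)
    return len(selected), len(background), pct
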