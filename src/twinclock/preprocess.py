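"""Expression normalization: log transform and whole-dataset quantile normalization.

The pipeline normalizes processed microarray intensities with an elementwise
logarithm (base 2 by default, the microarray convention) followed by quantile
normalization computed jointly over the whole supplied matrix, never per
batch.  No background correction or probe summarization is performed; input
is assumed to be vendor-processed intensities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

log = logging.getLogger(__name__)


def log_transform(matrix: ExpressionMatrix, base: float = 2.0, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log_base(value + offset)``.

    All shifted values must be strictly positive; otherwise the offending
    cells are reported and an error raised.  The optional ``offset`` (e.g. 1
    for matrices containing zeros) is off by default and logged prominently
    when engaged.
    """
    if offset:
        log.warning("log_transform applying offset +%g before the logarithm", offset)
    vals = matrix.values + offset
    bad = vals <= 0
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        cells = [
            f"(probe={matrix.values.index[r]!r}, sample={matrix.values.columns[c]!r}, "
            f"value={matrix.values.iat[r, c]!r})"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValueError(
            f"nonpositive value(s) under log transform (offset={offset}): {', '.join(cells)}"
        )
    out = np.log(vals) / np.log(base)
    return ExpressionMatrix(out, matrix.annotation)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the across-sample mean of sorted value vectors; each
    sample's values are replaced by the reference values at their ranks, so
    within-sample order is preserved.  Tied values receive the mean of the
    reference values at their tied rank positions.
    """
    vals = matrix.values
    if vals.shape[1] < 2:
        log.warning("quantile_normalize on a single sample is the identity")
        return ExpressionMatrix(vals.copy(), matrix.annotation)
    arr = vals.to_numpy(float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: average the reference values handed to equal inputs
        ser = pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = ser.to_numpy()
    normalized = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return ExpressionMatrix(normalized, matrix.annotation)
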