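"""Global quantile normalization of a log2 expression matrix.

Every sample (column) is forced onto a common reference distribution: the
row-wise mean of the column-sorted values. Within-column rank order is
preserved; tied values receive the mean of the reference values at their tied
rank positions. The operation acts on the log2 scale as loaded — upstream
summarization already produced log2 intensities, so no re-logging happens here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) against their common reference.

    Parameters
    ----------
    matrix
        Probe x sample log2 expression values; at least two samples, all
        finite.

    Returns
    -------
    A new DataFrame with identical index/columns in which every column's
    multiset of values equals the reference distribution (up to ties).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")

    order = np.argsort(values, axis=0, kind="stable")
    reference = np.take_along_axis(values, order, axis=0).mean(axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        mapped = reference.copy()
        # ties: average the reference over each run of equal input values
        start = 0
        for stop in range(1, n + 1):
            if stop == n or sorted_col[stop] != sorted_col[start]:
                if stop - start > 1:
                    mapped[start:stop] = reference[start:stop].mean()
                start = stop
        out[idx, j] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
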