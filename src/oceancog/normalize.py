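"""Equal-depth subsampling and normalized-abundance transforms.

The comparative analysis assumes libraries of equal sequencing depth.
:func:`subsample_counts` rarefies every dataset to a common number of
assigned reads by drawing without replacement (a multivariate hypergeometric
draw per dataset); :func:`to_normalized` optionally rescales to counts per
10⁴ reads; :func:`zscore_rows` standardizes each COG's profile across
datasets for heatmaps and clustering.

Subsampling is implemented so the draw for a given (COG id, dataset, seed)
does not depend on the order in which COG rows are stored: within each
dataset the reads are ordered lexicographically by COG id, each read gets an
independent uniform priority, and the ``target`` reads with the smallest
priorities are kept. Permuting the rows of the input therefore permutes the
output exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .io import COGCountMatrix

__all__ = ["subsample_counts", "to_normalized", "zscore_rows"]


def subsample_counts(
    matrix: COGCountMatrix, target: int, seed: int
) -> COGCountMatrix:
    """Rarefy every dataset to exactly ``target`` assigned reads.

    ``target`` must not exceed any dataset's assigned-read total (its count
    column sum). Column sums of the result equal ``target`` exactly and every
    subsampled count is bounded by the original count.
    """
    if target <= 0 or target != int(target):
        raise ValidationError(f"target must be a positive integer, got {target!r}")
    target = int(target)
    counts = matrix.counts
    colsums = counts.sum(axis=0)
    low = colsums[colsums < target]
    if len(low):
        raise ValidationError(
            f"target {target} exceeds assigned reads for datasets: "
            f"{low.index.tolist()} (min {int(colsums.min())})"
        )
    canon = np.argsort(np.asarray(counts.index, dtype=object), kind="stable")
    out = np.zeros(counts.shape, dtype=np.int64)
    arr = counts.to_numpy()
    for j, dataset in enumerate(counts.columns):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, j])
        col = arr[canon, j]
        n = int(col.sum())
        if n == target:
            out[:, j] = arr[:, j]
            continue
        priorities = rng.random(n)
        keep = np.zeros(n, dtype=bool)
        keep[np.argpartition(priorities, target - 1)[:target]] = True
        ends = np.cumsum(col)
        starts = ends - col
        ckeep = np.concatenate([[0], np.cumsum(keep)])
        kept_per_cog = ckeep[ends] - ckeep[starts]
        out[canon, j] = kept_per_cog
    result = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    lib = pd.Series(target, index=counts.columns, dtype=np.int64)
    return COGCountMatrix(result, lib)


def to_normalized(matrix: COGCountMatrix, per_10k: bool = False) -> pd.DataFrame:
    """Return normalized abundances as a float DataFrame.

    With ``per_10k=False`` (the default, for already equal-depth matrices)
    the values are the raw counts; with ``per_10k=True`` each column is
    rescaled to sum to 10⁴.
    """
    values = matrix.counts.astype(float)
    if not per_10k:
        return values
    colsum = values.sum(axis=0)
    if (colsum == 0).any():
        empty = colsum.index[colsum == 0].tolist()
        raise ValidationError(f"cannot scale zero-sum datasets: {empty}")
    return values / colsum * 1e4


def zscore_rows(norm: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Standardize each row to mean 0 and sample (n-1) standard deviation 1.

    Constant rows carry no profile information; they are dropped when
    ``drop_constant`` is true and raise :class:`DegenerateDataError`
    otherwise.
    """
    if norm.shape[1] < 2:
        raise ValidationError("z-scoring needs at least 2 datasets")
    values = norm.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0.0
    if constant.any() and not drop_constant:
        rows = norm.index[constant].tolist()
        raise DegenerateDataError(f"constant rows cannot be z-scored: {rows[:10]}")
    keep = ~constant
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=norm.index[keep], columns=norm.columns)
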