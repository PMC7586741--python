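"""Shannon-entropy expression specificity of marked vs unmarked genes.

For a gene with expression x_i across T conditions, p_i = x_i / sum(x) and
H = -sum p_i log p_i (natural log by default, 0*log 0 = 0).  H ranges from
0 (expression confined to one condition) to log T (perfectly uniform);
repressive-mark targets are expected to sit at the specific (low-entropy)
end.  Genes with zero total expression have no defined entropy and are
excluded with a count.

The marked-vs-unmarked contrast is a two-sided Wilcoxon rank-sum test on
the two entropy distributions; the test choice is this package's own
(distribution-free) and is recorded in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["shannon_entropy", "entropy_per_gene", "entropy_contrast", "EntropyContrast"]


def shannon_entropy(expr_row, base: float | None = None) -> float:
    """Entropy of one gene's normalized expression profile.

    ``base=None`` means natural log (nats); pass 2 or 10 for other units.
    Raises on all-zero or negative rows.
    """
    x = np.asarray(expr_row, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero expression row")
    p = x / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def entropy_per_gene(
    matrix: pd.DataFrame, base: float | None = None
) -> tuple[pd.Series, int]:
    """Entropy for every gene of a genes x conditions matrix.

    Returns (entropies indexed by gene, number of all-zero genes dropped).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    totals = matrix.sum(axis=1)
    nonzero = matrix.loc[totals > 0]
    n_dropped = len(matrix) - len(nonzero)
    x = nonzero.to_numpy(dtype=float)
    p = x / x.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    if base is not None:
        h = h / math.log(base)
    return pd.Series(h, index=nonzero.index, name="entropy"), n_dropped


@dataclass
class EntropyContrast:
    target_entropy: pd.Series
    nontarget_entropy: pd.Series
    statistic: float
    p_value: float
    median_target: float
    median_nontarget: float
    targets_more_specific: bool  # True when target median is lower
    n_zero_dropped: int
    test: str = "wilcoxon-rank-sum-two-sided"


def entropy_contrast(
    targets: set[str], matrix: pd.DataFrame, base: float | None = None
) -> EntropyContrast:
    """Compare entropy distributions of target vs non-target genes."""
    h, n_dropped = entropy_per_gene(matrix, base=base)
    in_targets = h.index.isin(targets)
    ht = h[in_targets]
    hn = h[~in_targets]
    if len(ht) == 0 or len(hn) == 0:
        raise ValueError("both target and non-target subsets must be non-empty")
    res = stats.ranksums(ht.to_numpy(), hn.to_numpy())
    mt, mn = float(ht.median()), float(hn.median())
    return EntropyContrast(
        target_entropy=ht,
        nontarget_entropy=hn,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_target=mt,
        median_nontarget=mn,
        targets_more_specific=mt < mn,
        n_zero_dropped=n_dropped,
    )
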