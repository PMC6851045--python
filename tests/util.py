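"""Shared helpers for the test suite."""

import numpy as np
from scipy.stats import rankdata


def binomial_envelope(alpha: float, n: int, z: float = 2.576):
    """99% binomial envelope around a nominal rejection rate."""
    half = z * np.sqrt(alpha * (1 - alpha) / n)
    return alpha - half, alpha + half


def auroc(scores, labels):
    """Rank-based AUROC (Mann-Whitney) of scores for labels (bool array)."""
    labels = np.asarray(labels, dtype=bool)
    r = rankdata(scores)
    n1 = labels.sum()
    n0 = labels.size - n1
    return (r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
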