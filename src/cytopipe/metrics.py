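"""Agreement metrics between detected clusters and reference populations."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = ["cluster_f_measure", "adjusted_rand_score"]


def cluster_f_measure(true_labels: np.ndarray, pred_labels: np.ndarray) -> float:
    """Size-weighted best-match F-measure of predicted vs reference classes.

    For each reference population, precision and recall are computed
    against its best-matching detected cluster and combined into an F
    score; the scores are averaged weighted by population size. 1.0
    means every reference population coincides with one cluster.
    """
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have the same length")
    n = t.size
    total = 0.0
    for cls in np.unique(t):
        mask_t = t == cls
        best = 0.0
        for k in np.unique(p):
            mask_p = p == k
            inter = np.sum(mask_t & mask_p)
            if inter == 0:
                continue
            f = 2.0 * inter / (mask_t.sum() + mask_p.sum())
            best = max(best, f)
        total += mask_t.sum() / n * best
    return float(total)
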