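"""Chromosomal clustering of homoeolog expression bias.

Per-gene bias deviations (delta-alpha: test-sample alpha minus null alpha)
are smoothed with a centered running average along each chromosome, and
clusters of concordant bias are scored against a genome-wide permutation
null: bias values are shuffled across all gene positions, and the genome-wide
maximum absolute running mean of each shuffle forms the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BiasCluster", "running_delta_alpha", "permutation_cluster_test"]

DIR_AA = "Aa_enriched"
DIR_AT = "At_enriched"


@dataclass
class BiasCluster:
    chrom: str
    start_index: int   # gene-order index of first window center in the run
    end_index: int     # inclusive
    mean_running: float
    direction: str
    p_value: float


def running_delta_alpha(values: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered moving average with truncated (not padded) ends.

    Output length is ``n - window + 1``; chromosomes shorter than the window
    yield an empty track.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    x = np.asarray(values, dtype=float)
    if x.size < window:
        return np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[window:] - c[:-window]) / window


def _max_abs_running(values: np.ndarray, lengths: list[int], window: int) -> float:
    best = 0.0
    off = 0
    for ln in lengths:
        tr = running_delta_alpha(values[off:off + ln], window)
        if tr.size:
            best = max(best, float(np.max(np.abs(tr))))
        off += ln
    return best


def permutation_cluster_test(delta: pd.DataFrame, window: int = 11,
                             n_perm: int = 10_000, seed: int = 0,
                             alpha: float = 0.05) -> list[BiasCluster]:
    """Find significant runs of concordant bias via a genome-wide shuffle.

    ``delta`` needs columns chrom, start, delta_alpha.  The null threshold is
    the 97.5th percentile of the permutation distribution of genome-wide
    maximum |running mean|; a cluster is a maximal run of window centers
    exceeding it, and its empirical p is the fraction of permutations whose
    global maximum reaches the cluster's mean running value.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    delta = delta.sort_values(["chrom", "start"])
    chroms = []
    values = []
    lengths = []
    for chrom, sub in delta.groupby("chrom", sort=True):
        chroms.append(chrom)
        values.append(sub["delta_alpha"].to_numpy(dtype=float))
        lengths.append(len(sub))
    flat = np.concatenate(values) if values else np.empty(0)
    if flat.size == 0:
        return []

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        null_max[k] = _max_abs_running(rng.permutation(flat), lengths, window)
    thr = float(np.percentile(null_max, 97.5))

    clusters: list[BiasCluster] = []
    for chrom, vals in zip(chroms, values):
        track = running_delta_alpha(vals, window)
        hot = np.abs(track) > thr
        i = 0
        while i < hot.size:
            if not hot[i]:
                i += 1
                continue
            j = i
            while j + 1 < hot.size and hot[j + 1]:
                j += 1
            mean_run = float(np.mean(track[i:j + 1]))
            p = float((np.sum(null_max >= abs(mean_run)) + 1) / (n_perm + 1))
            clusters.append(BiasCluster(
                chrom=chrom, start_index=i, end_index=j,
                mean_running=mean_run,
                direction=DIR_AA if mean_run > 0 else DIR_AT,
                p_value=p))
            i = j + 1
    return clusters
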