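"""Do network partners share homoeolog bias?

Two complementary readings of an interaction table (gene_a, gene_b,
connectedness):

* pair-level: among pairs where both genes carry a significant bias label,
  the concordant fraction is computed per connectedness bin and regressed on
  connectedness;
* network-level: connected components of the thresholded interaction graph
  containing >= 2 biased genes are partitioned into co-biased-At, co-biased-Aa
  and mixed, and tested against a binomial expectation with a chi-square
  goodness-of-fit (df = 2).

The binomial expectation: with p the global fraction of At-biased genes among
all biased genes, a component with k biased genes contributes p^k to the
expected all-At count, (1-p)^k to all-Aa, and the remainder to mixed, so the
expected counts sum to the number of components by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphamodel import LABEL_AA, LABEL_AT

__all__ = ["PairConcordance", "NetworkPartitionCounts", "pair_concordance",
           "concordance_by_bin", "partition_networks", "chi2_partition"]


@dataclass
class NetworkPartitionCounts:
    observed: tuple[int, int, int]       # (co_At, mixed, co_Aa)
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p: float
    n_networks: int


@dataclass
class PairConcordance:
    pairs: pd.DataFrame  # gene_a, gene_b, connectedness, concordant


def pair_concordance(edges: pd.DataFrame, labels: pd.Series) -> PairConcordance:
    """Keep pairs where both genes are significantly biased; mark concordance.

    ``labels`` maps gene_id -> {Aa_like, At_like}; other genes are treated
    as unlabeled and their pairs dropped.
    """
    biased = labels[labels.isin([LABEL_AA, LABEL_AT])]
    e = edges.copy()
    e["lab_a"] = e["gene_a"].map(biased)
    e["lab_b"] = e["gene_b"].map(biased)
    e = e.dropna(subset=["lab_a", "lab_b"]).reset_index(drop=True)
    e["concordant"] = e["lab_a"] == e["lab_b"]
    return PairConcordance(pairs=e[["gene_a", "gene_b", "connectedness",
                                    "concordant"]])


def concordance_by_bin(pc: PairConcordance, n_bins: int = 20,
                       min_per_bin: int = 5):
    """Equal-count connectedness bins -> concordant fraction, plus OLS fit.

    Returns (bin table, slope, r_squared).  Bins with fewer than
    ``min_per_bin`` pairs are merged into their neighbor.
    """
    pairs = pc.pairs.sort_values("connectedness").reset_index(drop=True)
    if len(pairs) < n_bins * 10:
        raise ValueError(f"need >= {n_bins * 10} labeled pairs, have {len(pairs)}")
    chunks = np.array_split(np.arange(len(pairs)), n_bins)
    merged: list[np.ndarray] = []
    for ch in chunks:
        if merged and ch.size < min_per_bin:
            merged[-1] = np.concatenate([merged[-1], ch])
        else:
            merged.append(ch)
    rows = []
    for ch in merged:
        sub = pairs.iloc[ch]
        rows.append((float(sub["connectedness"].mean()),
                     float(sub["concordant"].mean()), len(sub)))
    table = pd.DataFrame(rows, columns=["connectedness", "fraction_concordant",
                                        "n_pairs"])
    x = table["connectedness"].to_numpy()
    y = table["fraction_concordant"].to_numpy()
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return table, 0.0, 0.0  # flat response: zero-slope fit
    fit = stats.linregress(x, y)
    return table, float(fit.slope), float(fit.rvalue ** 2)


def _components(edges: pd.DataFrame, threshold: float) -> list[set[str]]:
    """Connected components of the thresholded interaction graph."""
    parent: dict[str, str] = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for r in edges.itertuples():
        if r.connectedness < threshold:
            continue
        for g in (r.gene_a, r.gene_b):
            parent.setdefault(g, g)
        ra, rb = find(r.gene_a), find(r.gene_b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for g in parent:
        comps.setdefault(find(g), set()).add(g)
    return list(comps.values())


def partition_networks(edges: pd.DataFrame, labels: pd.Series,
                       threshold: float = 0.5) -> NetworkPartitionCounts:
    """Classify networks as co-At / mixed / co-Aa and test vs expectation."""
    biased = labels[labels.isin([LABEL_AA, LABEL_AT])]
    p_at = float((biased == LABEL_AT).mean()) if len(biased) else np.nan
    if not (0.0 < p_at < 1.0):
        raise ValueError("degenerate global bias fraction; test refused")
    obs = np.zeros(3, dtype=int)        # co_At, mixed, co_Aa
    exp = np.zeros(3)
    n_net = 0
    for comp in _components(edges, threshold):
        labs = [biased[g] for g in comp if g in biased.index]
        k = len(labs)
        if k < 2:
            continue
        n_net += 1
        if all(l == LABEL_AT for l in labs):
            obs[0] += 1
        elif all(l == LABEL_AA for l in labs):
            obs[2] += 1
        else:
            obs[1] += 1
        e_at = p_at ** k
        e_aa = (1 - p_at) ** k
        exp += (e_at, 1 - e_at - e_aa, e_aa)
    chi2, df, p = chi2_partition(tuple(obs), tuple(exp))
    return NetworkPartitionCounts(observed=tuple(int(v) for v in obs),
                                  expected=tuple(float(v) for v in exp),
                                  chi2=chi2, df=df, p=p, n_networks=n_net)


def chi2_partition(observed, expected):
    """Chi-square goodness of fit on (co_At, mixed, co_Aa) counts, df = 2.

    Also usable directly on published count tables.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))
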