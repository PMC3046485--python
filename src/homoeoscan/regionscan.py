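"""Multi-gene alteration scan between the evolved and F1 allotetraploid.

Per gene, replicate-averaged probe intensities of the evolved sample are
paired with the F1 sample and compared with a Wilcoxon signed-rank test
(exact null for <= 25 informative probes, normal approximation with
continuity correction above; zero differences dropped).  A sliding window of
30 genes along each chromosome is flagged when at least 27 genes deviate in
the same direction and at least 9 are individually significant at BH
FDR < 0.05; overlapping flagged windows of equal direction are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dfcore import benjamini_hochberg

__all__ = ["GeneDiffCall", "AlterationRegion", "gene_diff_test",
           "scan_alteration_windows", "call_gene_table", "regions_to_bed"]

DIR_AS = "higher_in_As"
DIR_F1 = "higher_in_F1As"
DIR_NONE = "none"


@dataclass
class GeneDiffCall:
    gene_id: str
    n_probes: int
    statistic: float
    p_value: float
    direction: str
    testable: bool


@dataclass
class AlterationRegion:
    chrom: str
    start_gene_index: int
    end_gene_index: int  # inclusive
    start_bp: int
    end_bp: int
    n_genes: int
    n_same_direction: int
    n_significant: int
    direction: str


def gene_diff_test(as_means: np.ndarray, f1_means: np.ndarray,
                   gene_id: str = "", min_probes: int = 5) -> GeneDiffCall:
    """Paired signed-rank test of per-probe means (As - F1As)."""
    x = np.asarray(as_means, dtype=float)
    y = np.asarray(f1_means, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors differ in length")
    diffs = x - y
    nz = diffs[diffs != 0]
    if x.size < min_probes:
        return GeneDiffCall(gene_id, x.size, np.nan, np.nan, DIR_NONE, False)
    if nz.size == 0:
        return GeneDiffCall(gene_id, x.size, 0.0, 1.0, DIR_NONE, True)
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    med = np.median(diffs)
    if med > 0:
        direction = DIR_AS
    elif med < 0:
        direction = DIR_F1
    else:
        direction = DIR_NONE
    # signed statistic: positive when As hybridizes higher
    stat = float(res.statistic) * (1 if med >= 0 else -1)
    return GeneDiffCall(gene_id, x.size, stat, float(res.pvalue), direction, True)


def call_gene_table(calls: list[GeneDiffCall], fdr: float = 0.05) -> pd.DataFrame:
    """Assemble calls and apply BH FDR across testable genes."""
    df = pd.DataFrame([vars(c) for c in calls])
    df["q_value"] = np.nan
    ok = df["testable"]
    df.loc[ok, "q_value"] = benjamini_hochberg(df.loc[ok, "p_value"].to_numpy())
    df["significant"] = ok & (df["q_value"] < fdr)
    return df


def scan_alteration_windows(calls: pd.DataFrame, window: int = 30,
                            min_same_dir: int = 27, min_sig: int = 9
                            ) -> list[AlterationRegion]:
    """Slide a ``window``-gene window (step 1) per chromosome and merge hits.

    ``calls`` needs columns chrom, start, end (gene coordinates), direction,
    significant; genes are ordered by start within chromosome.  A window is
    flagged in a direction when >= ``min_same_dir`` genes share it and >=
    ``min_sig`` of those are significant; overlapping same-direction windows
    are collapsed into maximal regions.
    """
    regions: list[AlterationRegion] = []
    for chrom, sub in calls.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        n = len(sub)
        if n < window:
            continue
        dirs = sub["direction"].to_numpy()
        sig = sub["significant"].to_numpy()
        flagged = {DIR_AS: np.zeros(n - window + 1, dtype=bool),
                   DIR_F1: np.zeros(n - window + 1, dtype=bool)}
        for d in (DIR_AS, DIR_F1):
            same = (dirs == d).astype(int)
            sig_d = (same & sig).astype(int)
            cs = np.concatenate([[0], np.cumsum(same)])
            cg = np.concatenate([[0], np.cumsum(sig_d)])
            n_same = cs[window:] - cs[:-window]
            n_sig = cg[window:] - cg[:-window]
            flagged[d] = (n_same >= min_same_dir) & (n_sig >= min_sig)
        for d in (DIR_AS, DIR_F1):
            f = flagged[d]
            i = 0
            while i < f.size:
                if not f[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < f.size and f[j + 1]:
                    j += 1
                lo, hi = i, j + window - 1  # inclusive gene span of merged run
                span = sub.iloc[lo:hi + 1]
                in_dir = span["direction"] == d
                regions.append(AlterationRegion(
                    chrom=chrom, start_gene_index=lo, end_gene_index=hi,
                    start_bp=int(span["start"].min()),
                    end_bp=int(span["end"].max()),
                    n_genes=hi - lo + 1,
                    n_same_direction=int(in_dir.sum()),
                    n_significant=int((in_dir & span["significant"]).sum()),
                    direction=d))
                i = j + 1
    return regions


def regions_to_bed(regions: list[AlterationRegion]) -> pd.DataFrame:
    rows = [(r.chrom, r.start_bp, r.end_bp,
             f"{r.direction}:{r.n_genes}genes", r.n_significant)
            for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
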