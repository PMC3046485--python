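"""Gene-wise cross-genotype scaling and diagnostic-feature detection.

For every gene, the ratio of the mean reference-parent intensity (``T_i``)
to the mean non-reference-parent intensity (``A_i``) across its probes forms
a distribution whose dominant peak corresponds to probes conserved between
the parents; the kernel-density mode of that distribution (``x_max``) is the
scaling factor that puts both parents on a common per-gene scale.  Genes
whose ratio distribution is grossly non-normal (Shapiro-Wilk on log2 ratios)
are excluded as un-normalizable, as are genes where nearly every probe is
polymorphic.

Diagnostic features (DFs, array-detected single-feature polymorphisms) are
probes whose rescaled log2 intensities differ between parents by a Welch
t-test at genome-wide Benjamini-Hochberg FDR < 0.05 with a unanimous sign
across every replicate pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScalingResult",
    "GeneLedger",
    "scaling_factor",
    "kde_mode",
    "welch_t",
    "sign_unanimous",
    "detect_dfs",
    "normalize_and_detect",
]

STATUS_ANALYZED = "analyzed"
STATUS_TOO_FEW_PROBES = "too_few_probes"
STATUS_FAILED_NORMALITY = "failed_normality"
STATUS_TOO_MANY_DFS = "too_many_dfs"


@dataclass
class ScalingResult:
    gene_id: str
    ratios: np.ndarray
    x_max: float
    shapiro_p: float
    passed: bool


def kde_mode(values: np.ndarray, grid_points: int = 512,
             bandwidth: float | None = None,
             search_window: tuple[float, float] | None = None) -> float:
    """Argmax of a Gaussian KDE on a padded fine grid.

    ``bandwidth`` is an absolute kernel width; None falls back to
    Silverman's rule.  ``search_window`` restricts the argmax to an
    interval (used to keep per-gene modes near the genome-wide conserved
    peak).  Grid spans [min, max] padded by three bandwidths; argmax ties
    break toward the smallest value.  Degenerate (zero-spread) input
    returns the common value.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.ptp(x) == 0 or x.size == 1:
        return float(x[0])
    sd = x.std(ddof=1)
    if bandwidth is None or bandwidth <= 0:
        kde = stats.gaussian_kde(x, bw_method="silverman")
    else:
        kde = stats.gaussian_kde(x, bw_method=bandwidth / sd)
    bw = float(kde.factor * sd)
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    if search_window is not None:
        lo = max(lo, search_window[0])
        hi = min(hi, search_window[1])
        if lo >= hi:
            lo, hi = search_window
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])  # argmax returns first (smallest) tie


def scaling_factor(A: np.ndarray, T: np.ndarray, gene_id: str = "",
                   min_probes: int = 5, alpha_norm: float = 0.05,
                   log_bandwidth: float | None = None,
                   search_window: tuple[float, float] | None = None
                   ) -> ScalingResult:
    """Per-gene scaling factor x_max = KDE mode of the ratios X_i = T_i/A_i.

    The density is estimated on log2 ratios (where conserved probes form a
    symmetric peak at 0) and the mode mapped back to ratio space.
    ``log_bandwidth`` sets the kernel width; the right choice is the
    replicate-noise sd of a log ratio, which resolves the conserved-probe
    peak from the attenuated probes — Silverman's rule (the None fallback)
    oversmooths the multimodal ratio mixture at tiling-probe counts and
    drags the mode off the conserved peak.  ``search_window`` (log2 units)
    restricts the mode search, typically to a band around the genome-wide
    pooled mode: the conserved-probe hybridization ratio is a global
    property of the array pair, so a chance cluster of attenuated probes
    within one gene must not capture the gene's scaling factor.

    All non-reference intensities of the gene are meant to be multiplied by
    ``x_max`` downstream.  Normality of log2 ratios is recorded; ``passed``
    is False when the Shapiro-Wilk p-value falls below ``alpha_norm``.
    """
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    if A.size != T.size:
        raise ValueError("A and T length mismatch")
    if A.size < min_probes:
        raise ValueError(f"gene {gene_id!r}: fewer than {min_probes} probes")
    if np.any(A <= 0) or np.any(T <= 0):
        raise ValueError(f"gene {gene_id!r}: non-positive mean intensity")
    ratios = T / A
    log_ratios = np.log2(ratios)
    x_max = float(2.0 ** kde_mode(log_ratios, bandwidth=log_bandwidth,
                                  search_window=search_window))
    if np.ptp(log_ratios) == 0:
        shapiro_p = 1.0  # degenerate: treat an exactly constant ratio as clean
    else:
        shapiro_p = float(stats.shapiro(log_ratios).pvalue)
    return ScalingResult(gene_id=gene_id, ratios=ratios, x_max=x_max,
                         shapiro_p=shapiro_p, passed=shapiro_p >= alpha_norm)


def welch_t(x: np.ndarray, y: np.ndarray):
    """Welch t statistic and two-sided p along axis 1 (rows = probes)."""
    res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    return res.statistic, res.pvalue


def sign_unanimous(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """True where every (x_j, y_k) replicate pairing has the same sign of x-y."""
    return (x.min(axis=1) > y.max(axis=1)) | (x.max(axis=1) < y.min(axis=1))


@dataclass
class GeneLedger:
    """Accounts for every input gene exactly once."""
    status: pd.Series  # index = gene_id, values = STATUS_*

    def counts(self) -> pd.Series:
        return self.status.value_counts()


def detect_dfs(t_log2: np.ndarray, a_log2: np.ndarray) -> pd.DataFrame:
    """Per-probe Welch t on log2 replicate intensities (reference vs other).

    Returns a frame with t, p and the replicate-sign-unanimity flag; FDR is
    applied genome-wide by the caller so q-values are comparable across genes.
    """
    t_log2 = np.atleast_2d(t_log2)
    a_log2 = np.atleast_2d(a_log2)
    tstat, p = welch_t(t_log2, a_log2)
    # zero variance in both groups with equal means -> untestable, skip
    same = (np.ptp(t_log2, axis=1) == 0) & (np.ptp(a_log2, axis=1) == 0) & \
           (t_log2[:, 0] == a_log2[:, 0])
    p = np.where(same, np.nan, p)
    unanimous = sign_unanimous(t_log2, a_log2)
    sign = np.sign(t_log2.mean(axis=1) - a_log2.mean(axis=1)).astype(int)
    return pd.DataFrame({"t": tstat, "p": p, "sign": sign,
                         "unanimous": unanimous})


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values; NaNs are passed through untested."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def normalize_and_detect(genes: dict[str, dict], min_probes: int = 5,
                         alpha_norm: float = 0.05, fdr: float = 0.05,
                         max_df_fraction: float = 0.8,
                         anchor_halfwidth: float = 0.15):
    """Run scaling + DF detection over a gene collection.

    ``genes`` maps gene_id -> dict with at least ``t`` and ``a`` replicate
    matrices (probes x replicates, raw intensities) and ``probe_ids``.
    Returns (scaling table, DF table, ledger, per-gene rescaled data).

    The exclusion ledger classifies every gene exactly once: analyzed,
    too-few-probes, failed-normality or too-many-DFs.
    """
    status = {}
    scal_rows = []
    per_gene = {}
    frames = []

    # genome-wide anchor: pooled log ratios put the conserved-probe peak on
    # a sharp footing even where single genes have few conserved probes
    pooled = []
    for g in genes.values():
        t = np.asarray(g["t"], dtype=float)
        a = np.asarray(g["a"], dtype=float)
        if t.shape[0] >= min_probes:
            pooled.append(np.log2(t.mean(axis=1) / a.mean(axis=1)))
    window = None
    if pooled:
        pooled = np.concatenate(pooled)
        if np.ptp(pooled) > 0:
            sub = (pooled if pooled.size <= 20_000
                   else pooled[:: pooled.size // 20_000 + 1])
            center = kde_mode(sub, bandwidth=0.05)
            window = (center - anchor_halfwidth, center + anchor_halfwidth)

    for gid, g in genes.items():
        t = np.asarray(g["t"], dtype=float)
        a = np.asarray(g["a"], dtype=float)
        if t.shape[0] < min_probes:
            status[gid] = STATUS_TOO_FEW_PROBES
            continue
        A = a.mean(axis=1)
        T = t.mean(axis=1)
        # kernel width = measurement noise of a log ratio of replicate means
        r = t.shape[1]
        noise_bw = float(np.sqrt(np.mean(
            np.log2(t).var(axis=1, ddof=1) / r
            + np.log2(a).var(axis=1, ddof=1) / r)))
        res = scaling_factor(A, T, gene_id=gid, min_probes=min_probes,
                             alpha_norm=alpha_norm,
                             log_bandwidth=noise_bw if noise_bw > 0 else None,
                             search_window=window)
        scal_rows.append((gid, res.x_max, res.shapiro_p, res.passed))
        if not res.passed:
            status[gid] = STATUS_FAILED_NORMALITY
            continue
        a_scaled = res.x_max * a
        df = detect_dfs(np.log2(t), np.log2(a_scaled))
        df.insert(0, "probe_id", np.asarray(g["probe_ids"]))
        df.insert(0, "gene_id", gid)
        frames.append(df)
        per_gene[gid] = {"x_max": res.x_max, "A_scaled": res.x_max * A,
                         "T": T, "a_scaled": a_scaled, "t": t,
                         "probe_ids": np.asarray(g["probe_ids"])}
        status[gid] = STATUS_ANALYZED

    df_table = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["gene_id", "probe_id", "t", "p",
                                           "sign", "unanimous"]))
    if len(df_table):
        df_table["q"] = benjamini_hochberg(df_table["p"].to_numpy())
        df_table["is_df"] = (df_table["q"] < fdr) & df_table["unanimous"]
    else:
        df_table["q"] = []
        df_table["is_df"] = []

    # genes where nearly all probes are DFs cannot be normalized reliably
    if len(df_table):
        frac = df_table.groupby("gene_id")["is_df"].mean()
        for gid in frac.index[frac > max_df_fraction]:
            status[gid] = STATUS_TOO_MANY_DFS
            per_gene.pop(gid, None)
        df_table = df_table[df_table["gene_id"].map(
            lambda g: status.get(g) == STATUS_ANALYZED)]

    scaling = pd.DataFrame(scal_rows, columns=["gene_id", "x_max",
                                               "shapiro_p", "passed"])
    ledger = GeneLedger(status=pd.Series(status, name="status"))
    return scaling, df_table.reset_index(drop=True), ledger, per_gene
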