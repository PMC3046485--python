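"""Constrained two-source mixture model for homoeolog share estimation.

A hybrid sample's intensity at diagnostic probes of one gene is modeled as a
weighted mixture of the two parental mean signals,

    S_ij = alpha * A_i + (1 - alpha) * T_i + eps_ij,

where ``A_i``/``T_i`` are the (rescaled) non-reference / reference parental
means, replicates j are i.i.d. normal, and alpha is the non-reference (Aa)
share.  Under the sum-to-one constraint the least-squares estimate has the
closed form

    alpha_hat = sum_ij (S_ij - T_i)(A_i - T_i) / sum_ij (A_i - T_i)^2 .

Deviation of a test sample's alpha from a null reference (the F1 DNA for
retention, the evolved-allotetraploid DNA for expression) is tested with an
F-ratio ("X statistic") referenced to F(1, 6n-1) for n diagnostic features
and 3 replicates.  The printed df of 6n-1 is kept even though two fitted
means would suggest 6n-2; the difference is negligible for n >= 3 and is
quantified by the null-calibration test.

Hybrid arrays carry each homoeolog at half the parental dose, so before
fitting, each hybrid sample is put on the parental scale with a per-gene
dose factor taken from the unconstrained fit S ~ a*A + b*T over all probes
(gamma = a + b); the constrained estimate on S/gamma then equals the
scale-free ratio a/(a+b) exactly.  See docs/methods.md for why this is
preferred over a kernel-density rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dfcore import benjamini_hochberg, detect_dfs

__all__ = [
    "estimate_alpha",
    "dose_factor",
    "x_statistic",
    "classify_retention",
    "classify_expression",
    "expression_call",
    "permutation_test_alpha",
]

LABEL_AA = "Aa_like"
LABEL_AT = "At_like"
LABEL_NS = "not_significant"

EXCL_NO_DF = "too_few_dfs"
EXCL_UNIDENT = "alpha_unidentifiable"
EXCL_RESID = "failed_residual_normality"
EXCL_NOT_EXPR = "not_expressed"
EXCL_DEGENERATE = "degenerate_scale"


def estimate_alpha(S: np.ndarray, A: np.ndarray, T: np.ndarray) -> float:
    """Closed-form constrained least squares for the mixture weight.

    ``S`` may be (n,) or (n, replicates); ``A``/``T`` are per-probe means.
    Raises if alpha is unidentifiable (all A_i equal to T_i).
    """
    S = np.asarray(S, dtype=float)
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    d = A - T
    denom = float(np.sum(d * d)) * S.shape[1]
    if denom == 0:
        raise ValueError("alpha unidentifiable: A_i = T_i at every feature")
    num = float(np.sum((S - T[:, None]) * d[:, None]))
    return num / denom


def dose_factor(S: np.ndarray, A: np.ndarray, T: np.ndarray) -> float:
    """Per-gene dose/scale factor from the unconstrained two-source fit.

    Solves min ||S - aA - bT||^2 over all probes and replicates and returns
    gamma = a + b.  For a balanced hybrid gamma ~ 1; for a single-homoeolog
    (deleted) gene it recovers the half-dose exactly.
    """
    return dose_factor_with_variance(S, A, T)[0]


def dose_factor_with_variance(S: np.ndarray, A: np.ndarray, T: np.ndarray
                              ) -> tuple[float, float]:
    """Dose factor gamma = a + b plus its sampling variance from the OLS
    covariance of (a, b).  The variance feeds the plug-in correction of the
    mixture test: a scale estimated with ~1% error perturbs alpha-hat
    coherently across probes, which the i.i.d.-error F reference would
    otherwise ignore."""
    gamma, h, _, s2 = _dose_fit(S, A, T)
    return gamma, float(s2) * float(np.sum(h * h))


def _dose_fit(S: np.ndarray, A: np.ndarray, T: np.ndarray):
    """Unconstrained two-source fit over all probes and replicates.

    Returns (gamma, h, r, s2) where ``h`` are the observation weights of
    gamma-hat (gamma-hat = h . y), so Var(gamma-hat) = s2 * ||h||^2 and the
    covariance of gamma-hat with any other linear functional of the same
    observations is available exactly.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    r = S.shape[1]
    X = np.column_stack([np.repeat(np.asarray(A, float), r),
                         np.repeat(np.asarray(T, float), r)])
    y = S.ravel()
    XtX = X.T @ X
    try:
        inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(XtX)
    coef = inv @ (X.T @ y)
    h = X @ inv.sum(axis=1)
    resid = y - X @ coef
    dof = max(y.size - 2, 1)
    s2 = float(resid @ resid) / dof
    return float(coef.sum()), h, r, s2


def x_statistic(S: np.ndarray, F: np.ndarray, A: np.ndarray, T: np.ndarray,
                alpha1: float, alpha2: float):
    """F-ratio for H0: alpha1 = alpha2, referenced to F(1, 6n-1).

    X = 1/2 (a1-a2)^2 sum_{3n}(A_i-T_i)^2 / [(RSS_S + RSS_F)/(6n-1)],
    with probe terms repeated across replicates in the flattened sums.
    Returns (X, p, df2, pooled residual variance).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float).T).T
    F = np.atleast_2d(np.asarray(F, dtype=float).T).T
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    n, r = S.shape
    d = A - T
    ssd = r * float(np.sum(d * d))
    rss_s = float(np.sum((S - T[:, None] - alpha1 * d[:, None]) ** 2))
    rss_f = float(np.sum((F - T[:, None] - alpha2 * d[:, None]) ** 2))
    df2 = 2 * n * r - 1
    sigma2 = (rss_s + rss_f) / df2
    if sigma2 == 0:
        if alpha1 == alpha2:
            return 0.0, 1.0, df2, 0.0
        return np.inf, 0.0, df2, 0.0  # degenerate: flagged by caller via p==0
    X = 0.5 * (alpha1 - alpha2) ** 2 * ssd / sigma2
    p = float(stats.f.sf(X, 1, df2))
    return X, p, df2, sigma2


def _residual_normal(S, F, A, T, a1, a2, alpha: float) -> tuple[bool, float]:
    d = (A - T)[:, None]
    res = np.concatenate([(S - T[:, None] - a1 * d).ravel(),
                          (F - T[:, None] - a2 * d).ravel()])
    if np.ptp(res) == 0:
        return True, 1.0
    p = float(stats.shapiro(res).pvalue)
    return p >= alpha, p


@dataclass
class _GeneFit:
    gene_id: str
    alpha1: float
    alpha2: float
    n_df: int
    X: float
    p: float
    df2: int
    sigma2: float
    shapiro_p: float


def _fit_cohort(gene_iter, assay: str, fdr: float, alpha_resid: float,
                min_df: int):
    """Shared fitting loop for the retention and expression classifiers.

    ``gene_iter`` yields (gene_id, S, F, A, T, df_mask, dose_info) with S
    the test sample and F the null-reference sample, both already
    dose-normalized.  ``dose_info`` is None (no correction) or a pair of
    observation-weight vectors (h_S/gamma_S, h_F/gamma_F) from the dose
    fits; with them the reference variance of alpha1 - alpha2 accounts for
    the plug-in scale exactly to first order, including its covariance with
    the estimator (both are linear functionals of the same noise).
    """
    fits, excluded = [], []
    for gid, S, F, A, T, df_mask, dose_info in gene_iter:
        n = int(df_mask.sum())
        if n < min_df:
            excluded.append((gid, EXCL_NO_DF))
            continue
        Ad, Td = A[df_mask], T[df_mask]
        Sd, Fd = S[df_mask], F[df_mask]
        if np.all(Ad == Td):
            excluded.append((gid, EXCL_UNIDENT))
            continue
        a1 = estimate_alpha(Sd, Ad, Td)
        a2 = estimate_alpha(Fd, Ad, Td)
        ok, sp = _residual_normal(Sd, Fd, Ad, Td, a1, a2, alpha_resid)
        if not ok:
            excluded.append((gid, EXCL_RESID))
            continue
        X, p, df2, s2 = x_statistic(Sd, Fd, Ad, Td, a1, a2)
        if dose_info is not None and np.isfinite(X) and s2 > 0:
            hS, hF = dose_info
            d = Ad - Td
            r = Sd.shape[1]
            denom = r * float(np.sum(d * d))
            # alpha-hat as a linear functional of the observations
            u = np.zeros(A.size * r)
            u[np.flatnonzero(np.repeat(df_mask, r))] = np.repeat(d, r) / denom
            kS = float(np.sum(Sd * d[:, None])) / denom
            kF = float(np.sum(Fd * d[:, None])) / denom
            var_ref = s2 * (float(np.sum((u - kS * hS) ** 2))
                            + float(np.sum((u - kF * hF) ** 2)))
            if var_ref > 0:
                X_used = (a1 - a2) ** 2 / var_ref
                p = float(stats.f.sf(X_used, 1, df2))
        fits.append(_GeneFit(gid, a1, a2, n, X, p, df2, s2, sp))

    out = pd.DataFrame([vars(f) for f in fits])
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out["delta_alpha"] = out["alpha1"] - out["alpha2"]
        out["label"] = LABEL_NS
        sig = out["q"] < fdr
        out.loc[sig & (out["alpha1"] > out["alpha2"]), "label"] = LABEL_AA
        out.loc[sig & (out["alpha1"] < out["alpha2"]), "label"] = LABEL_AT
        out["assay"] = assay
        out["flag_alpha_outside"] = (out["alpha1"] < 0) | (out["alpha1"] > 1)
    excl = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    return out, excl


def classify_retention(per_gene: dict[str, dict], fdr: float = 0.05,
                       alpha_resid: float = 0.05, min_df: int = 3,
                       propagate_scale_uncertainty: bool = True):
    """Genomic retention bias: evolved-allotetraploid DNA vs F1 DNA.

    ``per_gene`` maps gene_id -> dict with A_scaled, T, S (As DNA matrix),
    F (F1As DNA matrix) and df_mask.  Both hybrid samples are dose-normalized
    per gene before the constrained fit; by default the dose factors'
    sampling uncertainty is propagated into the test variance.  Labels:
    Aa_like when alpha1 > alpha2 at BH FDR < ``fdr``; At_like for the
    reverse.
    """
    def it():
        for gid, g in per_gene.items():
            A, T = g["A_scaled"], g["T"]
            gS, hS, _, _ = _dose_fit(g["S"], A, T)
            gF, hF, _, _ = _dose_fit(g["F"], A, T)
            if gS <= 0 or gF <= 0:
                continue
            info = ((hS / gS, hF / gF)
                    if propagate_scale_uncertainty else None)
            yield gid, g["S"] / gS, g["F"] / gF, A, T, g["df_mask"], info

    return _fit_cohort(it(), "DNA_retention", fdr, alpha_resid, min_df)


def classify_expression(per_gene: dict[str, dict], fdr: float = 0.05,
                        alpha_resid: float = 0.05, min_df: int = 3,
                        df_source: str = "parental", df_fdr: float = 0.05,
                        propagate_scale_uncertainty: bool = True):
    """Expression bias: evolved-allotetraploid RNA vs its own DNA as null.

    RNA is dose/level-normalized per gene against the parental means (the
    unconstrained-fit factor absorbs expression level), then diagnostic
    features are reused from the parental DF set
    (``df_source='parental'``, default) or re-identified between RNA and DNA
    replicates (``df_source='rna_vs_dna'``; low-powered except for extreme
    biases, since the RNA-DNA contrast at a probe is the parental contrast
    scaled by the bias deviation).  The DNA alpha serves as the per-gene null.

    Genes must carry an ``expressed`` flag in ``per_gene``; unexpressed genes
    are excluded and counted.
    """
    prepared: dict[str, tuple] = {}
    excl_pre = []
    for gid, g in per_gene.items():
        if not g.get("expressed", True):
            excl_pre.append((gid, EXCL_NOT_EXPR))
            continue
        A, T = g["A_scaled"], g["T"]
        gS, hS, _, _ = _dose_fit(g["S"], A, T)
        gR, hR, _, _ = _dose_fit(g["rna"], A, T)
        if gS <= 0 or gR <= 0:
            excl_pre.append((gid, EXCL_DEGENERATE))
            continue
        info = (hR / gR, hS / gS) if propagate_scale_uncertainty else None
        prepared[gid] = (g["S"] / gS, g["rna"] / gR, A, T, g["df_mask"], info)

    if df_source == "rna_vs_dna":
        # genome-wide FDR over per-probe RNA-vs-DNA Welch tests
        frames = []
        for gid, (S, R, A, T, _, _) in prepared.items():
            d = detect_dfs(np.log2(np.maximum(R, 1e-9)),
                           np.log2(np.maximum(S, 1e-9)))
            d.insert(0, "gene_id", gid)
            frames.append(d)
        if frames:
            allp = pd.concat(frames, ignore_index=True)
            allp["q"] = benjamini_hochberg(allp["p"].to_numpy())
            allp["is_df"] = (allp["q"] < df_fdr) & allp["unanimous"]
            mask_of = {gid: grp["is_df"].to_numpy()
                       for gid, grp in allp.groupby("gene_id", sort=False)}
        else:
            mask_of = {}
    elif df_source == "parental":
        mask_of = {gid: prepared[gid][4] for gid in prepared}
    else:
        raise ValueError(f"unknown df_source {df_source!r}")

    def it():
        for gid, (S, R, A, T, _, info) in prepared.items():
            mask = mask_of.get(gid)
            if mask is None:
                mask = np.zeros(A.size, dtype=bool)
            yield gid, R, S, A, T, mask, info

    out, excl = _fit_cohort(it(), "RNA_use", fdr, alpha_resid, min_df)
    excl = pd.concat([pd.DataFrame(excl_pre, columns=["gene_id", "reason"]),
                      excl], ignore_index=True)
    return out, excl


def expression_call(gene_rna_median: pd.Series, intergenic_rna: np.ndarray,
                    percentile: float = 95.0,
                    fallback_threshold: float | None = None) -> pd.Series:
    """Expressed iff the gene's median RNA intensity clears the intergenic
    background percentile (default 95th)."""
    intergenic_rna = np.asarray(intergenic_rna, dtype=float)
    if intergenic_rna.size == 0:
        if fallback_threshold is None:
            raise ValueError("no intergenic probes and no fallback threshold")
        thr = float(fallback_threshold)
    else:
        thr = float(np.percentile(intergenic_rna, percentile))
    return gene_rna_median > thr


def permutation_test_alpha(S: np.ndarray, F: np.ndarray, A: np.ndarray,
                           T: np.ndarray, n_perm: int = 1000,
                           seed: int = 0) -> float:
    """Permutation cross-check of the X test: shuffle replicate columns
    between the test and null samples and recompute X."""
    rng = np.random.default_rng(seed)
    a1 = estimate_alpha(S, A, T)
    a2 = estimate_alpha(F, A, T)
    obs = x_statistic(S, F, A, T, a1, a2)[0]
    both = np.concatenate([S, F], axis=1)
    r = S.shape[1]
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(both.shape[1])
        Sp, Fp = both[:, idx[:r]], both[:, idx[r:]]
        b1 = estimate_alpha(Sp, A, T)
        b2 = estimate_alpha(Fp, A, T)
        if x_statistic(Sp, Fp, A, T, b1, b2)[0] >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
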