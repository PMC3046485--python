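"""End-to-end orchestration: probe table -> preprocessing -> parental
scaling and diagnostic features -> retention and expression bias tables.

This is the glue the CLI and the acceptance machinery drive; every step is
an op from the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import alphamodel, arrayio, dfcore, regionscan

__all__ = ["GeneBundles", "assemble_genes", "run_retention", "run_expression",
           "run_regionscan", "PipelineResult", "run_all"]


@dataclass
class GeneBundles:
    """Per-gene aligned matrices for every sample, plus intergenic RNA."""
    genes: dict[str, dict]
    intergenic_rna: np.ndarray
    probe_meta: pd.DataFrame


def assemble_genes(table: arrayio.ProbeIntensityTable) -> GeneBundles:
    """Pivot the long table into per-gene (probe x replicate) matrices.

    Probes are ordered by genomic position within gene; every present
    genotype/sample combination becomes a matrix under keys t (At DNA),
    a (Aa DNA), S (As DNA), F (F1As DNA), rna (As RNA).
    """
    df = table.df
    keymap = {("At", "DNA"): "t", ("Aa", "DNA"): "a", ("As", "DNA"): "S",
              ("F1As", "DNA"): "F", ("As", "RNA"): "rna"}
    wide = df.pivot_table(index=["gene_id", "chrom", "pos", "probe_id"],
                          columns=["genotype", "sample_type", "replicate"],
                          values="intensity", sort=False)
    wide = wide.sort_index(level=["gene_id", "pos"])
    meta = wide.index.to_frame(index=False)

    intergenic_rna = np.empty(0)
    genes: dict[str, dict] = {}
    for gid, sub in wide.groupby(level="gene_id", sort=True):
        mats = {}
        for (gt, st), name in keymap.items():
            try:
                m = sub.xs((gt, st), axis=1, level=("genotype", "sample_type"))
            except KeyError:
                continue
            mats[name] = m.to_numpy(dtype=float)
        mats["probe_ids"] = sub.index.get_level_values("probe_id").to_numpy()
        if gid == "":
            if "rna" in mats:
                intergenic_rna = mats["rna"].ravel()
            continue
        genes[gid] = mats
    return GeneBundles(genes=genes, intergenic_rna=intergenic_rna,
                       probe_meta=meta)


def _with_hybrids(per_gene: dict[str, dict], bundles: GeneBundles,
                  df_table: pd.DataFrame) -> dict[str, dict]:
    """Attach hybrid matrices and the DF mask to each analyzed gene."""
    df_probes = set(df_table.loc[df_table["is_df"], "probe_id"])
    out = {}
    for gid, g in per_gene.items():
        src = bundles.genes[gid]
        rec = dict(g)
        for key in ("S", "F", "rna"):
            if key in src:
                rec[key] = src[key]
        rec["df_mask"] = np.array([p in df_probes for p in g["probe_ids"]])
        out[gid] = rec
    return out


def run_retention(bundles: GeneBundles, min_probes: int = 5,
                  alpha_norm: float = 0.05, df_fdr: float = 0.05,
                  fdr: float = 0.05, min_df: int = 3):
    """Parental scaling + DF detection + retention classification."""
    scaling, df_table, ledger, per_gene = dfcore.normalize_and_detect(
        bundles.genes, min_probes=min_probes, alpha_norm=alpha_norm,
        fdr=df_fdr)
    per_gene = _with_hybrids(per_gene, bundles, df_table)
    result, excl = alphamodel.classify_retention(per_gene, fdr=fdr,
                                                 min_df=min_df)
    return result, {"scaling": scaling, "df_table": df_table,
                    "ledger": ledger, "per_gene": per_gene,
                    "excluded": excl}


def run_expression(bundles: GeneBundles, per_gene: dict[str, dict],
                   fdr: float = 0.05, min_df: int = 3,
                   df_source: str = "parental",
                   expression_percentile: float = 95.0):
    """Expression call + expression-bias classification.

    ``per_gene`` comes from :func:`run_retention` (rescaled parental means
    and hybrid matrices attached).
    """
    med = pd.Series({gid: float(np.median(g["rna"]))
                     for gid, g in per_gene.items() if "rna" in g})
    expressed = alphamodel.expression_call(med, bundles.intergenic_rna,
                                           percentile=expression_percentile,
                                           fallback_threshold=0.0)
    for gid, g in per_gene.items():
        g["expressed"] = bool(expressed.get(gid, False))
    result, excl = alphamodel.classify_expression(per_gene, fdr=fdr,
                                                  min_df=min_df,
                                                  df_source=df_source)
    return result, {"expressed": expressed, "excluded": excl}


def run_regionscan(bundles: GeneBundles, truth_positions: pd.DataFrame | None = None,
                   window: int = 30, min_same_dir: int = 27, min_sig: int = 9,
                   fdr: float = 0.05):
    """Per-gene paired tests and the sliding-window alteration scan.

    Gene coordinates are taken from the probe metadata (min/max probe pos).
    """
    calls = []
    for gid, g in bundles.genes.items():
        if "S" not in g or "F" not in g:
            continue
        s_mean = g["S"].mean(axis=1)
        f_mean = g["F"].mean(axis=1)
        calls.append(regionscan.gene_diff_test(s_mean, f_mean, gene_id=gid))
    call_df = regionscan.call_gene_table(calls, fdr=fdr)
    meta = bundles.probe_meta
    pos = meta[meta["gene_id"] != ""].groupby("gene_id").agg(
        chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max"))
    call_df = call_df.merge(pos, left_on="gene_id", right_index=True)
    regions = regionscan.scan_alteration_windows(
        call_df, window=window, min_same_dir=min_same_dir, min_sig=min_sig)
    return call_df, regions


@dataclass
class PipelineResult:
    retention: pd.DataFrame
    expression: pd.DataFrame
    gene_calls: pd.DataFrame
    regions: list
    extras: dict


def run_all(table: arrayio.ProbeIntensityTable, background: str = "none",
            **kw) -> PipelineResult:
    """Full analysis.

    Replicates are quantile-normalized within genotype throughout: the
    mixture pipeline gets cross-genotype comparability from per-gene
    scaling, and the region scan compares two hybrid samples whose arrays
    the generator draws on a common scale.  Joint As+F1As normalization
    (for arrays with technical scale differences) remains available via
    ``arrayio.preprocess(groups=arrayio.DEFAULT_GROUPS)``.
    """
    pre = arrayio.preprocess(table, background=background,
                             groups=arrayio.PER_GENOTYPE_GROUPS)
    bundles = assemble_genes(pre)
    retention, extras = run_retention(bundles, **kw)
    expression, expr_extras = run_expression(bundles, extras["per_gene"])
    gene_calls, regions = run_regionscan(bundles)
    extras.update(expr_extras)
    return PipelineResult(retention=retention, expression=expression,
                          gene_calls=gene_calls, regions=regions,
                          extras=extras)
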