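"""Truth-based evaluation harness for the synthetic study conditions.

Each function generates a cohort with the generator, runs the analysis
pipeline on it, and scores the result against the recorded ground truth.
Used by the validation suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import arrayio, pipeline, readpart, synthdata
from .alphamodel import LABEL_AA, LABEL_AT, LABEL_NS, estimate_alpha, x_statistic

__all__ = [
    "null_x_calibration",
    "retention_expression_recovery",
    "window_scan_recovery",
    "end_to_end_read_concordance",
]


def _alpha_bundles(cfg: synthdata.GeneratorConfig):
    bundle = synthdata.simulate(cfg)
    table = arrayio.ProbeIntensityTable(bundle.probes)
    pre = arrayio.preprocess(table, background="none",
                             groups=arrayio.PER_GENOTYPE_GROUPS)
    return bundle, pipeline.assemble_genes(pre)


def null_x_calibration(seed: int, n_genes: int = 10_000, n_df: int = 5,
                       n_replicates: int = 3) -> dict:
    """Distribution of the mixture F-ratio under the exact null model.

    Returns the KS comparison against F(1, 6n-1) and the empirical type-I
    error at nominal 0.05.
    """
    xs, ps = [], []
    for S, F, A, T in synthdata.simulate_null_model_genes(
            n_genes, n_df, n_replicates, seed=seed):
        a1 = estimate_alpha(S, A, T)
        a2 = estimate_alpha(F, A, T)
        X, p, df2, _ = x_statistic(S, F, A, T, a1, a2)
        xs.append(X)
        ps.append(p)
    xs = np.asarray(xs)
    ps = np.asarray(ps)
    df2 = 2 * n_df * n_replicates - 1
    ks = stats.kstest(xs, stats.f(1, df2).cdf)
    return {"ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            "type_one_error": float((ps < 0.05).mean()), "n": n_genes,
            "df2": df2}


def retention_expression_recovery(seeds=(0, 1, 2), n_genes: int = 2000) -> dict:
    """Label recovery on deletion cohorts with uniform expression bias.

    Sensitivity and false-discovery proportion are pooled over the cohort
    seeds (the realized FDP of a single Benjamini-Hochberg run fluctuates);
    the expression Spearman correlation is averaged.
    """
    called = false = n_del = correct = 0
    analyzed = total = 0
    rhos = []
    for seed in seeds:
        cfg = synthdata.GeneratorConfig(
            n_genes=n_genes, seed=seed, n_chromosomes=5,
            fraction_At_deleted=0.1, fraction_Aa_deleted=0.1)
        bundle, bundles = _alpha_bundles(cfg)
        retention, extras = pipeline.run_retention(bundles)
        expression, _ = pipeline.run_expression(bundles, extras["per_gene"])
        truth = bundle.truth.set_index("gene_id")

        m = retention.merge(truth, left_on="gene_id", right_index=True)
        analyzed += len(m)
        total += n_genes
        dele = m[m.retention_state != synthdata.RETENTION_BOTH]
        ok = (((dele.retention_state == synthdata.RETENTION_AT_DELETED)
               & (dele.label == LABEL_AA))
              | ((dele.retention_state == synthdata.RETENTION_AA_DELETED)
                 & (dele.label == LABEL_AT)))
        wrong = ((m.label != LABEL_NS)
                 & ~(((m.retention_state == synthdata.RETENTION_AT_DELETED)
                      & (m.label == LABEL_AA))
                     | ((m.retention_state == synthdata.RETENTION_AA_DELETED)
                        & (m.label == LABEL_AT))))
        n_del += len(dele)
        correct += int(ok.sum())
        called += int((m.label != LABEL_NS).sum())
        false += int(wrong.sum())

        me = expression.merge(truth, left_on="gene_id", right_index=True)
        me = me[me.retention_state == synthdata.RETENTION_BOTH]
        rhos.append(float(stats.spearmanr(
            me["alpha1"], me["expression_alpha_true"]).statistic))

    return {"sensitivity": correct / n_del,
            "fdr": false / max(called, 1),
            "spearman": float(np.mean(rhos)),
            "yield": analyzed / total,
            "n_deleted": n_del, "n_called": called,
            "n_genes_per_cohort": n_genes, "n_cohorts": len(seeds)}


def window_scan_recovery(seed: int, n_genes: int = 2000, block: int = 40,
                         n_null_runs: int = 20) -> dict:
    """Planted-block recovery plus the null false-region rate.

    The planted cohort carries one ``block``-gene homoeolog-loss run; null
    cohorts are scanned with the same thresholds (window 30, 27
    unidirectional, 9 significant).
    """
    cfg = synthdata.GeneratorConfig(
        n_genes=n_genes, seed=seed, n_chromosomes=5,
        cluster_spec=[synthdata.ClusterSpec(chrom="chr2", start_index=100,
                                            n_genes=block, direction="loss")])
    bundle, bundles = _alpha_bundles(cfg)
    _, regions = pipeline.run_regionscan(bundles)
    covered = any(r.chrom == "chr2" and r.start_gene_index <= 100
                  and r.end_gene_index >= 100 + block - 1 for r in regions)

    null_counts = []
    for k in range(n_null_runs):
        cfg0 = synthdata.GeneratorConfig(n_genes=n_genes,
                                         seed=(seed + 1) * 1000 + k,
                                         n_chromosomes=5)
        _, bundles0 = _alpha_bundles(cfg0)
        _, regions0 = pipeline.run_regionscan(bundles0)
        null_counts.append(len(regions0))

    return {"planted_regions": len(regions),
            "planted_block_covered": bool(covered),
            "null_false_regions_mean": float(np.mean(null_counts)),
            "n_null_runs": n_null_runs, "n_genes": n_genes}


def end_to_end_read_concordance(seed: int, n_genes: int = 100) -> dict:
    """Arrays and reads from one truth: array alpha vs read ratio, and
    read-assignment accuracy against recorded fragment origins."""
    cfg = synthdata.GeneratorConfig(n_genes=n_genes, seed=seed,
                                    indel_rate=0.005)
    bundle = synthdata.simulate(cfg, reads=True)
    table = arrayio.ProbeIntensityTable(bundle.probes)
    pre = arrayio.preprocess(table, background="none",
                             groups=arrayio.PER_GENOTYPE_GROUPS)
    bundles = pipeline.assemble_genes(pre)
    _, extras = pipeline.run_retention(bundles)
    expression, _ = pipeline.run_expression(bundles, extras["per_gene"])
    array_alpha = expression.set_index("gene_id")["alpha1"]

    seqs = bundle.sequences
    aligns = {g: readpart.align_ortholog_pair(seqs.at[g], seqs.aa[g],
                                              gene_id=g) for g in seqs.at}
    assignments = readpart.partition_fragments(bundle.reads, aligns)
    merged = assignments.merge(bundle.reads[["read_id", "origin"]],
                               on="read_id")
    overlapping = merged[merged["informative_sites"] > 0]
    calls = merged[merged["call"].isin(["At", "Aa"])]
    accuracy = float((calls["call"] == calls["origin"]).mean())
    call_rate = len(calls) / max(len(overlapping), 1)

    lengths = {g: (len(seqs.at[g]), len(seqs.aa[g])) for g in aligns}
    fpk = readpart.fpk_quantify(assignments, lengths)
    tab, r2, p = readpart.concordance_with_array(
        fpk.set_index("gene_id")["ratio"], array_alpha)
    return {"r_squared": r2, "p": p, "n_genes_compared": len(tab),
            "read_accuracy": accuracy, "read_call_rate": float(call_rate),
            "n_fragments": len(merged)}
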