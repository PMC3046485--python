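"""Synthetic allotetraploid array and read data with planted ground truth.

Emulates the measurement setting of a parental-reference tiling array applied
to an allotetraploid: two parental genomes (here called ``At`` and ``Aa``)
diverged at a configurable per-base rate, 25-mer probes tiled along the ``At``
reference, mismatch-driven signal attenuation for the non-reference parent, an
unevolved F1 allotetraploid (``F1As``) with exactly equal homoeolog dose, and
an evolved allotetraploid (``As``) carrying planted homoeolog deletions,
expression biases, clustered multi-gene alterations and network-correlated
biases.  A paired-end read simulator draws transcript fragments from the two
homoeologs so that read-partitioning can be validated against recorded truth.

Every generator op derives its random stream from ``(cfg.seed, op_tag)`` so a
fixed config reproduces outputs byte for byte, independently of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterSpec",
    "NetworkSpec",
    "GeneratorConfig",
    "SimulatedSequences",
    "SimBundle",
    "generate_parental_sequences",
    "generate_probe_intensities",
    "generate_reads",
    "generate_network",
    "simulate",
    "simulate_null_model_genes",
    "write_fasta",
    "write_fastq",
    "write_gff3",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed per-op salt for seed streams; changing these changes all outputs
_TAG_SEQ = 1
_TAG_ARRAY = 2
_TAG_READS = 3
_TAG_NETWORK = 4

RETENTION_BOTH = "both"
RETENTION_AT_DELETED = "At_deleted"
RETENTION_AA_DELETED = "Aa_deleted"


@dataclass(frozen=True)
class ClusterSpec:
    """A planted multi-gene alteration block.

    direction "loss" deletes one homoeolog (``deleted_parent``) in every gene
    of the block (weaker hybridization in As); "gain" raises As dosage by
    ``gain_factor`` (stronger hybridization in As).
    """

    chrom: str
    start_index: int          # gene-order index within the chromosome
    n_genes: int
    direction: str = "loss"   # {"loss", "gain"}
    deleted_parent: str = "At"
    gain_factor: float = 1.5


@dataclass(frozen=True)
class NetworkSpec:
    n_networks: int = 30
    genes_per_network: int = 6
    co_bias_strength: float = 0.9
    within_score: tuple[float, float] = (0.6, 1.0)
    background_score: tuple[float, float] = (0.0, 0.4)
    n_background_pairs: int = 300
    # alpha ranges used to plant a direction on member genes
    aa_alpha_range: tuple[float, float] = (0.75, 0.95)
    at_alpha_range: tuple[float, float] = (0.05, 0.25)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the measurement setting the analysis assumes: parental
    genomes diverged at 1/20 bases, 25-base probes every 35 bases, three
    i.i.d. biological replicates, paired 72-base reads.  Noise magnitudes
    (``noise_sd``, per-mismatch attenuation) were calibrated once so that
    diagnostic-feature detection at three replicates has intermediate power
    (neither saturated nor hopeless); see docs/methods.md.
    """

    n_genes: int = 200
    gene_length: int = 500
    n_chromosomes: int = 2
    intergenic_gap: int = 300
    probe_length: int = 25
    tiling_step: int = 35
    n_replicates: int = 3

    divergence: float = 0.05
    indel_rate: float = 0.0            # parental indels; keep 0 for array sims
    indel_max_len: int = 3
    # extra substitutions separating the As homoeolog copies from the extant
    # parental references (larger for Aa, which holds more standing variation)
    as_extra_divergence_at: float = 0.002
    as_extra_divergence_aa: float = 0.006

    # signal model
    base_log2_mean: float = 10.0
    base_log2_sd: float = 1.0
    probe_affinity_sd: float = 0.1
    loss_log2_per_mismatch: float = 0.45   # mean attenuation, factor ~0.73
    loss_log2_sd: float = 0.25             # per-substitution-site spread
    noise_sd: float = 0.12                 # replicate log2 noise
    additive_background: float = 0.0       # flat additive offset (a.u.)
    background_log2_mean: float = 6.0
    background_log2_sd: float = 0.5
    n_intergenic_probes: int = 400

    # planted truth
    fraction_At_deleted: float = 0.0
    fraction_Aa_deleted: float = 0.0
    expressed_fraction: float = 1.0
    alpha_mode: str = "uniform"            # {"uniform", "balanced"}
    expr_log2_sd: float = 0.8
    cluster_spec: list[ClusterSpec] = field(default_factory=list)
    network_spec: NetworkSpec | None = None

    # reads
    read_length: int = 72
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 20.0
    read_depth_fpk: float = 150.0          # expected fragments per kb at expr=1
    sequencing_error: float = 0.005

    seed: int = 0

    @property
    def probes_per_gene(self) -> int:
        return (self.gene_length - self.probe_length) // self.tiling_step + 1

    def validate(self) -> None:
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError(f"divergence must be in [0, 0.5], got {self.divergence}")
        if self.probe_length <= 0 or self.tiling_step <= 0:
            raise ValueError("probe_length and tiling_step must be positive")
        fdel = self.fraction_At_deleted + self.fraction_Aa_deleted
        if (min(self.fraction_At_deleted, self.fraction_Aa_deleted) < 0
                or fdel > 1):
            raise ValueError("deletion fractions must be in [0,1] and sum <= 1")
        if self.read_length > self.gene_length:
            raise ValueError("read length exceeds transcript length")
        if self.network_spec is not None and self.network_spec.genes_per_network < 2:
            raise ValueError("network size must be >= 2")
        if self.gene_length < self.probe_length:
            raise ValueError("gene shorter than a probe")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulatedSequences:
    """Per-gene parental and allotetraploid homoeolog sequences.

    ``at``/``aa`` are the extant parental references; ``as_at``/``as_aa`` the
    homoeolog copies carried by the evolved allotetraploid (slightly diverged
    from the references).  ``sub_positions``/``sub_losses`` record, on At
    coordinates, the parental substitution sites and the per-site log2 signal
    attenuation they cause under a 25-mer.
    """

    at: dict[str, str]
    aa: dict[str, str]
    as_at: dict[str, str]
    as_aa: dict[str, str]
    sub_positions: dict[str, np.ndarray]
    sub_losses: dict[str, np.ndarray]


@dataclass
class SimBundle:
    cfg: GeneratorConfig
    truth: pd.DataFrame
    sequences: SimulatedSequences
    probes: "pd.DataFrame"
    reads: pd.DataFrame | None = None
    network_edges: pd.DataFrame | None = None


def _rng(cfg: GeneratorConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), tag])


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Substitute bases at ``rate``; returns (mutated copy, positions)."""
    mask = rng.random(seq.size) < rate
    pos = np.flatnonzero(mask)
    out = seq.copy()
    if pos.size:
        out[pos] = (out[pos] + rng.integers(1, 4, size=pos.size)) % 4
    return out, pos


def _apply_indels(rng: np.random.Generator, seq: np.ndarray, rate: float,
                  max_len: int) -> np.ndarray:
    if rate <= 0:
        return seq
    n_events = rng.poisson(rate * seq.size)
    if n_events == 0:
        return seq
    out = seq
    for _ in range(n_events):
        p = int(rng.integers(0, out.size))
        ln = int(rng.integers(1, max_len + 1))
        if rng.random() < 0.5 and out.size > ln + 50:
            out = np.concatenate([out[:p], out[p + ln:]])
        else:
            ins = _random_seq(rng, ln)
            out = np.concatenate([out[:p], ins, out[p:]])
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def generate_parental_sequences(cfg: GeneratorConfig) -> tuple[SimulatedSequences, pd.DataFrame]:
    """Draw parental ortholog pairs and the planted per-gene truth table.

    The Aa ortholog derives from the At sequence by substitutions at
    ``cfg.divergence`` (optionally short indels); each substitution site gets
    a fixed log2 attenuation drawn once, so probe-level signal loss is
    sequence-determined.  Truth records retention state, expression alpha,
    cluster membership and dosage for every gene.
    """
    cfg.validate()
    rng = _rng(cfg, _TAG_SEQ)

    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    per_chrom = int(np.ceil(n / cfg.n_chromosomes))
    chroms, starts, chrom_index = [], [], []
    for i in range(n):
        c = i // per_chrom
        j = i % per_chrom
        chroms.append(f"chr{c + 1}")
        chrom_index.append(j)
        starts.append(j * (cfg.gene_length + cfg.intergenic_gap))

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": chroms,
        "chrom_gene_index": chrom_index,
        "start": starts,
        "end": [s + cfg.gene_length for s in starts],
        "retention_state": RETENTION_BOTH,
        "as_dosage": 1.0,
        "in_alteration_cluster": False,
        "network_id": pd.Series([pd.NA] * n, dtype="object"),
        "divergence_rate": float(cfg.divergence),
    })

    # planted clusters first (they own their genes), then random deletions
    clustered = np.zeros(n, dtype=bool)
    for spec in cfg.cluster_spec:
        sel = truth.index[(truth["chrom"] == spec.chrom)
                          & (truth["chrom_gene_index"] >= spec.start_index)
                          & (truth["chrom_gene_index"] < spec.start_index + spec.n_genes)]
        if len(sel) < spec.n_genes:
            raise ValueError(f"cluster {spec} does not fit on {spec.chrom}")
        truth.loc[sel, "in_alteration_cluster"] = True
        clustered[sel] = True
        if spec.direction == "loss":
            state = (RETENTION_AT_DELETED if spec.deleted_parent == "At"
                     else RETENTION_AA_DELETED)
            truth.loc[sel, "retention_state"] = state
        elif spec.direction == "gain":
            truth.loc[sel, "as_dosage"] = spec.gain_factor
        else:
            raise ValueError(f"unknown cluster direction {spec.direction!r}")

    free = np.flatnonzero(~clustered)
    rng.shuffle(free)
    n_at_del = int(round(cfg.fraction_At_deleted * n))
    n_aa_del = int(round(cfg.fraction_Aa_deleted * n))
    if n_at_del + n_aa_del > free.size:
        raise ValueError("deletion fractions exceed unclustered genes")
    truth.loc[free[:n_at_del], "retention_state"] = RETENTION_AT_DELETED
    truth.loc[free[n_at_del:n_at_del + n_aa_del], "retention_state"] = RETENTION_AA_DELETED

    truth["expressed"] = rng.random(n) < cfg.expressed_fraction
    truth["expr_log2"] = np.where(truth["expressed"],
                                  rng.normal(0.0, cfg.expr_log2_sd, size=n), 0.0)

    if cfg.alpha_mode == "uniform":
        alpha = rng.random(n)
    elif cfg.alpha_mode == "balanced":
        alpha = np.full(n, 0.5)
    else:
        raise ValueError(f"unknown alpha_mode {cfg.alpha_mode!r}")
    alpha[truth["retention_state"] == RETENTION_AT_DELETED] = 1.0
    alpha[truth["retention_state"] == RETENTION_AA_DELETED] = 0.0
    truth["expression_alpha_true"] = alpha

    at, aa, as_at, as_aa = {}, {}, {}, {}
    sub_pos, sub_loss = {}, {}
    for gid in gene_ids:
        ref = _random_seq(rng, cfg.gene_length)
        aa_sub, pos = _mutate(rng, ref, cfg.divergence)
        losses = rng.normal(cfg.loss_log2_per_mismatch, cfg.loss_log2_sd,
                            size=pos.size)
        aa_final = _apply_indels(rng, aa_sub, cfg.indel_rate, cfg.indel_max_len)
        at_copy, _ = _mutate(rng, ref, cfg.as_extra_divergence_at)
        aa_copy, _ = _mutate(rng, aa_final, cfg.as_extra_divergence_aa)
        at[gid] = _to_str(ref)
        aa[gid] = _to_str(aa_final)
        as_at[gid] = _to_str(at_copy)
        as_aa[gid] = _to_str(aa_copy)
        sub_pos[gid] = pos
        sub_loss[gid] = losses

    seqs = SimulatedSequences(at=at, aa=aa, as_at=as_at, as_aa=as_aa,
                              sub_positions=sub_pos, sub_losses=sub_loss)
    return seqs, truth


def probe_attenuation(cfg: GeneratorConfig, seqs: SimulatedSequences,
                      gene_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-probe (start, mismatch count, log2 attenuation) for one gene."""
    pos = seqs.sub_positions[gene_id]
    losses = seqs.sub_losses[gene_id]
    starts = np.arange(0, cfg.gene_length - cfg.probe_length + 1, cfg.tiling_step)
    mism = np.zeros(starts.size, dtype=int)
    att = np.zeros(starts.size)
    if pos.size:
        idx = np.searchsorted(pos, starts)
        idx_end = np.searchsorted(pos, starts + cfg.probe_length)
        cum = np.concatenate([[0.0], np.cumsum(losses)])
        mism = idx_end - idx
        att = cum[idx_end] - cum[idx]
    return starts, mism, att


def expected_probe_signal(cfg: GeneratorConfig, truth_row: pd.Series,
                          at_sig: np.ndarray, aa_sig: np.ndarray,
                          genotype: str, sample_type: str) -> np.ndarray:
    """Noise-free expected intensity for each probe of a gene.

    The F1 allotetraploid and balanced As carry each homoeolog at half the
    dose of the pure parent, so their expectation is the parental average; a
    deleted homoeolog contributes zero.
    """
    if sample_type == "DNA":
        if genotype == "At":
            return at_sig
        if genotype == "Aa":
            return aa_sig
        if genotype == "F1As":
            return (at_sig + aa_sig) / 2.0
        if genotype == "As":
            state = truth_row["retention_state"]
            dose = float(truth_row["as_dosage"])
            if state == RETENTION_BOTH:
                return dose * (at_sig + aa_sig) / 2.0
            if state == RETENTION_AT_DELETED:
                return dose * aa_sig / 2.0
            if state == RETENTION_AA_DELETED:
                return dose * at_sig / 2.0
            raise ValueError(f"unknown retention state {state!r}")
    if sample_type == "RNA" and genotype == "As":
        if not truth_row["expressed"]:
            return np.full(at_sig.shape, 2.0 ** cfg.background_log2_mean)
        a = float(truth_row["expression_alpha_true"])
        e = 2.0 ** float(truth_row["expr_log2"])
        return e * ((1.0 - a) * at_sig + a * aa_sig)
    raise ValueError(f"no array for genotype={genotype!r} sample={sample_type!r}")


ARRAYS = [("At", "DNA"), ("Aa", "DNA"), ("F1As", "DNA"), ("As", "DNA"), ("As", "RNA")]


def generate_probe_intensities(cfg: GeneratorConfig, seqs: SimulatedSequences,
                               truth: pd.DataFrame) -> pd.DataFrame:
    """Long-format probe table for all genotypes, replicates and sample types.

    Columns: probe_id, chrom, pos, gene_id, genotype, sample_type, replicate,
    intensity.  Includes intergenic probes (empty gene_id) carrying genomic
    DNA signal and background RNA signal.
    """
    cfg.validate()
    rng = _rng(cfg, _TAG_ARRAY)
    n_rep = cfg.n_replicates

    meta_frames = []
    at_sig_all, aa_sig_all = [], []
    expected: dict[tuple[str, str], list[np.ndarray]] = {k: [] for k in ARRAYS}

    missing = [g for g in truth["gene_id"] if g not in seqs.at]
    if missing:
        raise KeyError(f"missing sequence for gene(s): {missing[:5]}")

    for _, row in truth.iterrows():
        gid = row["gene_id"]
        starts, _, att = probe_attenuation(cfg, seqs, gid)
        base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)
        affinity = rng.normal(0.0, cfg.probe_affinity_sd, size=starts.size)
        at_sig = 2.0 ** (base + affinity)
        aa_sig = at_sig * 2.0 ** (-att)
        at_sig_all.append(at_sig)
        aa_sig_all.append(aa_sig)
        meta_frames.append(pd.DataFrame({
            "probe_id": [f"{gid}_p{k:03d}" for k in range(starts.size)],
            "chrom": row["chrom"],
            "pos": row["start"] + starts,
            "gene_id": gid,
        }))
        for gt, st in ARRAYS:
            expected[(gt, st)].append(
                expected_probe_signal(cfg, row, at_sig, aa_sig, gt, st))

    # intergenic probes: plain genomic signal, background RNA
    n_ig = cfg.n_intergenic_probes
    if n_ig:
        ig_base = 2.0 ** rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n_ig)
        ig_rna = 2.0 ** rng.normal(cfg.background_log2_mean,
                                   cfg.background_log2_sd, size=n_ig)
        meta_frames.append(pd.DataFrame({
            "probe_id": [f"ig_p{k:05d}" for k in range(n_ig)],
            "chrom": "chrU",
            "pos": np.arange(n_ig) * cfg.tiling_step,
            "gene_id": "",
        }))
        for gt, st in ARRAYS:
            expected[(gt, st)].append(ig_rna if st == "RNA" else ig_base)

    meta = pd.concat(meta_frames, ignore_index=True)
    n_probes = len(meta)

    records = []
    for gt, st in ARRAYS:
        exp = np.concatenate(expected[(gt, st)])
        for j in range(1, n_rep + 1):
            noise = 2.0 ** rng.normal(0.0, cfg.noise_sd, size=n_probes)
            rec = meta.copy()
            rec["genotype"] = gt
            rec["sample_type"] = st
            rec["replicate"] = j
            rec["intensity"] = np.maximum(exp * noise, 1e-6) + cfg.additive_background
            records.append(rec)
    return pd.concat(records, ignore_index=True)


def generate_reads(cfg: GeneratorConfig, seqs: SimulatedSequences,
                   truth: pd.DataFrame) -> pd.DataFrame:
    """Paired-end transcript fragments from the As homoeolog copies.

    Each fragment originates from the Aa homoeolog with probability
    ``expression_alpha_true``; the origin is recorded in the read name
    (``<gene>_f<k>_<origin>``) as the loss-free truth channel.  Returns one
    row per fragment with both mate sequences.
    """
    cfg.validate()
    rng = _rng(cfg, _TAG_READS)
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on 0..3 codes
    rows = []
    for _, row in truth.iterrows():
        if not row["expressed"]:
            continue
        gid = row["gene_id"]
        alpha = float(row["expression_alpha_true"])
        e = 2.0 ** float(row["expr_log2"])
        src = {
            "At": np.frombuffer(seqs.as_at[gid].encode(), dtype=np.uint8),
            "Aa": np.frombuffer(seqs.as_aa[gid].encode(), dtype=np.uint8),
        }
        # map ASCII back to 0..3
        lut = np.zeros(256, dtype=np.uint8)
        lut[ord("C")], lut[ord("G")], lut[ord("T")] = 1, 2, 3
        src = {k: lut[v] for k, v in src.items()}
        mean_len = min(len(src["At"]), len(src["Aa"]))
        depth = cfg.read_depth_fpk * (mean_len / 1000.0) * e
        n_frag = rng.poisson(depth)
        for k in range(n_frag):
            origin = "Aa" if rng.random() < alpha else "At"
            tpl = src[origin]
            flen = int(np.clip(rng.normal(cfg.fragment_length_mean,
                                          cfg.fragment_length_sd),
                               2 * cfg.read_length - 20, tpl.size))
            flen = min(flen, tpl.size)
            start = int(rng.integers(0, tpl.size - flen + 1))
            frag = tpl[start:start + flen]
            m1 = frag[:cfg.read_length].copy()
            m2 = comp[frag[-cfg.read_length:]][::-1].copy()
            for m in (m1, m2):
                err = rng.random(m.size) < cfg.sequencing_error
                ne = int(err.sum())
                if ne:
                    m[err] = (m[err] + rng.integers(1, 4, size=ne)) % 4
            rows.append((f"{gid}_f{k:05d}_{origin}", gid, origin,
                         _to_str(m1), _to_str(m2)))
    return pd.DataFrame(rows, columns=["read_id", "gene_id", "origin",
                                       "mate1", "mate2"])


def generate_network(cfg: GeneratorConfig, truth: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant co-biased interaction networks; returns (edges, updated truth).

    Within-network gene pairs receive high connectedness scores and share the
    network's bias direction with probability ``co_bias_strength``; background
    pairs get low scores and independent directions.  Member genes' expression
    alphas are overwritten to realize the planted direction, so this must run
    before :func:`generate_probe_intensities` / :func:`generate_reads`.
    """
    spec = cfg.network_spec
    if spec is None:
        raise ValueError("cfg.network_spec is not set")
    if spec.genes_per_network < 2:
        raise ValueError("network size must be >= 2")
    rng = _rng(cfg, _TAG_NETWORK)
    truth = truth.copy()

    eligible = truth.index[(truth["retention_state"] == RETENTION_BOTH)
                           & truth["expressed"]].to_numpy()
    need = spec.n_networks * spec.genes_per_network
    if eligible.size < need:
        raise ValueError(f"need {need} eligible genes, have {eligible.size}")
    members = rng.choice(eligible, size=need, replace=False)
    members = members.reshape(spec.n_networks, spec.genes_per_network)

    edges = []
    for net_i, idxs in enumerate(members):
        net_id = f"net{net_i:03d}"
        net_dir = "Aa" if rng.random() < 0.5 else "At"
        for idx in idxs:
            d = net_dir if rng.random() < spec.co_bias_strength else \
                ("Aa" if rng.random() < 0.5 else "At")
            lo, hi = (spec.aa_alpha_range if d == "Aa" else spec.at_alpha_range)
            truth.loc[idx, "expression_alpha_true"] = rng.uniform(lo, hi)
            truth.loc[idx, "network_id"] = net_id
        gids = truth.loc[idxs, "gene_id"].tolist()
        for a in range(len(gids)):
            for b in range(a + 1, len(gids)):
                edges.append((gids[a], gids[b],
                              rng.uniform(*spec.within_score), net_id))

    all_gids = truth["gene_id"].to_numpy()
    for _ in range(spec.n_background_pairs):
        a, b = rng.choice(all_gids, size=2, replace=False)
        edges.append((a, b, rng.uniform(*spec.background_score), ""))

    edges = pd.DataFrame(edges, columns=["gene_a", "gene_b", "connectedness",
                                         "network_id"])
    return edges, truth


def simulate(cfg: GeneratorConfig, reads: bool = False) -> SimBundle:
    """Run the full generator in the required order."""
    seqs, truth = generate_parental_sequences(cfg)
    edges = None
    if cfg.network_spec is not None:
        edges, truth = generate_network(cfg, truth)
    probes = generate_probe_intensities(cfg, seqs, truth)
    rd = generate_reads(cfg, seqs, truth) if reads else None
    return SimBundle(cfg=cfg, truth=truth, sequences=seqs, probes=probes,
                     reads=rd, network_edges=edges)


def simulate_null_model_genes(n_genes: int, n_df: int, n_replicates: int,
                              seed: int, sigma: float = 30.0,
                              alpha: float = 0.5):
    """Draw genes straight from the two-source linear model under the null.

    For each gene: parental means ``T_i`` (log-normal) and ``A_i`` (attenuated
    ``T_i``), then ``S_ij`` and ``F_ij`` both equal to
    ``alpha*A_i + (1-alpha)*T_i`` plus i.i.d. normal error with sd ``sigma``.
    Used to calibrate the null distribution of the mixture F statistic.

    Yields tuples ``(S, F, A, T)`` with S, F of shape (n_df, n_replicates).
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_genes):
        T = 2.0 ** rng.normal(10.0, 1.0, size=n_df)
        mism = 1 + rng.poisson(0.8, size=n_df)
        A = T * 0.8 ** mism
        mu = alpha * A + (1 - alpha) * T
        S = mu[:, None] + rng.normal(0.0, sigma, size=(n_df, n_replicates))
        F = mu[:, None] + rng.normal(0.0, sigma, size=(n_df, n_replicates))
        yield S, F, A, T


# ---------------------------------------------------------------------------
# writers (plain-text external formats)

def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq(path1, path2, reads: pd.DataFrame) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads.itertuples():
            q1 = "I" * len(r.mate1)
            q2 = "I" * len(r.mate2)
            f1.write(f"@{r.read_id}/1\n{r.mate1}\n+\n{q1}\n")
            f2.write(f"@{r.read_id}/2\n{r.mate2}\n+\n{q2}\n")


def write_gff3(path, truth: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in truth.itertuples():
            # internal 0-based half-open -> GFF3 1-based inclusive
            fh.write(f"{r.chrom}\tsynthdata\tgene\t{r.start + 1}\t{r.end}\t.\t+\t.\t"
                     f"ID={r.gene_id}\n")


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_network(path, edges: pd.DataFrame) -> None:
    edges.to_csv(path, sep="\t", index=False)
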