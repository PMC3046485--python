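"""Read-based validation: ortholog alignment, diagnostic variants, and
parent-of-origin read partitioning.

A global Needleman-Wunsch alignment (affine gaps) of each ortholog pair
yields a variant map (SNPs and short indels) between the two parental
transcripts.  Transcriptome reads are placed on both orthologs (exact-seed
candidate lookup followed by banded semi-global alignment via edlib,
tolerating up to 10 edits as in short-read mapping practice) and scanned for
the diagnostic variants they overlap: each overlapped SNP site votes for the
parent whose allele the read carries.  A read (or fragment, combining mates)
is assigned to a parent only when no opposing votes exceed the conflict
tolerance (default zero).  Per-gene counts are length-normalized to FPK
(fragments per kilobase of the transcript model); no per-million term is
used because the two orthologs are compared within one library.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Scoring", "Variant", "OrthologPairAlignment", "ReadAssignment",
    "HomoeologReadCounts", "align_ortholog_pair", "needleman_wunsch",
    "ReadMapper", "assign_read", "partition_fragments", "fpk_quantify",
    "concordance_with_array", "homoeolog_divergence", "read_sam_votes",
]

_NEG = -1e9
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0   # first gapped base
    gap_extend: float = -1.0  # each further gapped base


@dataclass(frozen=True)
class Variant:
    at_position: int   # 0-based on the At ortholog (site, or base before an insertion)
    aa_position: int
    type: str          # {"SNP", "insertion", "deletion"} relative to At
    at_allele: str
    aa_allele: str


@dataclass
class OrthologPairAlignment:
    gene_id: str
    at_seq: str
    aa_seq: str
    at_aligned: str
    aa_aligned: str
    score: float
    variants: list[Variant]
    divergence: float  # variant columns per aligned column


@dataclass
class ReadAssignment:
    read_id: str
    gene_id: str
    informative_sites: int
    at_support: int
    aa_support: int
    call: str  # {"At", "Aa", "ambiguous", "conflicting", "unmapped"}


def _check_alphabet(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{name}: non-nucleotide characters {sorted(bad)}")


def needleman_wunsch(s: str, t: str, scoring: Scoring = Scoring()
                     ) -> tuple[float, str, str]:
    """Global alignment with affine gaps; returns (score, s_aligned, t_aligned).

    A gap of length k scores gap_open + (k-1)*gap_extend.  Columns involving
    N score 0 (neutral).  Ties in the traceback prefer substitution, then a
    gap in ``t``, then a gap in ``s`` (deterministic).
    """
    n, m = len(s), len(t)
    sc = scoring
    sv = np.frombuffer(s.encode(), dtype=np.uint8)
    tv = np.frombuffer(t.encode(), dtype=np.uint8)
    isn_s = sv == ord("N")
    isn_t = tv == ord("N")
    # substitution score row for s[i-1] against all of t
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in t (consumes s)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in s (consumes t)
    M[0, 0] = 0.0
    if n:
        Ix[1:, 0] = sc.gap_open + np.arange(n) * sc.gap_extend
    if m:
        Iy[0, 1:] = sc.gap_open + np.arange(m) * sc.gap_extend
    ext = sc.gap_extend
    opn = sc.gap_open
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        subs = np.where(isn_t | isn_s[i - 1], 0.0,
                        np.where(tv == sv[i - 1], sc.match, sc.mismatch))
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = subs + best_prev[:-1]
        Ix[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:] + opn,
                                          Ix[i - 1, 1:] + ext),
                               Iy[i - 1, 1:] + opn)
        Ix[i, 0] = opn + (i - 1) * ext
        # within-row horizontal gap via running max
        cand = np.maximum(M[i, :-1] + opn, Ix[i, :-1] + opn)
        w = np.maximum.accumulate(cand - ext * (j_idx[:-1] + 1))
        Iy[i, 1:] = ext * j_idx[1:] + w

    def _pick(val, options):
        for st, v in options:
            if np.isclose(v, val, atol=1e-6):
                return st
        raise AssertionError("traceback failed")  # pragma: no cover

    out_s, out_t = [], []
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    score = float((M[n, m], Ix[n, m], Iy[n, m])[state])
    while i > 0 or j > 0:
        if state == 0:  # substitution column
            sub = 0.0 if (isn_s[i - 1] or isn_t[j - 1]) else \
                (sc.match if s[i - 1] == t[j - 1] else sc.mismatch)
            prev = M[i, j] - sub
            out_s.append(s[i - 1])
            out_t.append(t[j - 1])
            i, j = i - 1, j - 1
            state = _pick(prev, [(0, M[i, j]), (1, Ix[i, j]), (2, Iy[i, j])])
        elif state == 1:  # gap in t, consume s[i-1]
            val = Ix[i, j]
            out_s.append(s[i - 1])
            out_t.append("-")
            i -= 1
            state = _pick(val, [(0, M[i, j] + opn), (1, Ix[i, j] + ext),
                                (2, Iy[i, j] + opn)])
        else:  # gap in s, consume t[j-1]
            val = Iy[i, j]
            out_s.append("-")
            out_t.append(t[j - 1])
            j -= 1
            state = _pick(val, [(0, M[i, j] + opn), (1, Ix[i, j] + opn),
                                (2, Iy[i, j] + ext)])
    return score, "".join(reversed(out_s)), "".join(reversed(out_t))


def _extract_variants(at_al: str, aa_al: str) -> list[Variant]:
    variants: list[Variant] = []
    i = j = 0  # positions on At / Aa
    k = 0
    L = len(at_al)
    while k < L:
        a, b = at_al[k], aa_al[k]
        if a != "-" and b != "-":
            if a != b and a != "N" and b != "N":
                variants.append(Variant(i, j, "SNP", a, b))
            i += 1
            j += 1
            k += 1
        elif b == "-":  # run absent from Aa: deletion relative to At
            start_i, start_j = i, j
            run = []
            while k < L and aa_al[k] == "-":
                run.append(at_al[k])
                i += 1
                k += 1
            variants.append(Variant(start_i, start_j, "deletion",
                                    "".join(run), ""))
        else:  # run present only in Aa: insertion relative to At
            start_i, start_j = i, j
            run = []
            while k < L and at_al[k] == "-":
                run.append(aa_al[k])
                j += 1
                k += 1
            variants.append(Variant(start_i, start_j, "insertion",
                                    "", "".join(run)))
    return variants


def align_ortholog_pair(at_seq: str, aa_seq: str, gene_id: str = "",
                        scoring: Scoring = Scoring()) -> OrthologPairAlignment:
    """Globally align an ortholog pair and extract its variant map."""
    _check_alphabet(at_seq, "at_seq")
    _check_alphabet(aa_seq, "aa_seq")
    score, at_al, aa_al = needleman_wunsch(at_seq, aa_seq, scoring)
    variants = _extract_variants(at_al, aa_al)
    n_cols = len(at_al)
    n_var_cols = sum(1 for a, b in zip(at_al, aa_al)
                     if a != b and ("N" not in (a, b) or "-" in (a, b)))
    return OrthologPairAlignment(
        gene_id=gene_id, at_seq=at_seq, aa_seq=aa_seq,
        at_aligned=at_al, aa_aligned=aa_al, score=score,
        variants=variants, divergence=n_var_cols / n_cols)


def homoeolog_divergence(seq_a: str, seq_b: str) -> float:
    """Variant columns per aligned column between two homologous sequences."""
    return align_ortholog_pair(seq_a, seq_b).divergence


# ---------------------------------------------------------------------------
# read placement and partitioning


@dataclass
class Placement:
    side: str            # "At" or "Aa"
    target_start: int
    edit_distance: int
    query_aligned: str
    target_aligned: str
    reverse: bool


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReadMapper:
    """Seed-and-extend placement of reads on both orthologs of every gene.

    A 16-mer exact-match index over all ortholog sequences proposes candidate
    genes; candidates are verified by semi-global (infix) alignment with
    edlib, accepting placements within ``max_mismatches`` edits.
    """

    def __init__(self, pairs: dict[str, tuple[str, str]], k: int = 16,
                 max_mismatches: int = 10):
        self.k = k
        self.max_mismatches = max_mismatches
        self.refs: dict[tuple[str, str], str] = {}
        self.index: dict[str, set[str]] = {}
        for gid, (at_seq, aa_seq) in pairs.items():
            self.refs[(gid, "At")] = at_seq
            self.refs[(gid, "Aa")] = aa_seq
            for seq in (at_seq, aa_seq):
                for p in range(0, len(seq) - k + 1):
                    self.index.setdefault(seq[p:p + k], set()).add(gid)

    def _candidates(self, seq: str) -> set[str]:
        k = self.k
        cands: set[str] = set()
        offs = sorted({0, max(0, len(seq) // 2 - k // 2), max(0, len(seq) - k)})
        for off in offs:
            cands |= self.index.get(seq[off:off + k], set())
        return cands

    def place(self, seq: str) -> dict[str, tuple[str, Placement]]:
        """Best placement per gene side; tries both strands.

        Returns {side: (gene_id, Placement)} for the best-matching gene.
        """
        best: dict[str, tuple[str, Placement]] = {}
        for rev in (False, True):
            q = _revcomp(seq) if rev else seq
            for gid in self._candidates(q):
                for side in ("At", "Aa"):
                    ref = self.refs[(gid, side)]
                    res = edlib.align(q, ref, mode="HW", task="path",
                                      k=self.max_mismatches)
                    if res["editDistance"] < 0:
                        continue
                    loc = res["locations"][0]
                    nice = edlib.getNiceAlignment(res, q, ref)
                    pl = Placement(side=side, target_start=loc[0],
                                   edit_distance=res["editDistance"],
                                   query_aligned=nice["query_aligned"],
                                   target_aligned=nice["target_aligned"],
                                   reverse=rev)
                    cur = best.get(side)
                    if cur is None or pl.edit_distance < cur[1].edit_distance:
                        best[side] = (gid, pl)
        return best


def _read_base_at(pl: Placement, target_pos: int) -> str | None:
    """Query base aligned to ``target_pos`` (target coords), or None."""
    t = pl.target_start
    for qc, tc in zip(pl.query_aligned, pl.target_aligned):
        if tc != "-":
            if t == target_pos:
                return qc if qc != "-" else None
            t += 1
    return None


def _votes(placements: dict[str, Placement], variants: list[Variant]
           ) -> tuple[int, int, int]:
    """(informative sites overlapped, At votes, Aa votes) over SNP sites.

    The read base at each site is taken from the better-fitting placement
    (fewer edits) first: the alignment against the mismatching ortholog can
    shift bases around dense variant clusters, so it is only a fallback.
    """
    order = sorted(placements.values(), key=lambda p: p.edit_distance)
    sites = at_votes = aa_votes = 0
    for v in variants:
        if v.type != "SNP":
            continue
        base = None
        for pl in order:
            pos = v.at_position if pl.side == "At" else v.aa_position
            base = _read_base_at(pl, pos)
            if base is not None:
                break
        if base is None:
            continue
        sites += 1
        if base == v.at_allele:
            at_votes += 1
        elif base == v.aa_allele:
            aa_votes += 1
    return sites, at_votes, aa_votes


def _call(at_votes: int, aa_votes: int, sites: int, tol: int) -> str:
    if sites == 0:
        return "ambiguous"
    if at_votes >= 1 and aa_votes <= tol and at_votes > aa_votes:
        return "At"
    if aa_votes >= 1 and at_votes <= tol and aa_votes > at_votes:
        return "Aa"
    if at_votes == 0 and aa_votes == 0:
        return "ambiguous"
    return "conflicting"


def assign_read(read_id: str, gene_id: str, placements: dict[str, Placement],
                variants: list[Variant], conflict_tolerance: int = 0
                ) -> ReadAssignment:
    """Vote at every overlapped diagnostic SNP site and call the parent.

    The call requires a strict majority with at most ``conflict_tolerance``
    opposing votes; reads overlapping no site are ambiguous.
    """
    if not placements:
        return ReadAssignment(read_id, gene_id, 0, 0, 0, "unmapped")
    sites, at_v, aa_v = _votes(placements, variants)
    return ReadAssignment(read_id, gene_id, sites, at_v, aa_v,
                          _call(at_v, aa_v, sites, conflict_tolerance))


def partition_fragments(reads: pd.DataFrame,
                        alignments: dict[str, OrthologPairAlignment],
                        mapper: ReadMapper | None = None,
                        conflict_tolerance: int = 0) -> pd.DataFrame:
    """Assign every fragment (mate pair) to a parental homoeolog.

    ``reads`` has columns read_id, mate1, mate2 (gene_id optional, unused for
    placement).  Votes from both mates are pooled before calling.
    """
    if mapper is None:
        mapper = ReadMapper({g: (al.at_seq, al.aa_seq)
                             for g, al in alignments.items()})
    rows = []
    for r in reads.itertuples():
        votes = {"At": 0, "Aa": 0}
        sites = 0
        gene = None
        mapped = False
        for seq in (r.mate1, r.mate2):
            pls = mapper.place(seq)
            if not pls:
                continue
            mapped = True
            gid = next(iter(pls.values()))[0]
            gene = gene or gid
            placements = {side: pl for side, (g, pl) in pls.items() if g == gene}
            s, at_v, aa_v = _votes(placements, alignments[gene].variants)
            sites += s
            votes["At"] += at_v
            votes["Aa"] += aa_v
        if not mapped:
            rows.append((r.read_id, "", 0, 0, 0, "unmapped"))
            continue
        rows.append((r.read_id, gene, sites, votes["At"], votes["Aa"],
                     _call(votes["At"], votes["Aa"], sites, conflict_tolerance)))
    return pd.DataFrame(rows, columns=["read_id", "gene_id",
                                       "informative_sites", "at_support",
                                       "aa_support", "call"])


def fpk_quantify(assignments: pd.DataFrame,
                 exon_lengths: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-gene parent-specific fragment counts normalized to FPK.

    ``exon_lengths`` maps gene_id -> (At length, Aa length) in bases.
    Ambiguous/conflicting fragments are excluded from both counts but
    reported.  Genes with zero assigned fragments are flagged.
    """
    for gid, (la, lb) in exon_lengths.items():
        if la <= 0 or lb <= 0:
            raise ValueError(f"zero-length exon model for {gid!r}")
    rows = []
    grouped = assignments[assignments["gene_id"] != ""].groupby("gene_id")
    counts = {g: sub["call"].value_counts() for g, sub in grouped}
    for gid, (at_len, aa_len) in exon_lengths.items():
        c = counts.get(gid, pd.Series(dtype=int))
        at_n = int(c.get("At", 0))
        aa_n = int(c.get("Aa", 0))
        dropped = int(c.get("ambiguous", 0) + c.get("conflicting", 0))
        at_fpk = at_n / (at_len / 1000.0)
        aa_fpk = aa_n / (aa_len / 1000.0)
        tot = at_fpk + aa_fpk
        rows.append((gid, at_n, aa_n, dropped, at_fpk, aa_fpk,
                     aa_fpk / tot if tot > 0 else np.nan, at_n + aa_n == 0))
    return pd.DataFrame(rows, columns=["gene_id", "at_reads", "aa_reads",
                                       "dropped", "at_fpk", "aa_fpk",
                                       "ratio", "no_reads"])


def concordance_with_array(read_ratio: pd.Series, array_alpha: pd.Series):
    """OLS of the read-based Aa ratio on the array alpha estimate.

    Returns (joined table, r_squared, p) with r_squared None when fewer than
    10 genes carry both measurements.
    """
    tab = pd.DataFrame({"read_ratio": read_ratio,
                        "array_alpha": array_alpha}).dropna()
    if len(tab) < 10:
        return tab, None, None
    fit = stats.linregress(tab["array_alpha"], tab["read_ratio"])
    return tab, float(fit.rvalue ** 2), float(fit.pvalue)


def read_sam_votes(sam_path, alignments: dict[str, OrthologPairAlignment],
                   conflict_tolerance: int = 0) -> pd.DataFrame:
    """Partition pre-mapped reads from a SAM file.

    Reference names must be ``<gene_id>|At`` / ``<gene_id>|Aa``.  Votes from
    all records sharing a query name (mates) are pooled.
    """
    import pysam

    per_read: dict[str, dict] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            gid, _, side = rec.reference_name.partition("|")
            if gid not in alignments or side not in ("At", "Aa"):
                continue
            entry = per_read.setdefault(rec.query_name,
                                        {"gene": gid, "sites": 0,
                                         "At": 0, "Aa": 0})
            pairs = {t: q for q, t in rec.get_aligned_pairs(matches_only=True)}
            seq = rec.query_sequence
            for v in alignments[gid].variants:
                if v.type != "SNP":
                    continue
                pos = v.at_position if side == "At" else v.aa_position
                qi = pairs.get(pos)
                if qi is None or seq is None:
                    continue
                base = seq[qi]
                entry["sites"] += 1
                if base == v.at_allele:
                    entry["At"] += 1
                elif base == v.aa_allele:
                    entry["Aa"] += 1
    rows = [(rid, e["gene"], e["sites"], e["At"], e["Aa"],
             _call(e["At"], e["Aa"], e["sites"], conflict_tolerance))
            for rid, e in per_read.items()]
    return pd.DataFrame(rows, columns=["read_id", "gene_id",
                                       "informative_sites", "at_support",
                                       "aa_support", "call"])
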