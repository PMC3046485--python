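"""Probe-table I/O and cross-array preprocessing.

The probe table is a long, tab-delimited format: one row per probe per array
(probe_id, chrom, pos, gene_id, genotype, sample_type, replicate, intensity).
Preprocessing is deliberately simple: an optional quantile-shift background
correction followed by quantile normalization within configurable array
groups.  Replicates are normalized within genotype; the evolved and F1
allotetraploid DNA arrays are normalized jointly so they stay directly
comparable for the region scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ProbeIntensityTable",
    "read_probe_table",
    "quantile_normalize",
    "background_correct",
    "preprocess",
    "DEFAULT_GROUPS",
]

REQUIRED_COLUMNS = ["probe_id", "chrom", "pos", "gene_id", "genotype",
                    "sample_type", "replicate", "intensity"]

#: replicates quantile-normalized within genotype only — used by the
#: gene-wise scaling / diagnostic-feature / mixture pipeline, where cross-
#: genotype comparability comes from per-gene scaling, not global ranks.
PER_GENOTYPE_GROUPS = [
    [("At", "DNA")],
    [("Aa", "DNA")],
    [("As", "DNA")],
    [("F1As", "DNA")],
    [("As", "RNA")],
]

#: the evolved and F1 allotetraploid DNA arrays normalized jointly (in
#: addition to the per-genotype pass) — used by the region scan, which
#: compares raw probe levels between those two samples.  Joint ranks would
#: distort per-gene mixture fits when many genes carry deletions, so this
#: grouping is reserved for the scan.
DEFAULT_GROUPS = [
    [("At", "DNA")],
    [("Aa", "DNA")],
    [("As", "DNA"), ("F1As", "DNA")],
    [("As", "RNA")],
]


class ProbeIntensityTable:
    """Long-format per-probe, per-array intensity container.

    Wraps a :class:`pandas.DataFrame` and enforces the container invariants:
    strictly positive intensities, unique (probe, genotype, sample, replicate)
    keys, and at most one gene per probe.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        df = df.copy()
        df["gene_id"] = df["gene_id"].fillna("").astype(str)
        self.df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        if not np.issubdtype(df["intensity"].dtype, np.number):
            bad = df.index[pd.to_numeric(df["intensity"], errors="coerce").isna()]
            raise ValueError(f"non-numeric intensity at row(s) {list(bad[:5])}")
        neg = df.index[df["intensity"] <= 0]
        if len(neg):
            raise ValueError(
                f"non-positive intensity at row(s) {list(neg[:5])} "
                f"(probe {df.loc[neg[0], 'probe_id']!r})")
        key = ["probe_id", "genotype", "sample_type", "replicate"]
        dup = df.duplicated(key)
        if dup.any():
            first = df.loc[dup.idxmax(), key].tolist()
            raise ValueError(f"duplicate probe/array key: {first}")
        ngenes = df.groupby("probe_id")["gene_id"].nunique()
        multi = ngenes.index[ngenes > 1]
        if len(multi):
            raise ValueError(f"probe(s) assigned to multiple genes: {list(multi[:5])}")

    # -- accessors ---------------------------------------------------------
    def probes(self) -> pd.DataFrame:
        """Unique probe metadata, ordered by (chrom, pos)."""
        cols = ["probe_id", "chrom", "pos", "gene_id"]
        return (self.df[cols].drop_duplicates("probe_id")
                .sort_values(["chrom", "pos"]).reset_index(drop=True))

    def arrays(self) -> list[tuple[str, str, int]]:
        key = (self.df[["genotype", "sample_type", "replicate"]]
               .drop_duplicates().itertuples(index=False, name=None))
        return sorted(key)

    def matrix(self, genotype: str, sample_type: str) -> pd.DataFrame:
        """probe_id x replicate intensity matrix for one genotype/sample."""
        sub = self.df[(self.df["genotype"] == genotype)
                      & (self.df["sample_type"] == sample_type)]
        if sub.empty:
            raise KeyError(f"no arrays for ({genotype}, {sample_type})")
        return sub.pivot(index="probe_id", columns="replicate",
                         values="intensity")

    # -- I/O ---------------------------------------------------------------
    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def copy_with(self, intensities: pd.Series) -> "ProbeIntensityTable":
        df = self.df.copy()
        df["intensity"] = np.asarray(intensities, dtype=float)
        return ProbeIntensityTable(df, validate=False)


def read_probe_table(path) -> ProbeIntensityTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return ProbeIntensityTable(df)


def quantile_normalize(columns: np.ndarray) -> np.ndarray:
    """Force every column to the cross-column rank-wise mean distribution.

    ``columns`` is (n_values, n_arrays).  Within-column rank order is
    preserved; tied values receive the mean of the reference values their
    ranks span.  Raises on length mismatch (enforced by the 2-D shape).
    """
    x = np.asarray(columns, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (values x arrays) matrix")
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(m):
        out[order[:, j], j] = ref
        # ties: average the assigned reference values over tied runs
        col = x[:, j]
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inv, weights=out[:, j])
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
    return out


def background_correct(values: np.ndarray, method: str = "shift",
                       floor_quantile: float = 0.05,
                       eps: float = 1.0) -> np.ndarray:
    """Subtract a low-quantile floor ("shift") or pass through ("none").

    Output stays strictly positive so log2 remains defined downstream.
    """
    x = np.asarray(values, dtype=float)
    if method == "none":
        return x.copy()
    if method == "shift":
        floor = np.quantile(x, floor_quantile)
        return np.maximum(x - floor, eps)
    raise ValueError(f"unknown background method {method!r}")


def preprocess(table: ProbeIntensityTable, background: str = "shift",
               groups=None) -> ProbeIntensityTable:
    """Background-correct each array then quantile-normalize within groups.

    Deterministic; returns a new table with the same keys.
    """
    if groups is None:
        groups = DEFAULT_GROUPS
    df = table.df.copy()
    new = df["intensity"].to_numpy(dtype=float).copy()
    idx_of = {}
    for (gt, st, rep), sub in df.groupby(["genotype", "sample_type", "replicate"]):
        idx = sub.index.to_numpy()
        idx = idx[np.argsort(sub["probe_id"].to_numpy())]
        new[idx] = background_correct(new[idx], method=background)
        idx_of[(gt, st, rep)] = idx

    for group in groups:
        members = [k for k in idx_of if (k[0], k[1]) in group]
        if not members:
            continue
        cols = [idx_of[k] for k in sorted(members)]
        lengths = {c.size for c in cols}
        if len(lengths) != 1:
            raise ValueError("arrays in a normalization group differ in probe count")
        mat = np.column_stack([new[c] for c in cols])
        mat = quantile_normalize(mat)
        for j, c in enumerate(cols):
            new[c] = mat[:, j]

    df["intensity"] = new
    return ProbeIntensityTable(df, validate=False)
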