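"""ASV-table handling: quality filters, relative abundances, diversity metrics.

Taxa are abstract amplicon sequence variants (ASVs). A table holds integer
read counts (samples x taxa) plus per-sample metadata: a blank flag and the
experimental stage (inoculum, community, or dilution-to-extinction).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "AsvTable",
    "NoBlankError",
    "DegenerateSampleError",
    "UndefinedMetricError",
    "filter_min_depth",
    "remove_contaminants",
    "relative_abundance",
    "observed_richness",
    "rarefied_richness",
    "weighted_mpd",
    "weighted_mntd",
    "patristic_distances",
    "read_distance_tsv",
    "write_distance_tsv",
]

STAGES = ("inoculum", "community", "extinction")


class NoBlankError(ValueError):
    """The contaminant filter needs at least one blank sample."""


class DegenerateSampleError(ValueError):
    """A sample with zero total reads has no relative abundances."""


class UndefinedMetricError(ValueError):
    """A diversity metric needs at least two taxa with positive abundance."""


@dataclasses.dataclass
class AsvTable:
    """Samples x taxa integer read counts with per-sample metadata.

    counts: DataFrame indexed by sample id, one column per taxon id.
    meta:   DataFrame indexed by sample id with columns ``blank`` (bool) and
            ``stage`` (one of inoculum/community/extinction).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.counts.index)
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and taxon ids must be unique")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def blanks(self) -> "AsvTable":
        mask = self.meta["blank"].astype(bool)
        return self.select(self.counts.index[mask])

    def stage(self, stage: str) -> "AsvTable":
        mask = (self.meta["stage"] == stage) & ~self.meta["blank"].astype(bool)
        return self.select(self.counts.index[mask])

    def select(self, sample_ids: Iterable[str]) -> "AsvTable":
        ids = list(sample_ids)
        return AsvTable(self.counts.loc[ids].copy(), self.meta.loc[ids].copy())

    def drop_taxa(self, taxa: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.drop(columns=list(taxa)), self.meta.copy())

    def to_tsv(self, path) -> None:
        meta_cols = [c for c in ("blank", "stage", "raw_total") if c in self.meta.columns]
        out = pd.concat([self.meta[meta_cols], self.counts], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AsvTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"sample_id": str})
        meta_cols = [c for c in ("blank", "stage", "raw_total") if c in df.columns]
        meta = df[meta_cols].copy()
        meta["blank"] = meta["blank"].astype(bool)
        counts = df.drop(columns=meta_cols).astype(np.int64)
        return cls(counts, meta)


def filter_min_depth(table: AsvTable, min_reads: int = 2000) -> AsvTable:
    """Drop samples with fewer than ``min_reads`` total reads (strict <)."""
    totals = table.counts.sum(axis=1)
    keep = table.counts.index[totals >= min_reads]
    return table.select(keep)


def remove_contaminants(
    table: AsvTable,
    blank_fraction: float = 0.02,
    blank_prevalence: float = 0.20,
) -> tuple[AsvTable, list[str]]:
    """Remove ASVs over-represented in blank wells from every sample.

    An ASV is a contaminant if its relative abundance exceeds ``blank_fraction``
    (strict >) in a fraction of blanks strictly greater than
    ``blank_prevalence``. Returns the cleaned table and the removed taxon ids.

    Blank fractions are taken relative to each blank's raw read total (stored
    as a ``raw_total`` metadata column on the cleaned table), so removing a
    blank-dominating contaminant does not inflate the remaining taxa and the
    filter is idempotent.
    """
    blanks = table.blanks()
    if len(blanks.sample_ids) == 0:
        raise NoBlankError("contaminant filter requires at least one blank sample")
    if "raw_total" in blanks.meta.columns:
        totals = blanks.meta["raw_total"].astype(float)
    else:
        totals = blanks.counts.sum(axis=1)
    nonzero = totals > 0
    frac = blanks.counts.loc[nonzero].div(totals[nonzero], axis=0)
    exceed = (frac > blank_fraction).sum(axis=0) / max(int(nonzero.sum()), 1)
    contaminants = sorted(exceed.index[exceed > blank_prevalence])
    cleaned = table.drop_taxa(contaminants)
    if "raw_total" not in cleaned.meta.columns:
        cleaned.meta["raw_total"] = table.counts.sum(axis=1)
    return cleaned, contaminants


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample relative abundances R_C,i (rows sum to 1)."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(table.counts.index[totals == 0])
        raise DegenerateSampleError(f"samples with zero reads: {bad}")
    return table.counts.div(totals, axis=0)


def observed_richness(table: AsvTable) -> pd.Series:
    """Number of taxa with count > 0 per sample (N_C)."""
    return (table.counts > 0).sum(axis=1).rename("richness")


def rarefied_richness(counts, depth: int) -> float:
    """Expected richness at ``depth`` reads (hypergeometric rarefaction).

    E[S] = sum_i 1 - C(T - n_i, d) / C(T, d) with T the sample total.
    """
    n = np.asarray(counts, dtype=np.int64)
    n = n[n > 0]
    total = int(n.sum())
    if depth > total:
        raise ValueError("rarefaction depth exceeds sample total")
    if depth < 0:
        raise ValueError("rarefaction depth must be non-negative")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    keep = (total - n) >= depth
    p_absent = np.zeros(len(n))
    p_absent[keep] = np.exp(log_comb(total - n[keep], depth) - log_comb(total, depth))
    return float(np.sum(1.0 - p_absent))


def _present(abundances: Mapping[str, float] | pd.Series) -> pd.Series:
    f = pd.Series(abundances, dtype=float)
    f = f[f > 0]
    if len(f) < 2:
        raise UndefinedMetricError("need at least two taxa with positive abundance")
    return f / f.sum()


def weighted_mpd(abundances, distances: pd.DataFrame) -> float:
    """Abundance-weighted mean pairwise distance over present taxa.

    MPD = sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j with f renormalized
    over taxa present in the sample.
    """
    f = _present(abundances)
    d = distances.loc[f.index, f.index].to_numpy(dtype=float)
    w = np.outer(f.to_numpy(), f.to_numpy())
    np.fill_diagonal(w, 0.0)
    return float(np.sum(w * d) / np.sum(w))


def weighted_mntd(abundances, distances: pd.DataFrame) -> float:
    """Abundance-weighted mean nearest-taxon distance over present taxa.

    Each present taxon contributes its distance to the nearest other present
    taxon, weighted by its own (renormalized) abundance — the picante
    ``abundance.weighted`` convention.
    """
    f = _present(abundances)
    d = distances.loc[f.index, f.index].to_numpy(dtype=float).copy()
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    return float(np.sum(f.to_numpy() * nearest))


def patristic_distances(tree_source: str, taxa: Iterable[str]) -> pd.DataFrame:
    """Square patristic (path-length) distance matrix from a newick tree.

    ``tree_source`` is a newick string or a path to one. Every requested taxon
    must be a tip of the tree; extra tips are ignored.
    """
    import dendropy

    taxa = list(taxa)
    src = str(tree_source)
    if "(" in src:
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in by_label]
    if missing:
        raise ValueError(f"tree lacks tips for taxa: {missing}")
    mat = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                mat[i, j] = mat[j, i] = pdm.patristic_distance(by_label[a], by_label[b])
    return pd.DataFrame(mat, index=taxa, columns=taxa)


def read_distance_tsv(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", index_col=0)
    d.columns = d.columns.astype(str)
    d.index = d.index.astype(str)
    arr = d.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(arr, arr.T) or np.any(np.diag(arr) != 0):
        raise ValueError("distance matrix must be square and symmetric with zero diagonal")
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    return d


def write_distance_tsv(distances: pd.DataFrame, path) -> None:
    distances.to_csv(path, sep="\t", float_format="%.10g")
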