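"""Phage transcriptional-programme analysis and expression summaries.

Each phage gene's time-course is min-max normalised to [0, 1], averaged
across the infected wild-type replicates, and the resulting profiles are
grouped by agglomerative hierarchical clustering (complete linkage on
Euclidean distance by default) to delineate the early/middle/late phases of
the phage transcriptional programme. Separately, per-sample phage read
fractions quantify total phage expression, and group-mean ratios measure the
attenuation of phage expression in CRISPR-immune hosts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic import ExpressionMatrix

__all__ = [
    "PhageGeneProfile",
    "minmax_normalize",
    "average_replicates",
    "phage_gene_profiles",
    "cluster_programme",
    "ProgrammeClustering",
    "phage_read_fraction",
    "fold_difference",
    "linkage_to_newick",
]


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class PhageGeneProfile:
    """Normalised expression of one phage gene across timepoints."""

    gene: str
    values: tuple[float, ...]
    constant: bool = False

    def __post_init__(self):
        v = np.asarray(self.values)
        if not self.constant and (v.min() < 0 or v.max() > 1):
            raise ExpressionError(f"profile of {self.gene!r} outside [0, 1]")


def minmax_normalize(values) -> tuple[np.ndarray, bool]:
    """(v - min) / (max - min) per timepoint.

    Returns the scaled vector and a flag that is True for constant input,
    which maps to all zeros by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ExpressionError("need at least 2 timepoints to normalise")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v), True
    return (v - lo) / (hi - lo), False


def _group_samples(matrix: ExpressionMatrix, group: str) -> pd.DataFrame:
    samples = matrix.samples[matrix.samples["genotype"] == group]
    if samples.empty:
        raise ExpressionError(f"no samples in genotype group {group!r}")
    return samples


def average_replicates(matrix: ExpressionMatrix, group: str = "WT",
                       genes=None) -> pd.DataFrame:
    """Per-gene mean count at each timepoint across the replicates of a group.

    Returns genes x timepoints (columns sorted by minutes). Raises if some
    timepoint has no replicate in the group.
    """
    samples = _group_samples(matrix, group)
    minutes = sorted(samples["minutes"].unique())
    sub = matrix.counts if genes is None else matrix.counts.loc[genes]
    cols = {}
    for m in minutes:
        names = samples.loc[samples["minutes"] == m, "sample"]
        if names.empty:
            raise ExpressionError(f"group {group!r} has no replicate at {m} min")
        cols[m] = sub[list(names)].mean(axis=1)
    return pd.DataFrame(cols)


def phage_gene_profiles(matrix: ExpressionMatrix, group: str = "WT",
                        order: str = "normalize-first") -> list[PhageGeneProfile]:
    """Normalised mean time-course of every phage gene in a genotype group.

    ``order="normalize-first"`` min-max scales each replicate's time-course
    before averaging (then rescales the mean to span [0, 1]);
    ``order="average-first"`` averages raw counts across replicates first and
    scales the mean. The two differ whenever replicates disagree on scale.
    """
    if order not in ("normalize-first", "average-first"):
        raise ExpressionError(f"unknown order {order!r}")
    samples = _group_samples(matrix, group)
    minutes = sorted(samples["minutes"].unique())
    phage_genes = matrix.gene_origin[matrix.gene_origin == "phage"].index
    profiles = []
    if order == "average-first":
        means = average_replicates(matrix, group, genes=phage_genes)
        for gene in phage_genes:
            vals, const = minmax_normalize(means.loc[gene].to_numpy())
            profiles.append(PhageGeneProfile(gene, tuple(vals), constant=const))
        return profiles
    reps = sorted(samples["replicate"].unique())
    sample_of = {(r, m): s for s, r, m in
                 zip(samples["sample"], samples["replicate"], samples["minutes"])}
    for gene in phage_genes:
        per_rep = []
        for r in reps:
            series = [matrix.counts.at[gene, sample_of[(r, m)]] for m in minutes]
            vals, _ = minmax_normalize(series)
            per_rep.append(vals)
        mean = np.mean(per_rep, axis=0)
        vals, const = minmax_normalize(mean)
        profiles.append(PhageGeneProfile(gene, tuple(vals), constant=const))
    return profiles


@dataclass
class ProgrammeClustering:
    """Flat assignments plus the full merge tree of the programme clustering."""

    assignments: pd.Series          # gene -> cluster label (1..k)
    merge_tree: np.ndarray          # scipy linkage matrix
    genes: list[str]

    def to_newick(self) -> str:
        return linkage_to_newick(self.merge_tree, self.genes)


def cluster_programme(profiles: list[PhageGeneProfile], k: int = 3,
                      method: str = "complete") -> ProgrammeClustering:
    """Agglomerative clustering of normalised time-courses.

    Euclidean distance, complete linkage by default. Genes are sorted by id
    before clustering so the result is invariant to input order.
    """
    if len(profiles) < 2:
        raise ExpressionError("need at least 2 profiles to cluster")
    if not 1 <= k <= len(profiles):
        raise ExpressionError(f"k={k} outside [1, {len(profiles)}]")
    profiles = sorted(profiles, key=lambda p: p.gene)
    genes = [p.gene for p in profiles]
    data = np.array([p.values for p in profiles])
    tree = linkage(data, method=method, metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return ProgrammeClustering(
        assignments=pd.Series(labels, index=genes, name="cluster"),
        merge_tree=tree, genes=genes)


def linkage_to_newick(tree: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for idx, (left, right, height, _) in enumerate(tree):
        left, right = int(left), int(right)
        node_id = n + idx
        bl_l = height - heights[left]
        bl_r = height - heights[right]
        nodes[node_id] = f"({nodes[left]}:{bl_l:.6g},{nodes[right]}:{bl_r:.6g})"
        heights[node_id] = height
        del nodes[left], nodes[right]
    (root,) = nodes.values()
    return root + ";"


def phage_read_fraction(matrix: ExpressionMatrix) -> pd.Series:
    """Fraction of each sample's reads assigned to phage-origin genes."""
    totals = matrix.counts.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ExpressionError(f"zero library size in samples {empty}")
    phage = matrix.counts.loc[matrix.gene_origin == "phage"].sum(axis=0)
    frac = phage / totals
    frac.name = "phage_fraction"
    return frac


def fold_difference(fractions: pd.Series, samples: pd.DataFrame,
                    group_a: str = "WT", group_b: str = "BIM2",
                    n_boot: int = 1000, seed: int | None = 0):
    """Ratio mean(group_a) / mean(group_b) of per-sample phage fractions,
    with a seeded percentile-bootstrap confidence interval.

    Returns (ratio, (lo, hi)).
    """
    va = fractions[samples.loc[samples["genotype"] == group_a, "sample"]].to_numpy()
    vb = fractions[samples.loc[samples["genotype"] == group_b, "sample"]].to_numpy()
    if va.size == 0 or vb.size == 0:
        raise ExpressionError("both groups need at least one sample")
    if vb.mean() <= 0:
        raise ExpressionError(f"mean phage fraction of {group_b!r} is zero")
    ratio = va.mean() / vb.mean()
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        rb = rng.choice(vb, vb.size, replace=True).mean()
        if rb > 0:
            boots.append(rng.choice(va, va.size, replace=True).mean() / rb)
    lo, hi = (np.quantile(boots, [0.025, 0.975]) if boots else (np.nan, np.nan))
    return float(ratio), (float(lo), float(hi))
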