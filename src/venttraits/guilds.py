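"""Agglomerative clustering of the trait dissimilarity matrix into functional guilds.

A functional guild is a cluster of species with similar modality profiles
across all traits. Species are clustered hierarchically on the precomputed
Gower matrix; the cutoff is chosen automatically by scanning every partition
obtainable by cutting the dendrogram and maximizing a within/between distance
tradeoff (mean silhouette width by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .dissimilarity import DissimilarityMatrix, validate_matrix
from .trait_data import DataError, PooledSeries

LINKAGES = ("complete", "average", "ward")


@dataclass
class Dendrogram:
    """Merge history from agglomerative clustering.

    ``linkage_matrix`` is the standard (n-1) x 4 encoding: each row merges two
    nodes at a given height; heights are non-decreasing for the supported
    linkage methods on a valid dissimilarity matrix.
    """

    taxa: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Labels (0-based, relabelled by first appearance) for a k-cluster cut."""
        raw = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return _canonical(raw)

    def to_newick(self) -> str:
        """Newick string with merge heights as node depths (branch lengths)."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.taxa)
        return str(tree).strip()


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (determinism helper)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class GuildModel:
    """A dendrogram with a chosen cutoff and the resulting species -> guild labels.

    ``trace`` records the criterion score for every candidate number of
    clusters so alternative cutoffs can be compared after the fact.
    """

    dendrogram: Dendrogram
    cutoff_height: float
    labels: pd.Series  # index: species, values: 0-based guild id
    trace: pd.DataFrame  # columns: k, achieved_k, silhouette, within_between_ratio

    @property
    def n_guilds(self) -> int:
        return int(self.labels.nunique())

    def members(self, guild: int) -> list[str]:
        return list(self.labels.index[self.labels == guild])

    def to_csv(self, path) -> None:
        out = self.labels.rename("guild").rename_axis("species").reset_index()
        out["guild"] = [guild_name(g) for g in out["guild"]]
        out.to_csv(path, index=False)


def guild_name(label: int) -> str:
    """Letter name for a guild id (0 -> 'A', 25 -> 'Z', 26 -> 'AA', ...)."""
    name = ""
    label = int(label)
    while True:
        name = chr(ord("A") + label % 26) + name
        label = label // 26 - 1
        if label < 0:
            return name


def cluster(d: DissimilarityMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering on the precomputed dissimilarity matrix.

    ``linkage`` is one of complete (default), average, or ward (Ward's method
    applied to the dissimilarities as if Euclidean).
    """
    if linkage not in LINKAGES:
        raise DataError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if len(d.taxa) < 2:
        raise DataError("need at least 2 taxa to cluster")
    rep = validate_matrix(d)
    if not rep.ok:
        raise DataError(f"invalid dissimilarity matrix: {rep.problems}")
    Z = hierarchy.linkage(d.condensed(), method=linkage)
    return Dendrogram(list(d.taxa), Z, linkage)


def _within_between_ratio(d: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    if len(within) == 0 or len(between) == 0 or between.mean() == 0:
        return np.nan
    return float(within.mean() / between.mean())


def select_cutoff(dend: Dendrogram, d: DissimilarityMatrix,
                  k_range: tuple[int, int] | None = None,
                  criterion: str = "silhouette") -> GuildModel:
    """Choose the number of guilds by scanning dendrogram cuts.

    For each candidate k in ``k_range`` (default 2 .. n-1) the partition from
    cutting the dendrogram into k clusters is scored; the partition maximizing
    the criterion (mean silhouette width on the dissimilarity matrix, or the
    negated within/between mean-distance ratio) is returned. Ties, including a
    completely flat trace, resolve to the smallest k.
    """
    n = len(dend.taxa)
    if k_range is None:
        k_range = (2, n - 1)
    lo, hi = k_range
    lo, hi = max(2, lo), min(n - 1, hi)
    if lo > hi:
        raise DataError(f"empty k range: {k_range}")
    if criterion not in ("silhouette", "within_between"):
        raise DataError(f"unknown criterion {criterion!r}")

    rows = []
    partitions = {}
    for k in range(lo, hi + 1):
        labels = dend.cut(k)
        achieved = len(np.unique(labels))
        if achieved in partitions:  # tied heights can repeat a partition
            continue
        if achieved < 2 or achieved > n - 1:
            continue
        sil = float(silhouette_score(d.d, labels, metric="precomputed"))
        wb = _within_between_ratio(d.d, labels)
        partitions[achieved] = labels
        rows.append({"k": k, "achieved_k": achieved, "silhouette": sil,
                     "within_between_ratio": wb})
    if not rows:
        # fully tied merge heights: no height cut separates 2..n-1 groups;
        # fall back to an arbitrary (deterministic) split at the smallest k
        warnings.warn("cutoff criterion is flat (tied merge heights); "
                      "picking smallest k in range")
        labels = _canonical(hierarchy.cut_tree(dend.linkage_matrix,
                                               n_clusters=lo).ravel())
        sil = float(silhouette_score(d.d, labels, metric="precomputed"))
        rows.append({"k": lo, "achieved_k": lo, "silhouette": sil,
                     "within_between_ratio": _within_between_ratio(d.d, labels)})
        partitions[lo] = labels
    trace = pd.DataFrame(rows)
    score = trace["silhouette"] if criterion == "silhouette" \
        else -trace["within_between_ratio"]
    if len(trace) > 1 and np.ptp(score.to_numpy()) == 0:
        warnings.warn("cutoff criterion is flat across k; picking smallest k")
    best = trace.iloc[int(np.argmax(score.to_numpy()))]  # argmax -> first (smallest k)
    k_best = int(best["achieved_k"])
    labels = partitions[k_best]

    # cutoff height: midpoint of the height gap this partition corresponds to
    heights = np.sort(dend.heights)
    n_merges = len(heights)
    lower = heights[n_merges - k_best] if k_best <= n_merges else 0.0
    upper = heights[n_merges - k_best + 1] if k_best > 1 else np.inf
    cutoff = float(lower if not np.isfinite(upper) else (lower + upper) / 2)

    return GuildModel(
        dendrogram=dend,
        cutoff_height=cutoff,
        labels=pd.Series(labels, index=dend.taxa, name="guild"),
        trace=trace,
    )


def guild_counts(series: PooledSeries, model: GuildModel) -> pd.DataFrame:
    """Sum pooled species counts into guild counts (time x guild); totals conserved.

    If the series has a pre-eruption reference row it is appended with index
    ``"pre"``.
    """
    labels = model.labels
    missing = [t for t in series.taxa if t not in labels.index]
    if missing:
        raise DataError(f"taxa without guild labels: {missing}")
    guilds = sorted(labels.unique())
    cols = {}
    for g in guilds:
        members = [t for t in series.taxa if labels[t] == g]
        cols[guild_name(g)] = series.counts[members].sum(axis=1)
    out = pd.DataFrame(cols)
    if series.pre_counts is not None:
        pre = {guild_name(g): int(series.pre_counts[[t for t in series.taxa
                                                     if labels[t] == g]].sum())
               for g in guilds}
        out = pd.concat([out, pd.DataFrame(pre, index=["pre"])])
    return out


def scan_clustering(d: DissimilarityMatrix,
                    linkages: tuple[str, ...] = LINKAGES,
                    criteria: tuple[str, ...] = ("silhouette", "within_between"),
                    k_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Diagnostic scan over (linkage, criterion) pairs.

    Returns one row per pair with the selected number of guilds and its
    silhouette, for resolving which combination reproduces a published guild
    structure when the original method is unstated.
    """
    rows = []
    for method in linkages:
        dend = cluster(d, method)
        for crit in criteria:
            model = select_cutoff(dend, d, k_range=k_range, criterion=crit)
            sil = float(model.trace.set_index("achieved_k")
                        .loc[model.n_guilds, "silhouette"])
            rows.append({"linkage": method, "criterion": crit,
                         "k": model.n_guilds, "silhouette": sil,
                         "cutoff_height": model.cutoff_height})
    return pd.DataFrame(rows)
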