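"""Diversity indices per pooled time point.

Three indices track the recovering community:

* Hill number of order 1 for species — ``exp(-sum p_i ln p_i)``, the
  exponential of the Shannon-Wiener index, i.e. the effective number of
  equally abundant species;
* the same Hill number computed on guild counts (effective number of guilds);
* Rao's quadratic entropy, ``Q = sum_ij d_ij p_i p_j``, the abundance-weighted
  expected pairwise trait dissimilarity between two randomly drawn
  individuals. Q is reported in Gower-dissimilarity units (plain Rao 1982
  definition over ordered pairs; a d/2 convention is available for
  cross-checking against software that halves the distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix
from .guilds import GuildModel, guild_counts
from .trait_data import DataError, PooledSeries


def hill_q1(counts) -> float:
    """Effective number of categories: exponential of Shannon entropy.

    Zero-count categories are dropped (0 ln 0 := 0). Equals richness when
    counts are uniform; 1 when a single category holds all individuals.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DataError("negative counts")
    total = c.sum()
    if total <= 0:
        raise DataError("all-zero count vector")
    p = c[c > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


def raoq(counts, d: DissimilarityMatrix, taxa=None, halve: bool = False) -> float:
    """Rao's quadratic entropy of a community against a trait dissimilarity matrix.

    ``counts`` aligns with ``taxa`` (default: the matrix's own taxon order);
    every taxon with a positive count must be present in the matrix. With
    ``halve`` the d/2 convention is used instead of plain d.
    """
    c = np.asarray(counts, dtype=float)
    taxa = list(taxa) if taxa is not None else list(d.taxa)
    if len(c) != len(taxa):
        raise DataError("counts and taxa length mismatch")
    if (c < 0).any():
        raise DataError("negative counts")
    total = c.sum()
    if total <= 0:
        raise DataError("all-zero count vector")
    present = [(t, x) for t, x in zip(taxa, c) if x > 0]
    missing = [t for t, _ in present if t not in d.taxa]
    if missing:
        raise DataError(f"taxa with positive counts absent from matrix: {missing}")
    idx = [d.taxa.index(t) for t, _ in present]
    p = np.array([x for _, x in present]) / total
    sub = d.d[np.ix_(idx, idx)]
    q = float(p @ sub @ p)
    return q / 2 if halve else q


@dataclass
class DiversitySeries:
    """Per-time-point diversity indices (post-eruption series + optional pre row)."""

    table: pd.DataFrame  # index: time_months, columns: hill_species, hill_guild, raoq
    pre_row: pd.Series | None = None

    def to_tidy(self) -> pd.DataFrame:
        tidy = (self.table.rename_axis("time_months").reset_index()
                .melt(id_vars="time_months", var_name="metric", value_name="value"))
        if self.pre_row is not None:
            pre = pd.DataFrame({"time_months": "pre",
                                "metric": self.pre_row.index,
                                "value": self.pre_row.values})
            tidy = pd.concat([tidy, pre], ignore_index=True)
        return tidy


def diversity_series(series: PooledSeries, model: GuildModel,
                     d: DissimilarityMatrix, halve_raoq: bool = False) -> DiversitySeries:
    """Hill-species, Hill-guild and RaoQ for every pooled time point.

    RaoQ uses species-level relative abundances against the species Gower
    matrix; the guild Hill number uses counts summed within guilds.
    """
    gc = guild_counts(series, model)
    gc_post = gc.drop(index="pre") if "pre" in gc.index else gc
    rows = {}
    for t in series.counts.index:
        c = series.counts.loc[t]
        rows[t] = {
            "hill_species": hill_q1(c.to_numpy()),
            "hill_guild": hill_q1(gc_post.loc[t].to_numpy()),
            "raoq": raoq(c.to_numpy(), d, taxa=series.taxa, halve=halve_raoq),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "time_months"
    pre_row = None
    if series.pre_counts is not None:
        pre_row = pd.Series({
            "hill_species": hill_q1(series.pre_counts.to_numpy()),
            "hill_guild": hill_q1(gc.loc["pre"].to_numpy()),
            "raoq": raoq(series.pre_counts.to_numpy(), d, taxa=series.taxa,
                         halve=halve_raoq),
        })
    return DiversitySeries(table=table, pre_row=pre_row)
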