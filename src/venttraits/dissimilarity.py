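"""Gower dissimilarity over mixed ordered/categorical traits with missing values.

Pairwise species dissimilarity is the missing-value-aware weighted mean of
per-trait contributions:

    d(i, j) = sum_k w_ijk * delta_ijk / sum_k w_ijk

where ``w_ijk`` equals the trait weight when both species have a non-missing
value for trait ``k`` and 0 otherwise. Categorical traits contribute a simple
mismatch (0 if equal, else 1). Ordered traits use the rank-based, tie-corrected
treatment of ordinal variables (Podani 1999): with ``r`` the average ranks of
the trait's observed values over the species at hand and ``T_x`` the number of
species tied at the rank of ``x``,

    delta_ijk = (|r_ik - r_jk| - (T_ik - 1)/2 - (T_jk - 1)/2)
                / (r_max - r_min - (T_max - 1)/2 - (T_min - 1)/2)

with delta = 0 when the two values are equal, and 0 for the whole trait when
every species is tied (zero denominator): fully tied species are maximally
similar on that trait, matching categorical equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .trait_data import DataError, TraitSpec, TraitTable


@dataclass
class DissimilarityMatrix:
    """Symmetric species x species dissimilarity in [0, 1].

    ``defined`` masks pairs that share at least one jointly non-missing trait;
    undefined pairs hold NaN, never a silent zero.
    """

    taxa: list[str]
    d: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)

    def condensed(self) -> np.ndarray:
        """Condensed upper-triangle vector (scipy ordering)."""
        iu = np.triu_indices(len(self.taxa), k=1)
        return self.d[iu]

    def subset(self, taxa: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DissimilarityMatrix(list(taxa), self.d[np.ix_(idx, idx)],
                                   self.defined[np.ix_(idx, idx)])


def _ordinal_deltas(codes: np.ndarray) -> np.ndarray:
    """Podani tie-corrected pairwise dissimilarities for one ordered trait.

    ``codes`` holds level indices with -1 for missing. Returns an n x n matrix
    with NaN where either value is missing.
    """
    n = len(codes)
    out = np.full((n, n), np.nan)
    obs = codes >= 0
    vals = codes[obs]
    if len(vals) == 0:
        return out
    ranks = rankdata(vals)  # average ranks over observed species
    # tie count for each observed species = number sharing its value
    uniq, counts = np.unique(vals, return_counts=True)
    tie = counts[np.searchsorted(uniq, vals)]
    r_max, r_min = ranks.max(), ranks.min()
    t_max = tie[np.argmax(ranks)]
    t_min = tie[np.argmin(ranks)]
    denom = r_max - r_min - (t_max - 1) / 2 - (t_min - 1) / 2
    ii = np.where(obs)[0]
    if denom <= 0:  # all species tied on this trait
        out[np.ix_(ii, ii)] = 0.0
        return out
    num = (np.abs(ranks[:, None] - ranks[None, :])
           - (tie[:, None] - 1) / 2 - (tie[None, :] - 1) / 2)
    delta = np.clip(num / denom, 0.0, 1.0)
    delta[vals[:, None] == vals[None, :]] = 0.0
    out[np.ix_(ii, ii)] = delta
    return out


def gower_podani(traits: TraitTable, specs: Sequence[TraitSpec] | None = None,
                 weights: Mapping[str, float] | None = None,
                 rank_declared_levels: bool = False) -> DissimilarityMatrix:
    """Pairwise Gower dissimilarity with Podani's ordinal extension.

    Parameters
    ----------
    traits
        Species x trait modality table (missing values allowed).
    specs
        Trait definitions; defaults to the table's own specs.
    weights
        Per-trait non-negative weights; default 1 for every trait.
    rank_declared_levels
        When True, ordinal ranks are computed over the trait's declared level
        list rather than over the values observed in the species set. The
        default ranks observed values only: declared-but-unused levels carry
        no information about the species at hand.
    """
    specs = list(specs) if specs is not None else list(traits.specs)
    by_name = {s.name: s for s in specs}
    for trait in traits.traits:
        if trait not in by_name:
            raise DataError(f"no TraitSpec for trait {trait!r}")
    w = {t: 1.0 for t in traits.traits}
    if weights:
        for t, v in weights.items():
            if v < 0:
                raise DataError(f"negative weight for trait {t!r}")
            w[t] = float(v)

    species = traits.species
    n = len(species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for trait in traits.traits:
        spec = by_name[trait]
        col = traits.data[trait]
        codes = np.array([-1 if pd.isna(v) else spec.rank_of(v) for v in col])
        present = codes >= 0
        pair_ok = present[:, None] & present[None, :]
        if spec.kind == "categorical":
            delta = np.where(codes[:, None] == codes[None, :], 0.0, 1.0)
        else:
            if rank_declared_levels:
                # score levels by declared position, equally spaced, no ties
                span = max(len(spec.levels) - 1, 1)
                delta = np.abs(codes[:, None] - codes[None, :]) / span
            else:
                delta = _ordinal_deltas(codes)
        contrib = np.where(pair_ok, np.nan_to_num(delta), 0.0)
        num += w[trait] * contrib
        den += w[trait] * pair_ok

    defined = den > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(defined, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(defined, True)
    if not defined.all():
        bad = np.argwhere(~defined)
        i, j = bad[0]
        raise DataError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no "
            f"jointly non-missing trait; dissimilarity undefined")
    return DissimilarityMatrix(list(species), d, defined)


@dataclass
class ValidationReport:
    ok: bool
    problems: list[str]
    warnings: list[str]
    min_offdiag: float | None
    max_offdiag: float | None
    mean_offdiag: float | None
    n_undefined_pairs: int


def validate_matrix(m: DissimilarityMatrix) -> ValidationReport:
    """Check symmetry, range, zero diagonal; summarize off-diagonal values."""
    problems: list[str] = []
    warns: list[str] = []
    d, taxa = m.d, m.taxa
    n = len(taxa)
    if d.shape != (n, n):
        problems.append(f"shape {d.shape} does not match {n} taxa")
        return ValidationReport(False, problems, warns, None, None, None, 0)
    asym = np.argwhere(~np.isclose(d, d.T, equal_nan=True))
    if len(asym):
        i, j = asym[0]
        problems.append(f"asymmetric at pair ({taxa[i]!r}, {taxa[j]!r}): "
                        f"{d[i, j]} vs {d[j, i]}")
    if not np.allclose(np.diag(d), 0.0):
        k = int(np.argmax(np.abs(np.diag(d))))
        problems.append(f"nonzero diagonal at {taxa[k]!r}: {d[k, k]}")
    off = d[np.triu_indices(n, k=1)] if n > 1 else np.array([])
    finite = off[np.isfinite(off)]
    if len(finite) and (finite.min() < 0 or finite.max() > 1):
        problems.append(f"values outside [0, 1]: min {finite.min()}, "
                        f"max {finite.max()}")
    n_undef = int((~m.defined[np.triu_indices(n, k=1)]).sum()) if n > 1 else 0
    if n_undef:
        warns.append(f"{n_undef} undefined pairs")
    if len(finite) and finite.max() == 0:
        warns.append("no trait variation: all dissimilarities zero")
        warnings.warn("dissimilarity matrix has no trait variation")
    stats = (float(finite.min()), float(finite.max()), float(finite.mean())) \
        if len(finite) else (None, None, None)
    return ValidationReport(not problems, problems, warns, *stats, n_undef)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_matrix(m: DissimilarityMatrix, path) -> None:
    """Write the matrix as square CSV (taxa as header row and first column)."""
    m.to_frame().to_csv(path, index_label="species")


def read_matrix(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    d = df.to_numpy(dtype=float)
    return DissimilarityMatrix(list(df.columns), d, np.isfinite(d))


def write_matrix_long(m: DissimilarityMatrix, path) -> None:
    """Write the upper triangle as long-form CSV (i, j, d)."""
    rows = []
    for a in range(len(m.taxa)):
        for b in range(a + 1, len(m.taxa)):
            rows.append((m.taxa[a], m.taxa[b], m.d[a, b]))
    pd.DataFrame(rows, columns=["species_i", "species_j", "dissimilarity"]).to_csv(
        path, index=False)
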