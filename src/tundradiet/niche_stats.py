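"""Dietary niche statistics: overlap, niche width, individual specialization.

The statistics are the standard ones for proportional diet data:

* Schoener's overlap index  O(p, q) = 1 - 0.5 * sum_j |p_j - q_j|
  between two diets (0 = disjoint, 1 = identical), equivalently
  sum_j min(p_j, q_j).
* Trophic niche width (TNW): Shannon entropy of the population mean diet,
  TNW = -sum_j q_j ln q_j, in nats by default.
* Individual specialization (IS): the mean Schoener overlap between each
  individual diet and the population mean diet,
  IS = (1/N) sum_i [1 - 0.5 * sum_j |p_ij - q_j|];
  IS = 1 means every individual eats the population diet, small IS means
  strong among-individual specialization.

Group comparisons of heteroscedastic proportion data use a one-way ANOVA
on rank-transformed values; interactions in two-factor layouts use the
aligned rank transform, which removes estimated main effects before
ranking so the interaction test is not contaminated by them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import check_proportions, normalized
from .diet_composition import CompositionMatrix, DietProfile, population_mean_diet

__all__ = [
    "OverlapResult",
    "NicheStats",
    "AnovaResult",
    "schoener_overlap",
    "exclude_and_renormalize",
    "trophic_niche_width",
    "individual_specialization",
    "resampled_is",
    "rank_anova",
    "aligned_rank_anova",
]


@dataclass(frozen=True)
class OverlapResult:
    value: float
    taxon_set: str = "all"

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError("overlap outside [0, 1]")


@dataclass(frozen=True)
class NicheStats:
    tnw: float
    is_index: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float


def schoener_overlap(p: Mapping[str, float], q: Mapping[str, float],
                     taxon_set: str = "all", *,
                     normalize: bool = False) -> OverlapResult:
    """Schoener's proportional-similarity overlap between two diets.

    Computed over the union of taxa; missing taxa count as zero.  Inputs
    must each sum to 1 within 1e-6 unless ``normalize=True``, which rescales
    them first (useful when feeding rounded published percentages whose
    printed values do not sum exactly to 1).
    """
    if normalize:
        p, q = normalized(p), normalized(q)
    check_proportions(p, name="p")
    check_proportions(q, name="q")
    taxa = set(p) | set(q)
    o = 1.0 - 0.5 * sum(abs(p.get(t, 0.0) - q.get(t, 0.0)) for t in taxa)
    return OverlapResult(min(max(o, 0.0), 1.0), taxon_set)


def exclude_and_renormalize(p: Mapping[str, float],
                            excluded: set[str]) -> dict[str, float]:
    """Drop the excluded taxa and rescale the remainder to sum to 1.

    Used for overlap 'excluding the dominant family' style analyses.
    """
    kept = {t: v for t, v in p.items() if t not in excluded}
    if sum(kept.values()) <= 0:
        raise ValueError("exclusion removes all diet mass")
    return normalized(kept)


def trophic_niche_width(q: Mapping[str, float], base: float = math.e) -> float:
    """Shannon entropy of a population diet (nats by default)."""
    check_proportions(q, name="population diet")
    vals = np.asarray([v for v in q.values() if v > 0], dtype=float)
    return float(-(vals * (np.log(vals) / math.log(base))).sum())


def individual_specialization(cm: CompositionMatrix) -> float:
    """Mean overlap of each individual diet with the population mean diet."""
    if len(cm.profiles) < 2:
        raise ValueError("individual specialization needs >= 2 profiles")
    q = cm.population_mean
    overlaps = [schoener_overlap(p.proportions, q).value for p in cm.profiles]
    return float(np.mean(overlaps))


def resampled_is(cm: CompositionMatrix, n_sub: int, n_rep: int,
                 seed: int) -> tuple[float, float]:
    """Subsampled IS for sample-size-matched comparison between groups.

    Draws ``n_sub`` profiles without replacement ``n_rep`` times, recomputes
    IS on each subsample (against the subsample's own mean diet), and
    returns the mean and SD over replicates.  With ``n_sub`` equal to the
    number of profiles every replicate is the full sample and the SD is 0.
    """
    n = len(cm.profiles)
    if n_sub > n:
        raise ValueError(f"n_sub {n_sub} exceeds sample size {n}")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_rep):
        idx = rng.choice(n, size=n_sub, replace=False)
        sub = population_mean_diet([cm.profiles[i] for i in idx])
        values.append(individual_specialization(sub))
    return float(np.mean(values)), float(np.std(values))


def rank_anova(values: Sequence[float],
               groups: Sequence[str]) -> AnovaResult:
    """One-way fixed-effects ANOVA on mid-rank-transformed values.

    The rank transform is the usual remedy for heteroscedastic, non-normal
    proportion data; ties receive mid-ranks, so duplicated observations
    keep the ordering information.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(groups)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with < 2 observations: {small}")
    ranks = stats.rankdata(values)  # mid-ranks for ties
    if np.ptp(ranks) == 0:
        k = len(counts)
        return AnovaResult(0.0, (k - 1, len(values) - k), 1.0)
    by_group = [ranks[(labels == g).to_numpy()] for g in counts.index]
    f, p = stats.f_oneway(*by_group)
    if not np.isfinite(f):  # all within-group variance zero
        f, p = float("inf"), 0.0
    return AnovaResult(float(f), (len(counts) - 1, len(values) - len(counts)),
                       float(p))


def _twoway_interaction_f(ranks: np.ndarray, a: np.ndarray, b: np.ndarray,
                          ) -> AnovaResult:
    """Balanced two-way ANOVA on `ranks`; returns the A x B interaction."""
    a_levels, a_idx = np.unique(a, return_inverse=True)
    b_levels, b_idx = np.unique(b, return_inverse=True)
    I, J = len(a_levels), len(b_levels)
    n = len(ranks)
    cell_n = np.zeros((I, J))
    cell_sum = np.zeros((I, J))
    np.add.at(cell_n, (a_idx, b_idx), 1)
    np.add.at(cell_sum, (a_idx, b_idx), ranks)
    if (cell_n == 0).any():
        raise ValueError("empty cell in two-factor layout")
    if (cell_n < 2).any():
        raise ValueError("need >= 2 replicates per cell")
    grand = ranks.mean()
    cell_mean = cell_sum / cell_n
    row_mean = cell_sum.sum(axis=1) / cell_n.sum(axis=1)
    col_mean = cell_sum.sum(axis=0) / cell_n.sum(axis=0)
    ss_cells = (cell_n * (cell_mean - grand) ** 2).sum()
    ss_a = (cell_n.sum(axis=1) * (row_mean - grand) ** 2).sum()
    ss_b = (cell_n.sum(axis=0) * (col_mean - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    resid = ranks - cell_mean[a_idx, b_idx]
    ss_err = (resid ** 2).sum()
    df_ab = (I - 1) * (J - 1)
    df_err = n - I * J
    if ss_err <= 1e-12:
        if ss_ab <= 1e-12:
            return AnovaResult(0.0, (df_ab, df_err), 1.0)
        return AnovaResult(float("inf"), (df_ab, df_err), 0.0)
    f = (ss_ab / df_ab) / (ss_err / df_err)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df_ab, df_err))
    return AnovaResult(float(f), (df_ab, df_err), p)


def aligned_rank_anova(values: Sequence[float], factor_a: Sequence[str],
                       factor_b: Sequence[str]) -> AnovaResult:
    """Aligned-rank-transform test of the A x B interaction.

    Each observation is aligned for the interaction by stripping the
    estimated main effects: the cell residual plus the interaction estimate
    (cell mean - row mean - column mean + grand mean).  Aligned values are
    mid-ranked and a two-way ANOVA on the ranks yields the interaction F.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    a_levels, a_idx = np.unique(a, return_inverse=True)
    b_levels, b_idx = np.unique(b, return_inverse=True)
    I, J = len(a_levels), len(b_levels)
    cell_n = np.zeros((I, J))
    cell_sum = np.zeros((I, J))
    np.add.at(cell_n, (a_idx, b_idx), 1)
    np.add.at(cell_sum, (a_idx, b_idx), y)
    if (cell_n == 0).any():
        raise ValueError("empty cell in two-factor layout")
    if (cell_n < 2).any():
        raise ValueError("need >= 2 replicates per cell")
    cell_mean = cell_sum / cell_n
    grand = cell_mean.mean()                 # unweighted means, ART convention
    row_eff = cell_mean.mean(axis=1) - grand
    col_eff = cell_mean.mean(axis=0) - grand
    interaction_est = (cell_mean - grand
                       - row_eff[:, None] - col_eff[None, :])
    aligned = (y - cell_mean[a_idx, b_idx]) + interaction_est[a_idx, b_idx]
    if np.ptp(aligned) == 0:
        df_ab = (I - 1) * (J - 1)
        return AnovaResult(0.0, (df_ab, len(y) - I * J), 1.0)
    ranks = stats.rankdata(aligned)
    return _twoway_interaction_f(ranks, a, b)
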