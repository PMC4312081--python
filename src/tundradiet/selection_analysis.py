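"""Food selection: quadrat availability and Manly selection ratios.

Availability is estimated from clipped biomass quadrats: within a
taxonomic group (vascular plants or mosses, which are measured with
different field techniques and therefore never mixed), each quadrat's
biomass is normalized to proportions and averaged across quadrats, giving
the availability pi_i with an across-quadrat sampling variance.  A family
that dominates availability but is never eaten (Ericaceae in the intended
use) can be excluded before normalization so it does not push every other
family's selection ratio upward.

The selection ratio of Manly for design-II data (use and availability both
estimated from samples) is

    w_i = o_i / pi_i

with o_i the mean use proportion over pellet samples.  Its standard error
follows from the delta method for a ratio of two independently sampled
means:

    Var(w_i) = s2_o / (n_o * pi_i^2) + o_i^2 * s2_pi / (n_pi * pi_i^4)

where s2 are across-sample variances.  Ratios are classified against
w = 1 by the z score |w - 1| / SE: beyond 1.96 a clear sign (- or +),
between 1.28 and 1.96 a parenthesized tendency, otherwise 0; a family
present in diets but absent from every availability quadrat is NC
(not calculable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .diet_composition import DietProfile, FamilyGroups

__all__ = [
    "AvailabilityQuadrat",
    "AvailabilityTable",
    "SelectionResult",
    "availability_proportions",
    "manly_selection",
    "selection_ratio",
    "classify_selection",
    "read_quadrat_tsv",
    "write_selection_tsv",
]


@dataclass
class AvailabilityQuadrat:
    """Biomass (g/m2) per plant family in one randomly placed quadrat."""

    plot_id: str
    habitat: str
    biomass: Mapping[str, float]

    def __post_init__(self) -> None:
        for fam, b in self.biomass.items():
            if b < 0:
                raise ValueError(f"negative biomass for {fam}")


@dataclass
class AvailabilityTable:
    group: str
    pi: dict[str, float]
    var_pi: dict[str, float]
    n_quadrats: int
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n_quadrats < 2:
            raise ValueError("availability needs >= 2 quadrats")
        s = sum(self.pi.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"availability proportions sum to {s}")


@dataclass(frozen=True)
class SelectionResult:
    family: str
    o: float          # mean use proportion
    pi: float         # mean availability proportion
    w: float          # selection ratio o / pi
    se: float
    cls: str          # one of -, (-), 0, (+), +, NC


def availability_proportions(quadrats: Sequence[AvailabilityQuadrat],
                             group: str, groups: FamilyGroups,
                             exclude: set[str] | None = None,
                             ) -> AvailabilityTable:
    """Across-quadrat mean and variance of in-group biomass proportions.

    Families outside `group` and any in `exclude` are removed before each
    quadrat is normalized; quadrats left with zero in-group biomass are
    dropped with a warning count rather than contributing NaNs.
    """
    exclude = exclude or set()
    if len(quadrats) < 2:
        raise ValueError("need >= 2 quadrats")
    families = sorted({
        f for q in quadrats for f in q.biomass
        if f not in exclude and groups.group_of(f) == group})
    rows = []
    for q in quadrats:
        masses = np.array([q.biomass.get(f, 0.0) for f in families])
        total = masses.sum()
        if total <= 0:
            continue  # quadrat uninformative for this group
        rows.append(masses / total)
    if len(rows) < 2:
        raise ValueError("fewer than 2 quadrats with in-group biomass")
    mat = np.vstack(rows)
    return AvailabilityTable(
        group=group,
        pi=dict(zip(families, mat.mean(axis=0).tolist())),
        var_pi=dict(zip(families, mat.var(axis=0, ddof=1).tolist())),
        n_quadrats=len(rows),
        excluded=set(exclude),
    )


def selection_ratio(o: float, pi: float) -> float:
    """The Manly ratio, mean use over mean availability."""
    if pi <= 0:
        raise ValueError("availability must be positive for a ratio")
    return o / pi


def classify_selection(w: float, se: float,
                       z_clear: float = 1.96, z_tendency: float = 1.28) -> str:
    """Significance class of a selection ratio against neutrality (w = 1).

    z = |w - 1| / SE; z > 1.96 gives a clear sign, 1.28 < z <= 1.96 a
    parenthesized tendency, otherwise 0.  A zero SE with w != 1 is treated
    as a clear sign.
    """
    if se < 0:
        raise ValueError("negative standard error")
    sign = "+" if w > 1 else "-"
    if se == 0:
        return sign if w != 1 else "0"
    z = abs(w - 1.0) / se
    if z > z_clear:
        return sign
    if z > z_tendency:
        return f"({sign})"
    return "0"


def manly_selection(use_profiles: Sequence[DietProfile],
                    avail: AvailabilityTable) -> list[SelectionResult]:
    """Selection ratios with delta-method SEs over a family group.

    ``use_profiles`` must already be restricted and renormalized to the
    same group (and exclusion set) as ``avail`` — mixing vascular use with
    moss availability is a design error, not a data condition.  Families
    eaten but absent from all quadrats come back with class 'NC'.
    """
    if not use_profiles:
        raise ValueError("no use profiles")
    families = sorted(set(avail.pi) | {f for p in use_profiles
                                       for f in p.proportions})
    n_o = len(use_profiles)
    use_mat = np.array([[p.proportions.get(f, 0.0) for f in families]
                        for p in use_profiles])
    o_mean = use_mat.mean(axis=0)
    o_var = use_mat.var(axis=0, ddof=1) if n_o > 1 else np.zeros(len(families))
    results = []
    for j, fam in enumerate(families):
        o = float(o_mean[j])
        pi = float(avail.pi.get(fam, 0.0))
        if pi <= 0:
            if o > 0:
                results.append(SelectionResult(fam, o, pi, math.nan,
                                               math.nan, "NC"))
            continue
        w = selection_ratio(o, pi)
        var_w = (o_var[j] / (n_o * pi ** 2)
                 + o ** 2 * avail.var_pi.get(fam, 0.0)
                 / (avail.n_quadrats * pi ** 4))
        se = math.sqrt(max(var_w, 0.0))
        results.append(SelectionResult(fam, o, pi, w, se,
                                       classify_selection(w, se)))
    return results


# ---------------------------------------------------------------------------
# TSV dialects


def read_quadrat_tsv(path: str | Path) -> list[AvailabilityQuadrat]:
    """Wide TSV: plot_id, habitat, then one biomass column (g/m2) per family."""
    df = pd.read_csv(path, sep="\t")
    fams = [c for c in df.columns if c not in ("plot_id", "habitat")]
    return [AvailabilityQuadrat(str(r["plot_id"]), str(r["habitat"]),
                                {f: float(r[f]) for f in fams})
            for _, r in df.iterrows()]


def write_selection_tsv(results: Sequence[SelectionResult],
                        path: str | Path) -> None:
    pd.DataFrame(
        [(r.family, round_half_up(r.pi, 3) if not math.isnan(r.pi) else "",
          round_half_up(r.o, 3),
          round_half_up(r.w, 1) if not math.isnan(r.w) else "",
          round_half_up(r.se, 1) if not math.isnan(r.se) else "",
          r.cls) for r in results],
        columns=["family", "availability", "use", "w", "SE", "class"],
    ).to_csv(path, sep="\t", index=False)
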