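"""Per-sample diet profiles and the two-marker fusion rule.

Diet metabarcoding with the trnL P6 loop commonly runs two primer pairs:
one (g-h) that resolves vascular plants well but is biased against
bryophytes, and one (c-h) that amplifies all plants.  The fusion rule used
here takes the within-vascular family composition from the vascular-biased
marker and the vascular : bryophyte split (and the bryophyte family
composition) from the universal marker:

    p(vascular family f) = gh_prop(f) * V
    p(moss family m)     = ch_moss_prop(m) * (1 - V)

where V is the vascular read fraction of the universal marker.  When the
vascular-biased marker failed for a sample, its vascular composition falls
back to the universal marker's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import check_proportions, normalized

__all__ = [
    "FamilyGroups",
    "MarkerCounts",
    "DietProfile",
    "CompositionMatrix",
    "marker_family_proportions",
    "fuse_markers",
    "population_mean_diet",
    "group_proportions",
]

VASCULAR = "vascular"
BRYOPHYTE = "bryophyte"


@dataclass(frozen=True)
class FamilyGroups:
    """Family metadata: broad group (vascular/bryophyte) and clade.

    Ferns count as vascular; clades are dicot, monocot, fern or moss and
    drive the broad-group summaries (dicots/monocots/mosses).
    """

    group: Mapping[str, str]
    clade: Mapping[str, str] = field(default_factory=dict)

    def group_of(self, family: str) -> str:
        try:
            return self.group[family]
        except KeyError:
            raise KeyError(f"family {family!r} has no group tag") from None

    def clade_of(self, family: str) -> str:
        return self.clade.get(
            family, "moss" if self.group_of(family) == BRYOPHYTE else "dicot")


@dataclass
class MarkerCounts:
    """One sample's read counts per plant family for one marker."""

    sample_id: str
    marker: str
    counts: Mapping[str, int]
    groups: FamilyGroups

    def __post_init__(self) -> None:
        for fam, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {fam}")
            self.groups.group_of(fam)  # every family must be tagged

    def total(self, restrict_to: str | None = None) -> int:
        return sum(c for f, c in self.counts.items()
                   if restrict_to is None or self.groups.group_of(f) == restrict_to)


@dataclass
class DietProfile:
    """Proportional diet of one pellet sample over plant families (p_ij)."""

    sample_id: str
    proportions: dict[str, float]
    species: str | None = None
    habitat: str | None = None

    def __post_init__(self) -> None:
        check_proportions(self.proportions, tol=1e-9,
                          name=f"diet profile {self.sample_id}")


@dataclass
class CompositionMatrix:
    """Diet profiles over a common family universe plus their mean (q_j)."""

    profiles: list[DietProfile]
    families: list[str]
    population_mean: dict[str, float]

    def matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[p.proportions.get(f, 0.0) for f in self.families]
             for p in self.profiles],
            index=[p.sample_id for p in self.profiles], columns=self.families)


def marker_family_proportions(mc: MarkerCounts,
                              restrict_to: str | None = None,
                              ) -> dict[str, float]:
    """Family read proportions, optionally restricted to one broad group.

    With ``restrict_to='vascular'`` bryophyte reads are dropped before
    normalizing (and vice versa).  Zero in-scope reads is an error; callers
    use it to trigger the fusion fallback path.
    """
    in_scope = {f: c for f, c in mc.counts.items()
                if restrict_to is None or mc.groups.group_of(f) == restrict_to}
    total = sum(in_scope.values())
    if total <= 0:
        raise ValueError(
            f"sample {mc.sample_id}, marker {mc.marker}: zero reads in scope "
            f"({restrict_to or 'all'})")
    return {f: c / total for f, c in in_scope.items() if c > 0}


def fuse_markers(gh: MarkerCounts | None, ch: MarkerCounts,
                 species: str | None = None, habitat: str | None = None,
                 ) -> DietProfile:
    """Fuse the vascular-biased and universal markers into one profile.

    ``gh`` may be None (or have zero usable vascular reads) to signal a
    failed amplification, in which case the vascular family composition is
    taken from ``ch`` directly.
    """
    if ch.total() <= 0:
        raise ValueError(f"sample {ch.sample_id}: universal marker has no reads")
    v_frac = ch.total(VASCULAR) / ch.total()

    vascular_props: dict[str, float] | None = None
    if gh is not None:
        try:
            vascular_props = marker_family_proportions(gh, VASCULAR)
        except ValueError:
            vascular_props = None
    if vascular_props is None:  # fallback: vascular composition from c-h
        if v_frac > 0:
            vascular_props = marker_family_proportions(ch, VASCULAR)
        else:
            vascular_props = {}

    fused: dict[str, float] = {f: p * v_frac for f, p in vascular_props.items()}
    if v_frac < 1.0:
        moss_props = marker_family_proportions(ch, BRYOPHYTE)
        for f, p in moss_props.items():
            fused[f] = fused.get(f, 0.0) + p * (1.0 - v_frac)
    # guard against float drift before the profile invariant check
    fused = normalized(fused)
    sample_id = ch.sample_id
    return DietProfile(sample_id, fused, species=species, habitat=habitat)


def population_mean_diet(profiles: Sequence[DietProfile]) -> CompositionMatrix:
    """Unweighted mean diet over samples on the union family universe."""
    if not profiles:
        raise ValueError("no profiles")
    families = sorted({f for p in profiles for f in p.proportions})
    mat = np.array([[p.proportions.get(f, 0.0) for f in families]
                    for p in profiles])
    mean = mat.mean(axis=0)
    return CompositionMatrix(list(profiles), families,
                             dict(zip(families, mean.tolist())))


def group_proportions(p: Mapping[str, float], groups: FamilyGroups,
                      by: str = "clade") -> dict[str, float]:
    """Aggregate a family-level profile to broad groups.

    ``by='clade'`` gives dicot/monocot/fern/moss; ``by='group'`` gives
    vascular/bryophyte.  Sums are preserved.
    """
    out: dict[str, float] = {}
    for fam, frac in p.items():
        key = groups.clade_of(fam) if by == "clade" else groups.group_of(fam)
        out[key] = out.get(key, 0.0) + frac
    return out


# ---------------------------------------------------------------------------
# TSV dialects


def read_family_counts_tsv(path: str | Path, groups: FamilyGroups,
                           ) -> list[MarkerCounts]:
    """Long-format TSV (sample_id, marker, taxon, reads) -> MarkerCounts."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sample, marker), sub in df.groupby(["sample_id", "marker"], sort=True):
        counts = {r.taxon: int(r.reads) for r in sub.itertuples()
                  if r.taxon != "unidentified"}
        out.append(MarkerCounts(str(sample), str(marker), counts, groups))
    return out


def write_composition_tsv(cm: CompositionMatrix, path: str | Path) -> None:
    df = cm.matrix()
    meta = pd.DataFrame(
        {"species": [p.species for p in cm.profiles],
         "habitat": [p.habitat for p in cm.profiles]},
        index=df.index)
    pd.concat([meta, df], axis=1).to_csv(path, sep="\t",
                                         index_label="sample_id")


def read_composition_tsv(path: str | Path) -> CompositionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    fam_cols = [c for c in df.columns if c not in ("species", "habitat")]
    profiles = [
        DietProfile(str(idx),
                    {f: float(row[f]) for f in fam_cols if row[f] > 0},
                    species=row.get("species"), habitat=row.get("habitat"))
        for idx, row in df.iterrows()]
    return population_mean_diet(profiles)
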