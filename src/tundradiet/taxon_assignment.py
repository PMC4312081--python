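"""Assigning dietary sequence variants to plant taxa.

Each sequence variant (a dereplicated read with its per-sample count) is
looked up in the amplicon index of a formatted reference library: exact
match first, then a best-identity ungapped comparison against index keys of
similar length.  When several references match, the variant is assigned to
the lowest common ancestor over the family/genus/species ranks.  Downstream
cleaning follows the standard local-flora rules for dietary metabarcoding:
taxa absent from the study site are treated as identification errors or
contamination and removed, and species-level hits to absent species with a
local congener are reassigned to that congener.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_library import Lineage, ReferenceLibrary

__all__ = [
    "SequenceVariant",
    "TaxonAssignment",
    "LocalFlora",
    "assign_variants",
    "filter_by_local_flora",
    "aggregate_to_rank",
    "resolution_summary",
    "read_variant_tsv",
    "write_variant_tsv",
    "read_local_flora_tsv",
]

RANKS = ("family", "genus", "species")


@dataclass(frozen=True)
class SequenceVariant:
    sample_id: str
    marker: str
    sequence: str
    reads: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty variant sequence")
        if self.reads < 0:
            raise ValueError("negative read count")


@dataclass
class TaxonAssignment:
    variant: SequenceVariant
    lineage: Lineage
    rank: str                     # family | genus | species | unidentified
    status: str = "kept"          # kept | removed_absent_taxon | reassigned_congener
    identity: float | None = None


@dataclass
class LocalFlora:
    """Taxa known to occur at the study site, with congener replacements.

    ``congener_map`` sends a species name that is absent from the site to a
    congeneric species known to be present; every mapped-to species must be
    in ``species``.
    """

    families: set[str] = field(default_factory=set)
    genera: set[str] = field(default_factory=set)
    species: set[str] = field(default_factory=set)
    congener_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.congener_map.values()) - self.species
        if missing:
            raise ValueError(f"congener_map targets not in local species: {missing}")

    def is_empty(self) -> bool:
        return not (self.families or self.genera or self.species)


def _lca(lineages: Iterable[Lineage]) -> tuple[Lineage, str]:
    """Lowest common ancestor over family/genus/species.

    Ranks above family collapse to 'unidentified'.
    """
    lineages = list(lineages)
    fam = {l.family for l in lineages}
    if len(fam) != 1 or None in fam:
        return Lineage(), "unidentified"
    gen = {l.genus for l in lineages}
    if len(gen) != 1 or None in gen:
        return Lineage(family=fam.pop()), "family"
    spp = {l.species for l in lineages}
    if len(spp) != 1 or None in spp:
        return Lineage(family=fam.pop(), genus=gen.pop()), "genus"
    div = {l.division for l in lineages}
    return Lineage(division=div.pop() if len(div) == 1 else None,
                   family=fam.pop(), genus=gen.pop(),
                   species=spp.pop()), "species"


class _IdentityIndex:
    """Ungapped best-identity search over index keys, bucketed by length.

    Keys are packed into byte matrices per length so a query reduces to a
    handful of vectorized equality scans: for each candidate length within
    +-3 of the query, the shorter string is slid along the longer and the
    identity is matches / shorter length.
    """

    def __init__(self, index: Mapping[str, Iterable[Lineage]]):
        self._by_len: dict[int, tuple[np.ndarray, list[str]]] = {}
        self._index = {k: set(v) for k, v in index.items()}
        by_len: dict[int, list[str]] = {}
        for key in index:
            by_len.setdefault(len(key), []).append(key)
        for length, keys in by_len.items():
            mat = np.frombuffer("".join(keys).encode(), dtype=np.uint8)
            self._by_len[length] = (mat.reshape(len(keys), length), keys)

    def lookup(self, seq: str, threshold: float, max_len_diff: int = 3,
               ) -> tuple[set[Lineage], float] | None:
        exact = self._index.get(seq)
        if exact is not None:
            return exact, 1.0
        q = np.frombuffer(seq.encode(), dtype=np.uint8)
        best = 0.0
        best_keys: list[str] = []
        for length in range(len(seq) - max_len_diff, len(seq) + max_len_diff + 1):
            if length <= 0 or length not in self._by_len:
                continue
            mat, keys = self._by_len[length]
            short = min(length, len(seq))
            for off in range(abs(length - len(seq)) + 1):
                if length >= len(seq):
                    matches = (mat[:, off:off + short] == q).sum(axis=1)
                else:
                    matches = (mat == q[off:off + short]).sum(axis=1)
                ident = matches / short
                m = float(ident.max())
                if m > best + 1e-12:
                    best = m
                    best_keys = [keys[i] for i in np.flatnonzero(ident >= m - 1e-12)]
                elif abs(m - best) <= 1e-12 and m > 0:
                    best_keys.extend(keys[i] for i in np.flatnonzero(ident >= m - 1e-12))
        if best < threshold or not best_keys:
            return None
        lineages: set[Lineage] = set()
        for k in set(best_keys):
            lineages |= self._index[k]
        return lineages, best


def assign_variants(variants: Sequence[SequenceVariant], lib: ReferenceLibrary,
                    identity_threshold: float = 0.95) -> list[TaxonAssignment]:
    """Assign each variant to a lineage via the amplicon index.

    Exact index hits are taken first; otherwise the variant is compared
    ungapped against index keys within +-3 of its length and assigned at
    the best identity if it reaches ``identity_threshold``.  The assigned
    lineage is the lowest common ancestor of all tied best references; a
    variant with no qualifying match is returned rank='unidentified'.
    """
    if not lib.amplicon_index:
        raise ValueError("reference library has an empty amplicon index; "
                         "run in_silico_pcr first")
    searcher = _IdentityIndex(lib.amplicon_index)
    cache: dict[str, tuple[Lineage, str, float | None]] = {}
    out: list[TaxonAssignment] = []
    for v in variants:
        seq = v.sequence.upper()
        if seq not in cache:
            hit = searcher.lookup(seq, identity_threshold)
            if hit is None:
                cache[seq] = (Lineage(), "unidentified", None)
            else:
                lineages, ident = hit
                lineage, rank = _lca(lineages)
                cache[seq] = (lineage, rank, ident)
        lineage, rank, ident = cache[seq]
        out.append(TaxonAssignment(v, lineage, rank, identity=ident))
    return out


def filter_by_local_flora(assignments: Sequence[TaxonAssignment],
                          flora: LocalFlora) -> list[TaxonAssignment]:
    """Apply the local-flora cleaning rules in place of raw assignments.

    Assignments to families or genera absent from the site are marked
    ``removed_absent_taxon``.  Species-level assignments to an absent
    species are reassigned to a local congener when the congener map has
    one (status ``reassigned_congener``); reassignment never crosses genus
    boundaries.  An empty flora removes nothing.
    """
    if flora.is_empty():
        return [TaxonAssignment(a.variant, a.lineage, a.rank, "kept", a.identity)
                if a.rank != "unidentified" else a for a in assignments]
    out: list[TaxonAssignment] = []
    for a in assignments:
        lin, rank = a.lineage, a.rank
        if rank == "unidentified":
            out.append(a)
            continue
        status = "kept"
        if lin.family and flora.families and lin.family not in flora.families:
            status = "removed_absent_taxon"
        elif lin.genus and flora.genera and lin.genus not in flora.genera:
            status = "removed_absent_taxon"
        elif rank == "species" and flora.species and lin.species not in flora.species:
            local = flora.congener_map.get(lin.species)
            if local is not None:
                lin = Lineage(division=lin.division, family=lin.family,
                              genus=lin.genus, species=local)
                status = "reassigned_congener"
            else:
                # absent species, no known local congener: drop to genus
                lin = Lineage(division=lin.division, family=lin.family,
                              genus=lin.genus)
                rank = "genus"
        out.append(TaxonAssignment(a.variant, lin, rank, status, a.identity))
    return out


def removed_read_fraction(assignments: Sequence[TaxonAssignment]) -> float:
    """Fraction of reads removed as absent-taxon errors/contamination."""
    total = sum(a.variant.reads for a in assignments)
    if total == 0:
        return 0.0
    removed = sum(a.variant.reads for a in assignments
                  if a.status == "removed_absent_taxon")
    return removed / total


_RANK_ORDER = {"family": 0, "genus": 1, "species": 2}


def _name_at_rank(lin: Lineage, rank: str) -> str | None:
    return getattr(lin, rank)


def aggregate_to_rank(assignments: Sequence[TaxonAssignment],
                      rank: str = "family") -> pd.DataFrame:
    """Sum kept reads per (sample, marker, taxon-at-rank).

    Returns a long-format DataFrame with columns sample_id, marker, taxon,
    reads.  Unidentified variants, and identified variants not resolved to
    `rank`, contribute to an 'unidentified' bucket; removed variants are
    dropped entirely, so per-sample totals equal input totals minus removed
    reads.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    rows: dict[tuple[str, str, str], int] = {}
    for a in assignments:
        if a.status == "removed_absent_taxon":
            continue
        name = _name_at_rank(a.lineage, rank) if a.rank != "unidentified" else None
        taxon = name if name else "unidentified"
        key = (a.variant.sample_id, a.variant.marker, taxon)
        rows[key] = rows.get(key, 0) + a.variant.reads
    df = pd.DataFrame(
        [(s, m, t, r) for (s, m, t), r in sorted(rows.items())],
        columns=["sample_id", "marker", "taxon", "reads"])
    return df


def resolution_summary(assignments: Sequence[TaxonAssignment],
                       exclude_families: set[str] | None = None,
                       ) -> dict[str, float]:
    """Read-weighted fraction of sequences identified at each rank.

    Removed assignments are excluded; `exclude_families` drops whole
    families before the proportions are computed (used to quantify how a
    single low-resolution family depresses genus/species resolution).
    """
    excl = exclude_families or set()
    pool = [a for a in assignments
            if a.status != "removed_absent_taxon"
            and (a.lineage.family not in excl)]
    total = sum(a.variant.reads for a in pool)
    if total == 0:
        raise ValueError("no reads in scope for resolution summary")
    out = {}
    for rank in RANKS:
        reads = sum(a.variant.reads for a in pool
                    if a.rank in _RANK_ORDER
                    and _RANK_ORDER[a.rank] >= _RANK_ORDER[rank])
        out[rank] = reads / total
    return out


# ---------------------------------------------------------------------------
# TSV dialects


def read_variant_tsv(path: str | Path) -> list[SequenceVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "marker": str,
                                            "sequence": str, "reads": int})
    return [SequenceVariant(r.sample_id, r.marker, r.sequence, int(r.reads))
            for r in df.itertuples()]


def write_variant_tsv(variants: Sequence[SequenceVariant], path: str | Path) -> None:
    pd.DataFrame(
        [(v.sample_id, v.marker, v.sequence, v.reads) for v in variants],
        columns=["sample_id", "marker", "sequence", "reads"],
    ).to_csv(path, sep="\t", index=False)


def read_local_flora_tsv(path: str | Path) -> LocalFlora:
    """Columns: rank, name, local_replacement (optional, species rows only)."""
    flora = LocalFlora()
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rank, name = row["rank"].strip(), row["name"].strip()
            if rank == "family":
                flora.families.add(name)
            elif rank == "genus":
                flora.genera.add(name)
            elif rank == "species":
                flora.species.add(name)
            repl = (row.get("local_replacement") or "").strip()
            if repl:
                flora.species.add(repl)
                flora.congener_map[name] = repl
    return flora
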