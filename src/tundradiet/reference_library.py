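"""Plant barcode reference libraries and in-silico PCR.

A reference library holds short plastid barcode sequences (the trnL P6 loop
in the intended use) annotated with a taxonomic lineage.  Before it can be
used for taxon assignment the library is *formatted*: each record is trimmed
to the amplicon a given primer pair would produce, by locating both primer
binding sites with a mismatch tolerance and extracting the insert between
them.  The resulting amplicon index maps insert sequences to the set of
lineages carrying them.

The module also provides the diagnostic-site search used to design
species-specific primers for consumer (host) identification: given aligned
mitochondrial sequences of two species, it finds pairs of dinucleotide sites
at which the species are internally fixed and mutually distinct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Lineage",
    "PrimerPair",
    "ReferenceRecord",
    "ReferenceLibrary",
    "DiagnosticSitePair",
    "load_reference_fasta",
    "write_reference_fasta",
    "in_silico_pcr",
    "find_diagnostic_site_pairs",
    "export_amplicon_index",
]

_IUPAC = {k.upper(): frozenset(v.upper()) for k, v in ambiguous_dna_values.items()}
_IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")  # standard nucleotide codes only


@dataclass(frozen=True, order=True)
class Lineage:
    """Taxonomic lineage at the ranks the pipeline reports on.

    Lower ranks are optional but must not skip: a species implies a genus,
    a genus implies a family.
    """

    division: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.species and not self.genus:
            raise ValueError("species requires genus")
        if self.genus and not self.family:
            raise ValueError("genus requires family")

    @property
    def lowest_rank(self) -> str:
        if self.species:
            return "species"
        if self.genus:
            return "genus"
        if self.family:
            return "family"
        return "unidentified"


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its mismatch budget.

    Both primers are written 5'->3'; the reverse primer is reverse-
    complemented internally when scanning the template.  ``max_mismatch``
    applies to each primer separately (the tolerance convention of ecoPCR-
    style in-silico amplification).
    """

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{label} primer is empty")
            bad = set(seq.upper()) - _IUPAC_CODES
            if bad:
                raise ValueError(f"{label} primer has non-IUPAC symbols: {bad}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class ReferenceRecord:
    record_id: str
    lineage: Lineage
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id}: empty sequence")
        self.sequence = self.sequence.upper().replace("-", "")


@dataclass
class ReferenceLibrary:
    """A set of reference records plus, once formatted, an amplicon index."""

    records: list[ReferenceRecord] = field(default_factory=list)
    amplicon_index: dict[str, set[Lineage]] = field(default_factory=dict)
    n_skipped: int = 0           # malformed entries dropped at load time
    n_excluded: int = 0          # records without a primer hit pair
    flagged: list[str] = field(default_factory=list)  # ambiguous primer hits

    def __len__(self) -> int:
        return len(self.records)

    def rank_counts(self) -> dict[str, int]:
        """Distinct families/genera/species across records."""
        fams = {r.lineage.family for r in self.records if r.lineage.family}
        gens = {(r.lineage.family, r.lineage.genus)
                for r in self.records if r.lineage.genus}
        spps = {(r.lineage.genus, r.lineage.species)
                for r in self.records if r.lineage.species}
        return {"family": len(fams), "genus": len(gens), "species": len(spps)}


def _parse_lineage(description: str, syntax: Mapping[str, str]) -> Lineage:
    """Parse ``key=value`` tags from a FASTA description.

    `syntax` maps rank -> header key, e.g. {"family": "family"}.  Tags are
    separated by ';'.
    """
    tags: dict[str, str] = {}
    for chunk in description.split(";"):
        chunk = chunk.strip()
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            tags[k.strip()] = v.strip()
    return Lineage(
        division=tags.get(syntax.get("division", "division")),
        family=tags.get(syntax.get("family", "family")),
        genus=tags.get(syntax.get("genus", "genus")),
        species=tags.get(syntax.get("species", "species")),
    )


def load_reference_fasta(path: str | Path,
                         lineage_syntax: Mapping[str, str] | None = None,
                         ) -> ReferenceLibrary:
    """Read a lineage-annotated FASTA into a :class:`ReferenceLibrary`.

    Headers carry ``key=value;`` lineage tags after the identifier.  Entries
    whose lineage is malformed (e.g. a genus tag without a family) are
    skipped and counted in ``n_skipped``; a file yielding zero valid records
    is an error.
    """
    syntax = dict(lineage_syntax or {})
    lib = ReferenceLibrary()
    path = Path(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            desc = rec.description
            if desc.startswith(rec.id):  # SeqIO keeps the id in description
                desc = desc[len(rec.id):]
            lineage = _parse_lineage(desc, syntax)
            lib.records.append(
                ReferenceRecord(rec.id, lineage, str(rec.seq)))
        except ValueError:
            lib.n_skipped += 1
    if not lib.records:
        raise ValueError(f"{path}: no valid reference records")
    return lib


def write_reference_fasta(lib: ReferenceLibrary, path: str | Path) -> None:
    """Write records as 80-column FASTA with ``id key=value;...`` headers."""
    out = []
    for r in lib.records:
        tags = []
        for rank in ("division", "family", "genus", "species"):
            val = getattr(r.lineage, rank)
            if val:
                tags.append(f"{rank}={val}")
        out.append(SeqRecord(Seq(r.sequence), id=r.record_id,
                             description="; ".join(tags)))
    SeqIO.write(out, str(path), "fasta")


def _primer_matches(primer: str, window: str) -> int:
    """Mismatches between a primer and an equal-length template window.

    IUPAC ambiguity codes are expanded on the primer side only; the template
    is taken literally (an N in the template matches nothing but N-coded
    primer positions).
    """
    n = 0
    for p, t in zip(primer, window):
        if t not in _IUPAC.get(p, frozenset()):
            n += 1
    return n


def _find_hits(primer: str, template: str, max_mismatch: int) -> list[int]:
    """All start offsets where `primer` matches with <= max_mismatch."""
    lp = len(primer)
    return [i for i in range(len(template) - lp + 1)
            if _primer_matches(primer, template[i:i + lp]) <= max_mismatch]


def in_silico_pcr(lib: ReferenceLibrary, primers: PrimerPair) -> ReferenceLibrary:
    """Trim every record to the primer-pair amplicon and build the index.

    For each record the forward primer and the reverse-complemented reverse
    primer are located ungapped with at most ``max_mismatch`` mismatches
    each.  The insert between the two binding sites becomes an index key
    mapping to the record's lineage.  Records without a valid hit pair are
    excluded (counted in ``n_excluded``); records with several
    non-overlapping hit pairs are flagged and the leftmost pair is used.
    """
    rc_rev = str(Seq(primers.reverse).reverse_complement()).upper()
    fwd = primers.forward.upper()
    out = ReferenceLibrary(n_skipped=lib.n_skipped)
    for rec in lib.records:
        template = rec.sequence
        fwd_hits = _find_hits(fwd, template, primers.max_mismatch)
        pair = None
        n_pairs = 0
        for fh in fwd_hits:
            insert_start = fh + len(fwd)
            rev_hits = [h for h in _find_hits(rc_rev, template, primers.max_mismatch)
                        if h >= insert_start]
            if rev_hits:
                n_pairs += len(rev_hits)
                if pair is None:
                    pair = (insert_start, rev_hits[0])
        if pair is None:
            out.n_excluded += 1
            continue
        if n_pairs > 1:
            out.flagged.append(rec.record_id)
        insert = template[pair[0]:pair[1]]
        out.records.append(ReferenceRecord(rec.record_id, rec.lineage,
                                           insert or "N"))
        key = insert.upper().replace("-", "")
        if key:
            out.amplicon_index.setdefault(key, set()).add(rec.lineage)
    return out


def export_amplicon_index(lib: ReferenceLibrary, path: str | Path) -> None:
    """TSV dump of the amplicon index: amplicon, family, genus, species."""
    with open(path, "w") as fh:
        fh.write("amplicon\tfamily\tgenus\tspecies\n")
        for amp in sorted(lib.amplicon_index):
            for lin in sorted(lib.amplicon_index[amp]):
                fh.write(f"{amp}\t{lin.family or ''}\t{lin.genus or ''}"
                         f"\t{lin.species or ''}\n")


# ---------------------------------------------------------------------------
# Diagnostic-site search for consumer species identification


@dataclass(frozen=True)
class DiagnosticSitePair:
    """Two dinucleotide sites that jointly distinguish two species.

    ``positions`` are the 0-based alignment columns of the first nucleotide
    of each site; ``separation`` counts the nucleotides strictly between the
    two sites.  ``dinucleotides`` maps ("a"|"b", site-index) to the fixed
    dinucleotide of that species at that site.
    """

    positions: tuple[int, int]
    separation: int
    dinucleotides: dict[tuple[str, int], str] = field(hash=False, compare=False,
                                                      default_factory=dict)


def _fixed_dinucleotides(seqs: Sequence[str]) -> dict[int, str]:
    """Columns at which every sequence carries the same dinucleotide."""
    length = len(seqs[0])
    out: dict[int, str] = {}
    for i in range(length - 1):
        dints = {s[i:i + 2].upper() for s in seqs}
        if len(dints) == 1:
            d = next(iter(dints))
            if set(d) <= {"A", "C", "G", "T"}:
                out[i] = d
    return out


def consensus_sequence(seqs: Sequence[str]) -> str:
    """Strict-majority consensus; ties yield the ambiguity placeholder N."""
    length = len(seqs[0])
    cols = []
    for i in range(length):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[i].upper()] = counts.get(s[i].upper(), 0) + 1
        best = max(counts.values())
        winners = [b for b, c in counts.items() if c == best]
        cols.append(winners[0] if len(winners) == 1 else "N")
    return "".join(cols)


def find_diagnostic_site_pairs(seqs_a: Sequence[str], seqs_b: Sequence[str],
                               separation_range: tuple[int, int],
                               ) -> list[DiagnosticSitePair]:
    """Find dinucleotide site pairs that distinguish two species.

    Both input sets must be pre-aligned to a common length.  A column ``i``
    is an eligible site when all sequences of species A share one
    dinucleotide at (i, i+1), all of species B share another, and the two
    differ at both positions.  Returns every pair of eligible sites whose
    separation (nucleotides strictly between the sites) lies in
    ``separation_range`` inclusive, sorted by leftmost position.
    """
    if not seqs_a or not seqs_b:
        raise ValueError("need at least one sequence per species")
    lengths = {len(s) for s in itertools.chain(seqs_a, seqs_b)}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned to equal length")

    fixed_a = _fixed_dinucleotides(seqs_a)
    fixed_b = _fixed_dinucleotides(seqs_b)
    sites = sorted(
        i for i in fixed_a.keys() & fixed_b.keys()
        if fixed_a[i][0] != fixed_b[i][0] and fixed_a[i][1] != fixed_b[i][1]
    )
    lo, hi = separation_range
    pairs: list[DiagnosticSitePair] = []
    for i, j in itertools.combinations(sites, 2):
        sep = j - i - 2  # bases strictly between site (i,i+1) and (j,j+1)
        if sep < 0:  # overlapping dinucleotides cannot host two primers
            continue
        if lo <= sep <= hi:
            pairs.append(DiagnosticSitePair(
                positions=(i, j), separation=sep,
                dinucleotides={("a", 0): fixed_a[i], ("a", 1): fixed_a[j],
                               ("b", 0): fixed_b[i], ("b", 1): fixed_b[j]}))
    pairs.sort(key=lambda p: p.positions)
    return pairs
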