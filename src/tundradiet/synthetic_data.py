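"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the data a two-marker trnL P6-loop diet-
metabarcoding study produces, at the scale of the field study the
pipeline is modeled on:

* a reference library of short amplicons with lineage annotations,
  embedded in templates carrying real trnL primer binding sites;
* per-sample, per-marker read counts over plant families, drawn
  Dirichlet-multinomial: each sample's true diet is a Dirichlet draw
  around its consumer species' mean diet (capturing among-individual
  variation), and reads are multinomial over families with probabilities
  proportional to diet times a per-marker amplification bias (the
  vascular-biased marker nearly ignores bryophytes);
* sequencing depths drawn negative-binomial around per-marker means
  (defaults 608 and 299 reads/sample, uneven as real runs are);
* plant-availability quadrats with lognormal biomass variation around a
  fixed expected biomass per family.

Everything is reproducible from a seed, and every generated dataset
carries its ground truth so recovery tests can compare pipeline estimates
against it.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diet_composition import FamilyGroups, MarkerCounts
from .reference_library import (Lineage, PrimerPair, ReferenceLibrary,
                                ReferenceRecord, in_silico_pcr)
from .taxon_assignment import SequenceVariant
from .selection_analysis import AvailabilityQuadrat
from .datasets import BYLOT_FAMILY_GROUPS

__all__ = [
    "SyntheticTruth",
    "SyntheticDataset",
    "PRIMER_GH",
    "PRIMER_CH",
    "generate_truth",
    "generate_reference_library",
    "generate_sample_counts",
    "generate_availability_quadrats",
    "generate_amplicon_calls",
]

# Real trnL P6-loop primer sequences (g, c forward; h reverse).
PRIMER_GH = PrimerPair("g-h", "GGGCAATCCTGAGCCAA", "CCATTGAGTCTCTGCACCTATC",
                       max_mismatch=5)
PRIMER_CH = PrimerPair("c-h", "CGAAATCGGTAGACGCTACG", "CCATTGAGTCTCTGCACCTATC",
                       max_mismatch=5)

MARKERS = ("g-h", "c-h")
_PRIMERS = {"g-h": PRIMER_GH, "c-h": PRIMER_CH}


@dataclass
class SyntheticTruth:
    """Generator parameters: the ground truth recovery tests compare to."""

    families: FamilyGroups
    species_mean_diets: dict[str, dict[str, float]]
    concentration: float
    marker_bias: dict[str, dict[str, float]]     # marker -> group -> factor
    reads_per_sample: dict[str, float]           # marker -> mean depth
    depth_dispersion: float
    availability_mean: dict[str, float]          # family -> expected g/m2
    availability_sigma: float                    # lognormal dispersion
    habitat_probs: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for sp, diet in self.species_mean_diets.items():
            s = sum(diet.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"mean diet of {sp} sums to {s}")
            if any(v < 0 for v in diet.values()):
                raise ValueError(f"negative diet proportion for {sp}")
        for m, bias in self.marker_bias.items():
            if any(b < 0 for b in bias.values()):
                raise ValueError(f"negative bias factor for marker {m}")
        if any(d <= 0 for d in self.reads_per_sample.values()):
            raise ValueError("depths must be positive")


@dataclass
class SyntheticDataset:
    """Generated per-sample data plus its sample-level ground truth."""

    marker_counts: dict[tuple[str, str], MarkerCounts]   # (sample, marker)
    variants: list[SequenceVariant]
    metadata: dict[str, dict[str, str]]                  # sample -> species/habitat
    true_diets: dict[str, dict[str, float]]              # sample -> diet
    variant_truth: list[str] = field(default_factory=list)  # source family per variant


# --------------------------------------------------------------------------
# Presets

_BYLOT_COLLARED = {
    "Salicaceae": 0.78, "Polygonaceae": 0.03, "Rosaceae": 0.02,
    "Fabaceae": 0.01, "Saxifragaceae": 0.01,
    "Poaceae": 0.12, "Juncaceae": 0.02,
    "Polytrichaceae": 0.005, "Dicranaceae": 0.005,
}
_BYLOT_BROWN = {
    "Salicaceae": 0.55, "Polygonaceae": 0.04, "Saxifragaceae": 0.03,
    "Rosaceae": 0.02, "Fabaceae": 0.01,
    "Poaceae": 0.07, "Juncaceae": 0.02,
    "Polytrichaceae": 0.17, "Aulacomniaceae": 0.05, "Dicranaceae": 0.04,
}

# Expected biomass (g/m2): vascular scaled so Ericaceae is 58% of vascular
# biomass and the rest follows the snowbed availability proportions; moss
# biomass from cover-derived estimates.
_BYLOT_AVAILABILITY = {
    "Ericaceae": 58.0,
    "Salicaceae": 29.9, "Juncaceae": 4.75, "Poaceae": 2.3,
    "Rosaceae": 1.8, "Fabaceae": 0.55, "Polygonaceae": 0.35,
    "Saxifragaceae": 0.17, "Caryophyllaceae": 0.1,
    "Polytrichaceae": 13.4, "Scapaniaceae": 11.4, "Amblystegiaceae": 9.8,
    "Hylocomiaceae": 9.7, "Ptilidiaceae": 2.2, "Aulacomniaceae": 1.35,
    "Ditrichaceae": 0.95, "Dicranaceae": 0.75,
}

_UNIFORM_FAMS = ("Salicaceae", "Poaceae", "Juncaceae", "Rosaceae",
                 "Polygonaceae", "Polytrichaceae", "Dicranaceae",
                 "Aulacomniaceae")


def generate_truth(preset: str = "bylot-like", seed: int = 0) -> SyntheticTruth:
    """Build the ground-truth parameter set for a named scenario.

    Presets: ``bylot-like`` (Salicaceae-dominated diets, brown lemming with
    a quarter mosses, collared with almost none; broad-group overlap 0.75
    by construction), ``no-overlap`` (disjoint diets), ``uniform``
    (identical uniform diets).
    """
    common = dict(
        families=BYLOT_FAMILY_GROUPS,
        concentration=15.0,
        marker_bias={"g-h": {"vascular": 1.0, "bryophyte": 0.02},
                     "c-h": {"vascular": 1.0, "bryophyte": 1.0}},
        reads_per_sample={"g-h": 608.0, "c-h": 299.0},
        depth_dispersion=5.0,
        availability_mean=dict(_BYLOT_AVAILABILITY),
        availability_sigma=0.5,
        habitat_probs={"mesic": 0.40, "gully": 0.45, "wetland": 0.15},
        seed=seed,
    )
    if preset == "bylot-like":
        diets = {"Dicrostonyx": dict(_BYLOT_COLLARED),
                 "Lemmus": dict(_BYLOT_BROWN)}
    elif preset == "no-overlap":
        diets = {"Dicrostonyx": {"Salicaceae": 0.7, "Rosaceae": 0.3},
                 "Lemmus": {"Poaceae": 0.6, "Polytrichaceae": 0.4}}
    elif preset == "uniform":
        u = 1.0 / len(_UNIFORM_FAMS)
        diets = {"Dicrostonyx": {f: u for f in _UNIFORM_FAMS},
                 "Lemmus": {f: u for f in _UNIFORM_FAMS}}
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return SyntheticTruth(species_mean_diets=diets, **common)


# --------------------------------------------------------------------------
# Reference library

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_BASES, size=length)).decode()


def generate_reference_library(truth: SyntheticTruth, primers: PrimerPair,
                               seed: int, n_species_per_family: int = 3,
                               records_per_species: int = 1,
                               insert_length: tuple[int, int] = (40, 70),
                               families: Sequence[str] | None = None,
                               ) -> tuple[ReferenceLibrary, dict[str, list[str]]]:
    """A collision-free synthetic reference library for one marker.

    Each species receives a unique random amplicon insert embedded in a
    template ``flank + forward primer + insert + revcomp(reverse) + flank``
    so in-silico PCR recovers exactly the insert.  Returns the raw library
    and a map family -> its species' insert sequences (the generator's
    bookkeeping for recovery tests).
    """
    rng = np.random.default_rng(seed)
    fams = list(families) if families is not None else sorted(
        {f for diet in truth.species_mean_diets.values() for f in diet}
        | set(truth.availability_mean))
    from Bio.Seq import Seq
    rc_rev = str(Seq(primers.reverse).reverse_complement())
    lib = ReferenceLibrary()
    seen: set[str] = set()
    amplicons: dict[str, list[str]] = {}
    serial = itertools.count(1)
    for fam in fams:
        amplicons[fam] = []
        genus = fam[:-4] if fam.endswith("ceae") else fam  # e.g. Salica-
        for sp_i in range(n_species_per_family):
            length = int(rng.integers(insert_length[0], insert_length[1] + 1))
            insert = _random_seq(rng, length)
            while insert in seen:
                insert = _random_seq(rng, length)
            seen.add(insert)
            amplicons[fam].append(insert)
            lineage = Lineage(
                division=("Bryophyta"
                          if truth.families.group_of(fam) == "bryophyte"
                          else "Tracheophyta"),
                family=fam, genus=genus,
                species=f"{genus} synthetica{sp_i + 1}")
            for _ in range(records_per_species):
                flank5 = _random_seq(rng, int(rng.integers(5, 16)))
                flank3 = _random_seq(rng, int(rng.integers(5, 16)))
                template = (flank5 + primers.forward + insert
                            + rc_rev + flank3)
                lib.records.append(ReferenceRecord(
                    f"SYN{next(serial):05d}", lineage, template))
    return lib, amplicons


# --------------------------------------------------------------------------
# Sample counts


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return max(int(rng.negative_binomial(dispersion, p)), 1)


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    for i in np.flatnonzero(hit):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_sample_counts(truth: SyntheticTruth,
                           n_per_species: Mapping[str, int],
                           seed: int | None = None,
                           amplicons: Mapping[str, Mapping[str, Sequence[str]]]
                           | None = None,
                           error_rate: float = 0.0) -> SyntheticDataset:
    """Draw per-sample, per-marker family counts (and optionally variants).

    Per sample a true diet is drawn Dirichlet(concentration x species mean
    diet); per marker a sequencing depth is drawn negative-binomial and
    reads are multinomial over families with probabilities proportional to
    diet x marker bias.  When ``amplicons`` supplies per-marker family ->
    insert sequences, a sequence-variant table is also emitted with
    independent per-base errors at ``error_rate``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    families = truth.families
    habitats = list(truth.habitat_probs)
    hab_p = np.array([truth.habitat_probs[h] for h in habitats])
    hab_p = hab_p / hab_p.sum()

    marker_counts: dict[tuple[str, str], MarkerCounts] = {}
    variants: list[SequenceVariant] = []
    variant_truth: list[str] = []
    metadata: dict[str, dict[str, str]] = {}
    true_diets: dict[str, dict[str, float]] = {}
    sample_no = itertools.count(1)

    for species, n in n_per_species.items():
        mean = truth.species_mean_diets[species]
        fams = sorted(mean)
        alpha = np.array([mean[f] for f in fams]) * truth.concentration
        for _ in range(n):
            sid = f"S{next(sample_no):04d}"
            habitat = habitats[int(rng.choice(len(habitats), p=hab_p))]
            diet = rng.dirichlet(np.maximum(alpha, 1e-9))
            true_diets[sid] = dict(zip(fams, diet.tolist()))
            metadata[sid] = {"species": species, "habitat": habitat}
            for marker in MARKERS:
                bias = truth.marker_bias[marker]
                w = np.array([diet[i] * bias.get(families.group_of(f), 0.0)
                              for i, f in enumerate(fams)])
                if w.sum() <= 0:
                    counts = {}
                else:
                    depth = _nb_depth(rng, truth.reads_per_sample[marker],
                                      truth.depth_dispersion)
                    draw = rng.multinomial(depth, w / w.sum())
                    counts = {f: int(c) for f, c in zip(fams, draw) if c > 0}
                marker_counts[(sid, marker)] = MarkerCounts(
                    sid, marker, counts, families)
                if amplicons is not None:
                    for v, fam in _emit_variants(rng, sid, marker, counts,
                                                 amplicons[marker],
                                                 error_rate):
                        variants.append(v)
                        variant_truth.append(fam)
    return SyntheticDataset(marker_counts, variants, metadata, true_diets,
                            variant_truth)


def _emit_variants(rng: np.random.Generator, sid: str, marker: str,
                   counts: Mapping[str, int],
                   fam_amplicons: Mapping[str, Sequence[str]],
                   error_rate: float) -> list[tuple[SequenceVariant, str]]:
    out: list[tuple[SequenceVariant, str]] = []
    for fam, c in counts.items():
        seqs = fam_amplicons.get(fam)
        if not seqs:
            continue
        split = rng.multinomial(c, np.full(len(seqs), 1.0 / len(seqs)))
        for seq, n_reads in zip(seqs, split):
            if n_reads == 0:
                continue
            if error_rate <= 0:
                out.append((SequenceVariant(sid, marker, seq, int(n_reads)),
                            fam))
                continue
            p_clean = (1.0 - error_rate) ** len(seq)
            n_err = int(rng.binomial(n_reads, 1.0 - p_clean))
            if n_reads - n_err > 0:
                out.append((SequenceVariant(sid, marker, seq,
                                            int(n_reads - n_err)), fam))
            mutated: dict[str, int] = {}
            for _ in range(n_err):
                m = _mutate(rng, seq, error_rate)
                while m == seq:
                    m = _mutate(rng, seq, max(error_rate, 1.0 / len(seq)))
                mutated[m] = mutated.get(m, 0) + 1
            out.extend((SequenceVariant(sid, marker, m, k), fam)
                       for m, k in mutated.items())
    return out


# --------------------------------------------------------------------------
# Availability quadrats


def generate_availability_quadrats(truth: SyntheticTruth, n_quadrats: int,
                                   seed: int) -> list[AvailabilityQuadrat]:
    """Random biomass quadrats around the truth's expected biomasses.

    Each quadrat's total biomass is the expected total times a mean-one
    lognormal factor with sigma ``truth.availability_sigma``, and its
    family composition is Dirichlet around the truth's biomass proportions
    with concentration ``8 / sigma**2`` (so a single knob controls both
    total and compositional heterogeneity, and per-quadrat proportions stay
    unbiased for the truth).  ``sigma = 0`` yields identical quadrats.
    Quadrats alternate between the two snowbed habitats.
    """
    if n_quadrats < 2:
        raise ValueError("need >= 2 quadrats")
    rng = np.random.default_rng(seed)
    sigma = truth.availability_sigma
    fams = sorted(truth.availability_mean)
    means = np.array([truth.availability_mean[f] for f in fams])
    total = means.sum()
    pi = means / total
    quadrats = []
    for i in range(n_quadrats):
        if sigma > 0:
            t = total * rng.lognormal(-sigma ** 2 / 2.0, sigma)
            props = rng.dirichlet(pi * 8.0 / sigma ** 2)
        else:
            t, props = total, pi
        biomass = {f: float(t * p) for f, p in zip(fams, props)}
        quadrats.append(AvailabilityQuadrat(
            plot_id=f"Q{i + 1:02d}",
            habitat="mesic" if i % 2 == 0 else "gully",
            biomass=biomass))
    return quadrats


# --------------------------------------------------------------------------
# Species-ID calls


def generate_amplicon_calls(n: int, disagree_rate: float, seed: int,
                            centers: Mapping[str, float] | None = None,
                            length_sd: float = 1.5) -> list:
    """Synthetic field-vs-genetic identification calls.

    Each sample is a true species; the measured amplicon length is normal
    around that species' center, and with probability ``disagree_rate`` the
    field identification is set to the other species.
    """
    from .species_id import OBSERVED_CENTERS, AmpliconCall, \
        classify_by_amplicon_length
    centers = dict(centers or OBSERVED_CENTERS)
    rng = np.random.default_rng(seed)
    species = sorted(centers)
    calls = []
    for i in range(n):
        true_sp = species[int(rng.integers(len(species)))]
        length = float(rng.normal(centers[true_sp], length_sd))
        field_id = true_sp
        if rng.random() < disagree_rate:
            field_id = next(s for s in species if s != true_sp)
        calls.append(AmpliconCall(
            sample_id=f"P{i + 1:04d}", measured_length=max(length, 1.0),
            call=classify_by_amplicon_length(length, centers),
            field_id=field_id))
    return calls
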