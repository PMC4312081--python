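"""Reference values from the Bylot Island winter lemming-diet survey.

These are the published summary numbers of the field study the pipeline is
modeled on: broad-group mean diets of collared (*Dicrostonyx
groenlandicus*) and brown (*Lemmus trimucronatus*) lemmings, and the
availability/use/selection summary for the major food families in mesic
and stream-gully snowbeds.  They serve as worked-example inputs and as
regression anchors for the statistics modules; they are summaries (means
over samples), not the per-sample data, which were never deposited.
"""

from __future__ import annotations

from .diet_composition import FamilyGroups

__all__ = [
    "BYLOT_FAMILY_GROUPS",
    "BROAD_GROUP_DIETS",
    "SELECTION_SUMMARY",
    "CONCORDANCE_COUNTS",
]

#: Broad-group winter diet means (fractions of sequence reads).  The moss
#: share of collared lemmings was reported only as "< 1%" and is carried
#: here as 0.01; the rows therefore sum to 1.01 and 1.00 and should be fed
#: to overlap computations with normalize=True.
BROAD_GROUP_DIETS: dict[str, dict[str, float]] = {
    "Dicrostonyx": {"dicot": 0.86, "monocot": 0.14, "moss": 0.01},
    "Lemmus": {"dicot": 0.65, "monocot": 0.09, "moss": 0.26},
}

#: Field-vs-genetic species identification: matches / comparable samples.
CONCORDANCE_COUNTS = (73, 74)

#: Availability (pi), use (o), selection ratio (w), its SE and the reported
#: significance class for food items > 1% of the diet.  Availability
#: excludes Ericaceae (58% of vascular biomass, never eaten); vascular and
#: moss groups are normalized separately.  Keys: (consumer species, family).
SELECTION_SUMMARY: dict[tuple[str, str], dict[str, float | str]] = {
    ("Dicrostonyx", "Fabaceae"):     {"pi": 0.013, "o": 0.003, "w": 0.2, "se": 0.5, "cls": "(-)"},
    ("Dicrostonyx", "Juncaceae"):    {"pi": 0.113, "o": 0.018, "w": 0.2, "se": 0.1, "cls": "-"},
    ("Dicrostonyx", "Poaceae"):      {"pi": 0.054, "o": 0.124, "w": 2.2, "se": 2.4, "cls": "0"},
    ("Dicrostonyx", "Rosaceae"):     {"pi": 0.043, "o": 0.005, "w": 0.1, "se": 0.2, "cls": "-"},
    ("Dicrostonyx", "Salicaceae"):   {"pi": 0.713, "o": 0.839, "w": 1.2, "se": 0.2, "cls": "0"},
    ("Lemmus", "Fabaceae"):          {"pi": 0.013, "o": 0.010, "w": 0.8, "se": 1.9, "cls": "0"},
    ("Lemmus", "Juncaceae"):         {"pi": 0.113, "o": 0.029, "w": 0.3, "se": 0.2, "cls": "-"},
    ("Lemmus", "Poaceae"):           {"pi": 0.056, "o": 0.091, "w": 1.6, "se": 1.7, "cls": "0"},
    ("Lemmus", "Polygonaceae"):      {"pi": 0.008, "o": 0.049, "w": 6.5, "se": 19.0, "cls": "0"},
    ("Lemmus", "Rosaceae"):          {"pi": 0.043, "o": 0.048, "w": 1.1, "se": 1.7, "cls": "0"},
    ("Lemmus", "Salicaceae"):        {"pi": 0.713, "o": 0.727, "w": 1.0, "se": 0.2, "cls": "0"},
    ("Lemmus", "Saxifragaceae"):     {"pi": 0.004, "o": 0.036, "w": 8.4, "se": 33.0, "cls": "0"},
    ("Lemmus", "Aulacomniaceae"):    {"pi": 0.027, "o": 0.334, "w": 16.1, "se": 28.0, "cls": "0"},
    ("Lemmus", "Dicranaceae"):       {"pi": 0.015, "o": 0.062, "w": 4.1, "se": 8.3, "cls": "0"},
    ("Lemmus", "Polytrichaceae"):    {"pi": 0.267, "o": 0.501, "w": 1.9, "se": 0.8, "cls": "0"},
}

#: Rows of SELECTION_SUMMARY whose printed ratio cannot be recovered from
#: the printed (rounded to 3 decimals) availability and use columns —
#: the published ratios were evidently computed from unrounded inputs.
RATIO_INCONSISTENT_ROWS: frozenset[tuple[str, str]] = frozenset({
    ("Dicrostonyx", "Poaceae"),
    ("Lemmus", "Polygonaceae"),
    ("Lemmus", "Saxifragaceae"),
    ("Lemmus", "Aulacomniaceae"),
})

#: Group/clade tags for every family appearing in diets or availability at
#: the study site.  Ferns (Equisetaceae) count as vascular.
BYLOT_FAMILY_GROUPS = FamilyGroups(
    group={
        # vascular plants
        "Asteraceae": "vascular", "Brassicaceae": "vascular",
        "Caryophyllaceae": "vascular", "Cyperaceae": "vascular",
        "Ericaceae": "vascular", "Fabaceae": "vascular",
        "Juncaceae": "vascular", "Orobanchaceae": "vascular",
        "Papaveraceae": "vascular", "Poaceae": "vascular",
        "Polygonaceae": "vascular", "Ranunculaceae": "vascular",
        "Rosaceae": "vascular", "Salicaceae": "vascular",
        "Saxifragaceae": "vascular", "Equisetaceae": "vascular",
        # bryophytes
        "Aulacomniaceae": "bryophyte", "Bartramiaceae": "bryophyte",
        "Bryaceae": "bryophyte", "Dicranaceae": "bryophyte",
        "Ditrichaceae": "bryophyte", "Grimmiaceae": "bryophyte",
        "Polytrichaceae": "bryophyte", "Pottiaceae": "bryophyte",
        "Rhabdoweisiaceae": "bryophyte", "Timmiaceae": "bryophyte",
        "Scapaniaceae": "bryophyte", "Amblystegiaceae": "bryophyte",
        "Hylocomiaceae": "bryophyte", "Ptilidiaceae": "bryophyte",
    },
    clade={
        "Asteraceae": "dicot", "Brassicaceae": "dicot",
        "Caryophyllaceae": "dicot", "Cyperaceae": "monocot",
        "Ericaceae": "dicot", "Fabaceae": "dicot",
        "Juncaceae": "monocot", "Orobanchaceae": "dicot",
        "Papaveraceae": "dicot", "Poaceae": "monocot",
        "Polygonaceae": "dicot", "Ranunculaceae": "dicot",
        "Rosaceae": "dicot", "Salicaceae": "dicot",
        "Saxifragaceae": "dicot", "Equisetaceae": "fern",
    },
)
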