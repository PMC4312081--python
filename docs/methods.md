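# Methods

## Scope and data model

The package analyses proportional diet data derived from amplicon
sequencing of fecal pellets. Its in-memory contract is simple: a
`DietProfile` is a per-sample map family → proportion summing to 1 (±1e−9);
a `CompositionMatrix` is a cohort of profiles on the union family universe
with their unweighted mean. Everything downstream (overlap, niche width,
specialization, selection) consumes these. Counts reach profiles through
two stages: taxon assignment (sequence variants → family counts) and
two-marker fusion (per-marker counts → one profile per sample).

## Reference library and in-silico PCR

Reference records are short plastid barcode sequences with a lineage
(division, family, genus, species; lower ranks optional but never skipping
a rank). Formatting locates the forward primer and the reverse-complemented
reverse primer ungapped, expanding IUPAC ambiguity codes on the primer side
only, with an independent mismatch budget per primer (default 5, the
conventional in-silico PCR tolerance for the trnL system). The insert
between the binding sites becomes an index key mapping to the record's
lineage. Records with no hit pair are excluded and counted; records with
several non-overlapping hit pairs are flagged and resolved to the leftmost
pair, a deterministic and reportable rule. Retention is monotone in the
mismatch budget and re-amplifying a reconstructed insert+primers template
reproduces the index exactly; both properties are tested.

The diagnostic-site search used for consumer primer design requires, at a
candidate site, that every sequence of a species carries the same
dinucleotide (internal fixation) and that the two species differ at both
positions; a majority-rule consensus (ties → N, ineligible) is available
separately. Site pairs are reported with the count of bases strictly
between them, matching how primer-flanked spacing is described in practice.

## Taxon assignment and cleaning

Variants are looked up exactly first; failing that, compared ungapped
against index keys within ±3 of their length, sliding the shorter sequence
along the longer, with identity = matches / shorter length. The default
acceptance threshold is 0.95 — one to two errors on a typical 40–70 bp
P6-loop insert — chosen as a conservative round number; it is a parameter,
not a calibrated constant. Ties at the best identity are resolved to the
lowest common ancestor over family/genus/species; disagreement at family
collapses to unidentified. Cleaning follows the local-flora rules standard
in dietary metabarcoding: families or genera absent from the site are
treated as identification error or contamination and removed (with the
removed read fraction reported); species-level hits to absent species with
a known local congener are reassigned to it, never across genera.
Aggregation conserves reads: kept + removed + unidentified equals input,
asserted per sample in the tests.

## Two-marker fusion

Let V be the vascular read fraction of the universal marker (*c-h*) for a
sample. The fused profile is the *g-h* within-vascular composition scaled
by V, plus the *c-h* bryophyte family composition (renormalized among
bryophytes) scaled by 1 − V. Renormalization of the bryophyte block is
forced by the sum-to-one requirement. If *g-h* yielded no usable vascular
reads, the vascular composition falls back to *c-h*. Cohort means are
unweighted across samples (each pellet sample counts equally, matching the
mean ± SE presentation conventional for such surveys) rather than
read-weighted; read depth reflects amplification, not intake.

## Niche statistics

Schoener overlap, TNW (natural log by default; base configurable) and IS
are as in the README. IS is the Bolnick-style mean overlap between each
individual and the population mean diet — the variant that is literally an
extension of the Schoener index, which is why it was chosen over pairwise
alternatives. Between-species overlap is computed on the two species' mean
diet profiles, not as a mean of pairwise sample overlaps. The resampling
comparator draws subsamples without replacement and recomputes IS against
the subsample's own mean, so a full-size subsample reproduces the
full-sample IS exactly for every seed.

Group tests use one-way ANOVA on mid-rank-transformed values (robust to the
heteroscedastic, non-normal distributions typical of proportion data; its
type-I error is simulation-calibrated to [0.04, 0.06] at 2,000 null
replicates in the acceptance suite). Interaction tests use the aligned rank
transform: observations are aligned for the interaction (cell residual plus
the unweighted-means interaction estimate), mid-ranked, and tested with a
balanced two-way ANOVA on ranks. The two-way sums of squares are computed
directly (explicit balanced-design formulas) rather than through a model-
fitting layer; the simulation oracles call it thousands of times. Constant
or fully aligned data return F = 0, p = 1.

## Food selection

Availability comes from clipped-quadrat biomass: within a group (vascular
plants or mosses — sampled with different field techniques, never mixed),
each quadrat is normalized to proportions after removing excluded families;
the table stores the across-quadrat mean and variance (ddof = 1). Excluding
a dominant never-eaten family (Ericaceae in the motivating system, 58% of
vascular biomass) prevents a spurious positive shift in every other
family's ratio. Quadrats with zero in-group biomass are dropped rather than
propagating NaNs.

The Manly ratio and its delta-method variance for independently sampled use
and availability means are given in the README. The delta method is checked
against a 1,000-replicate parametric re-simulation at survey-like sizes
(47 use samples, 16 quadrats): the mean reported SE falls within 20% of the
Monte-Carlo SD of the ratio. Classification thresholds z = 1.96 / 1.28
(clear / tendency) were calibrated so that the published symbol table of
the motivating survey is reproduced for all fifteen printed (w, SE) pairs;
they are a calibration choice, not an authorial specification, and are
exposed as parameters. A family eaten but absent from every quadrat is
classed NC (not calculable). Four published ratio rows are internally
inconsistent with their own printed, rounded availability/use columns
(the originals were evidently computed from unrounded inputs); the golden
ratio tests cover only the self-consistent rows.

## Synthetic-data generator

The generator defines the study conditions for every recovery test:

- **Cohorts**: 54 brown + 22 collared samples by default; habitats drawn
  mesic/gully/wetland (0.40/0.45/0.15).
- **Diets**: per sample, Dirichlet(concentration × species mean diet);
  concentration 15 gives moderate individual variation (IS around 0.6–0.9
  on the default preset). The `bylot-like` preset plants collared
  broad-group means (0.85, 0.14, 0.01) and brown (0.65, 0.09, 0.26), so the
  truth overlap is 0.75 at the broad-group level by construction.
- **Markers**: read probabilities ∝ diet × per-marker group bias
  (vascular-biased marker: bryophyte factor 0.02 — direction is known from
  the chemistry, magnitude is a modeling choice); depths negative-binomial
  (dispersion 5) around 608 (*g-h*) and 299 (*c-h*) reads/sample.
- **Variants**: per family, reads split uniformly over that family's
  species amplicons, with independent per-base errors; unique random
  inserts of 40–70 bp embedded between real trnL primer sequences, so the
  in-silico PCR path is exercised for real.
- **Availability**: per quadrat, total biomass is lognormal (mean-one,
  sigma 0.5) around the expected total and the composition is Dirichlet
  around the true biomass proportions with concentration 8/σ². A Dirichlet
  composition (rather than independent per-family lognormal factors) keeps
  per-quadrat group proportions exactly unbiased for the truth under
  restriction and renormalization — independent noise would bias the
  dominant family's estimated availability by about 0.03 at these settings
  — while one knob still controls heterogeneity and σ = 0 degenerates to
  identical quadrats.

What the generator does not emulate: chimeras, tag jumping, PCR
stochasticity beyond multinomial sampling, chloroplast copy-number and
digestion biases, spatial structure among quadrats, and reference-library
gaps. Passing recovery tests therefore show the statistical machinery is
correct under the stated sampling model, not that field data meet that
model.

## Numerical conventions

- Reported statistics round half-up at the published precision (Decimal
  arithmetic, not banker's rounding).
- Profile validation tolerates 1e−9 drift; overlap inputs must sum to 1
  within 1e−6, with an explicit `normalize=True` escape hatch for rounded
  published percentages.
- Entropy uses 0·ln 0 := 0; overlap values are clamped to [0, 1] against
  float drift.
- Mid-ranks for all ties; degenerate ANOVA inputs return F = 0, p = 1;
  zero within-group variance with separated groups returns F = ∞, p = 0.
- Problem sizes in the test suite: simulation oracles run at 300–2,000
  replicates and cohorts of 12–200 samples, chosen to keep Monte-Carlo
  error well inside the asserted bounds.

## Known limitations

- Read proportions are treated as diet proportions; no correction for
  marker copy number or differential digestion is attempted (none is well
  defined for this system).
- The identity-threshold assignment has no external-database fallback for
  poor matches; such variants stay unidentified.
- The aligned-rank interaction test assumes a balanced-ish complete layout;
  severely unbalanced designs should use a dedicated mixed-model tool.
- Manly variances assume independent sampling of use and availability and
  large-ish n; for tiny availability shares the delta method understates
  tail behavior (visible as the huge SEs on rare families).
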