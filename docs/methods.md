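# Methods

## The problem and the model

Mitofusin 2 (MFN2) fuses outer mitochondrial membranes through a
GTP-driven cycle: nucleotide binding rearranges the GTP-binding site of
the GTPase domain (residues 95–339), two MFN2 molecules dimerize head to
head, GTP is hydrolysed, and the protein closes into a diamond-shaped
conformation held together by long-range electrostatic pairs between its
GTPase, HR1, HR2 and paddle domains. Missense mutations in the GTPase
domain cause CMT2A, and substitutions at the same residue position can
differ widely in clinical severity. The package asks a deliberately narrow
question: *within* one residue position, does the severity ranking of the
observed substitutions derived from clinical records agree with the
ranking derived from structural assessment of the mutant protein?
Restricting comparisons to substitutions at the same position removes most
confounding (same structural context, same biological function) and is
what gives the approach its discriminative power relative to generic
variant-effect predictors, which score each variant in isolation.

## Catalogue and grouping

Mutation records are protein-level HGVS-like labels (`p.Arg274Trp`),
parsed case-insensitively from 1- or 3-letter codes and canonicalised to
3-letter labels. Frameshift and nonsense notations are rejected as
non-missense; compound labels (`p.Arg250Trp + Arg400*`) keep their first
missense component and carry the rest as unscored annotations, because
nonsense alleles in trans are not treated as disease-causing here. The
pipeline filters to the GTPase domain (inclusive 1-based range, default
95–339), removes listed exclusions (variants without clinical data, one
in-cis double mutation), de-duplicates repeated literature reports, and
groups by position, keeping positions with at least two distinct
alternatives. A single substitution at a position offers nothing to rank,
which is why singletons are dropped rather than scored.

## The severity scale

The scale treats CMT2A as a systemic mitochondrial disorder rather than a
pure peripheral neuropathy: standard scales (CMTNS, FDS) are unusable
across heterogeneous literature reports and ignore the multisystem
features that dominate the severe end of the spectrum. The score is a sum
of an onset base term (early < 6 y: 1.5; classical 6–20 y: 1.0; late
> 20 y: 0.5) and fixed feature points (see README table); every additional
mitochondrial symptom contributes 0.5 with no cap — the severe early-onset
cases accumulate five or more such terms, and capping would compress
exactly the tail the scale exists to resolve.

Two boundary decisions deserve note. First, the onset categories as
commonly stated ("before 5" / "6–20") leave age 5 unassigned; the package
uses *early = age < 6* so the categories are exhaustive, and no bundled
case distinguishes 5 from 6. Second, a genetically confirmed but
clinically unaffected carrier is represented by an explicit
`asymptomatic` flag that suppresses the onset term, giving the score 0 —
an onset category would be meaningless for someone who never manifested.
When a report is compatible with several onset categories the score is the
interval over the alternatives; several reports of one mutation aggregate
to the interval hull, so scores attach to mutations, not patients.
"Extensor plantar responses" maps to the pyramidal-signs key (2 points),
and an unspecified "other minor symptom" is representable by a generic
0.5-point token.

## Ordering chains and concordance

Clinical chains are derived from scores: labels sorted by decreasing
interval midpoint (ties broken alphabetically before `=` assignment), with
adjacent relations assigned as

* `=` when midpoints are equal,
* `≥` when both scores are point values exactly 0.5 apart — one minor
  symptom, the resolution limit of the scale, is read as a tendency rather
  than a strict order,
* `>` otherwise (including any interval-valued score).

This derivation rule is a design choice of the package: it is the simplest
rule that reproduces all eleven bundled reference chains, including the
pair that would otherwise be inconsistent (position 259 yields `Leu ≥ Cys`
from point scores 2.5 vs 2.0, while position 250 yields `Trp > Gln` from
the intervals 1–1.5 vs 0.5–1 despite the same midpoint gap).

Comparison checks, for every adjacent pair of the clinical chain, the
composed relation between the same labels in the structural chain. A
clinical `≥` is compatible with `>` or `=` (it claims no strict order); a
`>`-vs-`=` disagreement in either direction makes the position *partial*
("incomplete but not discordant"); an actual rank reversal makes it
*discordant*. Only fully concordant positions enter the agreement
numerator; the percentage is rounded half-up (8/11 → 73%). The same
machinery compares rankings induced by external variant-effect-predictor
scores (descending score, exact ties → `=`); that comparison is labelled
methodology-dependent, since predictors are not calibrated within residue
positions.

## Static structure analysis

The structural module is deliberately static: it detects interactions in a
single coordinate set and encodes the curated interaction networks, but
computes no molecular dynamics, energies, docking or homology models — the
per-mutation structural severity orderings remain user-supplied
annotations that this module can support with evidence, not replace.

Detectors and defaults (heavy atoms only; models carry no hydrogens):

* **salt bridge** — minimum distance between carboxylate oxygens
  (Asp OD1/OD2, Glu OE1/OE2) and basic side-chain nitrogens
  (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2) ≤ 4.0 Å. Histidine is treated as
  protonatable and therefore cationic — an approximation needed because
  the curated dimer-interface contacts (His165–Glu268, His168–Glu272)
  involve neutral-pH histidines.
* **π-stacking** — ring-centroid distance ≤ 5.5 Å and interplanar angle
  ≤ 30° (parallel stacking; ring planes fitted by SVD; tryptophan uses its
  six-membered ring).
* **hydrophobic** — minimum side-chain carbon–carbon distance ≤ 4.5 Å
  between apolar residues (Ala, Val, Leu, Ile, Met, Pro, Phe, Trp).

These cutoffs follow common structural-biology practice, are configurable
on every entry point, and are echoed in all reports. Detectors are
invariant under rigid motions, report each residue pair once, and are
monotone in their cutoffs (property-tested against exhaustive all-pair
scans). PDB input uses the first model of a file (warning on more),
rejects insertion codes, and resolves alternate locations by highest
occupancy then altloc `A`.

The curated content comprises (a) the six long-range electrostatic closure
pairs (Asp210–Arg476, Lys243–Asp480, Arg250–Glu598, Glu542–Lys732,
Asp377/Glu370–Arg564, Glu359–Arg575), audited by `check_closure_network` —
a pair with alternative acidic partners counts as present if any of them
bridges the basic residue; and (b) the mechanism map assigning the 11
analysed positions to five categories: GTP-site rearrangement (277),
dimerization (104, 165, 259, 274, 276), GTP hydrolysis (127), closure
(210, 250) and unknown (244, 251). Both are versioned code constants with
user-overridable call parameters; the bundled tabular fixtures
(catalogue, clinical records, ordering annotations) ship as data files
with SHA-256 checksums verified before a reference run.

## Synthetic data

The generators produce every input class the pipeline consumes, under a
single integer seed and with exact round-trip guarantees:

* **catalogues** — a configurable number of multi-substitution positions
  (default 11, group sizes 2–4, positions within 95–339, mirroring the
  shape of the reference catalogue) plus optional singletons.
* **cohorts** — for each mutation a record whose score equals a sampled
  target exactly (targets are multiples of 0.5; default range 0.5–7, the
  range the reference table spans). Composition is greedy-deterministic —
  onset base, then majors in decreasing point order, then 0.5 minors — so
  goldens are reproducible; a sampled mode shuffles feature choice behind
  a flag. Targets above 16 points are unreachable under the vocabulary and
  rejected.
* **coordinate fixtures** — idealized side-chain templates placed so that
  the designated contact atoms sit at the requested distance exactly
  (stacking: ring centroids at the requested separation, parallel or
  perpendicular), one interaction per well-separated slot, with a 1.5 Å
  clash limit. Geometry is idealized, not chemically realistic: detectors
  consume atom positions only.
* **concordance scenarios** — chain pairs with known truth status,
  constructed by strictness flips (partial) or adjacent-label swaps across
  a strict relation (discordant).

What passing the synthetic suites shows — and what it does not: they
demonstrate that scoring inverts the generator exactly, that comparison
recovers constructed statuses, and that detectors find planted geometries
at format precision. They do not validate the scale against independent
clinical assessment, nor the detectors against experimental structures
with realistic side-chain conformations, crystallographic noise or missing
atoms.

## Numerical choices and degenerate inputs

Scores are validated as non-negative multiples of 0.5; interval scores
require min ≤ max. Percentages round half-up via `int(x + 0.5)` to avoid
banker's rounding on exact halves. Chain serialization uses `≥`, parsing
also accepts `>=`. Empty inputs: domain filtering and grouping accept
empty catalogues (empty output); the concordance summary refuses an empty
comparison list; an empty structure yields an all-missing closure report.
Conflicting wild-type residues at one position, onset-free symptomatic
records, unknown feature keys, label-set mismatches between chains and
residue-numbering mismatches between diffed structures are hard errors.

## Problem sizes

The reference analysis is desk-scale (26 records, 11 positions) and runs
in well under a second. Property suites use 1,000 random catalogues of up
to 50 records, 500 scored targets, hundreds of random chain pairs, and
random structures of ≤ 30 residues — sizes at which the brute-force
oracles are exact and the full test suite completes in a few seconds.

## Known limitations

* The severity scale is built from heterogeneous literature descriptions;
  unreported symptoms and alternative causes cannot be excluded, and the
  scale has no external validation cohort.
* The 73% agreement statistic rests on 11 positions; it is a consistency
  check, not a calibrated predictive accuracy.
* The structural module's static geometry cannot reproduce
  dynamics-derived severity judgments (trajectory stability, energetics),
  and the hinge-opening behaviour of the closure mechanism has no static
  analogue here.
* His-as-cation and heavy-atom hydrogen-bond proxies overcount
  interactions in structures where protonation or hydrogen geometry
  matters.
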