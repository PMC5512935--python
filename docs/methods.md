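# Methods and design notes

## The pedigree model

The toolkit represents a family as individuals, unions (partnerships) and
sibships, deliberately capped at three generations — the frame used by
questionnaire-driven intake, where each relative has a fixed slot on the
sheet and no slot exists that could express a fourth level. Generations are
stored as integers 1–3 and converted to Roman numerals I–III only at display
time; numerals are assigned by *rank among occupied levels*, so a chart
occupying only the bottom level still labels it I.

Pregnancy losses (spontaneous abortion, termination, ectopic pregnancy) are
ordinary individuals with a dedicated life stage rather than a separate
type: they occupy sibship positions, can carry affected status ("affected
SAB"), and map to the small-triangle glyph. Stillbirth and ectopic
pregnancy additionally receive auto-generated "SB"/"ECT" annotations, and
evaluation marks (E, Eu, E+) travel as plain annotation text — the same
remarks-based convention the symbol matrix documents for these rows.

Two modelling choices were genuinely open and decided as follows:

* **Siblings of grandparents.** Uncle/aunt slots of the oldest generation
  have parents outside the three-generation frame, so a sibship may have no
  parental union: it renders as a free sibling line. Kinship computations
  treat such a parentless sibship as one *implicit founder couple*, which is
  exactly what makes first-cousinship decidable inside the frame.
* **Multiple-individuals nodes** (one symbol standing for k or "n"
  relatives) cannot be proband, consultand, or a pregnancy; the n-symbol
  summarizes born individuals.

## Questionnaire semantics

The intake branch (client has a child / has none) is a pure relabelling of
a fixed slot topology; both branches produce identical slot-id sequences.
Default record names equal the relationship label and are treated as unset
— the interviewer must overwrite them to enter a real name, and a name left
at its default is never rendered as a name. A record left entirely at its
defaults yields no individual.

Four repeated *cousin* slot families (children of each uncle/aunt family,
selected by a `parent_index`) extend the printed correspondence table; they
exist because the consanguinity overlay needs a record for the spouse as
seen from the other branch (an uncle's child). Divorced-partner slots are
accepted per the schema but the builder draws at most one divorced partner
per central-couple member: relationship lines must stay between adjacent
symbols, which keeps marriage chains path-shaped (ex — husband — wife — ex).

Connector relatives (a parent pair required by an entered sibling, the
unnamed spouse of an uncle with entered children, the partner of an
individual whose union carries an infertility marker) are materialized as
sex-typed, unnamed, history-unknown individuals only when a filled slot
needs them — the chart stays minimal.

An affected record with no checked condition key fills with the base key
colour (key slot 1); a record with checked keys is affected by definition.
The custody checkbox sits on child records: checked on a child of a
divorced union, it marks the remaining central-couple parent as holding
primary responsibility, which displaces the break in the relationship line
toward the non-custodial side (1/3 from that end; centered for shared or
unspecified custody).

Twin groups form from a shared multiple-gestation ID within one sibship;
the builder orders children eldest-first with gestation groups consecutive.
Zygosity is monozygotic when the box is checked (members left sex-unknown
are harmonized; two different entered sexes are a build error), dizygotic
for unmarked pairs, trizygotic for triples, and "unknown" (annotated
"zygosity ?") beyond that.

## The consanguinity overlay

A first-cousin marriage cannot be drawn from one vantage point in three
generations, because the couple's shared grandparents sit outside one
branch's frame. The overlay therefore fuses two records carrying the same
Overlay ID — typically the spouse entered minimally on the client branch
and fully as an uncle's child. Attribute fusion lets blank defaults yield
to entered values and rejects conflicting entered values (different sex,
two different real names, incompatible ages or life stages); structural
fusion rewrites every union, sibship, twin-group and mark reference and
removes one individual. The fused person's partnership is then flagged
consanguineous. If the fused spouses are *not* first cousins the merge
still succeeds but emits a warning, since the overlay exists specifically
to draw first-cousin marriages. Sharing one Overlay ID across more than
two records is rejected.

First-cousinship is decided structurally: the two partners are not
siblings, and a parent of each shares a sibling line (including the
parentless kind, i.e. the implicit founder couple). The test suite verifies
this against an independent brute-force enumeration of grandparental
couples.

## Layout

Coordinates are abstract units (origin top-left, y downward; renderers
scale). Each occupied generation is one row. Within a row, individuals
follow the builder's slot ordering — husband's branch left of the wife's,
children in birth order — with union partners forced adjacent by walking
marriage chains as paths. X positions are assigned bottom row first
(sequential packing), then each upper row's chain block is centered over
its children where a left-to-right sweep allows (classic bottom-up sibship
packing with top-down centering, adapted to couples). Relationship lines
run between adjacent partners at symbol mid-height; a vertical drop meets
the horizontal sibship bar, and children hang by vertical descent lines
(dashed for adopted-in children). Twin lines converge diagonally on a
shared apex, so the "descent lines are vertical at their attachment"
invariant applies to non-twin hangers; monozygotic groups get a crossbar.
Consanguinity loops keep the double line straight between the adjacent
spouses and accept the crossing descent line to the fused spouse's parents
— crossings are permitted, symbol overlaps never (audited exhaustively).

Defaults: symbol size 30 units, horizontal gap 30 (≥ symbol size by
construction), vertical gap 50, margin 30. Any strictly positive values
satisfying those constraints are valid; geometry does not depend on the
pedigree's content beyond the structures above, so identical inputs yield
identical coordinates.

## Symbols and shading

Glyphs follow the standard mapping (square/circle/diamond by sex, small
triangle for pregnancies not carried to term; slash for deceased,
stillbirth, SAB and TOP; P/n/k/D/S center letters; dot for carriers,
vertical line for presymptomatic carriers; brackets for adoption; an arrow
— labelled P for the proband, unlabelled for consultands — at the lower
left; "?" above an individual whose history is unavailable). Conditions
fill quadrants clockwise from the upper left in key order; a single
condition fills the whole symbol; an affected pregnancy-loss triangle fills
below a horizontal bar. The four key shades are luminance-stepped variants
of one configurable colour, computed by blending the base colour toward
black or white until the sRGB relative luminance hits the targets
(0.13/0.32/0.55/0.82), giving pairwise gaps ≥ 0.15 for any base colour —
the chart survives a grayscale photocopy. The shipped feature checklist has
43 rows (the full symbol-matrix support set); `compliance_report` rebuilds
a minimal pedigree per row and verifies the feature in the derived glyph,
line style or rendered output.

## Rendering and privacy

SVG 1.1 is built with the standard-library XML tree in fixed attribute
order, so output is byte-deterministic (two renders of the same input are
identical, hence rasterize identically). By default no entered name appears
anywhere in the output bytes; `show_names=True` opts in, and names equal to
relationship-label defaults are structural, never sensitive. The legend
lists checked keys in slot order with their shade swatches; metadata
(family names, ancestries, date of intake, historian, reason, remarks) is
folded into a remarks block in the corner. A single generic sans-serif
family covers the "?", Roman-numeral and "wk" glyphs. Vector output is
SVG; no separate PDF writer is provided.

## Document container and protection

The container is versioned JSON carrying the questionnaire (the source of
truth), the built pedigree, comments, timestamps, and flags. Password
protection wraps the payload in an authenticated envelope built from
standard-library primitives: PBKDF2-SHA256 (120 000 iterations, random
16-byte salt) derives independent encryption and MAC keys; an
HMAC-SHA256-in-counter-mode keystream encrypts; an HMAC-SHA256 tag over
header and ciphertext authenticates (encrypt-then-MAC), so a wrong password
or tampering is detected, never silently garbled output. Read-only is
advisory metadata enforced by the toolkit: saving over a read-only file
requires explicitly clearing the flag. Timestamp overrides are allowed
(paper sheets are backfilled in cohort intake) but recorded in a
`times_overridden` marker for provenance. Default filenames concatenate the
date stamp with the first ten *characters* (spaces count — reversible and
language-neutral) of every checked key label in slot order.

PED export writes the six-column LINKAGE format. Multiple-individual nodes
and pregnancy losses cannot carry genotype rows and are skipped with a
logged warning; a skipped parent exports as founder 0, so parent references
always resolve within the file. Affection is 2 when the chosen key is among
an individual's condition keys, 1 for born unaffected individuals, 0
otherwise (pregnancies, or affected with a different key).

## Fixtures, the random generator, and concordance

The named scenarios are *synthetic* families authored to their stated
inheritance patterns (X-linked D, recessive-with-consanguinity P, dominant
VHL, a maximal "ultimate" chart, and a minimal lone client); they make no
claim of structural identity with any published scenario sheet. The random
generator emulates intake variability — branch choice, slot fill, affected
≈ 15 %, twins ≈ 10 % of eligible sheets, consanguineous overlays ≈ 5 %,
blank/unknown/numeric ages — while never emitting a sheet the builder
rejects. It does **not** emulate real-data pathologies such as inconsistent
ages between relatives, misremembered causes of death, or half-sibling
structures outside the slot set, so green property suites demonstrate
structural correctness of the pipeline, not robustness to noisy clinical
narratives.

Concordance between a produced pedigree and a reference aligns individuals
by generation rank and left-to-right position, then scores every element —
existence, sex, life stage, affected keys, carrier state, proband/consultand
marks, multiple-count, unions with status and consanguinity, sibships, twin
groups — at one point each. The published allocation-point weighting for
such scoring is not available, so equal weighting is used and declared in
the per-category breakdown, allowing any alternative weighting to be
layered on top. The fraction is matched over the union of both element
sets: extra structure costs as much as missing structure, and 1.0 is
attained exactly at attribute-identity up to id relabelling.

## Problem sizes and numerical notes

The test and acceptance suites run the full pipeline over 500 seeded random
questionnaires (about two seconds end to end), 40 container round trips (10
of them encrypted), and the five scenarios; these sizes exercise every code
path many times over while keeping the suites quick to run anywhere.
Shade computation bisects the blend parameter for 40 iterations (\~1e-12
resolution) before 8-bit quantization; layout uses exact arithmetic on
multiples of the grid unit, so coordinate comparisons in tests are exact.

## Known limitations

* Three generations by design; larger kindreds need a different frame.
* One divorced partner per central-couple member is drawable; additional
  ex-partners are schema-valid but rejected at build time.
* Consanguinity beyond first cousins (double cousins, avuncular unions) is
  not expressible through the overlay; the model itself can carry a
  consanguineous flag on any union.
* No risk calculation, kinship coefficients, HL7/FHIR family-history
  resources, or interactive editing.
* The crossing-minimization in consanguinity loops is heuristic; charts
  remain collision-free but not always minimal-crossing.
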