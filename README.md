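# ftree

A scriptable toolkit for collecting a three-generation family health history
through a structured questionnaire and turning it into a medical pedigree:
a validated graph, a standardized-nomenclature chart (SVG), a versioned —
optionally password-protected — document container, and PED/LINKAGE rows for
downstream genetic analysis.

It is aimed at genetic-counseling clinics and genome-cohort intake
workflows, where family histories are gathered in bulk by staff without
specialized training in clinical genetics or chart drawing: the interviewer
fills a multiple-choice sheet, and the chart draws itself.

## The model

A pedigree here is a typed graph restricted to **three generations**
(labelled I, II, III):

* **Individuals** carry sex, age, a life stage (living, deceased, pregnancy,
  SAB/TOP/stillbirth/ectopic outcome), affected status with up to **four
  condition keys**, carrier or presymptomatic-carrier state, proband and
  consultand marks, adoption/donor/surrogate roles, and free-text remarks.
* **Unions** (partnerships) carry divorce/separation, custody, infertility,
  no-children-by-choice and consanguinity flags.
* **Sibships** connect a union to its children in birth order and hold twin
  groups with zygosity.

The questionnaire branches once, at intake: *does the client have a child?*
The answer only relabels the fixed slot topology (with a child the client
couple is the central generation II couple; without one the central couple
is the client's parents and the client sits in generation III). Sixteen
"disease/KEY" entry fields name conditions of interest; the first four act
as condition keys whose luminance-stepped shades of one configurable colour
fill affected symbols — distinguishable even in a black-and-white photocopy.
First-cousin marriages are entered with the **overlay**: the same person is
recorded from two family vantage points (as the spouse, and as an
uncle's/aunt's child) with a shared Overlay ID, and the builder fuses the
two records into one individual, closing the loop drawn with a double
relationship line.

Every built pedigree passes a structural validator (generation cap, twin
consistency, carrier exclusivity, custody/divorce coupling, acyclic descent,
…), gets deterministic I/II/III × 1..k numbering, a collision-free layout,
and a privacy-preserving render: names stay out of the SVG bytes unless
explicitly requested.

## Worked example

Write the built-in X-linked demo family (scenario `D`, a synthetic Duchenne
muscular dystrophy history), validate it and export PED rows:

```sh
$ ftree demo D -o out/
wrote D demo files to out/
$ ftree validate out/D.ftgc.json
0 error(s), 0 warning(s)
$ head -4 out/D.ped
scenario_D_(synthetic)  i1  0   0   1   1
scenario_D_(synthetic)  i2  i5  i6  2   1
scenario_D_(synthetic)  i3  i1  i2  1   2
scenario_D_(synthetic)  i4  i1  i2  2   1
```

The PED columns are family, individual, father, mother, sex (1 = male,
2 = female), affection (2 = affected with key 1, 1 = unaffected, 0 =
unknown): `i3` is the affected boy (sex 1, affection 2) whose parents are
`i1`/`i2`, and `i2` — the carrier mother — is herself a child of the
grandparental couple `i5`/`i6`. The same family from Python:

```python
>>> from ftree import build_pedigree, scenario_questionnaire
>>> p = build_pedigree(scenario_questionnaire("D"))
>>> for i in p.individuals.values():
...     print(i.label, i.sex.value, i.life_stage.value,
...           "affected" if i.affected else "carrier" if i.carrier else "")
II-1 male living
II-2 female living carrier
III-1 male living affected
III-2 female living
I-1 male living
I-2 female living carrier
II-3 male deceased affected
```

Affected males (the generation III proband, the deceased maternal uncle
II-3) connect through unaffected carrier females — the X-linked pattern.
`out/D.svg` is the chart; `ftree render out/D.ftgc.json -o chart.svg
--show-names` re-renders it with names included.

Other commands: `ftree sheet --no-child -o blank.csv` (blank interview
sheet), `ftree build sheet.csv -o fam.ftgc.json`, `ftree filename
fam.ftgc.json` (the automatic name built from the date stamp and the first
ten characters of each checked key), `ftree export-ped … --key 1`, and
global `--password`, `--config`, `--log-level`, `--seed` options.

## Layout of the repository

```
src/ftree/
  model.py          # graph types + structural validation
  questionnaire.py  # slot schema, JSON & CSV interview-sheet dialects
  builder.py        # questionnaire -> pedigree, overlay merge, numbering
  symbols.py        # nomenclature glyphs, shade palette, compliance matrix
  layout.py         # deterministic chart coordinates and line routing
  render.py         # SVG output, legend, privacy defaults
  docio.py          # document container, encryption, filenames, PED export
  fixtures.py       # named scenarios, random questionnaires, concordance
  cli.py            # the `ftree` command
docs/methods.md     # modelling and design notes
docs/questionnaire_format.md  # the file dialects, field by field
```
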