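# Questionnaire file dialects

Both dialects are versioned (`format_version: "1.0"`), round-trip
losslessly, and reject unknown fields, unknown slots, and out-of-range
values with errors naming the offending field and row.

## Relationship slots

The slot topology is fixed; the client-has-a-child branch only changes
display labels. Slot ids, cardinality and branch labels:

| slot id | cardinality | label (has child) | label (no child) |
|---|---|---|---|
| `his_parents` | couple | Husband's (his) parents | Paternal grandparents |
| `his_paternal_uncles_aunts` | repeated | His paternal uncles/aunts | Siblings of paternal grandfather |
| `his_maternal_uncles_aunts` | repeated | His maternal uncles/aunts | Siblings of paternal grandmother |
| `his_paternal_cousins` | repeated | Children of his paternal uncles/aunts | Children of siblings of paternal grandfather |
| `his_maternal_cousins` | repeated | Children of his maternal uncles/aunts | Children of siblings of paternal grandmother |
| `his_siblings` | repeated | His siblings | Paternal uncles/aunts |
| `his_divorced_partners` | repeated | His divorced partners | Divorced partners of father |
| `client` | single | Client (consultand) couple (husband) | Parents of client (father) |
| `spouse` | single | Client (consultand) couple (wife) | Parents of client (mother) |
| `child` | repeated | Children of client couple | Client (consultand) |
| `her_parents` | couple | Wife's (her) parents | Maternal grandparents |
| `her_paternal_uncles_aunts` | repeated | Her paternal uncles/aunts | Siblings of maternal grandfather |
| `her_maternal_uncles_aunts` | repeated | Her maternal uncles/aunts | Siblings of maternal grandmother |
| `her_paternal_cousins` | repeated | Children of her paternal uncles/aunts | Children of siblings of maternal grandfather |
| `her_maternal_cousins` | repeated | Children of her maternal uncles/aunts | Children of siblings of maternal grandmother |
| `her_siblings` | repeated | Her siblings | Maternal uncles/aunts |
| `her_divorced_partners` | repeated | Her divorced partners | Divorced partners of mother |

Repeated slots carry a 1-based birth-order `index` (at most 9 entries per
family). Couple slots hold two records (index 1 = father, 2 = mother).
Under the no-child branch, `child` index 1 is the client; further indexes
are the client's siblings. Cousin records name their parent uncle/aunt with
`parent_index`.

## Person-record fields

| field | values | notes |
|---|---|---|
| `name` | text | defaults to the relationship label; a name equal to the default is treated as unset |
| `age` | `null` (blank), `"?"` (unknown), integer 0–130 | |
| `sex` | `male`, `female`, `unknown`, `null` = slot default | |
| `general_status` | subset of `affected`, `presymptomatic_carrier`, `carrier`, `deceased` | `carrier` and `presymptomatic_carrier` are mutually exclusive |
| `condition_key_refs` | ≤ 4 integers in 1–4 | indices into key-table slots 1–4 |
| `infertility`, `no_children_by_choice` | booleans | union markers |
| `pregnancy` | boolean | the record *is* the fetus node |
| `fetal_status` | `none`, `SAB`, `affected_SAB`, `TOP`, `affected_TOP`, `stillbirth`, `ectopic` | |
| `gestational_age` | `null`, `"?"`, integer 0–45 (weeks) | |
| `multiple_gestation_id` | integer or `null` | equal ids within a sibship form a twin group |
| `monozygotic` | boolean | requires `multiple_gestation_id` |
| `custody_flag` | boolean | on a child of a divorced union: the central parent has custody |
| `multiple_individuals` | `1`, integer k ≥ 2, or `"n"` | the n-symbol node |
| `adoption` | `none`, `adopted_in`, `adopted_out` | |
| `donor_surrogate` | `none`, `donor`, `surrogate` | |
| `consanguinity_flag` | boolean | required when `overlay_id` is set |
| `overlay_id` | integer or `null` | exactly two records may share one id |
| `is_proband`, `is_consultand` | booleans | at most one proband per sheet |
| `history_unknown` | boolean | draws "?" above the symbol |
| `parent_index` | integer | cousin slots only |
| `of_divorced_partner`, `divorced_side` | integer + `his`/`her` | attaches a child to an ex-partner union |
| `show_below`, `remarks` | text | text under the symbol / annotations |

## JSON dialect

```json
{
  "format_version": "1.0",
  "client_has_child": true,
  "metadata": {"family_names": "...", "date_of_intake": "2017-07-14", "...": "..."},
  "key_table": [{"label": "cancer", "checked": true,
                 "show_below_symbol": false, "shade_index": 1}, "... 16 entries ..."],
  "records": {
    "client": [{"index": 1, "sex": "male", "age": 36, "...": "..."}],
    "child":  [{"index": 1, "sex": "male", "age": 6,
                "general_status": ["affected"], "condition_key_refs": [1],
                "is_proband": true}]
  }
}
```

Writing is deterministic (stable key order); `key_table` always has exactly
16 entries.

## CSV interview-sheet dialect

UTF-8, comma-separated, fixed header row (see `CSV_HEADER` in
`ftree.questionnaire`). Three section kinds in column 1:

* `meta` rows — `format_version`, `client_has_child`, and the metadata
  fields, one per row (`meta,<field>,,<value>`);
* `key` rows — the 16 key-table slots
  (`key,<slot>,,<label>,<checked>,<show_below_symbol>,<shade_index>`);
* `record` rows — one per person record, with booleans as `yes`/`no`,
  unknown age as `?`, blank values as empty cells, condition keys joined
  with `;`.

`ftree sheet -o blank.csv` writes a fully populated blank sheet (every
record at its defaults, names equal to relationship labels) ready for a
data-entry clerk to fill and feed to `ftree build`.
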