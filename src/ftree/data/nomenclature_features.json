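[
  {"id": "name_of_proband_consultand", "label": "Name of proband/consultand", "via_remarks": false},
  {"id": "family_names", "label": "Family names", "via_remarks": false},
  {"id": "historian", "label": "Historian", "via_remarks": true},
  {"id": "date_of_intake", "label": "Date of intake/update", "via_remarks": false},
  {"id": "reason_for_pedigree", "label": "Reason for taking pedigree", "via_remarks": true},
  {"id": "ancestry", "label": "Ancestry of both sides of the family", "via_remarks": false},
  {"id": "age", "label": "Age", "via_remarks": false},
  {"id": "generation_roman_numerals", "label": "Generation numbered with Roman numerals I, II, III", "via_remarks": false},
  {"id": "individual_numbered", "label": "Individual numbered 1, 2, 3", "via_remarks": false},
  {"id": "individual", "label": "Individual", "via_remarks": false},
  {"id": "affected_individual", "label": "Affected individual", "via_remarks": false},
  {"id": "affected_multiple_conditions", "label": "Affected individual (> one condition)", "via_remarks": false},
  {"id": "multiple_individuals_known", "label": "Multiple individuals, number known", "via_remarks": false},
  {"id": "multiple_individuals_unknown", "label": "Multiple individuals, number unknown", "via_remarks": false},
  {"id": "deceased_individual", "label": "Deceased individual", "via_remarks": false},
  {"id": "consultand", "label": "Consultand", "via_remarks": false},
  {"id": "proband", "label": "Proband", "via_remarks": false},
  {"id": "stillbirth", "label": "Stillbirth (SB)", "via_remarks": true},
  {"id": "pregnancy", "label": "Pregnancy (P)", "via_remarks": false},
  {"id": "spontaneous_abortion", "label": "Spontaneous abortion (SAB)", "via_remarks": false},
  {"id": "affected_sab", "label": "Affected SAB", "via_remarks": false},
  {"id": "termination_of_pregnancy", "label": "Termination of pregnancy (TOP)", "via_remarks": false},
  {"id": "affected_top", "label": "Affected TOP", "via_remarks": false},
  {"id": "ectopic_pregnancy", "label": "Ectopic pregnancy", "via_remarks": true},
  {"id": "relationship_line", "label": "Relationship line", "via_remarks": false},
  {"id": "break_in_relationship_line", "label": "A break in relationship line", "via_remarks": false},
  {"id": "divorced_partner", "label": "Divorced partner", "via_remarks": false},
  {"id": "consanguinity", "label": "Consanguinity", "via_remarks": false},
  {"id": "twins_monozygotic", "label": "Multiple gestation, monozygotic", "via_remarks": false},
  {"id": "twins_dizygotic", "label": "Multiple gestation, dizygotic", "via_remarks": false},
  {"id": "twins_unknown_zygosity", "label": "Multiple gestation, unknown", "via_remarks": true},
  {"id": "twins_trizygotic", "label": "Multiple gestation, trizygotic", "via_remarks": false},
  {"id": "family_history_unavailable", "label": "Family history not available/known for individual", "via_remarks": false},
  {"id": "no_children_by_choice", "label": "No children by choice or reason unknown", "via_remarks": false},
  {"id": "infertility", "label": "Infertility", "via_remarks": false},
  {"id": "adoption", "label": "Adoption", "via_remarks": false},
  {"id": "gamete_donor", "label": "Ovum or sperm donor", "via_remarks": false},
  {"id": "surrogate", "label": "Surrogate (gestational carrier)", "via_remarks": false},
  {"id": "evaluation", "label": "Evaluation (E)", "via_remarks": true},
  {"id": "carrier", "label": "Carrier", "via_remarks": false},
  {"id": "presymptomatic_carrier", "label": "Asymptomatic/presymptomatic carrier", "via_remarks": false},
  {"id": "uninformative_study", "label": "Uninformative study (Eu)", "via_remarks": true},
  {"id": "affected_with_positive_evaluation", "label": "Affected individual with positive evaluation (E+)", "via_remarks": true}
]
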