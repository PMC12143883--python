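# Statistical recipes: which table gets which test with which factors.
# Tables are long-format CSVs; new analyses are additions here, not code edits.
- name: photometry_day7_rm_anova
  table: photometry_day7
  test: rm_anova
  subject: subject
  within: level
  dv: value

- name: preference_two_way
  table: preference
  test: two_way_anova
  f1: virus
  f2: drug
  dv: value

- name: sbs_partner_kruskal
  table: sbs_partner
  test: kruskal
  by: group
  dv: value

- name: sepsc_frequency_t
  table: sepsc_frequency
  test: unpaired_t
  by: group
  levels: [control, cohabitation]
  dv: value
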