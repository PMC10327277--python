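# Default avoidable-cause map: a representative OECD/Eurostat-style list
# of ICD-10 ranges grouped into IHD / treatable & preventable /
# preventable / treatable, with report labels.  Rules are resolved in
# group-precedence order (IHD first), then file order within a group;
# 4-character codes match 3-character patterns by prefix.  Deaths at or
# above age_limit are non-avoidable regardless of cause.  Supply your own
# YAML/CSV with the same schema for a full-fidelity list.
age_limit: 75
rules:
  # --- ischaemic heart disease (treatable & preventable, analysed alone)
  - {pattern: I20-I25, group: IHD, label: "Ischemic heart disease (IHD)"}

  # --- treatable & preventable
  - {pattern: I60-I69, group: treatable_preventable, label: "Cerebrovascular diseases"}
  - {pattern: E10-E14, group: treatable_preventable, label: "Diabetes mellitus"}
  - {pattern: I10-I15, group: treatable_preventable, label: "Hypertensive diseases"}
  - {pattern: I00-I09, group: treatable_preventable, label: "Other causes"}

  # --- preventable
  - {pattern: F10, group: preventable, label: "Alcohol-related deaths"}
  - {pattern: K70, group: preventable, label: "Alcohol-related deaths"}
  - {pattern: X45, group: preventable, label: "Alcohol-related deaths"}
  - {pattern: F11-F16, group: preventable, label: "Drug-related deaths"}
  - {pattern: F18-F19, group: preventable, label: "Drug-related deaths"}
  - {pattern: X40-X44, group: preventable, label: "Drug-related deaths"}
  - {pattern: C00-C16, group: preventable, label: "Cancers (including lung cancer)"}
  - {pattern: C22, group: preventable, label: "Cancers (including lung cancer)"}
  - {pattern: C32-C34, group: preventable, label: "Cancers (including lung cancer)"}
  - {pattern: C43, group: preventable, label: "Cancers (including lung cancer)"}
  - {pattern: C67, group: preventable, label: "Cancers (including lung cancer)"}
  - {pattern: A33-A37, group: preventable, label: "Infectious diseases"}
  - {pattern: A80, group: preventable, label: "Infectious diseases"}
  - {pattern: B05-B06, group: preventable, label: "Infectious diseases"}
  - {pattern: B15-B19, group: preventable, label: "Infectious diseases"}
  - {pattern: B20-B24, group: preventable, label: "Infectious diseases"}
  - {pattern: J40-J44, group: preventable, label: "Diseases of the respiratory system"}
  - {pattern: Q86, group: preventable, label: "Other causes"}
  - {pattern: V01-Y89, group: preventable, label: "Injuries"}

  # --- treatable (amenable)
  - {pattern: C18-C21, group: treatable, label: "Cancer"}
  - {pattern: C50, group: treatable, label: "Cancer"}
  - {pattern: C53-C55, group: treatable, label: "Cancer"}
  - {pattern: C62, group: treatable, label: "Cancer"}
  - {pattern: C73, group: treatable, label: "Cancer"}
  - {pattern: C81, group: treatable, label: "Cancer"}
  - {pattern: C91-C95, group: treatable, label: "Cancer"}
  - {pattern: K25-K28, group: treatable, label: "Diseases of the digestive system"}
  - {pattern: K35-K38, group: treatable, label: "Diseases of the digestive system"}
  - {pattern: K40-K46, group: treatable, label: "Diseases of the digestive system"}
  - {pattern: K80-K83, group: treatable, label: "Diseases of the digestive system"}
  - {pattern: N00-N39, group: treatable, label: "Diseases of the genitourinary system"}
  - {pattern: A00-A09, group: treatable, label: "Infectious diseases"}
  - {pattern: A15-A19, group: treatable, label: "Infectious diseases"}
  - {pattern: A38-A49, group: treatable, label: "Infectious diseases"}
  - {pattern: G00-G03, group: treatable, label: "Infectious diseases"}
  - {pattern: O00-O99, group: treatable, label: "Pregnancy, childbirth and perinatal period"}
  - {pattern: P00-P96, group: treatable, label: "Pregnancy, childbirth and perinatal period"}
  - {pattern: J09-J18, group: treatable, label: "Diseases of the respiratory system"}
  - {pattern: J45-J46, group: treatable, label: "Diseases of the respiratory system"}
  - {pattern: E00-E07, group: treatable, label: "Other causes"}
  - {pattern: G40-G41, group: treatable, label: "Other causes"}
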