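# Default condition definitions: billing-code sets used to ascertain the
# five neonatal critical conditions from claims, with the postnatal
# ascertainment window in days. Codes are printed as in the source
# vocabularies (CPT with thousands separators, ICD-9 with dots); the
# loader normalizes them. The six CPT codes marked deleted were retired
# from the vocabulary on 2009-01-01 but remain in the set because claims
# from earlier years still carry them; valid_through is informational
# unless validity enforcement is switched on.
conditions:
  NICU:
    window_days: 30
    year_restriction: [2004, 2010]   # BC checkbox exists only on the post-2003 form
    use_mother_records: true
    codes:
      - {system: CPT, pattern: "99,295", valid_through: 2008-12-31}
      - {system: CPT, pattern: "99,296", valid_through: 2008-12-31}
      - {system: CPT, pattern: "99,297", valid_through: 2008-12-31}
      - {system: CPT, pattern: "99,298", valid_through: 2008-12-31}
      - {system: CPT, pattern: "99,299", valid_through: 2008-12-31}
      - {system: CPT, pattern: "99,300", valid_through: 2008-12-31}
      - {system: CPT, pattern: "99,468"}
      - {system: CPT, pattern: "99,469"}
      - {system: CPT, pattern: "99,477"}
      - {system: CPT, pattern: "99,478"}
      - {system: CPT, pattern: "99,479"}
      - {system: CPT, pattern: "99,480"}
  RDS:
    window_days: 30
    use_mother_records: true
    codes:
      - {system: ICD9_DX, pattern: "769.xx"}   # respiratory distress syndrome in newborn
  SEIZURE:
    window_days: 30
    use_mother_records: true
    codes:
      - {system: ICD9_DX, pattern: "779.0x"}   # convulsions in newborn
  AV:
    window_days: 30
    use_mother_records: true
    codes:
      - {system: ICD9_PC, pattern: "96.7"}     # other continuous invasive mechanical ventilation
      - {system: ICD9_PC, pattern: "96.70"}
      - {system: ICD9_PC, pattern: "96.71"}
      - {system: ICD9_PC, pattern: "96.72"}
      - {system: ICD9_PC, pattern: "93.90"}    # non-invasive mechanical ventilation
  BIRTH_INJURY:
    window_days: 30
    use_mother_records: true
    codes:
      - {system: ICD9_DX, pattern: "767.xx"}   # birth trauma
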