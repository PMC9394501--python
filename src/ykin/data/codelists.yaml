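# Coronary artery disease (CAD) classification code lists.
#
# ICD-10 ranges like "I21-I23" are expanded at load time; all codes are
# matched by prefix after dots are stripped, so "I21" covers I21.0, I21.9 etc.
#
# The `medications` section maps exclusion medication classes to product
# codes. These product codes are SYNTHETIC stand-ins (the real cohort's
# medication coding dictionary is not redistributable); the class names and
# the exclusion rule itself are the real algorithm.
cad:
  case:
    self_report: [heart_attack, myocardial_infarction]
    hospital_icd9: ["4109", "4129"]
    hospital_icd10: ["I21-I23", "I25.2"]
    operation_opcs: ["K49", "K50", "K75", "K40-K46"]
    death_icd10_primary_or_secondary:
      ["I20", "I21", "I24", "I25.1", "I25.2", "I25.5", "I25.8", "I25.9"]
  exclude:
    self_report: [angina]
    hospital_icd9: ["4139"]
    hospital_icd10: ["I20.0", "I20.1", "I20.8", "I20.9"]
    medication_classes:
      [aspirin, glyceryl_trinitrate, isosorbide_mononitrate,
       isosorbide_dinitrate, nicorandil]
medications:
  aspirin: ["SYN-ASP-075", "SYN-ASP-300"]
  glyceryl_trinitrate: ["SYN-GTN-400", "SYN-GTN-SPRAY"]
  isosorbide_mononitrate: ["SYN-ISMN-060"]
  isosorbide_dinitrate: ["SYN-ISDN-010"]
  nicorandil: ["SYN-NIC-020"]
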