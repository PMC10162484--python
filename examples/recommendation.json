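{
  "id": "covid19-dexamethasone",
  "title": "Dexamethasone for critically ill COVID-19 patients requiring oxygen supply",
  "version": "1.0",
  "valid_from": "2020-06-16",
  "population": {
    "operator": "ALL_OF",
    "members": [
      {
        "kind": "condition",
        "concept": {
          "system": "ICD10",
          "code": "U07.1",
          "display": "COVID-19"
        },
        "negated": false
      },
      {
        "kind": "procedure_active",
        "concept": {
          "system": "SNOMED",
          "code": "57485005",
          "display": "Oxygen therapy"
        },
        "negated": false
      }
    ],
    "negated": false
  },
  "intervention": {
    "operator": "ALL_OF",
    "members": [
      {
        "kind": "drug_administration",
        "concept": {
          "system": "ATC",
          "code": "H02AB02",
          "display": "Dexamethasone"
        },
        "dosage": {
          "dose": {
            "value": 1.0,
            "unit": {
              "system": "UCUM",
              "code": "mg"
            }
          },
          "frequency_per_day": 1,
          "duration_days": 10
        },
        "negated": false
      }
    ],
    "negated": false
  }
}
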