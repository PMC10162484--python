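{
  "$defs": {
    "ConceptCode": {
      "additionalProperties": false,
      "description": "A terminology-coded clinical concept, e.g. ``(ICD10, U07.1)``.",
      "properties": {
        "system": {
          "enum": [
            "ICD10",
            "SNOMED",
            "ATC",
            "LOINC",
            "UCUM"
          ],
          "title": "System",
          "type": "string"
        },
        "code": {
          "minLength": 1,
          "title": "Code",
          "type": "string"
        },
        "display": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Display"
        }
      },
      "required": [
        "system",
        "code"
      ],
      "title": "ConceptCode",
      "type": "object"
    },
    "Criterion": {
      "additionalProperties": false,
      "description": "A single terminology-coded clinical test.\n\n``kind`` selects the evaluation semantics:\n\n- ``condition``: a diagnosis interval covers the day;\n- ``drug_administration``: an administration occurred that day (or, with a\n  :class:`DosageSpec`, a conformant course covers the day);\n- ``observation``: the most recent observation satisfies ``comparator``\n  against ``threshold``;\n- ``procedure_active``: a procedure/therapy episode covers the day;\n- ``episode_attribute``: an encounter of the coded ward type covers the day.\n\n``negated`` flips the result after closed-world evaluation.",
      "properties": {
        "kind": {
          "enum": [
            "condition",
            "drug_administration",
            "observation",
            "procedure_active",
            "episode_attribute"
          ],
          "title": "Kind",
          "type": "string"
        },
        "concept": {
          "$ref": "#/$defs/ConceptCode"
        },
        "dosage": {
          "anyOf": [
            {
              "$ref": "#/$defs/DosageSpec"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "comparator": {
          "anyOf": [
            {
              "enum": [
                "<",
                "<=",
                "=",
                ">=",
                ">"
              ],
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Comparator"
        },
        "threshold": {
          "anyOf": [
            {
              "$ref": "#/$defs/Quantity"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "negated": {
          "default": false,
          "title": "Negated",
          "type": "boolean"
        }
      },
      "required": [
        "kind",
        "concept"
      ],
      "title": "Criterion",
      "type": "object"
    },
    "CriterionCombination": {
      "additionalProperties": false,
      "description": "A boolean grouping of criteria: ``ALL_OF`` (conjunction) or\n``ANY_OF`` (disjunction), optionally negated, with arbitrary nesting.",
      "properties": {
        "operator": {
          "enum": [
            "ALL_OF",
            "ANY_OF"
          ],
          "title": "Operator",
          "type": "string"
        },
        "members": {
          "items": {
            "anyOf": [
              {
                "$ref": "#/$defs/Criterion"
              },
              {
                "$ref": "#/$defs/CriterionCombination"
              }
            ]
          },
          "minItems": 1,
          "title": "Members",
          "type": "array"
        },
        "negated": {
          "default": false,
          "title": "Negated",
          "type": "boolean"
        }
      },
      "required": [
        "operator",
        "members"
      ],
      "title": "CriterionCombination",
      "type": "object"
    },
    "DosageSpec": {
      "additionalProperties": false,
      "description": "A dosing schedule: dose per administration, administrations per day,\nand course duration in days (or ``\"unbounded\"`` for open-ended therapy).",
      "properties": {
        "dose": {
          "$ref": "#/$defs/Quantity"
        },
        "frequency_per_day": {
          "minimum": 1,
          "title": "Frequency Per Day",
          "type": "integer"
        },
        "duration_days": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "const": "unbounded",
              "type": "string"
            }
          ],
          "default": "unbounded",
          "title": "Duration Days"
        }
      },
      "required": [
        "dose",
        "frequency_per_day"
      ],
      "title": "DosageSpec",
      "type": "object"
    },
    "Quantity": {
      "additionalProperties": false,
      "description": "A numeric value with a UCUM unit (drug dose, lab value, threshold).",
      "properties": {
        "value": {
          "title": "Value",
          "type": "number"
        },
        "unit": {
          "$ref": "#/$defs/ConceptCode"
        }
      },
      "required": [
        "value",
        "unit"
      ],
      "title": "Quantity",
      "type": "object"
    }
  },
  "description": "A versioned guideline recommendation: metadata plus the population\n(P) and intervention (I) criterion trees.",
  "properties": {
    "id": {
      "minLength": 1,
      "title": "Id",
      "type": "string"
    },
    "title": {
      "title": "Title",
      "type": "string"
    },
    "version": {
      "title": "Version",
      "type": "string"
    },
    "valid_from": {
      "format": "date",
      "title": "Valid From",
      "type": "string"
    },
    "population": {
      "$ref": "#/$defs/CriterionCombination"
    },
    "intervention": {
      "$ref": "#/$defs/CriterionCombination"
    }
  },
  "required": [
    "id",
    "title",
    "version",
    "valid_from",
    "population",
    "intervention"
  ],
  "title": "Recommendation",
  "type": "object"
}
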