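{
  "$defs": {
    "Category": {
      "description": "The five study case categories.",
      "enum": [
        "cat1_screen_recommended",
        "cat2_screen_not_recommended",
        "cat3_normal_followup",
        "cat4_elevated_psa",
        "cat5_other"
      ],
      "title": "Category",
      "type": "string"
    },
    "DREStatus": {
      "enum": [
        "not_done",
        "normal",
        "abnormal"
      ],
      "title": "DREStatus",
      "type": "string"
    },
    "PSAContext": {
      "enum": [
        "screening",
        "follow_up",
        "symptomatic"
      ],
      "title": "PSAContext",
      "type": "string"
    },
    "PSAReading": {
      "description": "One serum PSA measurement in ng/mL, ``months_ago`` before the consult.",
      "properties": {
        "context": {
          "anyOf": [
            {
              "$ref": "#/$defs/PSAContext"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "months_ago": {
          "minimum": 0,
          "title": "Months Ago",
          "type": "integer"
        },
        "value": {
          "description": "PSA concentration in ng/mL",
          "minimum": 0,
          "title": "Value",
          "type": "number"
        }
      },
      "required": [
        "value",
        "months_ago"
      ],
      "title": "PSAReading",
      "type": "object"
    },
    "Preference": {
      "enum": [
        "requests_screening",
        "declines",
        "unstated"
      ],
      "title": "Preference",
      "type": "string"
    },
    "RiskFactor": {
      "enum": [
        "family_history_prostate_ca",
        "brca_carrier",
        "african_ancestry"
      ],
      "title": "RiskFactor",
      "type": "string"
    }
  },
  "properties": {
    "active_uti": {
      "default": false,
      "title": "Active Uti",
      "type": "boolean"
    },
    "age": {
      "description": "age in years",
      "maximum": 120,
      "minimum": 18,
      "title": "Age",
      "type": "integer"
    },
    "case_id": {
      "title": "Case Id",
      "type": "string"
    },
    "category": {
      "anyOf": [
        {
          "$ref": "#/$defs/Category"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "comorbidities": {
      "default": [],
      "items": {
        "type": "string"
      },
      "title": "Comorbidities",
      "type": "array"
    },
    "dre": {
      "$ref": "#/$defs/DREStatus",
      "default": "not_done"
    },
    "free_text": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Free Text"
    },
    "hematuria": {
      "default": false,
      "title": "Hematuria",
      "type": "boolean"
    },
    "luts": {
      "default": false,
      "title": "Luts",
      "type": "boolean"
    },
    "preference": {
      "$ref": "#/$defs/Preference",
      "default": "unstated"
    },
    "psa_history": {
      "default": [],
      "items": {
        "$ref": "#/$defs/PSAReading"
      },
      "title": "Psa History",
      "type": "array"
    },
    "risk_factors": {
      "default": [],
      "items": {
        "$ref": "#/$defs/RiskFactor"
      },
      "title": "Risk Factors",
      "type": "array"
    }
  },
  "required": [
    "case_id",
    "age"
  ],
  "title": "CaseScenario",
  "type": "object"
}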