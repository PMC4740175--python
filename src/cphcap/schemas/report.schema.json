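{
 "$defs": {
  "ClassifierSummary": {
   "additionalProperties": false,
   "properties": {
    "panel": {
     "items": {
      "type": "string"
     },
     "title": "Panel",
     "type": "array"
    },
    "threshold": {
     "title": "Threshold",
     "type": "number"
    },
    "ldc_ci": {
     "items": {
      "type": "number"
     },
     "title": "Ldc Ci",
     "type": "array"
    },
    "hdc_ci": {
     "items": {
      "type": "number"
     },
     "title": "Hdc Ci",
     "type": "array"
    },
    "ci_overlap": {
     "title": "Ci Overlap",
     "type": "boolean"
    }
   },
   "required": [
    "panel",
    "threshold",
    "ldc_ci",
    "hdc_ci",
    "ci_overlap"
   ],
   "title": "ClassifierSummary",
   "type": "object"
  },
  "ResampleSummary": {
   "additionalProperties": false,
   "properties": {
    "observed": {
     "title": "Observed",
     "type": "number"
    },
    "n_draws": {
     "title": "N Draws",
     "type": "integer"
    },
    "p_empirical": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "P Empirical"
    },
    "max_abs_null": {
     "title": "Max Abs Null",
     "type": "number"
    },
    "quantiles": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Quantiles",
     "type": "object"
    },
    "exhaustive": {
     "title": "Exhaustive",
     "type": "boolean"
    },
    "seed": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "title": "Seed"
    }
   },
   "required": [
    "observed",
    "n_draws",
    "p_empirical",
    "max_abs_null",
    "quantiles",
    "exhaustive",
    "seed"
   ],
   "title": "ResampleSummary",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "Top-level report bundle; stage sections are optional.",
 "properties": {
  "config": {
   "additionalProperties": true,
   "title": "Config",
   "type": "object"
  },
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "version": {
   "title": "Version",
   "type": "string"
  },
  "qc": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Qc"
  },
  "mvp": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Mvp"
  },
  "delta": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Delta"
  },
  "memory": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Memory"
  },
  "motif": {
   "anyOf": [
    {
     "items": {
      "additionalProperties": true,
      "type": "object"
     },
     "type": "array"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Motif"
  },
  "resampling": {
   "anyOf": [
    {
     "additionalProperties": {
      "anyOf": [
       {
        "$ref": "#/$defs/ResampleSummary"
       },
       {
        "type": "null"
       }
      ]
     },
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Resampling"
  },
  "classifier": {
   "anyOf": [
    {
     "$ref": "#/$defs/ClassifierSummary"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "predictions": {
   "anyOf": [
    {
     "items": {
      "additionalProperties": true,
      "type": "object"
     },
     "type": "array"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Predictions"
  },
  "evaluation": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Evaluation"
  },
  "clustering": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Clustering"
  },
  "corridor": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Corridor"
  }
 },
 "required": [
  "config",
  "seed",
  "version"
 ],
 "title": "ReportSchema",
 "type": "object"
}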