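{
  "additionalProperties": false,
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "stages": {
      "additionalProperties": true,
      "title": "Stages",
      "type": "object"
    },
    "wall_time_s": {
      "title": "Wall Time S",
      "type": "number"
    }
  },
  "required": [
    "config",
    "stages",
    "wall_time_s"
  ],
  "title": "_ReportModel",
  "type": "object"
}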