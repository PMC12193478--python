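{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "gaitvar keypoint trial",
  "description": "One walking trial as an ordered stream of 17-keypoint pose frames. Keypoint 15 is the left foot, 16 the right foot. Coordinates are pixels (origin top-left, y downward); confidences lie in [0, 1]. Frames may use the canonical object layout or a flat 51-float layout.",
  "type": "object",
  "required": ["frames"],
  "properties": {
    "subject_id": {"type": "string"},
    "trial_id": {"type": "string"},
    "frames": {
      "type": "array",
      "items": {
        "oneOf": [
          {
            "type": "object",
            "required": ["keypoints"],
            "properties": {
              "keypoints": {
                "type": "array",
                "minItems": 17,
                "maxItems": 17,
                "items": {
                  "oneOf": [
                    {
                      "type": "array",
                      "minItems": 3,
                      "maxItems": 3,
                      "items": {"type": "number"}
                    },
                    {"type": "null"}
                  ]
                }
              }
            }
          },
          {
            "type": "array",
            "minItems": 51,
            "maxItems": 51,
            "items": {"type": "number"}
          }
        ]
      }
    }
  }
}
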