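{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "cellflows visualization spec",
 "description": "Serialized multi-resolution cluster-flow graph with precomputed overlays. Structural constraints beyond this document (link endpoints exist among nodes, paint names registered under overlays.flow) are enforced by cellflows.export.validate_spec.",
 "type": "object",
 "required": ["schema_version", "n_cells", "resolutions", "nodes", "links", "ternary", "overlays"],
 "properties": {
  "schema_version": {"const": "1.0"},
  "n_cells": {"type": "integer", "minimum": 1},
  "resolutions": {"type": "array", "items": {"type": "string"}, "minItems": 2},
  "nodes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "resolution", "label", "size", "x", "y", "height", "hover"],
    "properties": {
     "id": {"type": "string", "pattern": "^.+_[0-9]+$"},
     "resolution": {"type": "string"},
     "label": {"type": "integer", "minimum": 0},
     "size": {"type": "integer", "minimum": 1},
     "x": {"type": "number", "minimum": 0, "maximum": 1},
     "y": {"type": "number", "minimum": 0},
     "height": {"type": "number", "minimum": 0},
     "hover": {"type": "object"},
     "stable_path": {"type": "integer", "minimum": 0}
    }
   }
  },
  "links": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["source", "target", "count", "forward_prop", "backward_prop", "paint"],
    "properties": {
     "source": {"type": "string"},
     "target": {"type": "string"},
     "count": {"type": "integer", "minimum": 1},
     "forward_prop": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
     "backward_prop": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
     "paint": {"type": "object"}
    }
   }
  },
  "ternary": {
   "type": "object",
   "required": ["axes", "points"],
   "properties": {
    "axes": {"type": "array", "items": {"type": "string"}, "maxItems": 3},
    "points": {
     "type": "array",
     "items": {
      "type": "object",
      "required": ["source", "target", "gep", "count", "size", "color"],
      "properties": {
       "gep": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}, "minItems": 3, "maxItems": 3},
       "count": {"type": "integer", "minimum": 1},
       "size": {"type": "number", "minimum": 0},
       "color": {"type": "string", "pattern": "^#[0-9A-F]{6}$"}
      }
     }
    }
   }
  },
  "overlays": {
   "type": "object",
   "required": ["flow", "node", "neutral"],
   "properties": {
    "flow": {"type": "array", "items": {"type": "string"}},
    "node": {"type": "array", "items": {"type": "string"}},
    "neutral": {"type": "string", "pattern": "^#[0-9A-F]{6}$"}
   }
  }
 }
}
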