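{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "treecohort/cohort.schema.json",
 "title": "Mutation-tree cohort",
 "description": "Canonical interchange format for tumor mutation-tree cohorts: named trees with per-node event dictionaries, optional matching labels and subclone sizes, optional clusters, pairwise distances and clinical annotations. Reference document; the package validator additionally enforces the cross-field invariants listed in each description.",
 "type": "object",
 "required": ["trees"],
 "properties": {
  "trees": {
   "type": "object",
   "minProperties": 1,
   "additionalProperties": {
    "type": "object",
    "required": ["nodes"],
    "properties": {
     "nodes": {
      "type": "array",
      "minItems": 1,
      "description": "Flat node list; exactly one node omits parent_id (the event-free germline root). Nested form with 'children' arrays is accepted on read and normalized.",
      "items": {
       "type": "object",
       "required": ["node_id", "events"],
       "properties": {
        "node_id": {"type": "string", "minLength": 1},
        "parent_id": {"type": "string", "minLength": 1},
        "events": {
         "type": "object",
         "description": "event_type -> gene symbol -> detail. snv details are variant strings; amp/del details are integer copy-number offsets >= 1 w.r.t. diploid. Gene mappings must be non-empty.",
         "additionalProperties": {
          "type": "object",
          "minProperties": 1,
          "additionalProperties": {"type": ["string", "integer"]}
         }
        },
        "matching_label": {"type": "string"},
        "size": {
         "type": "number",
         "minimum": 0,
         "description": "Relative subclone cell-population size; present on all non-root nodes or none."
        }
       }
      }
     },
     "clinical": {"type": "object"}
    }
   }
  },
  "clusters": {
   "type": "array",
   "description": "Disjoint groups of sample_ids, each present in trees.",
   "items": {"type": "array", "items": {"type": "string"}}
  },
  "distances": {
   "type": "object",
   "required": ["sample_ids", "matrix"],
   "description": "Symmetric zero-diagonal matrix over exactly the tree sample_ids.",
   "properties": {
    "sample_ids": {"type": "array", "items": {"type": "string"}},
    "matrix": {
     "type": "array",
     "items": {"type": "array", "items": {"type": "number", "minimum": 0}}
    }
   }
  }
 }
}
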