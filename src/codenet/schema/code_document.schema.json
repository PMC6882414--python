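{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "codenet canonical code-document dialect",
  "type": "object",
  "required": ["dialect", "version", "articles"],
  "properties": {
    "dialect": {"const": "codenet-document"},
    "version": {"const": 1},
    "metadata": {
      "type": "object",
      "properties": {
        "edition": {"type": "string"},
        "amendments": {"type": "array", "items": {"type": "string"}},
        "chapters": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["num", "first_article", "last_article"],
            "properties": {
              "num": {"type": "integer", "minimum": 1},
              "title": {"type": "string"},
              "first_article": {"type": "integer", "minimum": 1},
              "last_article": {"type": "integer", "minimum": 1}
            }
          }
        }
      }
    },
    "preamble": {
      "type": "object",
      "properties": {"title": {"type": "string"}, "body": {"type": "string"}}
    },
    "articles": {"type": "array", "items": {"$ref": "#/$defs/provision"}},
    "glossary": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["term"],
        "properties": {
          "term": {"type": "string", "minLength": 1},
          "definition": {"type": "string"},
          "variants": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "appendices": {
      "type": "array",
      "items": {
        "type": "object",
        "properties": {"title": {"type": "string"}, "body": {"type": "string"}}
      }
    }
  },
  "$defs": {
    "provision": {
      "type": "object",
      "required": ["kind"],
      "properties": {
        "kind": {"enum": ["article", "subarticle", "recommendation", "example"]},
        "num": {"type": "integer", "minimum": 1},
        "letter": {"type": "string", "pattern": "^[A-Z]+$"},
        "ordinal": {"type": "integer", "minimum": 1},
        "title": {"type": "string"},
        "body": {"type": "string"},
        "children": {"type": "array", "items": {"$ref": "#/$defs/provision"}}
      },
      "allOf": [
        {
          "if": {"properties": {"kind": {"enum": ["article", "subarticle"]}}},
          "then": {"required": ["num"]}
        },
        {
          "if": {"properties": {"kind": {"const": "recommendation"}}},
          "then": {"required": ["letter"]}
        }
      ]
    }
  }
}
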