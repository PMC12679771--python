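"""Canonical JSON byte writer shared by the serializer and the test oracle.

The output contract: UTF-8, 2-space indentation, LF line endings, no
trailing whitespace, key order taken from the input mapping (the caller is
responsible for building the tree in FHIR definition order), and a single
trailing newline.  Deterministic for equal input trees.
"""

from __future__ import annotations

import json
from typing import Any


def canonical_json_bytes(tree: dict[str, Any]) -> bytes:
    text = json.dumps(tree, ensure_ascii=False, indent=2, separators=(",", ": "))
    return (text + "\n").encode("utf-8")
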