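"""Deterministic content-derived identifiers for name-strings.

A version-5 UUID is the SHA-1 of the name-string's UTF-8 bytes in a fixed
namespace — the DNS namespace entry for ``globalnames.org`` — so any
party, anywhere, mints bit-identical identifiers for identical strings
without a registry.  The string is hashed raw (after NFC normalization
only): no trimming, case folding or canonicalization, because the
identifier must distinguish lookalikes — ``Homo sapiens`` with a Cyrillic
'а' is a different string and gets a different identifier.
"""

from __future__ import annotations

import unicodedata
import uuid

#: uuid5(NAMESPACE_DNS, "globalnames.org")
GN_NAMESPACE = uuid.uuid5(uuid.NAMESPACE_DNS, "globalnames.org")


def gn_uuid(name: str) -> str:
    """Mint the version-5 identifier of *name*; empty input is an error."""
    if not name:
        raise ValueError("cannot mint an identifier for an empty name-string")
    normalized = unicodedata.normalize("NFC", name)
    return str(uuid.uuid5(GN_NAMESPACE, normalized))
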