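"""Shared string normalization used by matching, indexing and dedupe."""
from __future__ import annotations

import re

# Trademark/registration glyphs appear in product names ("FluMist ®") but
# carry no lexical content; they are stripped before any comparison.
_TM_RE = re.compile(r"[®™]")
_WS_RE = re.compile(r"\s+")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def collapse_ws(text: str) -> str:
    """Collapse runs of whitespace to single spaces and trim the ends."""
    return _WS_RE.sub(" ", text).strip()


def fold(text: str) -> str:
    """Canonical comparison form: strip ®/™, Unicode-casefold, collapse whitespace."""
    return collapse_ws(_TM_RE.sub(" ", text).casefold())


def tokens(text: str) -> list[str]:
    """Alphanumeric tokens of *text* (punctuation-insensitive)."""
    return _TOKEN_RE.findall(text)
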