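"""Strict numeric token parsing shared by the dialect readers.

Accepts plain and scientific notation with '.' as the only decimal
separator; anything else (including locale commas or underscores,
which Python's ``float`` would let through) is a parse error.
"""

from __future__ import annotations

import re

from ..errors import ParseError

_NUM_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?\Z")


def parse_float(token: str, context: str = "") -> float:
    if not _NUM_RE.match(token):
        where = f" in {context}" if context else ""
        raise ParseError(f"non-numeric token {token!r}{where}")
    return float(token)


def is_float(token: str) -> bool:
    return bool(_NUM_RE.match(token))


def fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    return repr(float(x))
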