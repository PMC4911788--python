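"""Low-level text helpers shared across modules."""

from __future__ import annotations

import re

_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def canonicalize(name: str) -> str:
    """Canonical dictionary-lookup key for a surface name.

    Case-folded, punctuation replaced by spaces, whitespace collapsed.
    Plural stripping is deliberately not applied.
    """
    s = _PUNCT_RE.sub(" ", name.casefold())
    return _WS_RE.sub(" ", s).strip()


def token_dice(a: str, b: str) -> float:
    """Dice coefficient between the canonical token sets of two names."""
    ta, tb = set(canonicalize(a).split()), set(canonicalize(b).split())
    ta.discard("")
    tb.discard("")
    if not ta and not tb:
        return 0.0
    return 2.0 * len(ta & tb) / (len(ta) + len(tb))
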