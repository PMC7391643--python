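"""A PROSITE-syntax motif scanner.

Supports residue literals, classes ``[..]``, negated classes ``{..}``, the
wildcard ``x``, repeat counts ``(n)`` and ranges ``(n,m)``, and the ``<``/``>``
terminal anchors. Matching follows the semantics of the equivalent regular
expression with greedy quantifiers: for every start position the longest
match is reported, so overlapping occurrences at distinct starts all appear.

The matcher itself is a backtracking interpreter over the parsed elements;
it deliberately does not go through :mod:`re`, so regex translation can act
as an independent oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .errors import PatternSyntaxError

_AA = "ACDEFGHIKLMNPQRSTVWY"

_TOKEN_RE = re.compile(
    r"^(?:(?P<any>[xX])|(?P<lit>[A-Wa-wyzYZ])|\[(?P<cls>[A-Z]+)\]|\{(?P<neg>[A-Z]+)\})"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)


@dataclass(frozen=True)
class Element:
    allowed: frozenset  # residues accepted at this position
    min_rep: int
    max_rep: int


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str
    elements: Tuple[Element, ...]
    anchored_n: bool = False
    anchored_c: bool = False


def parse_prosite(name: str, pattern: str) -> MotifPattern:
    """Parse a PROSITE-syntax pattern string into a :class:`MotifPattern`."""
    text = pattern.strip()
    if text.endswith("."):
        text = text[:-1]
    if not text:
        raise PatternSyntaxError(f"{name}: empty pattern", 0)
    anchored_n = anchored_c = False
    if text.startswith("<"):
        anchored_n = True
        text = text[1:]
    if text.endswith(">"):
        anchored_c = True
        text = text[:-1]
    elements: List[Element] = []
    pos = 0
    for token in text.split("-"):
        if not token:
            raise PatternSyntaxError(f"{name}: empty element at offset {pos}", pos)
        m = _TOKEN_RE.match(token)
        if m is None:
            raise PatternSyntaxError(
                f"{name}: cannot parse element {token!r} at offset {pos}", pos
            )
        if m.group("any"):
            allowed = frozenset(_AA)
        elif m.group("lit"):
            allowed = frozenset(m.group("lit").upper())
        elif m.group("cls"):
            allowed = frozenset(m.group("cls"))
        else:
            allowed = frozenset(_AA) - frozenset(m.group("neg"))
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        if lo > hi or lo < 0:
            raise PatternSyntaxError(
                f"{name}: bad repeat ({lo},{hi}) at offset {pos}", pos
            )
        elements.append(Element(allowed, lo, hi))
        pos += len(token) + 1
    if not elements:
        raise PatternSyntaxError(f"{name}: pattern has no positions", 0)
    return MotifPattern(name, pattern, tuple(elements), anchored_n, anchored_c)


def _match_from(p: MotifPattern, s: str, idx: int, pos: int) -> Optional[int]:
    """Greedy-regex-equivalent match of elements[idx:] at ``pos``; returns end."""
    if idx == len(p.elements):
        if p.anchored_c and pos != len(s):
            return None
        return pos
    e = p.elements[idx]
    # feasibility: longest run of allowed residues from pos
    run = 0
    while run < e.max_rep and pos + run < len(s) and s[pos + run] in e.allowed:
        run += 1
    for r in range(run, e.min_rep - 1, -1):  # greedy: longest first
        end = _match_from(p, s, idx + 1, pos + r)
        if end is not None:
            return end
    return None


def scan_pattern(p: MotifPattern, seq) -> List[Tuple[int, int]]:
    """All matches of ``p`` in ``seq`` as (start, end) pairs, ascending starts.

    ``seq`` may be a string or anything with a ``.seq`` attribute. At each
    start position the greedy (longest-first backtracking) match is reported.
    """
    s = seq if isinstance(seq, str) else seq.seq
    if not s:
        raise ValueError("cannot scan an empty sequence")
    starts = [0] if p.anchored_n else range(len(s))
    out = []
    for start in starts:
        end = _match_from(p, s, 0, start)
        if end is not None:
            out.append((start, end))
    return out


def to_regex(p: MotifPattern) -> str:
    """Translate a parsed pattern to a Python regex (diagnostic helper)."""
    parts = []
    if p.anchored_n:
        parts.append("^")
    for e in p.elements:
        if len(e.allowed) == 1:
            atom = next(iter(e.allowed))
        else:
            atom = "[" + "".join(sorted(e.allowed)) + "]"
        if (e.min_rep, e.max_rep) == (1, 1):
            parts.append(atom)
        elif e.min_rep == e.max_rep:
            parts.append(f"{atom}{{{e.min_rep}}}")
        else:
            parts.append(f"{atom}{{{e.min_rep},{e.max_rep}}}")
    if p.anchored_c:
        parts.append("$")
    return "".join(parts)
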