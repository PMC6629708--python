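"""Codec for diagnostic-character strings.

Four dialects are supported, matching how molecular diagnoses are printed:

* nuclear derived          ``aly728.44.1:G672C``
  -- position 672 of exon 1, gene 44, scaffold 728 is C, changed from
  ancestral G;
* nuclear retained         ``aly5294.20.2:A548A (not C)``
  -- the diagnosed taxon keeps ancestral A where its sister clade changed
  to C;
* unknown ancestor         ``169A``
  -- the position carries A but the ancestral state cannot be polarised;
* COI barcode              ``A79T`` or ``59C``
  -- positions in the standard 658-bp COI barcode region, written without a
  ``scaffold.gene.exon:`` prefix.

``parse`` and ``render`` are exact inverses on all well-formed inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .alignio import COI_BARCODE_LENGTH, LocusRef

BASES = frozenset("ACGT")

KIND_DERIVED = "derived"
KIND_RETAINED_NOT = "retained_not"
KIND_STATE_ONLY = "state_only"
KINDS = (KIND_DERIVED, KIND_RETAINED_NOT, KIND_STATE_ONLY)


class NotationError(ValueError):
    """Malformed character string; carries the offset where parsing failed."""

    def __init__(self, message: str, text: str, offset: int):
        super().__init__(f"{message} in {text!r} at offset {offset}")
        self.text = text
        self.offset = offset


@dataclass(frozen=True)
class DiagnosticCharacter:
    """One diagnostic alignment position.

    ``locus`` is a :class:`LocusRef` for nuclear/Z/mito exon positions, or
    ``None`` for positions in the COI barcode coordinate frame.  For
    ``derived`` characters ``derived`` is the clade's state and ``ancestral``
    the outgroup state; for ``retained_not`` the clade keeps ``ancestral``
    and ``derived`` holds the state the sister clade changed to (the excluded
    state); for ``state_only`` the ancestor is unknown and ``derived`` holds
    the observed state.
    """

    locus: LocusRef | None
    position: int
    kind: str
    ancestral: str | None
    derived: str
    missing_count: int = 0
    min_coverage: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if self.locus is None and self.position > COI_BARCODE_LENGTH:
            raise ValueError(
                f"barcode position {self.position} > {COI_BARCODE_LENGTH}"
            )
        if self.derived not in BASES:
            raise ValueError(f"state {self.derived!r} not in ACGT")
        if self.kind == KIND_DERIVED:
            if self.ancestral not in BASES or self.ancestral == self.derived:
                raise ValueError("derived character needs ancestral != derived, both ACGT")
        elif self.kind == KIND_RETAINED_NOT:
            if self.ancestral not in BASES or self.ancestral == self.derived:
                raise ValueError("retained_not needs ancestral != excluded state, both ACGT")
        elif self.ancestral is not None:
            raise ValueError("state_only character has unknown (None) ancestor")
        if self.missing_count < 0:
            raise ValueError("missing_count must be >= 0")

    @property
    def is_barcode(self) -> bool:
        return self.locus is None

    def identity(self) -> tuple:
        """Location + states, ignoring ranking metadata."""
        return (self.locus, self.position, self.kind, self.ancestral, self.derived)


def render(ch: DiagnosticCharacter) -> str:
    """Render a character in its printed dialect."""
    if ch.kind == KIND_DERIVED:
        body = f"{ch.ancestral}{ch.position}{ch.derived}"
    elif ch.kind == KIND_RETAINED_NOT:
        body = f"{ch.ancestral}{ch.position}{ch.ancestral} (not {ch.derived})"
    else:
        body = f"{ch.position}{ch.derived}"
    if ch.locus is None:
        return body
    return f"{ch.locus}:{body}"


_PREFIX_RE = re.compile(r"^([a-z]+)(\d+)\.(\d+)\.(\d+):")
_BODY_FULL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])(?:\s*\(\s*not\s+([A-Z])\s*\))?$")
_BODY_BARE_RE = re.compile(r"^(\d+)([A-Z])$")


def parse(text: str) -> DiagnosticCharacter:
    """Parse one character string; inverse of :func:`render`.

    Whitespace around the ``(not X)`` clause is tolerated on input; rendering
    always reproduces the canonical single-space form.
    """
    s = text.strip()
    if not s:
        raise NotationError("empty character string", text, 0)
    locus: LocusRef | None = None
    body = s
    body_off = 0
    m = _PREFIX_RE.match(s)
    if m is not None:
        locus = LocusRef(m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4)))
        body = s[m.end():]
        body_off = m.end()
    elif ":" in s:
        raise NotationError("malformed scaffold.gene.exon prefix", text, s.index(":"))

    bare = _BODY_BARE_RE.match(body)
    if bare is not None:
        pos, state = int(bare.group(1)), bare.group(2)
        if state not in BASES:
            raise NotationError(f"state {state!r} not a nucleotide", text, body_off + len(bare.group(1)))
        try:
            return DiagnosticCharacter(locus, pos, KIND_STATE_ONLY, None, state)
        except ValueError as exc:
            raise NotationError(str(exc), text, body_off) from None

    full = _BODY_FULL_RE.match(body)
    if full is None:
        raise NotationError("unrecognised character dialect", text, body_off)
    anc, pos, obs, excluded = full.group(1), int(full.group(2)), full.group(3), full.group(4)
    for state, off in ((anc, 0), (obs, len(full.group(1)) + len(full.group(2)))):
        if state not in BASES:
            raise NotationError(f"state {state!r} not a nucleotide", text, body_off + off)
    try:
        if excluded is not None:
            if obs != anc:
                raise NotationError(
                    "retained character must repeat the ancestral state", text, body_off
                )
            if excluded not in BASES:
                raise NotationError(f"state {excluded!r} not a nucleotide", text, body_off)
            return DiagnosticCharacter(locus, pos, KIND_RETAINED_NOT, anc, excluded)
        if anc == obs:
            raise NotationError(
                "ancestral and derived states are equal (missing '(not X)'?)", text, body_off
            )
        return DiagnosticCharacter(locus, pos, KIND_DERIVED, anc, obs)
    except NotationError:
        raise
    except ValueError as exc:
        raise NotationError(str(exc), text, body_off) from None


_SPLIT_RE = re.compile(r",|\band\b")


def parse_diagnosis_list(text: str) -> list[DiagnosticCharacter]:
    """Parse a printed diagnosis list: comma- and/or 'and'-separated character
    strings, tolerating the Oxford comma and a trailing period."""
    items = [item.strip() for item in _SPLIT_RE.split(text.strip().rstrip("."))]
    items = [item for item in items if item]
    out = []
    for idx, item in enumerate(items):
        try:
            out.append(parse(item))
        except NotationError as exc:
            raise NotationError(
                f"item {idx + 1} of diagnosis list unparseable ({exc.args[0]})", item, exc.offset
            ) from None
    return out


def render_list(chars: list[DiagnosticCharacter], sep: str = ", ") -> str:
    return sep.join(render(ch) for ch in chars)
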