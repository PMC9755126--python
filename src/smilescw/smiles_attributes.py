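"""SMILES tokenization and extraction of local/global SMILES attributes.

The optimal-descriptor method works directly on the SMILES string: it is
first cut into "SMILES atoms" (bracket groups ``[...]``, the two-character
halogens ``Cl``/``Br``, ``%nn`` ring labels, and otherwise single
characters), and from the token stream two families of attributes are read:

* **local** attributes: every window of three consecutive tokens (SSS),
  canonicalized so that a window and its reversal share one key
  (``c…c…c…`` style keys);
* **global** attributes: presence patterns for heteroatoms (NOSP),
  halogens (HALO), bond symbols (BOND), their combinations (PAIR, HARD),
  the ring count (``Cmax.k``) and the nitrogen/oxygen totals
  (``Nmax.k`` / ``Omax.k``).

No chemistry perception is involved: rings are counted as matched
ring-closure label pairs and aromaticity is just lowercase, exactly as the
string-based method defines them.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "SmilesParseError",
    "TokenSequence",
    "AttributeProfile",
    "tokenize",
    "extract_local_triples",
    "extract_globals",
    "build_profile",
    "profile_dataset",
    "canonical_key",
    "SEP",
]

SEP = "…"  # "…", the separator used in attribute keys

_BRACKET_ELEMENT = re.compile(r"\[(?:\d+)?([A-Za-z][a-z]?)")


class SmilesParseError(ValueError):
    """Raised when a SMILES string violates the token grammar."""


@dataclass(frozen=True)
class TokenSequence:
    """Ordered SMILES atoms plus the source string they came from."""

    tokens: tuple[str, ...]
    source: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.tokens)

    def rejoin(self) -> str:
        """Concatenate tokens back into the original string."""
        return "".join(self.tokens)


@dataclass(frozen=True)
class AttributeProfile:
    """Attribute content of one molecule.

    ``local`` maps canonical three-token keys (and, optionally, one- and
    two-token keys) to their occurrence counts; ``globals_`` is the set of
    global presence-pattern keys, each of which occurs exactly once.
    """

    local: Mapping[str, int]
    globals_: frozenset[str]
    n_tokens: int = 0

    def all_keys(self) -> set[str]:
        return set(self.local) | set(self.globals_)


def tokenize(smiles: str) -> TokenSequence:
    """Cut a SMILES string into SMILES atoms.

    Bracket groups, ``Cl``/``Br`` and ``%nn`` ring labels are single
    tokens; every other character is its own token. Unbalanced brackets or
    parentheses and unclosed ring labels raise :class:`SmilesParseError`
    with the offending position.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    depth = 0
    open_rings: dict[str, int] = {}
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise SmilesParseError(f"unclosed '[' at position {i}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
            continue
        if ch == "]":
            raise SmilesParseError(f"unmatched ']' at position {i}")
        if ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesParseError(f"'%' not followed by two digits at position {i}")
            label = smiles[i : i + 3]
            _toggle_ring(open_rings, label, i)
            tokens.append(label)
            i += 3
            continue
        if ch in ("C", "B") and i + 1 < n and smiles[i : i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i : i + 2])
            i += 2
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SmilesParseError(f"unmatched ')' at position {i}")
        elif ch.isdigit():
            _toggle_ring(open_rings, ch, i)
        tokens.append(ch)
        i += 1
    if depth != 0:
        raise SmilesParseError("unclosed branch '(' in SMILES")
    if open_rings:
        label, pos = next(iter(open_rings.items()))
        raise SmilesParseError(f"unclosed ring label {label!r} opened at position {pos}")
    return TokenSequence(tokens=tuple(tokens), source=smiles)


def _toggle_ring(open_rings: dict[str, int], label: str, pos: int) -> None:
    if label in open_rings:
        del open_rings[label]
    else:
        open_rings[label] = pos


def canonical_key(window: Iterable[str]) -> str:
    """Canonical key for a token window: reversal-invariant.

    The first and last tokens are compared lexicographically; if the last
    sorts before the first, the window is reversed, so ``(a,b,c)`` and
    ``(c,b,a)`` map to the same key.
    """
    w = tuple(window)
    if w and w[-1] < w[0]:
        w = w[::-1]
    return "".join(t + SEP for t in w)


def extract_local_triples(seq: TokenSequence, order: int = 3) -> Counter[str]:
    """Multiset of canonical keys over every window of ``order`` tokens."""
    toks = seq.tokens
    out: Counter[str] = Counter()
    for i in range(len(toks) - order + 1):
        out[canonical_key(toks[i : i + order])] += 1
    return out


def _element_tokens(seq: TokenSequence) -> list[str]:
    """Element symbol of each token that denotes an atom ('' otherwise)."""
    out = []
    for t in seq.tokens:
        if t.startswith("["):
            m = _BRACKET_ELEMENT.match(t)
            out.append(m.group(1) if m else "")
        elif t in ("Cl", "Br") or (t.isalpha() and len(t) == 1):
            out.append(t)
        else:
            out.append("")
    return out


def extract_globals(seq: TokenSequence) -> frozenset[str]:
    """Global attribute keys of one molecule.

    Emits exactly one key for each of NOSP, HALO, BOND, PAIR and HARD
    presence patterns plus ``Cmax.k`` (matched ring-closure pairs),
    ``Nmax.k`` and ``Omax.k`` (nitrogen/oxygen totals, aromatic and
    bracketed forms included). Distinct presence patterns map to distinct
    keys; the encoding itself is a fixed-format string.
    """
    elements = _element_tokens(seq)
    upper = {e.upper() for e in elements if e}

    def flag(symbol: str) -> str:
        return "+" if symbol in upper else "-"

    nosp = f"N{flag('N')}O{flag('O')}S{flag('S')}P{flag('P')}"
    halo = f"F{flag('F')}Cl{flag('CL')}Br{flag('BR')}"
    joined = seq.source
    bond = (
        f"={'+' if '=' in joined else '-'}"
        f"#{'+' if '#' in joined else '-'}"
        f"@{'+' if '@' in joined else '-'}"
    )

    ring_pairs = 0
    open_rings: set[str] = set()
    for t in seq.tokens:
        if t.isdigit() or t.startswith("%"):
            if t in open_rings:
                open_rings.discard(t)
                ring_pairs += 1
            else:
                open_rings.add(t)

    nmax = sum(1 for e in elements if e in ("N", "n"))
    omax = sum(1 for e in elements if e in ("O", "o"))

    return frozenset(
        {
            f"NOSP:{nosp}",
            f"HALO:{halo}",
            f"BOND:{bond}",
            f"PAIR:{bond}|{nosp}",
            f"HARD:{nosp}|{halo}|{bond}",
            f"Cmax.{ring_pairs}",
            f"Nmax.{nmax}",
            f"Omax.{omax}",
        }
    )


def build_profile(
    smiles: str,
    *,
    include_singles: bool = False,
    include_pairs: bool = False,
) -> AttributeProfile:
    """Tokenize one SMILES and collect its attribute profile."""
    seq = tokenize(smiles)
    local = extract_local_triples(seq, order=3)
    if include_pairs:
        local.update(extract_local_triples(seq, order=2))
    if include_singles:
        local.update(extract_local_triples(seq, order=1))
    return AttributeProfile(
        local=dict(local), globals_=extract_globals(seq), n_tokens=len(seq)
    )


def profile_dataset(dataset, **kwargs) -> dict[str, AttributeProfile]:
    """Profile every compound of a dataset; abort naming the first offender."""
    profiles: dict[str, AttributeProfile] = {}
    for comp in dataset.compounds:
        try:
            profiles[comp.id] = build_profile(comp.smiles, **kwargs)
        except SmilesParseError as exc:
            raise SmilesParseError(f"compound {comp.id!r}: {exc}") from exc
    return profiles


def write_profiles(profiles: Mapping[str, AttributeProfile], path) -> None:
    """Export profiles as TSV rows of (id, key, multiplicity)."""
    with open(path, "w") as fh:
        fh.write("id\tkey\tmultiplicity\n")
        for cid in sorted(profiles):
            prof = profiles[cid]
            for key in sorted(prof.local):
                fh.write(f"{cid}\t{key}\t{prof.local[key]}\n")
            for key in sorted(prof.globals_):
                fh.write(f"{cid}\t{key}\t1\n")
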