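"""Reaction and metabolite-list parsing.

The input format is deliberately plain: one reaction per line,

    <id>: <substrate> [+ <substrate> ...] <arrow> <product> [+ <product> ...]

with ``<arrow>`` one of ``->``, ``<-``, ``<=>`` or ``=``, surrounded by
whitespace. Metabolite terms are separated by `` + `` (space, plus, space)
so names with an internal ``+`` such as ``NAD+`` or ``H+`` parse
unambiguously. A term may carry a leading integer stoichiometric
coefficient (``2 pyruvate``); coefficients are discarded because the
substrate-product network model links distinct chemical species only.
Metabolite identity is exact normalized-string match, case-sensitive by
default — curated compound lists distinguish chemically distinct names
that differ only in case or punctuation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

#: A metabolite is identified by its normalized name.
Metabolite = str

# longest token first so "<=>" is not consumed as "<-" / "="
_ARROW_RE = re.compile(r"\s+(<=>|->|<-|=)\s+")
_WS_RE = re.compile(r"\s+")
_INT_RE = re.compile(r"^\d+$")


class InvalidMetaboliteError(ValueError):
    """A metabolite name is empty after whitespace normalization."""


class ReactionParseError(ValueError):
    """One or more reaction lines failed to parse; message carries line numbers."""


def normalize_name(raw: str, *, case_fold: bool = False) -> Metabolite:
    """Normalize a metabolite name.

    Leading/trailing whitespace is stripped and internal whitespace runs
    collapse to a single space; case is preserved unless ``case_fold`` is
    set (off by default — see module docstring).

    Raises
    ------
    InvalidMetaboliteError
        If the name is empty after trimming.
    """
    name = _WS_RE.sub(" ", raw.strip())
    if not name:
        raise InvalidMetaboliteError(f"empty metabolite name from {raw!r}")
    return name.casefold() if case_fold else name


@dataclass(frozen=True)
class Reaction:
    """One biochemical transformation: an identifier plus substrate and
    product metabolite sets (deduplicated; stoichiometry discarded)."""

    id: str
    substrates: frozenset[Metabolite]
    products: frozenset[Metabolite]

    @property
    def metabolites(self) -> frozenset[Metabolite]:
        """Union of both sides."""
        return self.substrates | self.products


@dataclass
class MetaboliteList:
    """A labelled, deduplicated metabolite set (e.g. "common", "secondary",
    "Lipids")."""

    label: str
    members: set[Metabolite] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, name: object) -> bool:
        return name in self.members


def _parse_side(side: str, *, case_fold: bool) -> frozenset[Metabolite]:
    terms = re.split(r"\s+\+\s+", side.strip())
    names = []
    for term in terms:
        tokens = term.split()
        if not tokens:
            raise InvalidMetaboliteError("empty metabolite term")
        # leading integer coefficient, only when a name follows it
        if len(tokens) > 1 and _INT_RE.match(tokens[0]):
            tokens = tokens[1:]
        names.append(normalize_name(" ".join(tokens), case_fold=case_fold))
    return frozenset(names)


def parse_reaction(line: str, *, case_fold: bool = False) -> Reaction:
    """Parse one reaction line into a :class:`Reaction`.

    ``<-`` swaps the two sides so substrates are always the forward-sense
    left operand; the arrow kind carries no other meaning downstream
    (the network model is undirected).

    Raises
    ------
    ReactionParseError
        On a missing/duplicated arrow, missing ``:`` separator, empty id,
        or empty side.
    """
    head, colon, body = line.partition(":")
    if not colon:
        raise ReactionParseError(f"no ':' id separator in {line!r}")
    rid = head.strip()
    if not rid:
        raise ReactionParseError(f"empty reaction id in {line!r}")

    parts = _ARROW_RE.split(body)
    if len(parts) == 1:
        raise ReactionParseError(f"no reaction arrow in {line!r}")
    if len(parts) > 3:
        raise ReactionParseError(f"multiple reaction arrows in {line!r}")
    left, arrow, right = parts
    if not left.strip() or not right.strip():
        raise ReactionParseError(f"empty reaction side in {line!r}")

    try:
        lhs = _parse_side(left, case_fold=case_fold)
        rhs = _parse_side(right, case_fold=case_fold)
    except InvalidMetaboliteError as exc:
        raise ReactionParseError(f"{exc} in {line!r}") from exc

    if arrow == "<-":
        lhs, rhs = rhs, lhs
    return Reaction(id=rid, substrates=lhs, products=rhs)


def read_reaction_file(path: str | Path, *, case_fold: bool = False) -> list[Reaction]:
    """Read a reaction set, one reaction per line.

    Lines starting with ``#`` and blank lines are ignored. All line-level
    parse errors are aggregated into a single :class:`ReactionParseError`
    naming the offending line numbers; duplicate reaction ids are an error.
    """
    path = Path(path)
    reactions: list[Reaction] = []
    seen_ids: dict[str, int] = {}
    errors: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                rxn = parse_reaction(stripped, case_fold=case_fold)
            except ReactionParseError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if rxn.id in seen_ids:
                errors.append(
                    f"line {lineno}: duplicate reaction id {rxn.id!r}"
                    f" (first seen on line {seen_ids[rxn.id]})"
                )
                continue
            seen_ids[rxn.id] = lineno
            reactions.append(rxn)
    if errors:
        raise ReactionParseError(
            f"{path}: {len(errors)} bad line(s):\n" + "\n".join(errors)
        )
    return reactions


def read_metabolite_list(
    path: str | Path, label: str, *, case_fold: bool = False
) -> MetaboliteList:
    """Read a single-column metabolite list (one name per line, ``#``
    comments and blank lines ignored) into a deduplicated
    :class:`MetaboliteList` with the given label."""
    path = Path(path)
    members: set[Metabolite] = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            members.add(normalize_name(stripped, case_fold=case_fold))
    return MetaboliteList(label=label, members=members)


def write_reaction_file(reactions: Iterable[Reaction], path: str | Path) -> None:
    """Write reactions in the plain-text format read by
    :func:`read_reaction_file` (sides sorted for reproducible output)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rxn in reactions:
            lhs = " + ".join(sorted(rxn.substrates))
            rhs = " + ".join(sorted(rxn.products))
            fh.write(f"{rxn.id}: {lhs} -> {rhs}\n")
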