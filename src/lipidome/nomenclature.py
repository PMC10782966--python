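"""Shorthand lipid nomenclature: parsing and headgroup-charge classification.

Lipid species detected by LC-ESI-MS/MS are reported in shorthand
notation such as ``PG(14:1/15:1)``, ``CL(17:1/16:0/16:1/17:1)`` or
``HexCer(d18:2/16:1)_B``: a class token, then one composition term per
acyl-chain slot written ``carbons:double_bonds``.  Three reporting
conventions complicate the grammar and are all handled here:

* **Lyso forms** — a phospholipid with one empty acyl slot is written
  with a ``0:0`` placeholder, e.g. ``PG(18:1/0:0)``.
* **Sum compositions** — when chain fragments could not be resolved only
  the totals are given, e.g. ``PG(35:1)``.
* **Ambiguous dual annotations** — two indistinguishable isomeric
  assignments joined by ``/``, e.g. ``PE(16:0/18:1)/PE(16:1/18:0)``.
  The first annotation is primary; the rest are kept as alternates.
  Printed alternates always share totals, so downstream chain metrics
  are unaffected by the choice of primary.

A trailing ``_A``/``_B`` suffix is a chromatographic isomer label: same
structure, distinct measured feature.  A ``d`` prefix on a chain
(``d18:2``) marks a sphingoid long-chain base; its hydroxylation state
is not modeled beyond the flag.

Headgroup net charge is a pure function of the lipid class:
phosphatidylglycerols, cardiolipins and phosphatidic acids are anionic;
phosphatidylcholines and -ethanolamines are zwitterionic; glycerolipids
(DG, TG) and sphingolipids (Cer, HexCer) are neutral.  Lyso variants
inherit the parent class's charge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "ChainSummary",
    "LipidNameError",
    "parse_lipid_name",
    "classify_headgroup_charge",
    "chain_summary",
    "render_lipid_name",
    "LIPID_CLASSES",
    "SLOT_COUNT",
    "CHARGE_OF_CLASS",
]

#: Canonical acyl-chain slot count per class, counting "0:0" placeholders.
SLOT_COUNT: dict[str, int] = {
    "PG": 2,
    "PE": 2,
    "PC": 2,
    "PA": 2,
    "CL": 4,
    "DG": 3,
    "TG": 3,
    "Cer": 2,
    "HexCer": 2,
}

LIPID_CLASSES = frozenset(SLOT_COUNT)

#: Headgroup net-charge class.  PA carries a net negative charge and is
#: recorded as anionic on the species record; whether it participates in
#: charge-composition profiles is the profile's decision (see
#: :func:`lipidome.membrane_metrics.charge_profile`).
CHARGE_OF_CLASS: dict[str, str] = {
    "PG": "anionic",
    "CL": "anionic",
    "PA": "anionic",
    "PC": "zwitterionic",
    "PE": "zwitterionic",
    "DG": "neutral",
    "TG": "neutral",
    "Cer": "neutral",
    "HexCer": "neutral",
}

#: Classes for which an empty "0:0" slot denotes a lyso form.  For the
#: neutral glycerolipids (DG, TG) empty slots are positional placeholders
#: of the three-slot glycerol notation, not lyso markers: DG(14:0/16:1/0:0)
#: is an ordinary diacylglycerol.
_LYSO_CLASSES = frozenset({"PG", "PE", "PC", "PA", "CL"})


class LipidNameError(ValueError):
    """Raised when a shorthand lipid name cannot be parsed or validated."""


class AcylChain(NamedTuple):
    """One acyl-chain slot: carbon count, double bonds, sphingoid flag."""

    carbons: int
    double_bonds: int
    sphingoid: bool = False


class ChainSummary(NamedTuple):
    total_carbons: int
    total_double_bonds: int
    n_acyl_chains: int | None
    chain_length: int


@dataclass
class LipidSpecies:
    """A parsed shorthand lipid name.

    ``total_carbons`` / ``total_double_bonds`` are sums over chain slots
    for fully resolved species and the single composition term for
    sum-composition species.  ``chain_length`` for membrane statistics is
    ``total_carbons`` (the per-lipid total over all non-empty chains).
    """

    raw_name: str
    lipid_class: str
    chains: tuple[AcylChain, ...]
    resolution: str  # full_chain | sum_composition | ambiguous
    total_carbons: int
    total_double_bonds: int
    isomer_label: str | None = None
    alternates: list["LipidSpecies"] = field(default_factory=list)

    @property
    def is_lyso(self) -> bool:
        return self.lipid_class in _LYSO_CLASSES and any(
            c.carbons == 0 and c.double_bonds == 0 for c in self.chains
        )

    @property
    def n_acyl_chains(self) -> int | None:
        """Number of non-empty chains; ``None`` when unresolved."""
        if not self.chains:
            return None
        return sum(1 for c in self.chains if c.carbons > 0)

    @property
    def charge_class(self) -> str:
        return classify_headgroup_charge(self.lipid_class, self.is_lyso)

    @property
    def subclass(self) -> str:
        """Subclass label used in composition profiles (lyso prefix 'L')."""
        return ("L" + self.lipid_class) if self.is_lyso else self.lipid_class

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_lipid_name(self)


_CLASS_RE = re.compile(r"\s*([A-Za-z][A-Za-z0-9]*)\s*\(")
_CHAIN_RE = re.compile(r"(d?)(\d+):(\d+)")
_ISOMER_RE = re.compile(r"_([A-Za-z0-9]+)")


def classify_headgroup_charge(lipid_class: str, is_lyso: bool = False) -> str:
    """Headgroup net-charge class for a lipid class.

    Lyso variants inherit the parent class's assignment, so ``is_lyso``
    is accepted for interface symmetry but does not change the result.
    """
    try:
        return CHARGE_OF_CLASS[lipid_class]
    except KeyError:
        raise LipidNameError(
            f"unrecognized lipid class {lipid_class!r}; known classes: "
            + ", ".join(sorted(CHARGE_OF_CLASS))
        ) from None


def _parse_chain(term: str, pos: int) -> AcylChain:
    m = _CHAIN_RE.fullmatch(term.strip())
    if m is None:
        raise LipidNameError(
            f"malformed composition term {term.strip()!r} at position {pos}"
        )
    return AcylChain(int(m.group(2)), int(m.group(3)), sphingoid=bool(m.group(1)))


def _parse_single(text: str, offset: int = 0) -> LipidSpecies:
    """Parse one annotation: CLASS(term[/term...])[_isomer]."""
    m = _CLASS_RE.match(text)
    if m is None:
        raise LipidNameError(
            f"cannot find a class token in {text!r} at position {offset}"
        )
    token = m.group(1)
    if token not in LIPID_CLASSES:
        raise LipidNameError(
            f"unknown lipid class token {token!r}; known classes: "
            + ", ".join(sorted(LIPID_CLASSES))
        )
    close = text.find(")", m.end())
    if close < 0:
        raise LipidNameError(
            f"unclosed composition parenthesis at position {offset + m.end() - 1}"
        )
    body = text[m.end() : close]
    terms = body.split("/")
    chains = tuple(
        _parse_chain(t, offset + m.end() + sum(len(x) + 1 for x in terms[:i]))
        for i, t in enumerate(terms)
    )

    tail = text[close + 1 :].strip()
    isomer = None
    if tail:
        im = _ISOMER_RE.fullmatch(tail)
        if im is None:
            raise LipidNameError(
                f"unexpected trailing text {tail!r} at position {offset + close + 1}"
            )
        isomer = im.group(1)

    n_slots = SLOT_COUNT[token]
    if len(chains) == 1 and n_slots > 1:
        (term,) = chains
        if term.carbons == 0:
            raise LipidNameError(f"empty sum composition in {text.strip()!r}")
        return LipidSpecies(
            raw_name=text.strip(),
            lipid_class=token,
            chains=(),
            resolution="sum_composition",
            total_carbons=term.carbons,
            total_double_bonds=term.double_bonds,
            isomer_label=isomer,
        )
    if len(chains) != n_slots:
        raise LipidNameError(
            f"{token} requires {n_slots} chain slots, got {len(chains)} "
            f"in {text.strip()!r}"
        )
    return LipidSpecies(
        raw_name=text.strip(),
        lipid_class=token,
        chains=chains,
        resolution="full_chain",
        total_carbons=sum(c.carbons for c in chains),
        total_double_bonds=sum(c.double_bonds for c in chains),
        isomer_label=isomer,
    )


def _split_annotations(name: str) -> list[tuple[str, int]]:
    """Split a possibly dual annotation on '/' outside parentheses."""
    parts: list[tuple[str, int]] = []
    depth = 0
    start = 0
    for i, ch in enumerate(name):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise LipidNameError(f"unbalanced parenthesis at position {i}")
        elif ch == "/" and depth == 0:
            parts.append((name[start:i], start))
            start = i + 1
    parts.append((name[start:], start))
    return parts


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    A dual annotation ``NameA/NameB`` yields ``resolution="ambiguous"``
    with the first annotation as primary and the rest in ``alternates``.

    Raises
    ------
    LipidNameError
        On an unknown class token, a malformed composition term (with
        character position), or a chain-slot count that does not match
        the class.
    """
    if not name or not name.strip():
        raise LipidNameError("empty lipid name")
    parts = _split_annotations(name)
    specs = [_parse_single(text, offset) for text, offset in parts]
    primary = specs[0]
    if len(specs) > 1:
        primary = LipidSpecies(
            raw_name=name.strip(),
            lipid_class=primary.lipid_class,
            chains=primary.chains,
            resolution="ambiguous",
            total_carbons=primary.total_carbons,
            total_double_bonds=primary.total_double_bonds,
            isomer_label=primary.isomer_label,
            alternates=specs[1:],
        )
    return primary


def chain_summary(species: LipidSpecies) -> ChainSummary:
    """Totals consumed by the membrane statistics.

    The per-lipid ``chain_length`` is the total acyl carbon count over
    all non-empty chains — the only definition that is also valid for
    sum-composition species, and the one whose abundance-weighted mean
    is reported as "mean chain length".
    """
    return ChainSummary(
        total_carbons=species.total_carbons,
        total_double_bonds=species.total_double_bonds,
        n_acyl_chains=species.n_acyl_chains,
        chain_length=species.total_carbons,
    )


def _render_single(species: LipidSpecies) -> str:
    if species.resolution == "sum_composition":
        body = f"{species.total_carbons}:{species.total_double_bonds}"
    else:
        body = "/".join(
            ("d" if c.sphingoid else "") + f"{c.carbons}:{c.double_bonds}"
            for c in species.chains
        )
    suffix = f"_{species.isomer_label}" if species.isomer_label else ""
    return f"{species.lipid_class}({body}){suffix}"


def render_lipid_name(species: LipidSpecies) -> str:
    """Render a species back to canonical shorthand (no internal spaces)."""
    if species.resolution == "ambiguous":
        return "/".join(
            [_render_single(species)] + [_render_single(a) for a in species.alternates]
        )
    return _render_single(species)
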