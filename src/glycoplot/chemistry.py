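"""Monoisotopic mass arithmetic for elements, residues and modifications.

Everything downstream (peptide fragments, glycan masses, oxonium ions) is a
sum over this module's tables, so the conventions are fixed here once:

* monoisotopic masses only (atomic masses from the NIST table shipped with
  pyteomics);
* m/z of a fragment of charge ``z`` is ``(neutral + z * PROTON) / z`` with
  the proton mass constant 1.007276466 Da;
* modification positions on a peptide are 1-based, with the strings
  ``"N-term"`` / ``"C-term"`` for terminal modifications.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

from pyteomics import mass as _pmass

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Proton mass in Da; converts neutral fragment masses to m/z.
PROTON = 1.007276466

#: Monoisotopic atomic masses, element symbol -> Da.
ATOMIC_MASS: dict[str, float] = {
    el: iso[0][0] for el, iso in _pmass.nist_mass.items()
}

#: Monoisotopic residue masses of the 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

ElementComposition = dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


def mass_of_composition(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition.

    Counts may be negative (losses). The empty composition has mass 0.

    Raises
    ------
    FormatError
        If a symbol is not in the atomic-mass table.
    """
    total = 0.0
    for symbol, count in comp.items():
        try:
            total += ATOMIC_MASS[symbol] * count
        except KeyError:
            raise FormatError(f"unknown element symbol: {symbol!r}") from None
    return total


def parse_formula(text: str) -> ElementComposition:
    """Parse a chemical formula such as ``"HPO3"`` or ``"H-2O-1"``.

    Negative counts express net losses (e.g. deamidation ``"H-1N-1O"``).
    """
    comp: ElementComposition = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormatError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        if not match.group(0):
            break
        symbol = match.group(1)
        if symbol not in ATOMIC_MASS:
            raise FormatError(f"unknown element symbol: {symbol!r}")
        count = int(match.group(2)) if match.group(2) else 1
        comp[symbol] = comp.get(symbol, 0) + count
        pos = match.end()
    if pos != len(text):
        raise FormatError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return {k: v for k, v in comp.items() if v != 0}


WATER = mass_of_composition({"H": 2, "O": 1})
AMMONIA = mass_of_composition({"N": 1, "H": 3})
HYDROGEN = ATOMIC_MASS["H"]


def mz_from_neutral(neutral: float, charge: int, neutral_loss: float = 0.0) -> float:
    """m/z of a fragment given its neutral mass, charge and optional loss."""
    if charge < 1:
        raise ValidationError(f"charge must be >= 1, got {charge}")
    return (neutral - neutral_loss + charge * PROTON) / charge


@dataclass(frozen=True)
class Modification:
    """A peptide modification with mass, optional formula, sites and losses.

    ``sites`` holds one-letter residue codes and/or the terminus tags
    ``"N-term"`` / ``"C-term"``. ``neutral_losses`` are positive Da values
    subtracted from fragments that carry the modification (e.g. 97.9769 for
    H3PO4 loss from phosphopeptides).
    """

    name: str
    delta_mass: float
    composition: ElementComposition | None = None
    sites: frozenset[str] = frozenset()
    neutral_losses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValidationError(f"modification {self.name!r} has no sites")
        if self.composition:
            calc = mass_of_composition(self.composition)
            if abs(calc - self.delta_mass) > 1e-4:
                raise ValidationError(
                    f"modification {self.name!r}: delta_mass {self.delta_mass} "
                    f"disagrees with composition mass {calc:.6f}"
                )

    def admits(self, site: str) -> bool:
        return site in self.sites


def _mod(name: str, formula: str, sites: str, losses: tuple[float, ...] = ()) -> Modification:
    comp = parse_formula(formula)
    return Modification(
        name=name,
        delta_mass=mass_of_composition(comp),
        composition=comp,
        sites=frozenset(s.strip() for s in sites.split(",")),
        neutral_losses=losses,
    )


#: Phosphate neutral loss (H3PO4) used by the built-in Phospho entry.
H3PO4 = mass_of_composition(parse_formula("H3PO4"))

#: Default modification set; Unimod-standard formulas, overridable via config.
BUILTIN_MODIFICATIONS: dict[str, Modification] = {
    m.name: m
    for m in (
        _mod("Carbamidomethyl", "C2H3NO", "C"),
        _mod("Oxidation", "O", "M,W"),
        _mod("Phospho", "HPO3", "S,T,Y", (H3PO4,)),
        _mod("Deamidated", "H-1N-1O", "N,Q"),
        _mod("Acetyl", "C2H2O", "K,N-term"),
        _mod("Methyl", "CH2", "K,R"),
    )
}

PositionTag = Union[int, str]  # 1-based index, "N-term" or "C-term"

_VALID_TERMINI = {"N-term", "C-term"}


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with positioned modifications.

    Positions are 1-based indices into ``sequence`` or a terminus tag.
    Validation rejects positions out of range and modifications placed on a
    residue their site set does not admit.
    """

    sequence: str
    modifications: tuple[tuple[PositionTag, Modification], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("empty peptide sequence")
        for letter in self.sequence:
            if letter not in RESIDUE_MASS:
                raise ValidationError(f"unknown residue letter {letter!r}")
        for pos, mod in self.modifications:
            if isinstance(pos, str):
                if pos not in _VALID_TERMINI:
                    raise ValidationError(f"bad position tag {pos!r}")
                site = pos
            else:
                if not 1 <= pos <= len(self.sequence):
                    raise ValidationError(
                        f"modification position {pos} outside 1..{len(self.sequence)}"
                    )
                site = self.sequence[pos - 1]
            if not mod.admits(site):
                raise ValidationError(
                    f"modification {mod.name!r} does not admit site {site!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return format_peptide(self)


def format_peptide(p: Peptide) -> str:
    """Inline notation, e.g. ``GNAEGS(Phospho)SDEEGKLVIDEPAK``."""
    by_pos: dict[int, list[str]] = {}
    prefix = ""
    suffix = ""
    for pos, mod in p.modifications:
        if pos == "N-term":
            prefix += f"({mod.name})"
        elif pos == "C-term":
            suffix += f"({mod.name})"
        else:
            by_pos.setdefault(pos, []).append(mod.name)
    out = [prefix]
    for i, letter in enumerate(p.sequence, start=1):
        out.append(letter)
        for name in by_pos.get(i, ()):
            out.append(f"({name})")
    out.append(suffix)
    return "".join(out)


def peptide_neutral_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    total = WATER
    for letter in p.sequence:
        total += RESIDUE_MASS[letter]
    for _pos, mod in p.modifications:
        total += mod.delta_mass
    return total


class ModificationRegistry(dict):
    """Name-keyed modification table; duplicate names overwrite with a warning."""

    def register(self, mod: Modification) -> None:
        if mod.name in self:
            logger.warning("modification %r redefined; last definition wins", mod.name)
        self[mod.name] = mod


def default_registry() -> ModificationRegistry:
    reg = ModificationRegistry()
    reg.update(BUILTIN_MODIFICATIONS)
    return reg


def _parse_sites_and_losses(part: str, lineno: int) -> tuple[frozenset[str], tuple[float, ...]]:
    """Parse config part (4): ``site[,site...][;NL:mass[,mass...]]``."""
    sites: frozenset[str] = frozenset()
    losses: list[float] = []
    for chunk in part.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if chunk.upper().startswith("NL:"):
            for tok in chunk[3:].split(","):
                try:
                    losses.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: bad neutral-loss value {tok!r}"
                    ) from None
        else:
            sites = frozenset(s.strip() for s in chunk.split(",") if s.strip())
    return sites, tuple(losses)


def load_modification_config(
    path: str | Path, registry: ModificationRegistry | None = None
) -> ModificationRegistry:
    """Load a tab-separated modification config on top of the built-ins.

    Each non-comment line has exactly four tab-separated parts:
    name, delta mass (Da), chemical formula (or ``-``), and
    ``sites[;NL:losses]``. Example::

        Phospho\t79.96633\tHPO3\tS,T,Y;NL:97.97690
    """
    reg = registry if registry is not None else default_registry()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(
                f"line {lineno}: expected 4 tab-separated parts, got {len(parts)}"
            )
        name, mass_text, formula, sites_part = (p.strip() for p in parts)
        try:
            delta = float(mass_text)
        except ValueError:
            raise FormatError(f"line {lineno}: bad mass {mass_text!r}") from None
        comp = None if formula in ("", "-") else parse_formula(formula)
        sites, losses = _parse_sites_and_losses(sites_part, lineno)
        if not sites:
            raise FormatError(f"line {lineno}: no modification sites given")
        try:
            mod = Modification(name, delta, comp, sites, losses)
        except ValidationError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        reg.register(mod)
    return reg


def parse_modified_sequence(
    text: str, registry: Mapping[str, Modification] | None = None
) -> Peptide:
    """Parse inline-annotated peptide notation into a :class:`Peptide`.

    Accepts ``S(Phospho)`` / ``S[Phospho]`` after the modified residue,
    numeric deltas like ``M[+15.9949]``, and a leading ``(Acetyl)`` for the
    N-terminus.
    """
    reg = registry if registry is not None else BUILTIN_MODIFICATIONS
    seq: list[str] = []
    mods: list[tuple[PositionTag, Modification]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "([":
            close = ")" if ch == "(" else "]"
            end = text.find(close, i)
            if end < 0:
                raise FormatError(f"unbalanced {ch!r} in peptide {text!r}")
            token = text[i + 1 : end]
            pos: PositionTag = len(seq) if seq else "N-term"
            site = seq[-1] if seq else "N-term"
            mods.append((pos, _resolve_mod(token, site, reg)))
            i = end + 1
        else:
            if not ch.isalpha():
                raise FormatError(f"unexpected character {ch!r} in peptide {text!r}")
            seq.append(ch.upper())
            i += 1
    return Peptide("".join(seq), tuple(mods))


def _resolve_mod(token: str, site: str, reg: Mapping[str, Modification]) -> Modification:
    token = token.strip()
    if token in reg:
        return reg[token]
    try:
        delta = float(token)
    except ValueError:
        raise FormatError(f"unknown modification name {token!r}") from None
    return Modification(
        name=f"{delta:+.4f}", delta_mass=delta, sites=frozenset({site})
    )
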