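"""Theoretical fragment enumeration for (glyco)peptides.

Peptide backbone series depend on the dissociation method: collisional
activation (CID/HCD) yields b/y ions, electron-driven activation (ETD/ECD)
yields c/z ions, and the hybrid methods (EThcD/ETciD) yield all four.
Glycosidic bonds are labile under collisional activation, so glycan Y ions
(peptide + reducing-end glycan remnant), B ions (detached non-reducing
fragments) and low-mass oxonium ions are generated only when a collisional
component is present.

Glycan Y enumeration walks every branch of the glycan tree from the root
outward, combining partial branches at each junction; the closure of that
stepping is exactly the set of root-containing connected subtrees, and
fragments with duplicate composition collapse to one ion. B ions come from
the direction-reversed walk: the complete subtree hanging below each single
glycosidic cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .chemistry import (
    AMMONIA,
    HYDROGEN,
    PROTON,
    RESIDUE_MASS,
    WATER,
    Peptide,
    mz_from_neutral,
    peptide_neutral_mass,
)
from .glycan import (
    GlycanComposition,
    GlycanNode,
    GlycanTree,
    format_composition,
    glycan_mass,
    parse_composition,
)
from .errors import ValidationError


class DissociationMethod(Enum):
    """Activation method; fixes the enabled peptide ion series."""

    CID = "CID"
    HCD = "HCD"
    ETD = "ETD"
    ECD = "ECD"
    ETHCD = "EThcD"
    ETCID = "ETciD"

    @property
    def ion_series(self) -> frozenset[str]:
        if self in (DissociationMethod.CID, DissociationMethod.HCD):
            return frozenset("by")
        if self in (DissociationMethod.ETD, DissociationMethod.ECD):
            return frozenset("cz")
        return frozenset("bycz")

    @property
    def collisional(self) -> bool:
        """True when a collisional component is present (enables glycan ions)."""
        return self not in (DissociationMethod.ETD, DissociationMethod.ECD)

    @classmethod
    def from_name(cls, name: str) -> "DissociationMethod":
        for member in cls:
            if member.value.lower() == name.strip().lower():
                return member
        raise ValidationError(f"unknown dissociation method {name!r}")


# z ions are z-dot radicals: y - NH3 + H. c ions: b + NH3.
_SERIES_OFFSET = {"b": 0.0, "y": 0.0, "c": AMMONIA, "z": HYDROGEN - AMMONIA}

#: Known neutral-loss masses mapped to display formulas for labels.
LOSS_NAMES = {
    97.976896: "H3PO4",
    18.010565: "H2O",
    17.026549: "NH3",
    63.961901: "SO2",
}


def _loss_label(mass: float) -> str:
    for ref, name in LOSS_NAMES.items():
        if abs(mass - ref) < 0.01:
            return name
    return f"{mass:.2f}"


@dataclass(frozen=True)
class TheoreticalIon:
    """One predicted fragment ion.

    ``neutral_mass`` is the fragment's neutral mass before any neutral loss;
    ``mz = (neutral_mass - neutral_loss + charge * proton) / charge``.
    ``ordinal`` is the cleavage index for peptide series and the glycan
    composition for Y/B/oxonium series.
    """

    series: str  # b, y, c, z, Y, B, oxonium, precursor
    ordinal: object
    charge: int
    neutral_mass: float
    mz: float
    neutral_loss: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValidationError("ion charge must be >= 1")


def _charge_suffix(charge: int) -> str:
    return "" if charge == 1 else f"^{charge}+"


def _make_ion(
    series: str,
    ordinal: object,
    charge: int,
    neutral: float,
    base_label: str,
    loss: float | None = None,
) -> TheoreticalIon:
    label = base_label
    if loss is not None:
        label += f"-{_loss_label(loss)}"
    label += _charge_suffix(charge)
    return TheoreticalIon(
        series=series,
        ordinal=ordinal,
        charge=charge,
        neutral_mass=neutral,
        mz=mz_from_neutral(neutral, charge, loss or 0.0),
        neutral_loss=loss,
        label=label,
    )


def peptide_fragments(
    p: Peptide, method: DissociationMethod, max_charge: int
) -> list[TheoreticalIon]:
    """Enumerate backbone fragments for every enabled series.

    One ion per (series, cleavage index 1..n-1, charge 1..max_charge), with
    modification masses assigned to the fragment containing the modified
    residue and a neutral-loss satellite for every distinct declared loss
    carried by the fragment (e.g. the -97.977 Da H3PO4 losses of
    phosphopeptides).
    """
    if max_charge < 1:
        raise ValidationError(f"max_charge must be >= 1, got {max_charge}")
    n = len(p.sequence)
    if n < 2:
        raise ValidationError("peptide must have at least 2 residues to fragment")

    # effective 1-based position of each modification for prefix assignment
    mod_delta = [0.0] * (n + 1)
    mod_losses: list[tuple[int, float]] = []  # (effective position, loss mass)
    for pos, mod in p.modifications:
        eff = 1 if pos == "N-term" else n if pos == "C-term" else int(pos)
        mod_delta[eff] += mod.delta_mass
        for loss in mod.neutral_losses:
            mod_losses.append((eff, loss))

    prefix = [0.0] * (n + 1)
    for i in range(1, n + 1):
        prefix[i] = prefix[i - 1] + RESIDUE_MASS[p.sequence[i - 1]] + mod_delta[i]
    total_residue = prefix[n]

    ions: list[TheoreticalIon] = []
    for series in sorted(method.ion_series):
        nterm = series in ("b", "c")
        for i in range(1, n):
            if nterm:
                neutral = prefix[i] + _SERIES_OFFSET[series]
                losses = {loss for eff, loss in mod_losses if eff <= i}
            else:
                neutral = total_residue - prefix[n - i] + WATER + _SERIES_OFFSET[series]
                losses = {loss for eff, loss in mod_losses if eff > n - i}
            base_label = f"{series}{i}"
            for charge in range(1, max_charge + 1):
                ions.append(_make_ion(series, i, charge, neutral, base_label))
                for loss in sorted(losses):
                    ions.append(_make_ion(series, i, charge, neutral, base_label, loss))
    return ions


def _subtree_compositions(node: GlycanNode) -> set[GlycanComposition]:
    """Compositions of connected subtrees of ``node``'s subtree containing it.

    Branch-stepping closure: each child branch contributes either nothing or
    one of its own node-containing subtrees; junctions combine branch
    partials, and composition equality deduplicates as it goes.
    """
    own = GlycanComposition({node.monosaccharide.symbol: 1})
    result = {own}
    for child in node.children:
        child_sets = _subtree_compositions(child)
        result = {base + ext for base in result for ext in child_sets} | result
    return result


def enumerate_glycan_Y(tree: GlycanTree) -> set[GlycanComposition]:
    """All Y-fragment compositions: root-containing connected subtrees.

    Includes the empty composition (Y0, bare peptide) and the intact glycan;
    duplicates by composition are removed.
    """
    return _subtree_compositions(tree.root) | {GlycanComposition()}


def enumerate_glycan_B(tree: GlycanTree) -> set[GlycanComposition]:
    """All B-fragment compositions: the complete subtree below each node.

    These are the non-reducing-end products of a single glycosidic cleavage,
    including the whole glycan detached from the peptide; internal
    (doubly-cleaved) fragments are not generated.
    """

    def _closure(node: GlycanNode) -> GlycanComposition:
        comp = GlycanComposition({node.monosaccharide.symbol: 1})
        for child in node.children:
            comp = comp + _closure(child)
        return comp

    return {_closure(node) for node in tree.nodes()}


def _sorted_compositions(comps: Iterable[GlycanComposition]) -> list[GlycanComposition]:
    return sorted(comps, key=lambda c: (glycan_mass(c), format_composition(c)))


def glycopeptide_Y_ions(
    p: Peptide, tree: GlycanTree, max_charge: int
) -> list[TheoreticalIon]:
    """Y ions of a glycopeptide: peptide neutral mass + glycan remnant mass.

    Y0 (bare peptide) is labelled ``Y0``; other ions carry the retained
    composition, e.g. ``Y-Hex(2)HexNAc(2)``.
    """
    if max_charge < 1:
        raise ValidationError(f"max_charge must be >= 1, got {max_charge}")
    pep_mass = peptide_neutral_mass(p)
    ions: list[TheoreticalIon] = []
    for comp in _sorted_compositions(enumerate_glycan_Y(tree)):
        neutral = pep_mass + glycan_mass(comp)
        base = "Y0" if not comp else f"Y-{format_composition(comp)}"
        for charge in range(1, max_charge + 1):
            ions.append(_make_ion("Y", comp, charge, neutral, base))
    return ions


def glycan_B_ions(tree: GlycanTree, max_charge: int = 1) -> list[TheoreticalIon]:
    """B ions: detached glycan fragments, neutral mass = residue-mass sum."""
    ions: list[TheoreticalIon] = []
    for comp in _sorted_compositions(enumerate_glycan_B(tree)):
        neutral = glycan_mass(comp)
        base = f"B-{format_composition(comp)}"
        for charge in range(1, max_charge + 1):
            ions.append(_make_ion("B", comp, charge, neutral, base))
    return ions


@dataclass(frozen=True)
class OxoniumEntry:
    """One diagnostic-ion rule: emitted when ``required`` is contained."""

    name: str
    required: GlycanComposition
    loss_mass: float = 0.0

    def neutral(self) -> float:
        return glycan_mass(self.required) - self.loss_mass


def _ox(name: str, required: str, loss_formula: str | None = None) -> OxoniumEntry:
    from .chemistry import mass_of_composition, parse_formula

    loss = mass_of_composition(parse_formula(loss_formula)) if loss_formula else 0.0
    return OxoniumEntry(name, parse_composition(required), loss)


#: Built-in diagnostic oxonium table. The HexNAc ladder covers the familiar
#: 204.087 / 186.076 / 168.066 / 138.055 / 126.055 satellites; sialic-acid
#: ions discriminate NeuAc (292.103) from NeuGc (308.098).
OXONIUM_TABLE: list[OxoniumEntry] = [
    _ox("HexNAc", "HexNAc(1)"),
    _ox("HexNAc-H2O", "HexNAc(1)", "H2O"),
    _ox("HexNAc-2H2O", "HexNAc(1)", "H4O2"),
    _ox("HexNAc-CH6O3", "HexNAc(1)", "CH6O3"),
    _ox("HexNAc-C2H6O3", "HexNAc(1)", "C2H6O3"),
    _ox("Hex", "Hex(1)"),
    _ox("Hex-H2O", "Hex(1)", "H2O"),
    _ox("NeuAc", "NeuAc(1)"),
    _ox("NeuAc-H2O", "NeuAc(1)", "H2O"),
    _ox("NeuGc", "NeuGc(1)"),
    _ox("NeuGc-H2O", "NeuGc(1)", "H2O"),
    _ox("HexHexNAc", "Hex(1)HexNAc(1)"),
    _ox("NeuAcHexHexNAc", "Hex(1)HexNAc(1)NeuAc(1)"),
]


def _contains(comp: Mapping[str, int], required: GlycanComposition) -> bool:
    return all(comp.get(sym, 0) >= count for sym, count in required.items())


def oxonium_ions(
    comp: GlycanComposition, max_charge: int = 1, table: Sequence[OxoniumEntry] | None = None
) -> list[TheoreticalIon]:
    """Diagnostic oxonium ions for a glycan composition.

    Each table entry whose required monosaccharides are contained in ``comp``
    yields one ion per charge (singly charged by default).
    """
    entries = OXONIUM_TABLE if table is None else table
    ions: list[TheoreticalIon] = []
    for entry in entries:
        if not _contains(comp, entry.required):
            continue
        neutral = entry.neutral()
        for charge in range(1, max_charge + 1):
            ions.append(
                _make_ion("oxonium", entry.required, charge, neutral, entry.name)
            )
    return ions


def load_oxonium_config(path, table: list[OxoniumEntry] | None = None) -> list[OxoniumEntry]:
    """Extend the oxonium table from a 4-field tab-separated config.

    Fields: name, observed m/z (or ``-`` to compute from the composition),
    required composition string, loss formula (or ``-``). A given m/z wins
    over the computed value by adjusting the loss term.
    """
    from pathlib import Path

    from .errors import FormatError

    out = list(OXONIUM_TABLE if table is None else table)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"line {lineno}: expected 4 tab-separated parts")
        name, mz_text, comp_text, loss_text = (x.strip() for x in parts)
        required = parse_composition(comp_text)
        if loss_text in ("", "-"):
            loss = 0.0
        else:
            from .chemistry import mass_of_composition, parse_formula

            loss = mass_of_composition(parse_formula(loss_text))
        if mz_text not in ("", "-"):
            target_neutral = float(mz_text) - PROTON
            loss = glycan_mass(required) - target_neutral
        out.append(OxoniumEntry(name, required, loss))
    return out


def assemble_ions(
    peptide: Peptide,
    method: DissociationMethod,
    max_charge: int,
    glycan_tree: GlycanTree | None = None,
    glycan_composition: GlycanComposition | None = None,
    oxonium_table: Sequence[OxoniumEntry] | None = None,
) -> list[TheoreticalIon]:
    """Full theoretical ion set for one identification.

    Peptide series always; glycan Y/B/oxonium only under collisional
    activation. With a structure, the complete Y/B enumeration runs; with a
    composition only, Y0 plus the intact-glycan Y ion and oxonium ions are
    generated (the intermediate ladder needs the topology).
    """
    ions = peptide_fragments(peptide, method, max_charge)
    if not method.collisional:
        return ions
    comp = glycan_composition
    if glycan_tree is not None:
        comp = glycan_tree.composition()
        ions += glycopeptide_Y_ions(peptide, glycan_tree, max_charge)
        ions += glycan_B_ions(glycan_tree, min(2, max_charge))
    elif comp is not None and comp:
        pep_mass = peptide_neutral_mass(peptide)
        for c, base in ((GlycanComposition(), "Y0"), (comp, f"Y-{format_composition(comp)}")):
            neutral = pep_mass + glycan_mass(c)
            for charge in range(1, max_charge + 1):
                ions.append(_make_ion("Y", c, charge, neutral, base))
    if comp is not None and comp:
        ions += oxonium_ions(comp, 1, oxonium_table)
    return ions
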