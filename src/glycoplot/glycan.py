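"""Glycan data model: monosaccharide table, compositions, rooted trees,
and parsers for composition strings, GlycoCT condensed, and a WURCS 2.0
subset.

The tree's root is the reducing-end residue (the peptide attachment point).
Linkage positions and anomericity carry no mass information here, so the
parsers keep only the topology: which residue is attached to which. That is
all the Y/B fragment enumeration needs.

Residue masses are the dehydrated (in-chain) monoisotopic masses, computed
from elemental formulas rather than stored as literals, so every downstream
m/z (including diagnostic oxonium ions such as NeuGc at 308.098) traces back
to the atomic-mass table.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .chemistry import ElementComposition, mass_of_composition, parse_formula
from .errors import FormatError, UnsupportedStructureError, ValidationError


@dataclass(frozen=True)
class Monosaccharide:
    """One row of the monosaccharide table."""

    symbol: str
    alias: str  # one-letter code used in compact figure labels
    composition: ElementComposition
    residue_mass: float

    def __post_init__(self) -> None:
        if self.residue_mass <= 0:
            raise ValidationError(f"{self.symbol}: residue mass must be positive")


def _mono(symbol: str, alias: str, formula: str) -> Monosaccharide:
    comp = parse_formula(formula)
    return Monosaccharide(symbol, alias, comp, mass_of_composition(comp))


#: Built-in residue table (dehydrated formulas). Extensible at run time via
#: :func:`register_monosaccharide`.
MONOSACCHARIDES: dict[str, Monosaccharide] = {
    m.symbol: m
    for m in (
        _mono("Hex", "H", "C6H10O5"),
        _mono("HexNAc", "N", "C8H13NO5"),
        _mono("Fuc", "F", "C6H10O4"),
        _mono("NeuAc", "A", "C11H17NO8"),
        _mono("NeuGc", "G", "C11H17NO9"),
        _mono("Xyl", "X", "C5H8O4"),
    )
}

#: Alternate names accepted by the parsers, mapped to canonical symbols.
SYMBOL_ALIASES: dict[str, str] = {"dHex": "Fuc", "Pent": "Xyl"}
SYMBOL_ALIASES.update({m.alias: m.symbol for m in MONOSACCHARIDES.values()})

#: Canonical symbol order used when formatting compositions.
_SYMBOL_ORDER = ("Hex", "HexNAc", "Fuc", "NeuAc", "NeuGc", "Xyl")


def register_monosaccharide(symbol: str, alias: str, formula: str) -> Monosaccharide:
    """Extend the residue table (same spirit as the modification config)."""
    if any(m.alias == alias for m in MONOSACCHARIDES.values()):
        raise ValidationError(f"alias {alias!r} already in use")
    mono = _mono(symbol, alias, formula)
    MONOSACCHARIDES[symbol] = mono
    SYMBOL_ALIASES[alias] = symbol
    return mono


def _canonical_symbol(name: str) -> str:
    if name in MONOSACCHARIDES:
        return name
    if name in SYMBOL_ALIASES:
        return SYMBOL_ALIASES[name]
    raise FormatError(f"unknown monosaccharide symbol {name!r}")


class GlycanComposition(Mapping[str, int]):
    """Immutable multiset of monosaccharide counts.

    Equality and hashing are count-wise, so composition sets deduplicate Y/B
    fragments exactly as required. Addition merges counts.
    """

    __slots__ = ("_items",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int) -> None:
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for name, count in src.items():
                symbol = _canonical_symbol(name)
                if count < 0:
                    raise ValidationError(f"negative count for {symbol}")
                if count:
                    merged[symbol] = merged.get(symbol, 0) + count
        order = {s: i for i, s in enumerate(_SYMBOL_ORDER)}
        self._items: tuple[tuple[str, int], ...] = tuple(
            sorted(merged.items(), key=lambda kv: (order.get(kv[0], 99), kv[0]))
        )

    def __getitem__(self, key: str) -> int:
        key = _canonical_symbol(key)
        for sym, count in self._items:
            if sym == key:
                return count
        raise KeyError(key)

    def get(self, key: str, default: int = 0) -> int:  # type: ignore[override]
        try:
            return self[key]
        except (KeyError, FormatError):
            return default

    def __iter__(self) -> Iterator[str]:
        return (sym for sym, _ in self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __hash__(self) -> int:
        return hash(self._items)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GlycanComposition):
            return self._items == other._items
        if isinstance(other, Mapping):
            return self._items == GlycanComposition(other)._items
        return NotImplemented

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        merged = dict(self._items)
        for sym, count in other.items():
            merged[sym] = merged.get(sym, 0) + count
        return GlycanComposition(merged)

    def __bool__(self) -> bool:
        return bool(self._items)

    @property
    def total(self) -> int:
        return sum(c for _, c in self._items)

    def mass(self) -> float:
        return glycan_mass(self)

    def __str__(self) -> str:
        return format_composition(self)

    def __repr__(self) -> str:
        return f"GlycanComposition({format_composition(self)!r})"


_COMPOSITION_TOKEN = re.compile(r"([A-Za-z]+)\((\d+)\)")


def parse_composition(text: str) -> GlycanComposition:
    """Parse ``"Hex(4)HexNAc(5)Fuc(2)"``-style composition strings."""
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _COMPOSITION_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormatError(f"malformed composition at {text[pos:]!r}")
        symbol = _canonical_symbol(match.group(1))
        counts[symbol] = counts.get(symbol, 0) + int(match.group(2))
        pos = match.end()
    if pos != len(text):
        raise FormatError(f"malformed composition at {text[pos:]!r}")
    return GlycanComposition(counts)


def format_composition(comp: GlycanComposition) -> str:
    return "".join(f"{sym}({count})" for sym, count in comp.items())


def glycan_mass(comp: Mapping[str, int]) -> float:
    """Sum of residue masses; the glycan's contribution to a glycopeptide."""
    total = 0.0
    for name, count in comp.items():
        total += MONOSACCHARIDES[_canonical_symbol(name)].residue_mass * count
    return total


@dataclass
class GlycanNode:
    monosaccharide: Monosaccharide
    children: list["GlycanNode"] = field(default_factory=list)

    def add(self, child: "GlycanNode") -> "GlycanNode":
        self.children.append(child)
        return child


class GlycanTree:
    """Rooted tree of monosaccharide nodes; root is the reducing end."""

    def __init__(self, root: GlycanNode) -> None:
        self.root = root
        seen: set[int] = set()
        stack = [root]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise ValidationError("glycan tree contains a cycle or shared node")
            seen.add(id(node))
            stack.extend(node.children)
        self._n_nodes = len(seen)

    def nodes(self) -> Iterator[GlycanNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __len__(self) -> int:
        return self._n_nodes

    def composition(self) -> GlycanComposition:
        return composition_of(self)

    @property
    def depth(self) -> int:
        def _d(node: GlycanNode) -> int:
            return 1 + max((_d(c) for c in node.children), default=0)

        return _d(self.root)

    def degree_sequence(self) -> tuple[int, ...]:
        return tuple(sorted(len(n.children) for n in self.nodes()))

    def __repr__(self) -> str:
        return f"GlycanTree({format_composition(self.composition())}, n={len(self)})"


def tree_from_nested(spec: tuple) -> GlycanTree:
    """Build a tree from ``(symbol, [children...])`` nested tuples.

    Convenient for programmatic fixtures, e.g. the N-glycan core is
    ``("HexNAc", [("HexNAc", [("Hex", [("Hex", []), ("Hex", [])])])])``.
    """

    def _build(item: tuple) -> GlycanNode:
        symbol, children = item
        node = GlycanNode(MONOSACCHARIDES[_canonical_symbol(symbol)])
        for child in children:
            node.add(_build(child))
        return node

    return GlycanTree(_build(spec))


def composition_of(tree: GlycanTree) -> GlycanComposition:
    counts: dict[str, int] = {}
    for node in tree.nodes():
        sym = node.monosaccharide.symbol
        counts[sym] = counts.get(sym, 0) + 1
    return GlycanComposition(counts)


# --------------------------------------------------------------------------
# GlycoCT condensed
# --------------------------------------------------------------------------

_GLYCOCT_RES = re.compile(r"^(\d+)([bs]):(.*)$")
_GLYCOCT_LIN = re.compile(
    r"^(\d+):(\d+)[a-z]\([\d?+|-]+\)(\d+)[a-z]$"
)

# superclass token + substituent set -> table symbol
def _classify_glycoct(descriptor: str, substituents: frozenset[str]) -> str:
    parts = descriptor.split("|")
    tokens = parts[0].split("-")
    superclass = None
    for tok in tokens:
        if tok.isupper() and len(tok) == 3:
            superclass = tok
    deoxy = any(p.endswith(":d") or p == "6:d" for p in parts[1:])
    if superclass == "HEX":
        if "n-acetyl" in substituents:
            return "HexNAc"
        if deoxy:
            return "Fuc"
        return "Hex"
    if superclass == "NON":
        if "n-glycolyl" in substituents:
            return "NeuGc"
        if "n-acetyl" in substituents:
            return "NeuAc"
        raise UnsupportedStructureError(
            f"nonulosonic residue without N-acyl substituent: {descriptor!r}"
        )
    if superclass == "PEN":
        return "Xyl"
    raise UnsupportedStructureError(f"unmappable GlycoCT residue {descriptor!r}")


def parse_glycoct(text: str) -> GlycanTree:
    """Parse GlycoCT condensed text (RES/LIN sections) into a tree.

    Substituents (``s`` residues, e.g. ``n-acetyl``) are folded into their
    base residue to pick the table symbol. Repeat (REP), undetermined (UND)
    and alternative (ALT) sections are outside the supported subset.
    """
    section = None
    residues: dict[int, tuple[str, str]] = {}  # idx -> (kind, descriptor)
    links: list[tuple[int, int]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line in ("RES", "LIN"):
            section = line
            continue
        if line in ("REP", "UND", "ALT", "ISO", "NON"):
            raise UnsupportedStructureError(f"GlycoCT section {line} not supported")
        if section == "RES":
            m = _GLYCOCT_RES.match(line)
            if not m:
                raise FormatError(f"bad GlycoCT RES line {line!r}")
            residues[int(m.group(1))] = (m.group(2), m.group(3))
        elif section == "LIN":
            m = _GLYCOCT_LIN.match(line)
            if not m:
                raise FormatError(f"bad GlycoCT LIN line {line!r}")
            links.append((int(m.group(2)), int(m.group(3))))
        else:
            raise FormatError(f"GlycoCT line outside RES/LIN: {line!r}")
    if not residues:
        raise FormatError("GlycoCT text contains no residues")

    for parent, child in links:
        for idx in (parent, child):
            if idx not in residues:
                raise FormatError(f"GlycoCT LIN references missing residue {idx}")

    substituents: dict[int, set[str]] = {idx: set() for idx in residues}
    base_children: dict[int, list[int]] = {
        idx: [] for idx, (kind, _) in residues.items() if kind == "b"
    }
    incoming: dict[int, int] = {}
    for parent, child in links:
        child_kind = residues[child][0]
        if child_kind == "s":
            substituents[parent].add(residues[child][1])
        else:
            if residues[parent][0] != "b":
                raise UnsupportedStructureError("substituent with glycosidic child")
            base_children[parent].append(child)
            if child in incoming:
                raise UnsupportedStructureError(
                    f"residue {child} has two parents (not a tree)"
                )
            incoming[child] = parent

    roots = [idx for idx in base_children if idx not in incoming]
    if len(roots) != 1:
        raise UnsupportedStructureError(
            f"expected one root residue, found {len(roots)} (disconnected or cyclic)"
        )

    def _build(idx: int, seen: set[int]) -> GlycanNode:
        if idx in seen:
            raise UnsupportedStructureError("cyclic GlycoCT linkage")
        seen.add(idx)
        symbol = _classify_glycoct(residues[idx][1], frozenset(substituents[idx]))
        node = GlycanNode(MONOSACCHARIDES[symbol])
        for child in sorted(base_children[idx]):
            node.add(_build(child, seen))
        return node

    seen: set[int] = set()
    tree = GlycanTree(_build(roots[0], seen))
    if len(seen) != len(base_children):
        raise UnsupportedStructureError("disconnected GlycoCT residues")
    return tree


def to_glycoct(tree: GlycanTree) -> str:
    """Serialize a tree back to GlycoCT condensed (topology only).

    Linkage positions are emitted as unknown (``-1``/``?``-free numeric
    placeholders) since the model does not track them.
    """
    res_lines: list[str] = []
    lin_lines: list[str] = []
    counter = itertools.count(1)
    link_counter = itertools.count(1)

    base_desc = {
        "Hex": ("x-xxx-HEX-1:5", None),
        "HexNAc": ("x-xxx-HEX-1:5", "n-acetyl"),
        "Fuc": ("x-xxx-HEX-1:5|6:d", None),
        "NeuAc": ("x-xxx-NON-2:6|1:a|2:keto|3:d", "n-acetyl"),
        "NeuGc": ("x-xxx-NON-2:6|1:a|2:keto|3:d", "n-glycolyl"),
        "Xyl": ("x-xxx-PEN-1:5", None),
    }

    def _emit(node: GlycanNode, parent_idx: int | None) -> None:
        sym = node.monosaccharide.symbol
        if sym not in base_desc:
            raise UnsupportedStructureError(f"no GlycoCT encoding for {sym}")
        desc, sub = base_desc[sym]
        idx = next(counter)
        res_lines.append(f"{idx}b:{desc}")
        if parent_idx is not None:
            lin_lines.append(f"{next(link_counter)}:{parent_idx}o(1+1){idx}d")
        if sub is not None:
            sidx = next(counter)
            res_lines.append(f"{sidx}s:{sub}")
            lin_lines.append(f"{next(link_counter)}:{idx}d(2+1){sidx}n")
        for child in node.children:
            _emit(child, idx)

    _emit(tree.root, None)
    out = ["RES", *res_lines]
    if lin_lines:
        out += ["LIN", *lin_lines]
    return "\n".join(out)


# --------------------------------------------------------------------------
# WURCS 2.0 subset
# --------------------------------------------------------------------------

_WURCS_HEAD = re.compile(
    r"^WURCS=2\.0/(\d+),(\d+),(\d+)/((?:\[[^\]]*\])+)/([0-9\-]+)/(.*)$"
)


def _classify_wurcs(descriptor: str) -> str:
    """Map a WURCS unique-residue descriptor to a table symbol.

    Classification uses the skeleton code length (carbon count), a terminal
    ``m`` (deoxy) and the N-acyl substituents ``NCC/3=O`` (acetyl) /
    ``NCCO/3=O`` (glycolyl); anything else is outside the subset.
    """
    fields = descriptor.split("_")
    skeleton = fields[0].split("-")[0]
    subs = [f for f in fields[1:] if "*" in f]
    n_acetyl = any(s.endswith("*NCC/3=O") for s in subs)
    n_glycolyl = any(s.endswith("*NCCO/3=O") for s in subs)
    other_subs = [s for s in subs if not (s.endswith("*NCC/3=O") or s.endswith("*NCCO/3=O"))]
    carbons = len(skeleton)
    if other_subs:
        raise UnsupportedStructureError(
            f"unmappable WURCS substituent in {descriptor!r}"
        )
    if carbons == 9:
        if n_glycolyl:
            return "NeuGc"
        if n_acetyl:
            return "NeuAc"
    elif carbons == 6:
        if skeleton.endswith("m"):
            return "Fuc"
        if skeleton.endswith("h"):
            return "HexNAc" if n_acetyl else "Hex"
    elif carbons == 5 and skeleton.endswith("h"):
        return "Xyl"
    raise UnsupportedStructureError(f"unmappable WURCS residue {descriptor!r}")


def _wurcs_letter_index(letter: str) -> int:
    if not ("a" <= letter <= "z"):
        raise UnsupportedStructureError(f"WURCS residue label {letter!r} not supported")
    return ord(letter) - ord("a") + 1


def parse_wurcs(text: str) -> GlycanTree:
    """Parse a WURCS 2.0 string with a definite tree topology.

    The first residue in the sequence section is taken as the reducing end
    (WURCS orders residues from the reducing end), and link tokens are
    oriented away from it, so either donor/acceptor order in the LIN section
    yields the same tree. Ambiguous or repeating structures (``?``, ``|``,
    ``{``/``}``, ``*`` in the link section) raise.
    """
    text = text.strip()
    m = _WURCS_HEAD.match(text)
    if not m:
        raise FormatError(f"not a WURCS=2.0 string: {text[:40]!r}")
    n_unique, n_res, n_lin = (int(m.group(i)) for i in (1, 2, 3))
    uniques = re.findall(r"\[([^\]]*)\]", m.group(4))
    if len(uniques) != n_unique:
        raise FormatError("WURCS unique-residue count mismatch")
    symbols = [_classify_wurcs(u) for u in uniques]
    seq = m.group(5).split("-")
    if len(seq) != n_res:
        raise FormatError("WURCS residue count mismatch")
    try:
        residue_symbols = [symbols[int(tok) - 1] for tok in seq]
    except (ValueError, IndexError):
        raise FormatError(f"bad WURCS sequence section {m.group(5)!r}") from None

    lin_section = m.group(6)
    for bad in ("?", "|", "{", "}", "*"):
        if bad in lin_section:
            raise UnsupportedStructureError(
                f"ambiguous WURCS linkage segment {lin_section!r}"
            )
    adjacency: dict[int, set[int]] = {i: set() for i in range(1, n_res + 1)}
    n_edges = 0
    if lin_section:
        for token in lin_section.split("_"):
            ends = re.findall(r"([a-zA-Z])(\d+)", token)
            if len(ends) != 2:
                raise UnsupportedStructureError(f"bad WURCS link token {token!r}")
            u = _wurcs_letter_index(ends[0][0])
            v = _wurcs_letter_index(ends[1][0])
            if u == v or not (1 <= u <= n_res and 1 <= v <= n_res):
                raise FormatError(f"WURCS link {token!r} references bad residues")
            adjacency[u].add(v)
            adjacency[v].add(u)
            n_edges += 1
    if n_edges != n_lin:
        raise FormatError("WURCS linkage count mismatch")
    if n_edges != n_res - 1:
        raise UnsupportedStructureError("WURCS topology is not a tree")

    nodes = {i: GlycanNode(MONOSACCHARIDES[residue_symbols[i - 1]]) for i in adjacency}
    visited = {1}
    queue = [1]
    while queue:
        current = queue.pop(0)
        for nbr in sorted(adjacency[current]):
            if nbr not in visited:
                visited.add(nbr)
                nodes[current].add(nodes[nbr])
                queue.append(nbr)
    if len(visited) != n_res:
        raise UnsupportedStructureError("disconnected WURCS topology")
    return GlycanTree(nodes[1])


def parse_glycan(text: str) -> tuple[GlycanTree | None, GlycanComposition]:
    """Dispatch on the leading token: WURCS, GlycoCT, or composition string.

    Returns ``(tree, composition)``; the tree is ``None`` when only a
    composition was given.
    """
    stripped = text.strip()
    if stripped.startswith("WURCS"):
        tree = parse_wurcs(stripped)
        return tree, tree.composition()
    if stripped.startswith("RES"):
        tree = parse_glycoct(stripped)
        return tree, tree.composition()
    return None, parse_composition(stripped)
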