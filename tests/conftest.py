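"""Shared fixtures: reference mass tables, glycan trees, brute-force oracles.

The oracle helpers here deliberately avoid the package's own enumeration and
mass code paths: fragment masses are recomputed from an independently
published residue-mass table, and glycan fragment sets come from exhaustive
subset enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import glycoplot as gp
from glycoplot.glycan import MONOSACCHARIDES, GlycanNode, GlycanTree

# Published monoisotopic residue masses (independent of pyteomics).
ORACLE_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.010565
ORACLE_PROTON = 1.0072765
ORACLE_NH3 = 17.026549
ORACLE_H = 1.0078250


def oracle_by_masses(sequence: str, mod_masses: dict[int, float] | None = None):
    """Independent b/y neutral masses for each cleavage (1-based positions)."""
    mods = mod_masses or {}
    n = len(sequence)
    b, y = {}, {}
    for i in range(1, n):
        b[i] = sum(ORACLE_RESIDUE_MASS[c] for c in sequence[:i]) + sum(
            m for p, m in mods.items() if p <= i
        )
        y[n - i] = (
            sum(ORACLE_RESIDUE_MASS[c] for c in sequence[i:])
            + sum(m for p, m in mods.items() if p > i)
            + ORACLE_WATER
        )
    return b, y


def comp_key(comp) -> frozenset:
    """Composition as an order-free hashable key."""
    return frozenset(dict(comp).items())


def brute_force_Y(tree: GlycanTree) -> set[frozenset]:
    """All root-containing connected subtree compositions, by 2^|V| subsets.

    In a rooted tree a vertex subset induces a connected subgraph containing
    the root iff it contains the root and is closed under taking parents.
    """
    nodes = list(tree.nodes())
    parent_index = {id(nodes[0]): None}
    for node in nodes:
        for child in node.children:
            parent_index[id(child)] = id(node)
    index_of = {id(node): k for k, node in enumerate(nodes)}
    out = {frozenset()}
    for mask in range(1, 2 ** len(nodes)):
        if not mask & 1:  # node 0 is the root (preorder)
            continue
        chosen = [k for k in range(len(nodes)) if mask >> k & 1]
        ok = all(
            parent_index[id(nodes[k])] is None
            or index_of[parent_index[id(nodes[k])]] in chosen
            for k in chosen
        )
        if not ok:
            continue
        counts: dict[str, int] = {}
        for k in chosen:
            sym = nodes[k].monosaccharide.symbol
            counts[sym] = counts.get(sym, 0) + 1
        out.add(frozenset(counts.items()))
    return out


def brute_force_B(tree: GlycanTree) -> set[frozenset]:
    """Per-node descendant-closure compositions."""

    def closure(node: GlycanNode) -> dict[str, int]:
        counts = {node.monosaccharide.symbol: 1}
        for child in node.children:
            for sym, c in closure(child).items():
                counts[sym] = counts.get(sym, 0) + c
        return counts

    return {frozenset(closure(node).items()) for node in tree.nodes()}


def random_tree(rng: np.random.Generator, max_nodes: int = 12) -> GlycanTree:
    """Uniform random recursive tree with random monosaccharide labels."""
    symbols = list(MONOSACCHARIDES)
    n = int(rng.integers(1, max_nodes + 1))
    nodes = [GlycanNode(MONOSACCHARIDES[symbols[rng.integers(len(symbols))]])]
    for k in range(1, n):
        parent = nodes[int(rng.integers(0, k))]
        child = GlycanNode(MONOSACCHARIDES[symbols[rng.integers(len(symbols))]])
        parent.add(child)
        nodes.append(child)
    return GlycanTree(nodes[0])


def random_peptide(rng: np.random.Generator, min_len: int = 5, max_len: int = 25) -> str:
    letters = list(ORACLE_RESIDUE_MASS)
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(letters[int(rng.integers(len(letters)))] for _ in range(n))


@pytest.fixture
def registry():
    return gp.default_registry()


@pytest.fixture
def biantennary_tree() -> GlycanTree:
    """Hex(4)HexNAc(4)NeuAc(1)Fuc(1) core-fucosylated biantennary structure."""
    return gp.biantennary_sialofucosylated()


@pytest.fixture
def core_tree() -> GlycanTree:
    return gp.nglycan_core()


@pytest.fixture
def phosphopeptide_s6(registry) -> gp.Peptide:
    return gp.Peptide("GNAEGSSDEEGKLVIDEPAK", ((6, registry["Phospho"]),))


@pytest.fixture
def glycopeptide_synth(biantennary_tree):
    spec = gp.SynthSpec(
        peptide=gp.Peptide("TPASDPHGDNLTYSVFYTK"),
        glycan_tree=biantennary_tree,
        precursor_charge=3,
        fraction=1.0,
        seed=7,
    )
    return gp.synth_spectrum(spec)
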