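"""881-bit substructure-key fingerprint definition table.

The layout follows the public PubChem/CACTVS substructure-key
architecture: seven sections occupying fixed bit ranges of an 881-bit
vector.

========  =========  ================================================
section   bit range  content
========  =========  ================================================
1         0-114      hierarchic element counts (count-type keys)
2         115-262    ring counts by size / saturation / heteroatoms
3         263-326    element-pair bonds
4         327-415    atom neighborhoods, any/aromatic bonds
5         416-459    atom neighborhoods with explicit bond orders
6         460-712    simple substructure SMARTS
7         713-880    ring-context / complex substructure SMARTS
========  =========  ================================================

Count-type keys (section 1 and the ring-count keys of section 2 when the
count threshold exceeds the matched ring multiplicity) have no meaningful
atom provenance and are reported with empty atom sets; pattern-type keys
carry the atoms of every match. Positions in sections 4-7 whose public
definition could not be reproduced offline are reserved and never set;
the fingerprint length and section boundaries are unaffected.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

N_BITS = 881

SECTION_BOUNDS = {
    "element_counts": (0, 115),
    "rings": (115, 263),
    "atom_pairs": (263, 327),
    "neighbors_simple": (327, 416),
    "neighbors_detailed": (416, 460),
    "smarts_simple": (460, 713),
    "smarts_complex": (713, 881),
}

# --------------------------------------------------------------------------
# section 1: element counts, (threshold, element symbol) per bit 0..114
# --------------------------------------------------------------------------

ELEMENT_COUNT_KEYS: list[tuple[int, str]] = [
    (4, "H"), (8, "H"), (16, "H"), (32, "H"),
    (1, "Li"), (2, "Li"),
    (1, "B"), (2, "B"), (4, "B"),
    (2, "C"), (4, "C"), (8, "C"), (16, "C"), (32, "C"),
    (1, "N"), (2, "N"), (4, "N"), (8, "N"),
    (1, "O"), (2, "O"), (4, "O"), (8, "O"), (16, "O"),
    (1, "F"), (2, "F"), (4, "F"),
    (1, "Na"), (2, "Na"),
    (1, "Si"), (2, "Si"),
    (1, "P"), (2, "P"), (4, "P"),
    (1, "S"), (2, "S"), (4, "S"), (8, "S"),
    (1, "Cl"), (2, "Cl"), (4, "Cl"), (8, "Cl"),
    (1, "K"), (2, "K"),
    (1, "Br"), (2, "Br"), (4, "Br"),
    (1, "I"), (2, "I"), (4, "I"),
    (1, "Be"), (1, "Mg"), (1, "Ca"), (1, "Sc"), (1, "Ti"), (1, "V"),
    (1, "Cr"), (1, "Mn"), (1, "Fe"), (1, "Co"), (1, "Ni"), (1, "Cu"),
    (1, "Zn"), (1, "Ga"), (1, "Ge"), (1, "As"), (1, "Se"), (1, "Kr"),
    (1, "Rb"), (1, "Sr"), (1, "Y"), (1, "Zr"), (1, "Nb"), (1, "Mo"),
    (1, "Ru"), (1, "Rh"), (1, "Pd"), (1, "Ag"), (1, "Cd"), (1, "In"),
    (1, "Sn"), (1, "Sb"), (1, "Te"), (1, "Xe"), (1, "Cs"), (1, "Ba"),
    (1, "Lu"), (1, "Hf"), (1, "Ta"), (1, "W"), (1, "Re"), (1, "Os"),
    (1, "Ir"), (1, "Pt"), (1, "Au"), (1, "Hg"), (1, "Tl"), (1, "Pb"),
    (1, "Bi"), (1, "La"), (1, "Ce"), (1, "Pr"), (1, "Nd"), (1, "Pm"),
    (1, "Sm"), (1, "Eu"), (1, "Gd"), (1, "Tb"), (1, "Dy"), (1, "Ho"),
    (1, "Er"), (1, "Tm"), (1, "Yb"), (1, "Tc"), (1, "U"), (1, "Al"),
]
assert len(ELEMENT_COUNT_KEYS) == 115

# --------------------------------------------------------------------------
# section 2: ring-count keys. For each ring size, seven predicates are
# tested at each count threshold: any ring; saturated-or-aromatic
# carbon-only; saturated-or-aromatic nitrogen-containing;
# saturated-or-aromatic heteroatom-containing; unsaturated non-aromatic
# carbon-only; unsaturated non-aromatic nitrogen-containing; unsaturated
# non-aromatic heteroatom-containing. The count ladder depends on size.
# The section closes with aromatic / hetero-aromatic ring-count keys.
# --------------------------------------------------------------------------

RING_SIZE_COUNTS = {3: 2, 4: 2, 5: 5, 6: 5, 7: 2, 8: 2, 9: 1, 10: 1}
RING_PREDICATES = (
    "any",
    "sat_or_arom_carbon_only",
    "sat_or_arom_nitrogen",
    "sat_or_arom_heteroatom",
    "unsat_carbon_only",
    "unsat_nitrogen",
    "unsat_heteroatom",
)
AROMATIC_RING_COUNTS = 4  # >=1..>=4 aromatic rings and hetero-aromatic rings


def _ring_section_layout() -> list[tuple[int, int, str]]:
    """(size, count_threshold, predicate) per bit, then aromatic keys."""
    layout: list[tuple[int, int, str]] = []
    for size in sorted(RING_SIZE_COUNTS):
        for count in range(1, RING_SIZE_COUNTS[size] + 1):
            for pred in RING_PREDICATES:
                layout.append((size, count, pred))
    return layout


RING_KEYS = _ring_section_layout()
assert len(RING_KEYS) + 2 * AROMATIC_RING_COUNTS == 148

# --------------------------------------------------------------------------
# section 3: element-pair bonds ("~" = any bond). A trailing "H" partner
# means the first element carrying at least one hydrogen.
# --------------------------------------------------------------------------

ATOM_PAIR_KEYS: list[tuple[str, str]] = [
    ("Li", "H"), ("Li", "Li"), ("Li", "B"), ("Li", "C"), ("Li", "O"),
    ("Li", "F"), ("Li", "P"), ("Li", "S"), ("Li", "Cl"),
    ("B", "H"), ("B", "B"), ("B", "C"), ("B", "N"), ("B", "O"), ("B", "F"),
    ("B", "Si"), ("B", "P"), ("B", "S"), ("B", "Cl"), ("B", "Br"),
    ("C", "H"), ("C", "C"), ("C", "N"), ("C", "O"), ("C", "F"),
    ("C", "Na"), ("C", "Mg"), ("C", "Al"), ("C", "Si"), ("C", "P"),
    ("C", "S"), ("C", "Cl"), ("C", "As"), ("C", "Se"), ("C", "Br"),
    ("C", "I"),
    ("N", "H"), ("N", "N"), ("N", "O"), ("N", "F"), ("N", "Si"),
    ("N", "P"), ("N", "S"), ("N", "Cl"), ("N", "Br"),
    ("O", "H"), ("O", "O"), ("O", "Mg"), ("O", "Na"), ("O", "Al"),
    ("O", "Si"), ("O", "P"), ("O", "K"),
    ("F", "P"), ("F", "S"),
    ("Si", "H"), ("Si", "Si"), ("Si", "Cl"),
    ("P", "H"), ("P", "P"),
    ("As", "H"), ("As", "As"),
]
# pad to the 64-bit section width with reserved (never-set) positions
ATOM_PAIR_SECTION_WIDTH = 64
assert len(ATOM_PAIR_KEYS) <= ATOM_PAIR_SECTION_WIDTH

# --------------------------------------------------------------------------
# sections 4-7: SMARTS-evaluable keys. Specified as (center, [(bond,
# neighbor), ...]) tuples for the neighborhood sections and as plain
# SMARTS for sections 6-7. "~"=any bond, ":"=aromatic, "-"/"="/"#"
# explicit orders; neighbor "H" counts hydrogens on the center.
# --------------------------------------------------------------------------

NEIGHBOR_SIMPLE_KEYS: list[tuple[str, list[tuple[str, str]]]] = [
    ("C", [("~", "Br"), ("~", "C")]),
    ("C", [("~", "Br"), ("~", "C"), ("~", "C")]),
    ("C", [("~", "Br"), ("~", "H")]),
    ("C", [("~", "Br"), (":", "C")]),
    ("C", [("~", "Br"), (":", "N")]),
    ("C", [("~", "C"), ("~", "C")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "C")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "C"), ("~", "C")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "C"), ("~", "H")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "C"), ("~", "N")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "C"), ("~", "O")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "H"), ("~", "N")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "H"), ("~", "O")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "N")]),
    ("C", [("~", "C"), ("~", "C"), ("~", "O")]),
    ("C", [("~", "C"), ("~", "Cl")]),
    ("C", [("~", "C"), ("~", "Cl"), ("~", "H")]),
    ("C", [("~", "C"), ("~", "H")]),
    ("C", [("~", "C"), ("~", "H"), ("~", "N")]),
    ("C", [("~", "C"), ("~", "H"), ("~", "O")]),
    ("C", [("~", "C"), ("~", "H"), ("~", "O"), ("~", "O")]),
    ("C", [("~", "C"), ("~", "H"), ("~", "P")]),
    ("C", [("~", "C"), ("~", "H"), ("~", "S")]),
    ("C", [("~", "C"), ("~", "I")]),
    ("C", [("~", "C"), ("~", "N")]),
    ("C", [("~", "C"), ("~", "O")]),
    ("C", [("~", "C"), ("~", "S")]),
    ("C", [("~", "C"), ("~", "Si")]),
    ("C", [("~", "C"), (":", "C")]),
    ("C", [("~", "C"), (":", "C"), (":", "C")]),
    ("C", [("~", "C"), (":", "C"), (":", "N")]),
    ("C", [("~", "C"), (":", "N")]),
    ("C", [("~", "C"), (":", "N"), (":", "N")]),
    ("C", [("~", "Cl"), ("~", "Cl")]),
    ("C", [("~", "Cl"), ("~", "H")]),
    ("C", [("~", "Cl"), (":", "C")]),
    ("C", [("~", "F"), ("~", "F")]),
    ("C", [("~", "F"), (":", "C")]),
    ("C", [("~", "H"), ("~", "N")]),
    ("C", [("~", "H"), ("~", "O")]),
    ("C", [("~", "H"), ("~", "O"), ("~", "O")]),
    ("C", [("~", "H"), ("~", "S")]),
    ("C", [("~", "H"), ("~", "Si")]),
    ("C", [("~", "H"), (":", "C")]),
    ("C", [("~", "H"), (":", "C"), (":", "C")]),
    ("C", [("~", "H"), (":", "C"), (":", "N")]),
    ("C", [("~", "H"), (":", "N")]),
    ("C", [("~", "H"), ("~", "H"), ("~", "H")]),
    ("C", [("~", "N"), ("~", "N")]),
    ("C", [("~", "N"), (":", "C")]),
    ("C", [("~", "N"), (":", "C"), (":", "C")]),
    ("C", [("~", "N"), (":", "C"), (":", "N")]),
    ("C", [("~", "N"), (":", "N")]),
    ("C", [("~", "O"), ("~", "O")]),
    ("C", [("~", "O"), (":", "C")]),
    ("C", [("~", "O"), (":", "C"), (":", "C")]),
    ("C", [("~", "S"), (":", "C")]),
    ("C", [(":", "C"), (":", "C")]),
    ("C", [(":", "C"), (":", "C"), (":", "C")]),
    ("C", [(":", "C"), (":", "C"), (":", "N")]),
    ("C", [(":", "C"), (":", "N")]),
    ("C", [(":", "C"), (":", "N"), (":", "N")]),
    ("C", [(":", "N"), (":", "N")]),
    ("N", [("~", "C"), ("~", "C")]),
    ("N", [("~", "C"), ("~", "C"), ("~", "C")]),
    ("N", [("~", "C"), ("~", "C"), ("~", "H")]),
    ("N", [("~", "C"), ("~", "H")]),
    ("N", [("~", "C"), ("~", "H"), ("~", "N")]),
    ("N", [("~", "C"), ("~", "O")]),
    ("N", [("~", "C"), (":", "C")]),
    ("N", [("~", "C"), (":", "C"), (":", "C")]),
    ("N", [("~", "H"), ("~", "N")]),
    ("N", [("~", "H"), (":", "C")]),
    ("N", [("~", "H"), (":", "C"), (":", "C")]),
    ("N", [("~", "O"), ("~", "O")]),
    ("N", [("~", "O"), (":", "O")]),
    ("N", [(":", "C"), (":", "C")]),
    ("N", [(":", "C"), (":", "C"), (":", "C")]),
    ("O", [("~", "C"), ("~", "C")]),
    ("O", [("~", "C"), ("~", "H")]),
    ("O", [("~", "C"), ("~", "P")]),
    ("O", [("~", "H"), ("~", "S")]),
    ("O", [(":", "C"), (":", "C")]),
    ("P", [("~", "C"), ("~", "C")]),
    ("P", [("~", "O"), ("~", "O")]),
    ("S", [("~", "C"), ("~", "C")]),
    ("S", [("~", "C"), ("~", "H")]),
    ("S", [("~", "C"), ("~", "O")]),
    ("Si", [("~", "C"), ("~", "C")]),
]
NEIGHBOR_SIMPLE_WIDTH = 89
assert len(NEIGHBOR_SIMPLE_KEYS) <= NEIGHBOR_SIMPLE_WIDTH

NEIGHBOR_DETAILED_KEYS: list[tuple[str, list[tuple[str, str]]]] = [
    ("C", [("-", "C"), ("=", "C")]),
    ("C", [("-", "C"), ("=", "N")]),
    ("C", [("-", "C"), ("=", "O")]),
    ("C", [("-", "Cl"), ("=", "O")]),
    ("C", [("-", "H"), ("=", "C")]),
    ("C", [("-", "H"), ("=", "N")]),
    ("C", [("-", "H"), ("=", "O")]),
    ("C", [("-", "N"), ("=", "C")]),
    ("C", [("-", "N"), ("=", "N")]),
    ("C", [("-", "N"), ("=", "O")]),
    ("C", [("-", "O"), ("=", "C")]),
    ("C", [("-", "O"), ("=", "N")]),
    ("C", [("-", "O"), ("=", "O")]),
    ("C", [("-", "S"), ("=", "O")]),
    ("C", [("-", "S"), ("=", "S")]),
    ("C", [("-", "C"), ("#", "C")]),
    ("C", [("-", "C"), ("#", "N")]),
    ("C", [("-", "H"), ("#", "C")]),
    ("C", [("-", "H"), ("#", "N")]),
    ("C", [("=", "C"), ("=", "C")]),
    ("N", [("-", "C"), ("=", "C")]),
    ("N", [("-", "C"), ("=", "N")]),
    ("N", [("-", "C"), ("=", "O")]),
    ("N", [("-", "H"), ("=", "C")]),
    ("N", [("-", "H"), ("=", "N")]),
    ("N", [("-", "O"), ("=", "O")]),
    ("N", [("=", "C"), ("-", "O")]),
    ("N", [("-", "N"), ("=", "C")]),
    ("O", [("-", "C"), ("-", "C")]),
    ("O", [("-", "C"), ("-", "H")]),
    ("O", [("-", "C"), ("-", "N")]),
    ("O", [("-", "C"), ("-", "P")]),
    ("O", [("-", "C"), ("-", "S")]),
    ("O", [("-", "N"), ("-", "N")]),
    ("P", [("-", "O"), ("=", "O")]),
    ("P", [("-", "C"), ("=", "O")]),
    ("P", [("-", "N"), ("=", "O")]),
    ("S", [("-", "C"), ("=", "O")]),
    ("S", [("-", "O"), ("=", "O")]),
    ("S", [("-", "N"), ("=", "O")]),
    ("S", [("=", "O"), ("=", "O")]),
    ("S", [("-", "C"), ("-", "C")]),
    ("S", [("-", "C"), ("-", "H")]),
    ("S", [("-", "C"), ("-", "N")]),
]
NEIGHBOR_DETAILED_WIDTH = 44
assert len(NEIGHBOR_DETAILED_KEYS) <= NEIGHBOR_DETAILED_WIDTH

SMARTS_SIMPLE_KEYS: list[str] = [
    # two-atom bonded fragments, explicit order
    "[#6]-[#6]", "[#6]=[#6]", "[#6]#[#6]", "[#6]:[#6]",
    "[#6]-[#7]", "[#6]=[#7]", "[#6]#[#7]", "[#6]:[#7]",
    "[#6]-[#8]", "[#6]=[#8]", "[#6]:[#8]",
    "[#6]-[#16]", "[#6]=[#16]", "[#6]:[#16]",
    "[#6]-[#15]", "[#6]-[#14]",
    "[#6]-[#9]", "[#6]-[#17]", "[#6]-[#35]", "[#6]-[#53]",
    "[#7]-[#7]", "[#7]=[#7]", "[#7]:[#7]",
    "[#7]-[#8]", "[#7]=[#8]", "[#7]:[#8]",
    "[#7]-[#16]", "[#8]-[#8]", "[#8]-[#15]", "[#8]=[#15]",
    "[#8]-[#16]", "[#8]=[#16]", "[#16]-[#16]", "[#15]=[#16]",
    # three-atom chains
    "[#6]-[#6]-[#6]", "[#6]-[#6]=[#6]", "[#6]-[#6]#[#6]",
    "[#6]=[#6]-[#6]=[#6]", "[#6]-[#6]-[#7]", "[#6]-[#7]-[#6]",
    "[#6]-[#6]-[#8]", "[#6]-[#8]-[#6]", "[#6]-[#6]-[#16]",
    "[#6]-[#16]-[#6]", "[#6]-[#7]-[#7]", "[#6]-[#8]-[#8]",
    "[#8]=[#6]-[#6]", "[#8]=[#6]-[#7]", "[#8]=[#6]-[#8]",
    "[#7]-[#6]=[#7]", "[#7]-[#6]=[#8]", "[#7]-[#6]=[#16]",
    "[#7]=[#6]-[#7]", "[#8]-[#6]=[#8]", "[#8]-[#6]=[#7]",
    "[#16]-[#6]=[#7]", "[#8]=[#16]=[#8]", "[#8]=[#7]-[#8]",
    "[#7]#[#6]-[#6]", "[#6]-[#6](-[#6])-[#6]",
    "[#6]-[#6](-[#7])-[#6]", "[#6]-[#6](-[#8])-[#6]",
    "[#6]-[#6](=[#8])-[#7]", "[#6]-[#6](=[#8])-[#8]",
    "[#6]-[#7](-[#6])-[#6]", "[#6]-[#8]-[#6]=[#8]",
    "[#6]-[#7]-[#6]=[#8]", "[#7]-[#6](=[#8])-[#7]",
    "[#8]=[#6]-[#6]=[#8]", "[#6]=[#6]-[#6]=[#8]",
    "[#6]-[#6]-[#6]-[#6]", "[#6]-[#6]-[#6]-[#7]",
    "[#6]-[#6]-[#6]-[#8]", "[#6]-[#6]-[#8]-[#6]",
    "[#6]-[#6]-[#7]-[#6]", "[#8]-[#6]-[#6]-[#8]",
    "[#8]-[#6]-[#6]-[#7]", "[#7]-[#6]-[#6]-[#7]",
    "[#9]-[#6]-[#6]", "[#17]-[#6]-[#6]", "[#35]-[#6]-[#6]",
    "[#9]-[#6](-[#9])-[#9]", "[#6]-[#6]=[#6]-[#6]",
    "[#6]#[#6]-[#6]=[#6]",
    # hydrogen-qualified centers
    "[#6;!H0]-[#8;!H0]", "[#6;!H0]-[#7;!H0]", "[#7;!H0]-[#6]=[#8]",
    "[#8;!H0]-[#6]=[#8]", "[#16;!H0]-[#6]", "[#7;!H0]-[#7]",
]
SMARTS_SIMPLE_WIDTH = 253
assert len(SMARTS_SIMPLE_KEYS) <= SMARTS_SIMPLE_WIDTH

SMARTS_COMPLEX_KEYS: list[str] = [
    # carbocyclic aromatic ring and substituted variants
    "c1ccccc1",
    "[#6]-c1ccccc1", "[#7]-c1ccccc1", "[#8]-c1ccccc1", "[#16]-c1ccccc1",
    "[#9]-c1ccccc1", "[#17]-c1ccccc1", "[#35]-c1ccccc1", "[#53]-c1ccccc1",
    # disubstituted benzenes (ortho / meta / para) over C, N, O, Cl
    "[#6]-c1ccccc1-[#6]", "[#6]-c1cccc(-[#6])c1", "[#6]-c1ccc(-[#6])cc1",
    "[#7]-c1ccccc1-[#6]", "[#7]-c1cccc(-[#6])c1", "[#7]-c1ccc(-[#6])cc1",
    "[#8]-c1ccccc1-[#6]", "[#8]-c1cccc(-[#6])c1", "[#8]-c1ccc(-[#6])cc1",
    "[#17]-c1ccccc1-[#6]", "[#17]-c1cccc(-[#6])c1", "[#17]-c1ccc(-[#6])cc1",
    "[#7]-c1ccccc1-[#7]", "[#7]-c1cccc(-[#7])c1", "[#7]-c1ccc(-[#7])cc1",
    "[#8]-c1ccccc1-[#8]", "[#8]-c1cccc(-[#8])c1", "[#8]-c1ccc(-[#8])cc1",
    # aromatic heterocycles
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1cncnc1", "c1ccnnc1", "c1cnccn1",
    "c1cnc[nH]1", "c1cnn[cH]1", "c1ocnc1", "c1scnc1", "c1ocnn1",
    # fused aromatic systems
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1",
    "c1ccc2sccc2c1", "c1ccc2ncccc12", "c1ccc2[nH]cnc2c1",
    "c1ccc2nc[nH]c2c1", "c1cc2cc[nH]c2nc1",
    # saturated heterocycles
    "C1CCNCC1", "C1CCOCC1", "C1CCNC1", "C1CCOC1", "C1CNCCN1",
    "C1COCCN1", "C1CCSC1",
    # carbonyl-in-ring / lactam-like
    "O=C1CCCCC1", "O=C1CCCN1", "O=C1CCCO1", "O=C1NCCN1",
    # common pharmacophoric attachments on aromatics
    "O=C(-[#6])-c1ccccc1", "O=C(-[#7])-c1ccccc1", "O=C(-[#8])-c1ccccc1",
    "[#7]-[#6](=O)-c1ccccc1", "O=S(=O)(-[#7])-c1ccccc1",
    "[#6]-[#8]-c1ccccc1", "[#6]-[#7]-c1ccccc1", "[#6]-[#16]-c1ccccc1",
    "c1ccccc1-c1ccccc1", "c1ccccc1-[#6]-c1ccccc1",
    "c1ccccc1-[#7]-c1ccccc1", "c1ccccc1-[#8]-c1ccccc1",
]
SMARTS_COMPLEX_WIDTH = 168
assert len(SMARTS_COMPLEX_KEYS) <= SMARTS_COMPLEX_WIDTH


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


def _h_min_smarts(n: int) -> str:
    return ";".join(f"!H{i}" for i in range(n))


def neighborhood_smarts(center: str, neighbors: list[tuple[str, str]]) -> str:
    """Build a SMARTS for a center atom with the given bonded neighbors."""
    n_h = sum(1 for _, nbr in neighbors if nbr == "H")
    others = [(bond, nbr) for bond, nbr in neighbors if nbr != "H"]
    z = Chem.GetPeriodicTable().GetAtomicNumber(center)
    h_clause = f";{_h_min_smarts(n_h)}" if n_h else ""
    parts = [f"[#{z}{h_clause}]"]
    for bond, nbr in others:
        zn = Chem.GetPeriodicTable().GetAtomicNumber(nbr)
        parts.append(f"({bond}[#{zn}])")
    return "".join(parts)


@lru_cache(maxsize=1)
def _compiled_keys() -> dict[int, tuple[str, object]]:
    """bit index -> (kind, payload). Kinds: 'element_count', 'ring',
    'aromatic_rings', 'hetero_aromatic_rings', 'pattern'."""
    table: dict[int, tuple[str, object]] = {}
    bit = 0
    for threshold, element in ELEMENT_COUNT_KEYS:
        table[bit] = ("element_count", (threshold, element))
        bit += 1
    for size, count, pred in RING_KEYS:
        table[bit] = ("ring", (size, count, pred))
        bit += 1
    for count in range(1, AROMATIC_RING_COUNTS + 1):
        table[bit] = ("aromatic_rings", count)
        bit += 1
    for count in range(1, AROMATIC_RING_COUNTS + 1):
        table[bit] = ("hetero_aromatic_rings", count)
        bit += 1
    assert bit == SECTION_BOUNDS["atom_pairs"][0]

    for a, b in ATOM_PAIR_KEYS:
        if b == "H":
            z = Chem.GetPeriodicTable().GetAtomicNumber(a)
            smarts = f"[#{z};!H0]"
        else:
            za = Chem.GetPeriodicTable().GetAtomicNumber(a)
            zb = Chem.GetPeriodicTable().GetAtomicNumber(b)
            smarts = f"[#{za}]~[#{zb}]"
        table[bit] = ("pattern", Chem.MolFromSmarts(smarts))
        bit += 1
    bit = SECTION_BOUNDS["neighbors_simple"][0]

    for center, neighbors in NEIGHBOR_SIMPLE_KEYS:
        table[bit] = ("pattern", Chem.MolFromSmarts(neighborhood_smarts(center, neighbors)))
        bit += 1
    bit = SECTION_BOUNDS["neighbors_detailed"][0]

    for center, neighbors in NEIGHBOR_DETAILED_KEYS:
        table[bit] = ("pattern", Chem.MolFromSmarts(neighborhood_smarts(center, neighbors)))
        bit += 1
    bit = SECTION_BOUNDS["smarts_simple"][0]

    for smarts in SMARTS_SIMPLE_KEYS:
        table[bit] = ("pattern", Chem.MolFromSmarts(smarts))
        bit += 1
    bit = SECTION_BOUNDS["smarts_complex"][0]

    for smarts in SMARTS_COMPLEX_KEYS:
        table[bit] = ("pattern", Chem.MolFromSmarts(smarts))
        bit += 1
    assert bit <= N_BITS

    for key, (kind, payload) in table.items():
        if kind == "pattern" and payload is None:
            raise RuntimeError(f"unparsable SMARTS at bit {key}")
    return table


def _ring_matches(mol: Chem.Mol, size: int, pred: str) -> list[tuple[int, ...]]:
    out = []
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) != size:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        aromatic = all(a.GetIsAromatic() for a in atoms)
        bonds = [
            mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % size])
            for i in range(size)
        ]
        saturated = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
        carbon_only = all(a.GetAtomicNum() == 6 for a in atoms)
        has_nitrogen = any(a.GetAtomicNum() == 7 for a in atoms)
        has_hetero = any(a.GetAtomicNum() != 6 for a in atoms)
        sat_or_arom = saturated or aromatic
        unsat = not saturated and not aromatic
        ok = {
            "any": True,
            "sat_or_arom_carbon_only": sat_or_arom and carbon_only,
            "sat_or_arom_nitrogen": sat_or_arom and has_nitrogen,
            "sat_or_arom_heteroatom": sat_or_arom and has_hetero,
            "unsat_carbon_only": unsat and carbon_only,
            "unsat_nitrogen": unsat and has_nitrogen,
            "unsat_heteroatom": unsat and has_hetero,
        }[pred]
        if ok:
            out.append(tuple(ring))
    return out


def evaluate(mol: Chem.Mol) -> tuple[list[int], dict[int, list[tuple[int, ...]]]]:
    """Evaluate all keys on a molecule.

    Returns (set bit indices, bit -> list of matched atom tuples).
    Count-type keys appear with an empty match list.
    """
    bits: list[int] = []
    provenance: dict[int, list[tuple[int, ...]]] = {}
    table = _compiled_keys()

    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()

    ri = mol.GetRingInfo()
    arom_rings = []
    hetero_arom_rings = []
    for ring in ri.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() for a in atoms):
            arom_rings.append(tuple(ring))
            if any(a.GetAtomicNum() != 6 for a in atoms):
                hetero_arom_rings.append(tuple(ring))

    for bit, (kind, payload) in table.items():
        if kind == "element_count":
            threshold, element = payload
            if counts.get(element, 0) >= threshold:
                bits.append(bit)
                provenance[bit] = []
        elif kind == "ring":
            size, count, pred = payload
            matches = _ring_matches(mol, size, pred)
            if len(matches) >= count:
                bits.append(bit)
                provenance[bit] = matches
        elif kind == "aromatic_rings":
            if len(arom_rings) >= payload:
                bits.append(bit)
                provenance[bit] = arom_rings
        elif kind == "hetero_aromatic_rings":
            if len(hetero_arom_rings) >= payload:
                bits.append(bit)
                provenance[bit] = hetero_arom_rings
        else:
            matches = mol.GetSubstructMatches(payload)
            if matches:
                bits.append(bit)
                provenance[bit] = [tuple(m) for m in matches]
    return bits, provenance
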