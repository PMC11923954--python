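"""An 881-bit substructure-key fingerprint in the PubChem layout.

PubChem's server-side CACTVS fingerprint is organised in sections: hierarchic
element counts, ring counts by size and composition, atom-pair bonds, and
SMARTS-defined substructure neighbourhoods, for 881 binary keys in total.
No installed cheminformatics library computes those exact keys, so this
module provides a *dialect* with the same length and sectional layout:

* positions 0-114   — hierarchic element counts,
* positions 115-262 — ring counts by size, saturation and composition,
* positions 263-326 — element-pair bonds,
* positions 327-880 — substructure SMARTS keys.

Keys are computed from the molecular graph, so equivalent SMILES spellings
give identical bits.  Positions whose official CACTVS definition is not
reproduced here are fixed at zero; the fingerprint is therefore NOT
bit-compatible with PubChem's server output, but it is deterministic,
binary, of the documented length, and structurally informative, which is
what downstream feature assembly and modelling rely on.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from rdkit import Chem

PUBCHEM_FP_LENGTH = 881

# ---- section 1: hierarchic element counts (positions 0-114) ---------------
# (atomic number, count thresholds); H thresholds count all hydrogens
# including implicit ones.
_ELEMENT_COUNT_KEYS: list[tuple[int, tuple[int, ...]]] = [
    (1, (4, 8, 16, 32)),        # H
    (3, (1, 2)),                # Li
    (4, (1,)),                  # Be
    (5, (1, 2, 4)),             # B
    (6, (2, 4, 8, 16, 32)),     # C
    (7, (1, 2, 4, 8)),          # N
    (8, (1, 2, 4, 8, 16)),      # O
    (9, (1, 2, 4)),             # F
    (11, (1, 2)),               # Na
    (12, (1,)),                 # Mg
    (13, (1,)),                 # Al
    (14, (1, 2)),               # Si
    (15, (1, 2, 4)),            # P
    (16, (1, 2, 4, 8)),         # S
    (17, (1, 2, 4, 8)),         # Cl
    (19, (1, 2)),               # K
    (20, (1,)),                 # Ca
    (35, (1, 2, 4)),            # Br
    (53, (1, 2, 4)),            # I
] + [
    (z, (1,))
    for z in (
        # one >=1 key per additional element, in atomic-number order
        2, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 36, 37,
        38, 39, 40, 41, 42, 44, 45, 46, 47, 48, 49, 50, 51, 52, 54, 55, 56,
        71, 72, 73, 74, 75, 76, 77, 78, 79, 80, 81, 82, 83, 92,
    )
]

_N_ELEMENT_BITS = 115

# ---- section 3: element-pair bonds (positions 263-326) ---------------------
_BOND_PAIR_SMARTS: list[str] = [
    "[#6]~[#6]", "[#6]~[#7]", "[#6]~[#8]", "[#6]~[#16]", "[#6]~[#15]",
    "[#6]~[#9]", "[#6]~[#17]", "[#6]~[#35]", "[#6]~[#53]", "[#6]~[#14]",
    "[#6]~[#5]", "[#7]~[#7]", "[#7]~[#8]", "[#7]~[#16]", "[#7]~[#15]",
    "[#8]~[#8]", "[#8]~[#16]", "[#8]~[#15]", "[#16]~[#16]", "[#15]~[#15]",
    "[#6]=[#6]", "[#6]#[#6]", "[#6]=[#7]", "[#6]#[#7]", "[#6]=[#8]",
    "[#6]=[#16]", "[#7]=[#7]", "[#7]=[#8]", "[#15]=[#8]", "[#16]=[#8]",
    "c:c", "c:n", "c:o", "c:s", "n:n", "n:o",
]

# ---- sections 4-7: substructure SMARTS keys (positions 327-880) ------------
_SUBSTRUCTURE_SMARTS: list[str] = [
    # oxygen functional groups
    "[OX2H]", "[OX2H][CX4]", "[OX2H]c", "[CX3]=[OX1]", "[CX3](=O)[OX2H1]",
    "[CX3](=O)[OX2][#6]", "[CX3H1]=O", "[CX3](=O)[#6]", "[OX2]([#6])[#6]",
    "[OX2](c)[#6]", "[OX2](c)c", "O=C-O-C=O",
    # nitrogen functional groups
    "[NX3;H2][CX4]", "[NX3;H1]([CX4])[CX4]", "[NX3]([CX4])([CX4])[CX4]",
    "[NX3][CX3]=[OX1]", "[NX3;H2][CX3]=[OX1]", "[CX3](=O)[NX3]",
    "[NX1]#[CX2]", "[NX3](=O)=O", "[NX2]=[NX2]", "[NX3;H2]c", "[nX2]",
    "[nX3;H1]", "[NX3][NX3]", "C=N-O", "[NX3][CX3](=[NX2])",
    # sulfur / phosphorus
    "[SX2H]", "[SX2]([#6])[#6]", "[SX4](=O)(=O)", "[SX4](=O)(=O)[NX3]",
    "[SX4](=O)(=O)[OX2H]", "[PX4](=O)", "[PX4](=O)([OX2])[OX2]",
    # halogens on carbon
    "[CX4][F]", "[CX4][Cl]", "[CX4][Br]", "[CX4][I]",
    "c[F]", "c[Cl]", "c[Br]", "c[I]", "[CX4]([F])[F]", "C(F)(F)F",
    # hydrocarbon environments
    "[CX4H3]", "[CX4H2]", "[CX4H1]", "[CX4H0]", "[CX3H2]=[CX3]",
    "[CX3H1]=[CX3H1]", "[CX2]#[CX2]", "[CX4]([CX4])([CX4])[CX4]",
    "[CX4]([CX4])([CX4])([CX4])[CX4]",
    # aromatic environments
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1cnccn1", "c1ccc2ccccc2c1", "cc(c)c", "c[CX4]", "c[CX3]=[OX1]",
    "c[NX3]", "c[OX2]", "c[SX2]", "cC=C", "c-c",
    # mixed two-bond neighbourhoods
    "O=C-C=O", "O=C-C-N", "O=C-C-O", "N-C-C-N", "N-C-C-O", "O-C-C-O",
    "C-O-C-C", "C-N-C-C", "C-S-C-C", "C=C-C=C", "C=C-C=O", "N-C=N",
    "O-C=N", "S-C=N", "C-C(=O)-C", "C-C(C)-C",
    # ring-attachment neighbourhoods
    "[R][CX4;!R]", "[R][NX3;!R]", "[R][OX2;!R]", "[R]=[OX1]",
    "[R][CX3;!R]=[OX1]", "[R;r5]", "[R;r6]", "[R;r7]",
    "[cR2]", "[CR2]", "[NR]", "[OR]", "[SR]", "[R]!@[R]",
]

_RING_SECTION_START = 115
_BOND_SECTION_START = 263
_SMARTS_SECTION_START = 327


@lru_cache(maxsize=512)
def _compiled(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:  # pragma: no cover - patterns are fixed and valid
        raise ValueError(f"bad SMARTS pattern: {smarts}")
    return patt


def _element_bits(mol: Chem.Mol, bits: np.ndarray) -> None:
    counts: dict[int, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        counts[atom.GetAtomicNum()] = counts.get(atom.GetAtomicNum(), 0) + 1
        n_h += atom.GetTotalNumHs()
    counts[1] = counts.get(1, 0) + n_h
    pos = 0
    for z, thresholds in _ELEMENT_COUNT_KEYS:
        for t in thresholds:
            if pos >= _N_ELEMENT_BITS:
                return
            if counts.get(z, 0) >= t:
                bits[pos] = 1
            pos += 1


def _ring_bits(mol: Chem.Mol, bits: np.ndarray) -> None:
    """7 keys per ring size 3..10, then aromatic-ring count keys."""
    ring_info = mol.GetRingInfo()
    rings = ring_info.AtomRings()
    by_size: dict[int, list[tuple[int, ...]]] = {}
    for ring in rings:
        by_size.setdefault(len(ring), []).append(ring)

    def ring_props(ring: tuple[int, ...]) -> tuple[bool, bool, bool, bool]:
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        carbon_only = all(a.GetAtomicNum() == 6 for a in atoms)
        has_n = any(a.GetAtomicNum() == 7 for a in atoms)
        hetero = any(a.GetAtomicNum() != 6 for a in atoms)
        bonds = []
        n_atoms = len(ring)
        for i in range(n_atoms):
            bonds.append(mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % n_atoms]))
        saturated = all(
            b.GetBondType() == Chem.BondType.SINGLE and not b.GetIsAromatic()
            for b in bonds
        )
        return carbon_only, has_n, hetero, saturated

    pos = _RING_SECTION_START
    for size in range(3, 11):
        members = by_size.get(size, [])
        props = [ring_props(r) for r in members]
        keys = [
            len(members) >= 1,
            len(members) >= 2,
            any(p[0] for p in props),          # carbon-only ring
            any(p[1] for p in props),          # nitrogen-containing ring
            any(p[2] for p in props),          # heteroatom ring
            any(p[3] for p in props),          # saturated ring
            any(not p[3] for p in props),      # unsaturated ring
        ]
        for k in keys:
            bits[pos] = int(k)
            pos += 1

    n_aromatic = 0
    n_hetero_aromatic = 0
    for ring in rings:
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() for a in atoms):
            n_aromatic += 1
            if any(a.GetAtomicNum() != 6 for a in atoms):
                n_hetero_aromatic += 1
    for t in (1, 2, 3, 4):
        bits[pos] = int(n_aromatic >= t)
        pos += 1
    for t in (1, 2, 3, 4):
        bits[pos] = int(n_hetero_aromatic >= t)
        pos += 1
    # remaining ring-section positions up to _BOND_SECTION_START stay zero


def _pattern_bits(mol: Chem.Mol, bits: np.ndarray) -> None:
    for i, smarts in enumerate(_BOND_PAIR_SMARTS):
        if mol.HasSubstructMatch(_compiled(smarts)):
            bits[_BOND_SECTION_START + i] = 1
    for i, smarts in enumerate(_SUBSTRUCTURE_SMARTS):
        if mol.HasSubstructMatch(_compiled(smarts)):
            bits[_SMARTS_SECTION_START + i] = 1


def pubchem_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """Compute the 881-bit substructure-key fingerprint for a molecule."""
    bits = np.zeros(PUBCHEM_FP_LENGTH, dtype=np.uint8)
    _element_bits(mol, bits)
    _ring_bits(mol, bits)
    _pattern_bits(mol, bits)
    return bits
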