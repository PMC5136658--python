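"""Per-residue chemical annotation tables used by the contact classifier.

All tables operate on heavy atoms only: membrane-protein crystal structures
rarely resolve hydrogens, so donor/acceptor roles are assigned to the parent
heavy atoms and no hydrogen-bond angle criterion is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def three_to_one(name3: str) -> str:
    """One-letter code for a three-letter residue name; 'X' if nonstandard."""
    return THREE_TO_ONE.get(name3.upper(), "X")


@dataclass(frozen=True)
class ResidueTyping:
    """Chemical roles of the heavy atoms of one residue type.

    An atom may hold several roles (e.g. Tyr OH is donor and acceptor).
    His is treated as donor+acceptor and aromatic, not charged, by default.
    """

    pos_charged: frozenset = frozenset()   # cationic group heavy atoms
    neg_charged: frozenset = frozenset()   # anionic group heavy atoms
    donors: frozenset = frozenset()
    acceptors: frozenset = frozenset()
    aromatic: frozenset = frozenset()      # ring heavy atoms
    apolar_carbons: frozenset = frozenset()  # side-chain C not in a polar group

    @property
    def polar(self) -> frozenset:
        return self.donors | self.acceptors | self.pos_charged | self.neg_charged


def _fs(*names: str) -> frozenset:
    return frozenset(names)


ATOM_TYPING: dict[str, ResidueTyping] = {
    "ALA": ResidueTyping(apolar_carbons=_fs("CB")),
    "ARG": ResidueTyping(
        pos_charged=_fs("NE", "CZ", "NH1", "NH2"),
        donors=_fs("NE", "NH1", "NH2"),
        apolar_carbons=_fs("CB", "CG", "CD"),
    ),
    "ASN": ResidueTyping(
        donors=_fs("ND2"), acceptors=_fs("OD1"), apolar_carbons=_fs("CB"),
    ),
    "ASP": ResidueTyping(
        neg_charged=_fs("OD1", "OD2", "CG"),
        acceptors=_fs("OD1", "OD2"),
        apolar_carbons=_fs("CB"),
    ),
    "CYS": ResidueTyping(
        donors=_fs("SG"), acceptors=_fs("SG"), apolar_carbons=_fs("CB"),
    ),
    "GLN": ResidueTyping(
        donors=_fs("NE2"), acceptors=_fs("OE1"), apolar_carbons=_fs("CB", "CG"),
    ),
    "GLU": ResidueTyping(
        neg_charged=_fs("OE1", "OE2", "CD"),
        acceptors=_fs("OE1", "OE2"),
        apolar_carbons=_fs("CB", "CG"),
    ),
    "GLY": ResidueTyping(),
    "HIS": ResidueTyping(
        donors=_fs("ND1", "NE2"), acceptors=_fs("ND1", "NE2"),
        aromatic=_fs("CG", "ND1", "CD2", "CE1", "NE2"),
        apolar_carbons=_fs("CB"),
    ),
    "ILE": ResidueTyping(apolar_carbons=_fs("CB", "CG1", "CG2", "CD1")),
    "LEU": ResidueTyping(apolar_carbons=_fs("CB", "CG", "CD1", "CD2")),
    "LYS": ResidueTyping(
        pos_charged=_fs("NZ"), donors=_fs("NZ"),
        apolar_carbons=_fs("CB", "CG", "CD", "CE"),
    ),
    "MET": ResidueTyping(apolar_carbons=_fs("CB", "CG", "SD", "CE")),
    "PHE": ResidueTyping(
        aromatic=_fs("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        apolar_carbons=_fs("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ),
    "PRO": ResidueTyping(apolar_carbons=_fs("CB", "CG", "CD")),
    "SER": ResidueTyping(donors=_fs("OG"), acceptors=_fs("OG")),
    "THR": ResidueTyping(
        donors=_fs("OG1"), acceptors=_fs("OG1"), apolar_carbons=_fs("CG2"),
    ),
    "TRP": ResidueTyping(
        donors=_fs("NE1"),
        aromatic=_fs("CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        apolar_carbons=_fs("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
    "TYR": ResidueTyping(
        donors=_fs("OH"), acceptors=_fs("OH"),
        aromatic=_fs("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        apolar_carbons=_fs("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ),
    "VAL": ResidueTyping(apolar_carbons=_fs("CB", "CG1", "CG2")),
}

# Maximum side-chain extension from CA to the farthest heavy atom, Angstrom,
# for a fully extended (all-trans) side chain. Used to estimate whether a
# substituted side chain can reach a partner ("reach" heuristic).
SIDECHAIN_REACH: dict[str, float] = {
    "G": 0.0, "A": 1.5, "S": 2.4, "C": 2.8, "T": 2.6, "V": 2.6,
    "P": 2.4, "D": 3.7, "N": 3.7, "I": 3.9, "L": 3.9, "E": 5.0,
    "Q": 5.0, "H": 4.5, "M": 5.2, "F": 5.1, "K": 6.3, "W": 6.0,
    "Y": 6.4, "R": 7.3,
}

# One-letter capability sets used by the mutation annotator.
POS_CHARGED_AA = frozenset("RK")
NEG_CHARGED_AA = frozenset("DE")
DONOR_AA = frozenset("RNQHKSTWYC")
ACCEPTOR_AA = frozenset("DNEQHSTYC")
AROMATIC_AA = frozenset("FYWH")
APOLAR_AA = frozenset("AVLIMFWYCP")  # has apolar side-chain carbons


def typing_for(name3: str) -> ResidueTyping:
    """Atom typing for a residue name; empty typing for nonstandard residues."""
    return ATOM_TYPING.get(name3.upper(), ResidueTyping())
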