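"""Atomic-structure I/O and the uniform residue/atom model.

Structures are read from PDB or mmCIF via biotite and exposed as a small
chain -> residue -> atom hierarchy keyed by author numbering (with insertion
codes), which is the only residue key the rest of the package uses. Only the
first model of multi-model files is considered; alternate locations are
resolved to the highest-occupancy conformer (ties broken alphabetically by
altloc id). Waters and non-amino-acid heteroatoms are dropped by default.

Fusion constructs (e.g. a lysozyme inserted into a loop) are *not* removed:
transmembrane-helix annotations select the receptor residues downstream.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io import pdb as bt_pdb
from biotite.structure.io import pdbx as bt_pdbx

from .chemdata import BACKBONE_ATOMS, three_to_one
from .errors import (
    ChainLookupError,
    EmptyStructureError,
    HeptahelixError,
    ParseError,
)

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "TMAnnotation",
    "read_structure",
    "write_structure",
    "chain_sequence",
    "missing_report",
    "fetch_structure",
]

TM_NAMES = tuple(f"TM{i}" for i in range(1, 8))


@dataclass
class AtomRecord:
    """One heavy (or hydrogen) atom with author metadata."""

    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name3: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name3)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_ca(self) -> bool:
        return self.atom("CA") is not None

    def coords(self, names=None, exclude_backbone: bool = False) -> np.ndarray:
        """Stacked coordinates, optionally restricted by atom name."""
        sel = self.atoms
        if names is not None:
            names = set(names)
            sel = [a for a in sel if a.name in names]
        if exclude_backbone:
            sel = [a for a in sel if not a.is_backbone]
        if not sel:
            return np.empty((0, 3))
        return np.stack([a.coord for a in sel])

    def sidechain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_backbone and a.element != "H"]

    def label(self) -> str:
        return f"{self.name3}{self.number}{self.icode}".strip()


class StructureModel:
    """Parsed structure: ordered residues grouped by chain, author numbering."""

    def __init__(self, id: str, chains: dict[str, list[Residue]],
                 source_format: str = "synthetic"):
        self.id = id
        self.source_format = source_format
        self.chains: dict[str, list[Residue]] = {}
        for cid, residues in chains.items():
            self.chains[cid] = sorted(residues, key=lambda r: r.key)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ChainLookupError(
                f"chain {chain_id!r} not in structure {self.id} "
                f"(chains: {sorted(self.chains)})"
            ) from None

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for r in self.chain(chain_id):
            if r.number == number and r.icode == icode:
                return r
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains.values() for r in c)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with coordinates mapped x -> R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        chains = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                Residue(r.chain_id, r.number, r.icode, r.name3,
                        [AtomRecord(a.name, a.element, rotation @ a.coord + translation,
                                    a.altloc, a.occupancy) for a in r.atoms])
                for r in residues
            ]
        return StructureModel(self.id, chains, self.source_format)

    def copy(self) -> "StructureModel":
        return self.transformed(np.eye(3), np.zeros(3))


@dataclass
class TMAnnotation:
    """Inclusive author-number ranges of the transmembrane helices of a chain.

    ``extracellular_end_of_TM1`` fixes the orientation convention: whether the
    first or last residue of TM1 faces the extracellular side. Successive
    helices alternate direction (antiparallel bundle).
    """

    chain_id: str
    helices: dict[str, tuple[int, int]]
    extracellular_end_of_TM1: str = "first"
    anchor_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.extracellular_end_of_TM1 not in ("first", "last"):
            raise ValueError("extracellular_end_of_TM1 must be 'first' or 'last'")
        spans = []
        for name, (start, end) in sorted(self.helices.items()):
            if end - start + 1 < 8:
                raise ValueError(f"{name}: helix range must span >= 8 residues")
            spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"helix ranges {n1} and {n2} overlap")

    def helix_range(self, name: str) -> tuple[int, int]:
        return self.helices[name]

    def helix_of(self, number: int) -> str | None:
        for name, (start, end) in self.helices.items():
            if start <= number <= end:
                return name
        return None

    def numbers(self, name: str) -> range:
        start, end = self.helices[name]
        return range(start, end + 1)

    def extracellular_end(self, name: str) -> str:
        """'first' or 'last' residue of the named helix faces extracellular."""
        idx = int(name[2:]) if name.startswith("TM") else 8
        tm1_first = self.extracellular_end_of_TM1 == "first"
        # odd helices share TM1's orientation, even ones are flipped
        same = idx % 2 == 1
        return "first" if (tm1_first == same) else "last"

    @classmethod
    def from_yaml(cls, path) -> "TMAnnotation":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            helices = {k: (int(v[0]), int(v[1])) for k, v in raw["helices"].items()}
            return cls(
                chain_id=str(raw["chain_id"]),
                helices=helices,
                extracellular_end_of_TM1=raw.get("extracellular_end_of_TM1", "first"),
                anchor_overrides={str(k): int(v) for k, v in
                                  (raw.get("anchor_overrides") or {}).items()},
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"bad TM annotation file {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        payload = {
            "chain_id": self.chain_id,
            "helices": {k: list(v) for k, v in self.helices.items()},
            "extracellular_end_of_TM1": self.extracellular_end_of_TM1,
        }
        if self.anchor_overrides:
            payload["anchor_overrides"] = dict(self.anchor_overrides)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# reading


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # sniff: mmCIF starts with 'data_'
    with open(path) as fh:
        head = fh.read(2048)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _resolve_altlocs(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep the highest-occupancy altloc per atom site; ties -> alphabetical."""
    altloc = atoms.altloc_id
    plain = (altloc == "") | (altloc == ".") | (altloc == "?") | (altloc == " ")
    if plain.all():
        return atoms
    occ = atoms.occupancy if "occupancy" in atoms.get_annotation_categories() \
        else np.ones(atoms.array_length())
    best: dict[tuple, int] = {}
    for i in range(atoms.array_length()):
        key = (atoms.chain_id[i], atoms.res_id[i], atoms.ins_code[i], atoms.atom_name[i])
        if plain[i]:
            best[key] = i if key not in best else best[key]
            continue
        j = best.get(key)
        if j is None or occ[i] > occ[j] or (occ[i] == occ[j] and altloc[i] < altloc[j]):
            best[key] = i
    keep = np.zeros(atoms.array_length(), dtype=bool)
    keep[list(best.values())] = True
    return atoms[keep]


def read_structure(path, format_hint: str | None = None, *,
                   keep_hetero: bool = False, id: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    First model only; altlocs resolved to highest occupancy; waters and
    non-amino-acid heteroatoms excluded unless ``keep_hetero`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = _detect_format(path, format_hint)
    try:
        if fmt == "pdb":
            fobj = bt_pdb.PDBFile.read(str(path))
            atoms = fobj.get_structure(
                model=1, altloc="all", extra_fields=["occupancy"])
        elif fmt == "mmcif":
            fobj = bt_pdbx.CIFFile.read(str(path))
            atoms = bt_pdbx.get_structure(
                fobj, model=1, altloc="all", extra_fields=["occupancy"])
        else:
            raise ParseError(f"unknown structure format {fmt!r}")
    except HeptahelixError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if atoms is None or atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no coordinates in file")

    atoms = _resolve_altlocs(atoms)
    if not keep_hetero:
        keep = struc.filter_amino_acids(atoms)
        atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no atoms left after filtering")

    chains: dict[str, list[Residue]] = {}
    index: dict[tuple, Residue] = {}
    altloc = atoms.altloc_id
    occupancy = atoms.occupancy if "occupancy" in atoms.get_annotation_categories() \
        else np.ones(atoms.array_length())
    for i in range(atoms.array_length()):
        cid = str(atoms.chain_id[i])
        icode = str(atoms.ins_code[i]).strip()
        rkey = (cid, int(atoms.res_id[i]), icode)
        res = index.get(rkey)
        if res is None:
            res = Residue(cid, int(atoms.res_id[i]), icode, str(atoms.res_name[i]))
            index[rkey] = res
            chains.setdefault(cid, []).append(res)
        alt = str(altloc[i]).strip(" .?")
        res.atoms.append(AtomRecord(
            name=str(atoms.atom_name[i]),
            element=str(atoms.element[i]),
            coord=atoms.coord[i],
            altloc=alt,
            occupancy=float(min(max(occupancy[i], 0.0), 1.0)),
        ))
    return StructureModel(id or path.stem, chains, source_format=fmt)


def write_structure(model: StructureModel, path) -> None:
    """Write the model as a PDB file (single model, heavy-atom records)."""
    n = model.n_atoms
    atoms = struc.AtomArray(n)
    atoms.add_annotation("occupancy", dtype=float)
    i = 0
    for cid in model.chains:
        for res in model.chains[cid]:
            for a in res.atoms:
                atoms.chain_id[i] = cid
                atoms.res_id[i] = res.number
                atoms.ins_code[i] = res.icode
                atoms.res_name[i] = res.name3
                atoms.atom_name[i] = a.name
                atoms.element[i] = a.element or a.name[0]
                atoms.coord[i] = a.coord
                atoms.occupancy[i] = a.occupancy
                atoms.hetero[i] = False
                i += 1
    fobj = bt_pdb.PDBFile()
    fobj.set_structure(atoms)
    fobj.write(str(path))


# ---------------------------------------------------------------------------
# derived views


def chain_sequence(model: StructureModel, chain_id: str) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus the aligned author-number list.

    Nonstandard residues become 'X'.
    """
    residues = model.chain(chain_id)
    seq = "".join(r.one_letter for r in residues)
    numbers = [r.number for r in residues]
    return seq, numbers


def missing_report(model: StructureModel, annotation: TMAnnotation) -> list[dict]:
    """Annotated residues absent from the coordinates, or present without CA."""
    report = []
    chain_numbers = {}
    for r in model.chain(annotation.chain_id):
        chain_numbers.setdefault(r.number, r)
    for helix in annotation.helices:
        for num in annotation.numbers(helix):
            res = chain_numbers.get(num)
            if res is None:
                report.append({"helix": helix, "number": num, "reason": "missing"})
            elif not res.has_ca:
                report.append({"helix": helix, "number": num, "reason": "incomplete"})
    return report


# ---------------------------------------------------------------------------
# optional network helper (never used by the core test suite)


def fetch_structure(accession: str, directory, *, fmt: str = "pdb",
                    timeout: float = 15.0) -> Path:
    """Download a public PDB entry by accession. Requires network access."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = "pdb" if fmt == "pdb" else "cif"
    target = directory / f"{accession.lower()}.{suffix}"
    if target.exists():
        return target
    url = f"https://files.rcsb.org/download/{accession.upper()}.{suffix}"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    target.write_bytes(data)
    return target
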