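"""Inter-residue distance measurement and contact-tier classification.

Contacts between side chains are binned into a qualitative vocabulary by
heavy-atom distances alone (membrane-protein crystal structures rarely have
hydrogens, so no angle criteria are used). The tier ladder, first match wins:

==========================  ==========================================  =========
tier                        realizing atoms                             distance
==========================  ==========================================  =========
salt_bridge                 oppositely charged group heavy atoms        <= 4.0 A
hbond                       donor -- acceptor heavy atoms               <= 3.5 A
weak_polar                  donor -- acceptor heavy atoms               3.5-4.0 A
aromatic                    ring atom -- ring atom (both aromatic)      <= 4.5 A
hydrophobic_strong          apolar side-chain C -- apolar C             <= 4.0 A
hydrophobic_weak            apolar C -- apolar C                        4.0-4.5 A
induced_dipole              charged/polar atom -- apolar C              <= 4.5 A
water_mediated_possible     donor/acceptor pair                         4.0-6.0 A
none                        --                                          above all
==========================  ==========================================  =========

``water_mediated_possible`` marks pairs close enough for a bridging water;
it is reported alongside real contacts, never counted as one. Histidine is
treated as donor+acceptor and aromatic, never charged, by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .chemdata import typing_for
from .errors import MeasurementError
from .structure_io import Residue, StructureModel
from .bw import BWMap

__all__ = ["Cutoffs", "InteractionRecord", "pair_distance", "classify_pair",
           "interaction_map", "records_to_tsv"]

CONTACT_TIERS = ("salt_bridge", "hbond", "weak_polar", "aromatic",
                 "hydrophobic_strong", "hydrophobic_weak", "induced_dipole")


@dataclass(frozen=True)
class Cutoffs:
    """Distance thresholds (Angstrom). Defaults are calibrated so that the
    literature's worked examples classify correctly: a 3.4 A apolar pair is a
    contact, 3.8 A N/O is weak polar, 4.6 A Tyr-Tyr is non-interacting yet
    water-bridgeable, and 4.9 A apolar is nothing."""

    salt_bridge: float = 4.0
    hbond: float = 3.5
    weak_polar_upper: float = 4.0
    aromatic: float = 4.5
    hydrophobic_strong: float = 4.0
    hydrophobic_weak_upper: float = 4.5
    induced_dipole: float = 4.5
    water_mediated_upper: float = 6.0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"cutoff {name} must be positive")


@dataclass
class InteractionRecord:
    res_a: str               # e.g. "A/ARG519"
    res_b: str
    bw_a: str | None
    bw_b: str | None
    tier: str
    distance_A: float
    atom_a: str | None
    atom_b: str | None
    water_mediated_possible: bool = False

    @property
    def is_contact(self) -> bool:
        return self.tier in CONTACT_TIERS

    def involves(self, res_id: str) -> bool:
        return self.res_a == res_id or self.res_b == res_id


def _res_id(res: Residue) -> str:
    return f"{res.chain_id}/{res.name3}{res.number}{res.icode}"


def _min_pair(coords_a: np.ndarray, names_a: list[str],
              coords_b: np.ndarray, names_b: list[str]):
    if len(coords_a) == 0 or len(coords_b) == 0:
        return None
    d = cdist(coords_a, coords_b)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), names_a[i], names_b[j]


def _heavy(res: Residue, names: frozenset | None = None,
           exclude_backbone: bool = False):
    atoms = [a for a in res.atoms if a.element.upper() != "H"]
    if exclude_backbone:
        atoms = [a for a in atoms if not a.is_backbone]
    if names is not None:
        atoms = [a for a in atoms if a.name in names]
    if not atoms:
        return np.empty((0, 3)), []
    return np.stack([a.coord for a in atoms]), [a.name for a in atoms]


def pair_distance(res_a: Residue, res_b: Residue, mode: str = "min_heavy",
                  atoms: tuple[str, str] | None = None) -> float:
    """Distance between two residues under a named convention.

    Modes: ``ca`` (alpha carbons), ``min_sidechain_heavy`` (side-chain heavy
    atoms; glycine falls back to CA with a warning), ``min_heavy`` (all heavy
    atoms), ``named_atoms`` (explicit atom-name pair via ``atoms``).
    """
    if mode == "ca":
        a, b = res_a.atom("CA"), res_b.atom("CA")
        missing = [r.label() for r, at in ((res_a, a), (res_b, b)) if at is None]
        if missing:
            raise MeasurementError(f"CA missing in: {missing}")
        return float(np.linalg.norm(a.coord - b.coord))
    if mode == "named_atoms":
        if atoms is None:
            raise MeasurementError("mode 'named_atoms' requires atoms=(name_a, name_b)")
        a, b = res_a.atom(atoms[0]), res_b.atom(atoms[1])
        missing = [n for n, at in zip(atoms, (a, b)) if at is None]
        if missing:
            raise MeasurementError(f"atoms not found: {missing}")
        return float(np.linalg.norm(a.coord - b.coord))
    if mode == "min_sidechain_heavy":
        sets = []
        for res in (res_a, res_b):
            ca, names = _heavy(res, exclude_backbone=True)
            if len(ca) == 0:
                if res.name3 == "GLY" and res.has_ca:
                    warnings.warn(f"{res.label()}: glycine, using CA for side-chain mode")
                    ca, names = _heavy(res, names=frozenset({"CA"}))
                else:
                    raise MeasurementError(f"{res.label()}: no side-chain heavy atoms")
            sets.append((ca, names))
        result = _min_pair(*sets[0], *sets[1])
        return result[0]
    if mode == "min_heavy":
        ca_a, names_a = _heavy(res_a)
        ca_b, names_b = _heavy(res_b)
        if len(ca_a) == 0 or len(ca_b) == 0:
            raise MeasurementError("residue without heavy atoms")
        return _min_pair(ca_a, names_a, ca_b, names_b)[0]
    raise MeasurementError(f"unknown distance mode {mode!r}")


def _role_coords(res: Residue, names: frozenset):
    return _heavy(res, names=names)


def classify_pair(res_a: Residue, res_b: Residue,
                  cutoffs: Cutoffs = Cutoffs(),
                  bw_a: str | None = None, bw_b: str | None = None) -> InteractionRecord:
    """Classify one residue pair into the contact-tier vocabulary.

    Symmetric in its arguments. Glycine contributes its CA as a stand-in
    apolar atom so the hydrophobic tiers remain evaluable.
    """
    ta, tb = typing_for(res_a.name3), typing_for(res_b.name3)

    def roles(res, typ):
        pos = _role_coords(res, typ.pos_charged)
        neg = _role_coords(res, typ.neg_charged)
        don = _role_coords(res, typ.donors)
        acc = _role_coords(res, typ.acceptors)
        aro = _role_coords(res, typ.aromatic)
        apo = _role_coords(res, typ.apolar_carbons)
        if res.name3 == "GLY" and res.has_ca:
            apo = _heavy(res, names=frozenset({"CA"}))
        polar_names = typ.donors | typ.acceptors | typ.pos_charged | typ.neg_charged
        pol = _role_coords(res, polar_names)
        return dict(pos=pos, neg=neg, don=don, acc=acc, aro=aro, apo=apo, pol=pol)

    ra, rb = roles(res_a, ta), roles(res_b, tb)

    def best(role_a, role_b):
        hits = []
        m1 = _min_pair(*ra[role_a], *rb[role_b])
        m2 = _min_pair(*ra[role_b], *rb[role_a])
        hits = [m for m in (m1, m2) if m is not None]
        # m2 is (dist, name_in_a, name_in_b) with roles swapped, already a/b order
        return min(hits, key=lambda h: h[0]) if hits else None

    donacc = best("don", "acc")
    water_possible = bool(
        donacc and cutoffs.weak_polar_upper < donacc[0] <= cutoffs.water_mediated_upper)

    def record(tier, hit, water=water_possible):
        d, na, nb = hit
        return InteractionRecord(_res_id(res_a), _res_id(res_b), bw_a, bw_b,
                                 tier, round(d, 3), na, nb,
                                 water_mediated_possible=water)

    sb = best("pos", "neg")
    if sb and sb[0] <= cutoffs.salt_bridge:
        return record("salt_bridge", sb)
    if donacc and donacc[0] <= cutoffs.hbond:
        return record("hbond", donacc)
    if donacc and donacc[0] <= cutoffs.weak_polar_upper:
        return record("weak_polar", donacc)
    aro = _min_pair(*ra["aro"], *rb["aro"])
    if aro and aro[0] <= cutoffs.aromatic:
        return record("aromatic", aro)
    apo = _min_pair(*ra["apo"], *rb["apo"])
    if apo and apo[0] <= cutoffs.hydrophobic_strong:
        return record("hydrophobic_strong", apo)
    if apo and apo[0] <= cutoffs.hydrophobic_weak_upper:
        return record("hydrophobic_weak", apo)
    ind = best("pol", "apo")
    if ind and ind[0] <= cutoffs.induced_dipole:
        return record("induced_dipole", ind)
    if water_possible:
        return record("water_mediated_possible", donacc)
    # distance reported for the closest side-chain heavy atoms, if any
    all_a = _heavy(res_a, exclude_backbone=True)
    all_b = _heavy(res_b, exclude_backbone=True)
    closest = _min_pair(*all_a, *all_b)
    if closest is None:
        return InteractionRecord(_res_id(res_a), _res_id(res_b), bw_a, bw_b,
                                 "none", float("inf"), None, None, False)
    return record("none", closest, water=False)


def interaction_map(model: StructureModel, bwmap: BWMap,
                    cutoffs: Cutoffs = Cutoffs(),
                    max_ca_distance: float = 18.0) -> list[InteractionRecord]:
    """All classified pairs among BW-labelled residues, sorted by distance.

    Inter-helix pairs are always considered; intra-helix pairs only when the
    sequence separation exceeds 4 (one helical turn). Pairs whose CA atoms are
    farther apart than ``max_ca_distance`` are skipped for speed.
    """
    chain = model.chain(bwmap.chain_id)
    labelled = [(r, bwmap.label_of(r.number)) for r in chain
                if bwmap.label_of(r.number) is not None and r.has_ca]
    records = []
    for (res_a, la), (res_b, lb) in combinations(labelled, 2):
        helix_a, helix_b = la.split(".")[0], lb.split(".")[0]
        if helix_a == helix_b and abs(res_a.number - res_b.number) <= 4:
            continue
        if np.linalg.norm(res_a.atom("CA").coord - res_b.atom("CA").coord) \
                > max_ca_distance:
            continue
        rec = classify_pair(res_a, res_b, cutoffs, la, lb)
        if rec.tier != "none":
            records.append(rec)
    records.sort(key=lambda r: r.distance_A)
    return records


def records_to_tsv(records: list[InteractionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("res_a\tbw_a\tres_b\tbw_b\ttier\tdistance_A\tatom_a\tatom_b"
                 "\twater_mediated_possible\n")
        for r in records:
            fh.write(f"{r.res_a}\t{r.bw_a or ''}\t{r.res_b}\t{r.bw_b or ''}\t"
                     f"{r.tier}\t{r.distance_A:.3f}\t{r.atom_a or ''}\t"
                     f"{r.atom_b or ''}\t{int(r.water_mediated_possible)}\n")
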