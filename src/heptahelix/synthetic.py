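"""Synthetic seven-helix bundles with planted, known structural features.

The generator stands in for receptor models that are not publicly deposited:
it produces idealized transmembrane bundles in which every feature the
analysis stages look for -- kinks, alpha-bulges, residue contacts at set
distances, rigid activation-like motions -- is planted with known ground
truth, so each detector can be validated without downloads.

Helices are built residue-by-residue (NeRF chain extension) with backbone
torsions solved numerically to reproduce the requested rise and twist
exactly; side chains are grafted from the idealized residue templates of the
chemical component dictionary bundled with biotite (one canonical rotamer
per type). Helices sit on a circle, axes vertical (extracellular = +z),
alternating N->C direction so odd helices run extracellular->intracellular.
Bundles are geometrically idealized: realism is not a goal, testability is.

Determinism: identical spec + seed give identical coordinates. The seed
drives only small coordinate jitter and a global rigid scatter of the
bundle; planted features are realized after jitter, so their contracts hold
for every seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import fsolve
from scipy.spatial.transform import Rotation

import biotite.structure.info as bt_info

from .chemdata import BACKBONE_ATOMS
from .errors import FeasibilityError, HeptahelixError
from .structure_io import AtomRecord, Residue, StructureModel, TMAnnotation
from .bw import AnchorSet, BWMap, assign_bw
from .interactions import pair_distance
from .activation import CHARGED_GROUP, BASIC, ACIDIC

__all__ = ["Kink", "Bulge", "ContactPair", "RigidMotion", "SyntheticBundleSpec",
           "MovementPlan", "build_ideal_helix", "build_bundle", "make_state_pair",
           "DEFAULT_ACTIVATION_PLAN"]

# ideal backbone internal coordinates (Engh & Huber-like)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = 111.0, 116.6, 121.7, 120.8, 110.5
OMEGA = 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Place atom D bonded to C with |CD|=r, angle(BCD)=theta, dihedral(ABCD)=chi."""
    theta, chi = math.radians(theta_deg), math.radians(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -r * math.cos(theta),
        r * math.sin(theta) * math.cos(chi),
        r * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phis: np.ndarray, psis: np.ndarray):
    """N/CA/C/O/CB coordinate arrays for a chain with per-residue torsions."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = math.radians(A_N_CA_C)
    C[0] = CA[0] + (B_CA_C * math.cos(math.pi - ang),
                    B_CA_C * math.sin(math.pi - ang), 0.0)
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psis[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, OMEGA)
        C[i] = _nerf(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phis[i])
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        O[i] = _nerf(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psis[i] + 180.0)
        CB[i] = _nerf(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, 122.6)
    return N, CA, C, O, CB


def _screw_params(phi: float, psi: float) -> tuple[float, float]:
    """Rise (A/residue) and twist (deg/residue) of the (phi, psi) helix."""
    n = 12
    _N, CA, _C, _O, _CB = _build_backbone(
        n, np.full(n, phi), np.full(n, psi))
    centred = CA - CA.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0]
    if np.dot(axis, CA[-1] - CA[0]) < 0:
        axis = -axis
    z = centred @ axis
    rise = float(np.mean(np.diff(z)))
    perp = centred - np.outer(z, axis)
    twists = []
    for i in range(n - 1):
        v1, v2 = perp[i], perp[i + 1]
        ang = math.degrees(math.atan2(np.dot(np.cross(v1, v2), axis),
                                      np.dot(v1, v2)))
        twists.append(ang % 360.0)
    return rise, float(np.mean(twists))


@lru_cache(maxsize=16)
def _torsions_for(rise: float, twist: float) -> tuple[float, float]:
    """Backbone (phi, psi) reproducing the requested rise and twist."""

    def residual(x):
        r, t = _screw_params(x[0], x[1])
        return [r - rise, t - twist]

    sol = fsolve(residual, x0=np.array([-57.8, -47.0]), full_output=False,
                 xtol=1e-10)
    r, t = _screw_params(sol[0], sol[1])
    if abs(r - rise) > 1e-4 or abs(t - twist) > 1e-3:
        raise HeptahelixError(
            f"no alpha-helical torsions give rise={rise}, twist={twist}")
    return float(sol[0]), float(sol[1])


# pi-helix-like torsions used to widen one turn into an alpha-bulge; the
# values were chosen so the i->i+4 carbonyl registry around the edit shifts
# to i->i+5 (verified by the registry detector on the built fixture).
PI_BULGE_TORSIONS = (-80.0, -70.0)
PI_BULGE_SPAN = 2  # residues rebuilt with pi torsions


@lru_cache(maxsize=64)
def _ccd_sidechain(res_name: str):
    """Idealized heavy side-chain atoms + backbone frame from the CCD."""
    tmpl = bt_info.residue(res_name)
    if tmpl is None:
        raise HeptahelixError(f"no ideal template for residue {res_name!r}")
    heavy = tmpl[(tmpl.element != "H") & (tmpl.atom_name != "OXT")]
    frame = {}
    for name in ("N", "CA", "C"):
        sel = heavy[heavy.atom_name == name]
        if sel.array_length() != 1:
            raise HeptahelixError(f"{res_name}: bad template backbone")
        frame[name] = sel.coord[0]
    side = [(str(heavy.atom_name[i]), str(heavy.element[i]), heavy.coord[i])
            for i in range(heavy.array_length())
            if heavy.atom_name[i] not in BACKBONE_ATOMS]
    return frame, side


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    u, _s, vt = np.linalg.svd((mobile - cm).T @ (reference - cr))
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cr - rot @ cm


def graft_sidechain(res: Residue, res_name: str) -> None:
    """Replace the residue's side chain with the ideal template of ``res_name``,
    keeping backbone atoms fixed (template superposed on N, CA, C)."""
    frame, side = _ccd_sidechain(res_name.upper())
    host = {}
    for name in ("N", "CA", "C"):
        atom = res.atom(name)
        if atom is None:
            raise HeptahelixError(f"{res.label()}: backbone incomplete, cannot graft")
        host[name] = atom.coord
    mob = np.stack([frame[n] for n in ("N", "CA", "C")])
    ref = np.stack([host[n] for n in ("N", "CA", "C")])
    rot, trans = _kabsch(mob, ref)
    res.atoms = [a for a in res.atoms if a.is_backbone]
    for name, element, coord in side:
        res.atoms.append(AtomRecord(name, element, rot @ coord + trans))
    res.name3 = res_name.upper()


def build_ideal_helix(n_res: int, rise: float = 1.5, twist: float = 100.0,
                      ca_radius: float = 2.3, sequence: str | None = None,
                      start_number: int = 1, chain_id: str = "A",
                      bulge_at: int | None = None) -> list[Residue]:
    """Canonical alpha-helix with full backbone (N, CA, C, O) plus CB.

    The helix is returned axis-aligned with +z, centroid at the origin and
    the N terminus at the top. ``rise`` and ``twist`` are honoured exactly
    (torsions are solved for them); the CA radius is a consequence of ideal
    backbone geometry (~2.3 A) -- a ``ca_radius`` more than 0.3 A from the
    achieved value raises, as it cannot be met without distorting bonds.
    ``bulge_at`` (0-based residue index) rebuilds one turn with pi-helix
    torsions, creating an alpha-bulge at that point.
    """
    if n_res < 4:
        raise HeptahelixError("an ideal helix needs n_res >= 4")
    phi, psi = _torsions_for(rise, twist)
    phis, psis = np.full(n_res, phi), np.full(n_res, psi)
    if bulge_at is not None:
        if not 2 <= bulge_at <= n_res - PI_BULGE_SPAN - 2:
            raise HeptahelixError("bulge position too close to a helix end")
        for k in range(PI_BULGE_SPAN):
            phis[bulge_at + k] = PI_BULGE_TORSIONS[0]
            psis[bulge_at + k] = PI_BULGE_TORSIONS[1]
    N, CA, C, O, CB = _build_backbone(n_res, phis, psis)

    # axis-align: screw axis of the CA trace -> +z, N terminus up, centroid at
    # origin. For an ideal helix the second differences of the CA trace are
    # exactly radial, so consecutive cross products give the exact screw axis
    # (the principal axis of a finite helix is biased by end effects).
    centred_origin = CA.mean(axis=0)
    if bulge_at is None and n_res >= 5:
        d2 = CA[2:] - 2.0 * CA[1:-1] + CA[:-2]
        crosses = np.cross(d2[:-1], d2[1:])
        axis = crosses.mean(axis=0)
        axis /= np.linalg.norm(axis)
    else:
        _, _, vt = np.linalg.svd(CA - centred_origin)
        axis = vt[0]
    if np.dot(axis, CA[0] - CA[-1]) < 0:
        axis = -axis  # point from C-term toward N-term (up)
    rot, _ = _kabsch(np.stack([axis, np.zeros(3)]),
                     np.stack([np.array([0.0, 0.0, 1.0]), np.zeros(3)]))
    achieved_radius = float(np.mean(
        np.linalg.norm((CA - centred_origin)
                       - np.outer((CA - centred_origin) @ axis, axis), axis=1)))
    if abs(achieved_radius - ca_radius) > 0.3 and bulge_at is None:
        raise HeptahelixError(
            f"requested CA radius {ca_radius} incompatible with ideal backbone "
            f"geometry (achieved {achieved_radius:.2f})")

    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    from .chemdata import ONE_TO_THREE
    residues: list[Residue] = []
    for i in range(n_res):
        name3 = ONE_TO_THREE.get(sequence[i].upper(), "ALA")
        atoms = [
            AtomRecord("N", "N", rot @ (N[i] - centred_origin)),
            AtomRecord("CA", "C", rot @ (CA[i] - centred_origin)),
            AtomRecord("C", "C", rot @ (C[i] - centred_origin)),
            AtomRecord("O", "O", rot @ (O[i] - centred_origin)),
        ]
        if name3 != "GLY":
            atoms.append(AtomRecord("CB", "C", rot @ (CB[i] - centred_origin)))
        res = Residue(chain_id, start_number + i, "", "ALA", atoms)
        if name3 not in ("ALA", "GLY"):
            graft_sidechain(res, name3)
        else:
            res.name3 = name3
        residues.append(res)
    return residues


# ---------------------------------------------------------------------------
# planted features


@dataclass(frozen=True)
class Kink:
    helix: int
    angle_deg: float
    position: int | None = None  # author number; None = helix midpoint


@dataclass(frozen=True)
class Bulge:
    helix: int
    position: int | None = None


@dataclass(frozen=True)
class ContactPair:
    bw_a: str
    res_type_a: str
    bw_b: str
    res_type_b: str
    target_distance: float
    orient: bool = True   # rotate both helices so the side chains face each other


@dataclass(frozen=True)
class RigidMotion:
    helix: int
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0          # about the helix's own axis
    segment: str = "all"               # "all" | "ic_half" | "ec_half"


@dataclass(frozen=True)
class SyntheticBundleSpec:
    n_helices: int = 7
    residues_per_helix: int = 31
    bundle_radius: float = 9.0
    helix_tilt_deg: float = 0.0
    planted_features: tuple = ()
    seed: int = 0
    jitter_A: float = 0.02
    scatter: bool = True    # random global rigid placement of the whole bundle

    def with_features(self, *features) -> "SyntheticBundleSpec":
        return replace(self, planted_features=tuple(self.planted_features)
                       + tuple(features))


# per-helix anchor index (0-based) of the x.50 residue; chosen so the whole
# diagnostic panel (1.39 .. 7.53) falls inside 31-residue helices
ANCHOR_INDEX = {1: 15, 2: 15, 3: 22, 4: 15, 5: 15, 6: 24, 7: 15}


def _helix_start(helix: int) -> int:
    return 100 * helix + 1


class _Bundle:
    """Mutable assembly state during bundle construction."""

    def __init__(self, spec: SyntheticBundleSpec):
        self.spec = spec
        self.helices: dict[int, list[Residue]] = {}
        self.rng = np.random.default_rng(spec.seed)

    def helix_residues(self, helix: int) -> list[Residue]:
        return self.helices[helix]

    def helix_axis_and_centroid(self, helix: int):
        ca = np.stack([r.atom("CA").coord for r in self.helices[helix]])
        centroid = ca.mean(axis=0)
        _, _, vt = np.linalg.svd(ca - centroid)
        axis = vt[0]
        # orient IC -> EC (+z-ish before scatter)
        ec_first = helix % 2 == 1
        ec_ca = ca[0] if ec_first else ca[-1]
        ic_ca = ca[-1] if ec_first else ca[0]
        if np.dot(axis, ec_ca - ic_ca) < 0:
            axis = -axis
        return axis / np.linalg.norm(axis), centroid

    def transform_helix(self, helix: int, rot: np.ndarray, trans: np.ndarray,
                        numbers: set[int] | None = None):
        for res in self.helices[helix]:
            if numbers is not None and res.number not in numbers:
                continue
            for atom in res.atoms:
                atom.coord = rot @ atom.coord + trans

    def rotate_about_own_axis(self, helix: int, angle_deg: float,
                              numbers: set[int] | None = None):
        axis, centroid = self.helix_axis_and_centroid(helix)
        rot = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
        trans = centroid - rot @ centroid
        self.transform_helix(helix, rot, trans, numbers)

    def residue_by_number(self, helix: int, number: int) -> Residue:
        for res in self.helices[helix]:
            if res.number == number:
                return res
        raise HeptahelixError(f"TM{helix}: residue {number} absent")


def _bw_to_number(bw_label: str) -> tuple[int, int]:
    helix_s, pos_s = str(bw_label).split(".")
    helix, pos = int(helix_s), int(pos_s)
    anchor_number = _helix_start(helix) + ANCHOR_INDEX[helix]
    return helix, anchor_number + (pos - 50)


def _realizing_distance(res_a: Residue, res_b: Residue) -> tuple[float, np.ndarray]:
    """Distance between planted groups and the unit direction a<-b at closest
    approach. Charged-group atoms for an opposite-charge pair, side-chain
    heavy atoms otherwise."""
    if res_a.name3 in BASIC and res_b.name3 in ACIDIC or \
            res_a.name3 in ACIDIC and res_b.name3 in BASIC:
        coords_a = res_a.coords(names=CHARGED_GROUP[res_a.name3])
        coords_b = res_b.coords(names=CHARGED_GROUP[res_b.name3])
    else:
        coords_a = np.stack([a.coord for a in res_a.sidechain_atoms()])
        coords_b = np.stack([a.coord for a in res_b.sidechain_atoms()])
    diff = coords_a[:, None] - coords_b[None]
    d = np.linalg.norm(diff, axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    direction = diff[i, j] / d[i, j]
    return float(d[i, j]), direction


def _plant_contact(bundle: _Bundle, feat: ContactPair):
    if feat.target_distance < 2.5:
        raise FeasibilityError(
            f"contact target {feat.target_distance} A below heavy-atom "
            "van der Waals contact (~2.5 A)")
    helix_a, num_a = _bw_to_number(feat.bw_a)
    helix_b, num_b = _bw_to_number(feat.bw_b)
    if helix_a == helix_b:
        raise FeasibilityError("contact pair must span two helices")
    res_a = bundle.residue_by_number(helix_a, num_a)
    res_b = bundle.residue_by_number(helix_b, num_b)
    graft_sidechain(res_a, feat.res_type_a)
    graft_sidechain(res_b, feat.res_type_b)

    if feat.orient:
        # rotate each helix about its own axis so the planted CB azimuths
        # face the partner residue
        for helix, res, partner in ((helix_a, res_a, res_b),
                                    (helix_b, res_b, res_a)):
            axis, centroid = bundle.helix_axis_and_centroid(helix)
            ca, cb = res.atom("CA"), res.atom("CB")
            if cb is None:
                continue
            v_side = cb.coord - ca.coord
            v_target = partner.atom("CA").coord - ca.coord
            v_side -= np.dot(v_side, axis) * axis
            v_target -= np.dot(v_target, axis) * axis
            if np.linalg.norm(v_side) < 1e-6 or np.linalg.norm(v_target) < 1e-6:
                continue
            ang = math.atan2(np.dot(np.cross(v_side, v_target), axis),
                             np.dot(v_side, v_target))
            bundle.rotate_about_own_axis(helix, math.degrees(ang))

    for _ in range(8):
        d, direction = _realizing_distance(res_a, res_b)
        err = d - feat.target_distance
        if abs(err) <= 0.05:
            break
        bundle.transform_helix(helix_b, np.eye(3), direction * err)
    d, _ = _realizing_distance(res_a, res_b)
    if abs(d - feat.target_distance) > 0.3:
        raise FeasibilityError(
            f"could not realize contact {feat.bw_a}-{feat.bw_b} at "
            f"{feat.target_distance} A (got {d:.2f})")


def _plant_kink(bundle: _Bundle, feat: Kink):
    residues = bundle.helix_residues(feat.helix)
    numbers = [r.number for r in residues]
    apex = feat.position if feat.position is not None else numbers[len(numbers) // 2]
    if apex not in numbers:
        raise HeptahelixError(f"kink position {apex} outside TM{feat.helix}")
    axis, _ = bundle.helix_axis_and_centroid(feat.helix)
    pivot = bundle.residue_by_number(feat.helix, apex).atom("CA").coord
    # bend about a fixed perpendicular of the helix axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    bend_axis = np.cross(axis, ref)
    bend_axis /= np.linalg.norm(bend_axis)
    rot = Rotation.from_rotvec(np.radians(feat.angle_deg) * bend_axis).as_matrix()
    trans = pivot - rot @ pivot
    moved = {n for n in numbers if n > apex}
    bundle.transform_helix(feat.helix, rot, trans, moved)


def _plant_rigid_motion(bundle: _Bundle, feat: RigidMotion):
    residues = bundle.helix_residues(feat.helix)
    numbers = [r.number for r in residues]
    if feat.segment == "all":
        selected = None
    else:
        half = len(numbers) // 2
        ec_first = feat.helix % 2 == 1
        first_half, second_half = set(numbers[:half]), set(numbers[half:])
        if feat.segment == "ec_half":
            selected = first_half if ec_first else second_half
        elif feat.segment == "ic_half":
            selected = second_half if ec_first else first_half
        else:
            raise HeptahelixError(f"unknown segment {feat.segment!r}")
    if feat.rotation_deg:
        bundle.rotate_about_own_axis(feat.helix, feat.rotation_deg, selected)
    bundle.transform_helix(feat.helix, np.eye(3),
                           np.asarray(feat.translation, float), selected)


def build_bundle(spec: SyntheticBundleSpec
                 ) -> tuple[StructureModel, TMAnnotation, BWMap]:
    """Assemble the bundle and return it with its annotation and BW map."""
    if not 2 <= spec.n_helices <= 7:
        raise HeptahelixError("n_helices must be between 2 and 7")
    bundle = _Bundle(spec)
    n = spec.residues_per_helix
    helices = {}
    for k in range(1, spec.n_helices + 1):
        residues = build_ideal_helix(n, start_number=_helix_start(k),
                                     chain_id="A")
        # odd helices: N terminus (first residue) extracellular (top, +z)
        if k % 2 == 0:
            flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
            for res in residues:
                for atom in res.atoms:
                    atom.coord = flip @ atom.coord
        angle = 2.0 * math.pi * (k - 1) / spec.n_helices
        offset = np.array([spec.bundle_radius * math.cos(angle),
                           spec.bundle_radius * math.sin(angle), 0.0])
        tilt = Rotation.from_rotvec(
            math.radians(spec.helix_tilt_deg)
            * np.array([-math.sin(angle), math.cos(angle), 0.0])).as_matrix()
        for res in residues:
            for atom in res.atoms:
                atom.coord = tilt @ atom.coord + offset
        helices[k] = residues
    bundle.helices = helices

    if spec.jitter_A > 0:
        for k in helices:
            for res in helices[k]:
                for atom in res.atoms:
                    atom.coord = atom.coord + bundle.rng.normal(
                        0.0, spec.jitter_A, 3)

    # torsion-level features first (they rebuild a helix), then bends and
    # motions, then contacts (which may translate whole helices)
    feats = list(spec.planted_features)
    for feat in [f for f in feats if isinstance(f, Bulge)]:
        residues = helices[feat.helix]
        numbers = [r.number for r in residues]
        pos = feat.position if feat.position is not None \
            else numbers[len(numbers) // 2]
        idx = numbers.index(pos)
        axis, centroid = bundle.helix_axis_and_centroid(feat.helix)
        old_first_ca = residues[0].atom("CA").coord.copy()
        rebuilt = build_ideal_helix(len(numbers), start_number=numbers[0],
                                    chain_id="A", bulge_at=idx)
        if feat.helix % 2 == 0:
            flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
            for res in rebuilt:
                for atom in res.atoms:
                    atom.coord = flip @ atom.coord
        for res in rebuilt:
            for atom in res.atoms:
                atom.coord = atom.coord + centroid
        helices[feat.helix] = rebuilt
        bundle.helices = helices
    for feat in [f for f in feats if isinstance(f, Kink)]:
        _plant_kink(bundle, feat)
    for feat in [f for f in feats if isinstance(f, RigidMotion)]:
        _plant_rigid_motion(bundle, feat)
    for feat in [f for f in feats if isinstance(f, ContactPair)]:
        _plant_contact(bundle, feat)

    if spec.scatter:
        rot = Rotation.random(random_state=int(
            bundle.rng.integers(0, 2**31 - 1))).as_matrix()
        trans = bundle.rng.uniform(-20, 20, 3)
        for k in helices:
            for res in helices[k]:
                for atom in res.atoms:
                    atom.coord = rot @ atom.coord + trans

    all_residues = [r for k in sorted(helices) for r in helices[k]]
    model = StructureModel("synthetic_bundle", {"A": all_residues},
                           source_format="synthetic")
    ranges = {f"TM{k}": (_helix_start(k), _helix_start(k) + n - 1)
              for k in helices}
    annotation = TMAnnotation(chain_id="A", helices=ranges,
                              extracellular_end_of_TM1="first")
    anchors = AnchorSet({k: _helix_start(k) + ANCHOR_INDEX[k]
                         for k in range(1, 8)})
    bwmap = assign_bw(annotation, anchors)
    return model, annotation, bwmap


# ---------------------------------------------------------------------------
# activation-like state pairs


@dataclass(frozen=True)
class MovementPlan:
    """Per-helix-end displacements (A) applied to the active-state copy.

    ``end_moves`` maps helix index -> end ("extracellular"/"intracellular")
    -> {"radial": out+, "axial": toward extracellular +, "tangential": ...}.
    """

    end_moves: dict = field(default_factory=dict)
    tm6_rotation_deg: float = 0.0
    toggle_target_A: float | None = None  # re-plant Tyr7.53-Tyr5.58 distance

    @property
    def is_empty(self) -> bool:
        return (not self.end_moves and self.tm6_rotation_deg == 0.0
                and self.toggle_target_A is None)


DEFAULT_ACTIVATION_PLAN = MovementPlan(
    end_moves={
        1: {"extracellular": {"radial": -1.5}, "intracellular": {"radial": 2.0}},
        3: {"extracellular": {"axial": -1.5}, "intracellular": {"axial": -1.5}},
        5: {"intracellular": {"radial": -2.0}},
        6: {"extracellular": {"axial": 1.0}, "intracellular": {"radial": 5.0}},
        7: {"extracellular": {"radial": -1.5}, "intracellular": {"radial": -2.0}},
    },
    tm6_rotation_deg=30.0,
    toggle_target_A=4.6,
)


def _apply_end_moves(bundle: _Bundle, helix: int, moves: dict):
    """Rigid motion whose end displacements approximate the requested ones."""
    axis, centroid = bundle.helix_axis_and_centroid(helix)
    ca = np.stack([r.atom("CA").coord for r in bundle.helices[helix]])
    z = (ca - centroid) @ axis
    half_len = float((z.max() - z.min()) / 2.0)

    # bundle axis is +z pre-scatter (plans are applied before scatter)
    bundle_axis = np.array([0.0, 0.0, 1.0])
    disp = {}
    for end in ("extracellular", "intracellular"):
        spec_move = moves.get(end, {})
        end_z = half_len if end == "extracellular" else -half_len
        point = centroid + end_z * axis
        rel = point.copy()
        rel[2] = 0.0
        nrm = np.linalg.norm(rel)
        radial_dir = rel / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        tang_dir = np.cross(bundle_axis, radial_dir)
        disp[end] = (spec_move.get("radial", 0.0) * radial_dir
                     + spec_move.get("axial", 0.0) * bundle_axis
                     + spec_move.get("tangential", 0.0) * tang_dir)
    translation = (disp["extracellular"] + disp["intracellular"]) / 2.0
    delta = disp["extracellular"] - disp["intracellular"]
    delta_perp = delta - np.dot(delta, axis) * axis
    if np.linalg.norm(delta_perp) > 1e-9 and half_len > 1e-9:
        w = np.cross(axis, delta_perp / np.linalg.norm(delta_perp))
        theta = np.linalg.norm(delta_perp) / (2.0 * half_len)
        rot = Rotation.from_rotvec(theta * w).as_matrix()
    else:
        rot = np.eye(3)
    trans = centroid - rot @ centroid + translation
    bundle.transform_helix(helix, rot, trans)


def make_state_pair(base_spec: SyntheticBundleSpec,
                    movement_plan: MovementPlan = DEFAULT_ACTIVATION_PLAN
                    ) -> tuple[StructureModel, StructureModel,
                               TMAnnotation, BWMap]:
    """Inactive/active bundle pair sharing one BW map.

    The inactive state carries a planted Arg3.50-Asp6.30 salt bridge at
    3.0 A and a Tyr7.53/Tyr5.58 pair ~11 A apart (side chains). The active
    state applies the movement plan; with ``toggle_target_A`` set, TM7 is
    additionally translated so the tyrosine pair reaches that distance.
    """
    for helix in movement_plan.end_moves:
        if helix > base_spec.n_helices:
            raise HeptahelixError(
                f"movement plan references TM{helix}, bundle has "
                f"{base_spec.n_helices} helices")
    base_features = (
        ContactPair("3.50", "ARG", "6.30", "ASP", 3.0),
        ContactPair("7.53", "TYR", "5.58", "TYR", 11.0),
    )
    spec = replace(base_spec, scatter=False,
                   planted_features=base_features + tuple(
                       base_spec.planted_features))

    def assemble(apply_plan: bool):
        bundle = _Bundle(spec)
        inner = replace(spec, scatter=False)
        model, annotation, bwmap = _build_raw(bundle, inner)
        if apply_plan:
            if movement_plan.tm6_rotation_deg:
                bundle.rotate_about_own_axis(6, movement_plan.tm6_rotation_deg)
            for helix, moves in movement_plan.end_moves.items():
                _apply_end_moves(bundle, helix, moves)
            if movement_plan.toggle_target_A is not None:
                helix_a, num_a = _bw_to_number("7.53")
                helix_b, num_b = _bw_to_number("5.58")
                r753 = bundle.residue_by_number(helix_a, num_a)
                r558 = bundle.residue_by_number(helix_b, num_b)
                for _ in range(8):
                    d, direction = _realizing_distance(r753, r558)
                    err = d - movement_plan.toggle_target_A
                    if abs(err) <= 0.05:
                        break
                    bundle.transform_helix(helix_a, np.eye(3), -direction * err)
        all_residues = [r for k in sorted(bundle.helices)
                        for r in bundle.helices[k]]
        label = "synthetic_active" if apply_plan else "synthetic_inactive"
        return StructureModel(label, {"A": all_residues}, "synthetic"), \
            annotation, bwmap

    inactive, annotation, bwmap = assemble(False)
    active, _, _ = assemble(True)
    return inactive, active, annotation, bwmap


def _build_raw(bundle: _Bundle, spec: SyntheticBundleSpec):
    """build_bundle body operating on a caller-owned _Bundle (shared by
    make_state_pair so both states start from identical coordinates)."""
    model, annotation, bwmap = build_bundle(spec)
    # rebuild bundle.helices from the model for further editing
    chain = model.chain("A")
    helices: dict[int, list[Residue]] = {}
    for res in chain:
        helices.setdefault(res.number // 100, []).append(res)
    bundle.helices = helices
    return model, annotation, bwmap
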