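"""Activation-state diagnostics and inactive <-> active conformational change.

The activation fingerprint of a single structure collects the features that
distinguish the two states of a class A GPCR:

* the ionic lock, a salt bridge between Arg3.50 (E/DRY or ERW box) and
  Asp/Glu6.30 -- present in the inactive state, broken on activation;
* the tyrosine toggle, the Tyr7.53 (NPxxY) to Tyr5.58 side-chain distance --
  far apart when inactive, close enough for a water-bridged hydrogen bond
  when active;
* the hydrogen-bond network of Asp2.50 (partners among 7.49, 7.46, 3.39);
* hydrophobic-core contact tiers (3.43 vs 6.40/6.41/2.46, 5.50 vs 3.40/3.44);
* the 3.30-4.58 contact, a glycoprotein-hormone-receptor peculiarity.

Only the lock and the toggle vote on the state call; the other panels are
reported but carry no decision thresholds.

Conformational change between an inactive/active pair is measured after a
closed-form (Kabsch) CA superposition matched by identical BW labels: per
helix end, the mean displacement of the terminal turn is decomposed into
radial (outward from the bundle axis positive), axial (toward the
extracellular side positive) and tangential components, and the rotation of
TM6 about its own axis is tracked by the azimuth of a marker side chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, MeasurementError
from .structure_io import Residue, StructureModel, TMAnnotation
from .bw import BWMap
from .interactions import Cutoffs, classify_pair, pair_distance

__all__ = ["ActivationFingerprint", "SuperpositionResult", "HelixMovementReport",
           "ionic_lock_status", "fingerprint", "superpose_by_bw",
           "helix_movements", "helix_rotation"]

CHARGED_GROUP = {
    "ARG": ("NE", "NH1", "NH2", "CZ"),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
}
BASIC = {"ARG", "LYS"}
ACIDIC = {"ASP", "GLU"}

CORE_CONTACT_PAIRS = (("3.43", "6.40"), ("3.43", "6.41"), ("3.43", "2.46"),
                      ("5.50", "3.40"), ("5.50", "3.44"))
D250_PARTNERS = ("7.49", "7.46", "3.39")


def _residue_at(model: StructureModel, bwmap: BWMap, label: str) -> Residue | None:
    number = bwmap.number_of(label)
    if number is None:
        return None
    return model.residue(bwmap.chain_id, number)


def ionic_lock_status(model: StructureModel, bwmap: BWMap,
                      cutoff: float = 4.0) -> dict:
    """Arg/Lys3.50 -- Asp/Glu6.30 charged-group distance and presence call."""
    r350 = _residue_at(model, bwmap, "3.50")
    r630 = _residue_at(model, bwmap, "6.30")
    if r350 is None or r630 is None:
        return {"available": False, "regime": "unavailable",
                "distance_A": None, "present": None}
    if r350.name3 not in BASIC or r630.name3 not in ACIDIC:
        return {"available": True, "regime": "not_applicable",
                "distance_A": None, "present": None,
                "residues": (r350.label(), r630.label())}
    coords_a = r350.coords(names=CHARGED_GROUP[r350.name3])
    coords_b = r630.coords(names=CHARGED_GROUP[r630.name3])
    if len(coords_a) == 0 or len(coords_b) == 0:
        return {"available": False, "regime": "unavailable",
                "distance_A": None, "present": None}
    d = float(np.min(np.linalg.norm(coords_a[:, None] - coords_b[None], axis=-1)))
    return {"available": True, "regime": "applicable", "distance_A": round(d, 3),
            "present": d <= cutoff, "residues": (r350.label(), r630.label())}


@dataclass
class ActivationFingerprint:
    ionic_lock: dict
    tyrosine_toggle: dict
    d250_network: list[str]
    core_contacts: dict[str, str]
    gphr_contact: str | None
    state_call: str

    def to_dict(self) -> dict:
        return {
            "ionic_lock": self.ionic_lock,
            "tyrosine_toggle": self.tyrosine_toggle,
            "d250_network": self.d250_network,
            "core_contacts": self.core_contacts,
            "gphr_contact": self.gphr_contact,
            "state_call": self.state_call,
        }


def fingerprint(model: StructureModel, bwmap: BWMap,
                cutoffs: Cutoffs = Cutoffs()) -> ActivationFingerprint:
    """Activation fingerprint of one structure. Missing panel positions
    degrade gracefully to 'unavailable' entries rather than failing."""
    lock = ionic_lock_status(model, bwmap, cutoffs.salt_bridge)

    r753 = _residue_at(model, bwmap, "7.53")
    r558 = _residue_at(model, bwmap, "5.58")
    if r753 is None or r558 is None:
        toggle = {"available": False, "distance_A": None, "regime": "unavailable"}
    else:
        try:
            d = pair_distance(r753, r558, "min_sidechain_heavy")
        except MeasurementError:
            toggle = {"available": False, "distance_A": None, "regime": "unavailable"}
        else:
            if d <= cutoffs.salt_bridge:
                regime = "bonded"
            elif d <= cutoffs.water_mediated_upper:
                regime = "water_mediated_possible"
            else:
                regime = "apart"
            toggle = {"available": True, "distance_A": round(d, 3),
                      "regime": regime,
                      "residues": (r753.label(), r558.label())}

    r250 = _residue_at(model, bwmap, "2.50")
    network: list[str] = []
    if r250 is not None:
        for label in D250_PARTNERS:
            partner = _residue_at(model, bwmap, label)
            if partner is None:
                continue
            rec = classify_pair(r250, partner, cutoffs, "2.50", label)
            if rec.tier in ("hbond", "salt_bridge"):
                network.append(label)

    core: dict[str, str] = {}
    for la, lb in CORE_CONTACT_PAIRS:
        ra, rb = _residue_at(model, bwmap, la), _residue_at(model, bwmap, lb)
        key = f"{la}-{lb}"
        if ra is None or rb is None:
            core[key] = "unavailable"
        else:
            core[key] = classify_pair(ra, rb, cutoffs, la, lb).tier

    r330, r458 = _residue_at(model, bwmap, "3.30"), _residue_at(model, bwmap, "4.58")
    gphr = None
    if r330 is not None and r458 is not None:
        gphr = classify_pair(r330, r458, cutoffs, "3.30", "4.58").tier

    if lock["present"] is True:
        call = "inactive_like"
    elif lock["present"] is False and toggle.get("regime") in (
            "bonded", "water_mediated_possible"):
        call = "active_like"
    else:
        call = "indeterminate"
    return ActivationFingerprint(lock, toggle, network, core, gphr, call)


# ---------------------------------------------------------------------------
# superposition and movements


@dataclass
class SuperpositionResult:
    """Rigid map x -> R x + t taking the mobile CA set onto the reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_A: float
    n_pairs: int
    matched_labels: list[str] = field(default_factory=list)

    def apply(self, model: StructureModel) -> StructureModel:
        return model.transformed(self.rotation, self.translation)


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rotation+translation (reflection-free) mobile -> reference."""
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cr - rot @ cm
    return rot, trans


def superpose_by_bw(reference: StructureModel, mobile: StructureModel,
                    bw_ref: BWMap, bw_mob: BWMap,
                    core_selection: tuple[str, ...] | None = None
                    ) -> SuperpositionResult:
    """Closed-form CA superposition over residues matched by identical BW label.

    ``core_selection`` names the helices to match (default: all seven TMs).
    Returns the transform mapping ``mobile`` onto ``reference``.
    """
    if core_selection is None:
        core_selection = tuple(f"TM{i}" for i in range(1, 8))
    wanted = {h[2:] if h.startswith("TM") else h for h in core_selection}
    ref_pts, mob_pts, labels = [], [], []
    for label, num_ref in sorted(bw_ref._label_to_num.items()):
        if label.split(".")[0] not in wanted:
            continue
        num_mob = bw_mob.number_of(label)
        if num_mob is None:
            continue
        res_r = reference.residue(bw_ref.chain_id, num_ref)
        res_m = mobile.residue(bw_mob.chain_id, num_mob)
        if res_r is None or res_m is None or not (res_r.has_ca and res_m.has_ca):
            continue
        ref_pts.append(res_r.atom("CA").coord)
        mob_pts.append(res_m.atom("CA").coord)
        labels.append(label)
    if len(labels) < 3:
        raise InsufficientDataError(
            f"only {len(labels)} shared BW-labelled CA pairs; need >= 3")
    ref_pts, mob_pts = np.asarray(ref_pts), np.asarray(mob_pts)
    rot, trans = _kabsch(mob_pts, ref_pts)
    moved = mob_pts @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_pts) ** 2, axis=-1))))
    return SuperpositionResult(rot, trans, rmsd, len(labels), labels)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[0] / np.linalg.norm(vt[0])


def _matched_ca(reference, mobile_s, bw_ref, bw_mob, helix: str):
    """(label, number_ref, ca_ref, ca_mob) tuples for one helix, ordered by
    reference residue number."""
    idx = helix[2:]
    out = []
    for label, num_ref in bw_ref._label_to_num.items():
        if label.split(".")[0] != idx:
            continue
        num_mob = bw_mob.number_of(label)
        if num_mob is None:
            continue
        res_r = reference.residue(bw_ref.chain_id, num_ref)
        res_m = mobile_s.residue(bw_mob.chain_id, num_mob)
        if res_r is None or res_m is None or not (res_r.has_ca and res_m.has_ca):
            continue
        out.append((label, num_ref, res_r.atom("CA").coord, res_m.atom("CA").coord))
    out.sort(key=lambda t: t[1])
    return out


@dataclass
class HelixMovementReport:
    per_helix: dict[str, dict[str, dict]]
    tm6_rotation_deg: float | None
    superposition: SuperpositionResult
    bundle_axis: np.ndarray

    def component(self, helix: str, end: str, name: str) -> float | None:
        entry = self.per_helix.get(helix, {}).get(end)
        return None if entry is None or "error" in entry else entry[name]

    def to_dict(self) -> dict:
        out = {"tm6_rotation_deg": self.tm6_rotation_deg,
               "superposition_rmsd_A": self.superposition.rmsd_A,
               "n_matched_pairs": self.superposition.n_pairs,
               "helices": {}}
        for helix, ends in self.per_helix.items():
            out["helices"][helix] = {}
            for end, entry in ends.items():
                if "error" in entry:
                    out["helices"][helix][end] = entry
                else:
                    out["helices"][helix][end] = {
                        "displacement_A": [round(x, 3) for x in entry["displacement"]],
                        "radial_A": round(entry["radial"], 3),
                        "axial_A": round(entry["axial"], 3),
                        "tangential_A": round(entry["tangential"], 3),
                    }
        return out


def _core_superpose(inactive, active, bw_inactive, bw_active,
                    max_rounds: int = 5) -> SuperpositionResult:
    """Outlier-trimmed CA superposition: fit, drop pairs far off the median
    residual, refit. Keeps the frame anchored to the static core so large
    local movements (e.g. an outswung helix end) are not averaged away."""
    sup = superpose_by_bw(inactive, active, bw_inactive, bw_active)
    kept = set(sup.matched_labels)
    for _ in range(max_rounds):
        active_s = sup.apply(active)
        residuals = {}
        for label in sup.matched_labels:
            num_r = bw_inactive.number_of(label)
            num_m = bw_active.number_of(label)
            res_r = inactive.residue(bw_inactive.chain_id, num_r)
            res_m = active_s.residue(bw_active.chain_id, num_m)
            residuals[label] = float(np.linalg.norm(
                res_r.atom("CA").coord - res_m.atom("CA").coord))
        med = float(np.median(list(residuals.values())))
        threshold = max(2.0, 2.0 * med)
        new_kept = {l for l, r in residuals.items() if r <= threshold}
        if len(new_kept) < max(10, 3) or new_kept == kept:
            break
        kept = new_kept
        sup = _superpose_on_labels(inactive, active, bw_inactive,
                                   bw_active, kept)
    return sup


def _superpose_on_labels(reference, mobile, bw_ref, bw_mob, labels):
    ref_pts, mob_pts, used = [], [], []
    for label in sorted(labels):
        num_ref, num_mob = bw_ref.number_of(label), bw_mob.number_of(label)
        res_r = reference.residue(bw_ref.chain_id, num_ref)
        res_m = mobile.residue(bw_mob.chain_id, num_mob)
        if res_r is None or res_m is None or not (res_r.has_ca and res_m.has_ca):
            continue
        ref_pts.append(res_r.atom("CA").coord)
        mob_pts.append(res_m.atom("CA").coord)
        used.append(label)
    rot, trans = _kabsch(np.asarray(mob_pts), np.asarray(ref_pts))
    moved = np.asarray(mob_pts) @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - np.asarray(ref_pts)) ** 2,
                                        axis=-1))))
    return SuperpositionResult(rot, trans, rmsd, len(used), used)


def helix_movements(inactive: StructureModel, active: StructureModel,
                    bw_inactive: BWMap, bw_active: BWMap,
                    annotation: TMAnnotation,
                    terminal_turn: int = 4,
                    rotation_marker_bw: str = "6.29",
                    trim: bool = True) -> HelixMovementReport:
    """Per-helix, per-end displacement decomposition between two conformations.

    The active structure is first superposed onto the inactive one over
    matched CA pairs (outlier-trimmed by default, so the frame follows the
    static core rather than averaging large movements away); the bundle axis
    is the principal axis of the pooled matched CA set, oriented toward the
    extracellular side. End displacement is the mean CA shift of the terminal
    ``terminal_turn`` matched residues (damps end fraying).
    """
    if trim:
        sup = _core_superpose(inactive, active, bw_inactive, bw_active)
    else:
        sup = superpose_by_bw(inactive, active, bw_inactive, bw_active)
    active_s = sup.apply(active)

    helices = [h for h in annotation.helices if h.startswith("TM")]
    all_pts = []
    per_helix_matches = {}
    for helix in helices:
        matches = _matched_ca(inactive, active_s, bw_inactive, bw_active, helix)
        per_helix_matches[helix] = matches
        for _l, _n, ca_r, ca_m in matches:
            all_pts.extend((ca_r, ca_m))
    all_pts = np.asarray(all_pts)
    axis = _principal_axis(all_pts)
    centre = all_pts.mean(axis=0)

    # orient the bundle axis extracellular-positive using TM1's convention
    tm1 = per_helix_matches.get("TM1") or per_helix_matches[helices[0]]
    ec_end = annotation.extracellular_end("TM1")
    ec_ca = tm1[0][2] if ec_end == "first" else tm1[-1][2]
    ic_ca = tm1[-1][2] if ec_end == "first" else tm1[0][2]
    if np.dot(axis, ec_ca - ic_ca) < 0:
        axis = -axis

    report: dict[str, dict[str, dict]] = {}
    for helix in helices:
        matches = per_helix_matches[helix]
        report[helix] = {}
        ec_is_first = annotation.extracellular_end(helix) == "first"
        for end in ("extracellular", "intracellular"):
            take_first = (end == "extracellular") == ec_is_first
            sel = matches[:terminal_turn] if take_first else matches[-terminal_turn:]
            if len(sel) < terminal_turn:
                report[helix][end] = {"error": "fewer than "
                                      f"{terminal_turn} matched terminal residues"}
                continue
            ref = np.mean([m[2] for m in sel], axis=0)
            mob = np.mean([m[3] for m in sel], axis=0)
            disp = mob - ref
            rel = ref - centre
            rel_perp = rel - np.dot(rel, axis) * axis
            nrm = np.linalg.norm(rel_perp)
            radial_dir = rel_perp / nrm if nrm > 1e-9 else np.zeros(3)
            radial = float(np.dot(disp, radial_dir))
            axial = float(np.dot(disp, axis))
            tang_dir = np.cross(axis, radial_dir)
            tangential = float(np.dot(disp, tang_dir))
            report[helix][end] = {"displacement": disp, "radial": radial,
                                  "axial": axial, "tangential": tangential}

    rotation = None
    try:
        rotation = helix_rotation(inactive, active, bw_inactive, bw_active,
                                  annotation, helix="TM6",
                                  marker_bw=rotation_marker_bw,
                                  _superposition=sup)
    except (InsufficientDataError, MeasurementError):
        rotation = None
    return HelixMovementReport(report, rotation, sup, axis)


def _sidechain_centroid(res: Residue) -> np.ndarray:
    atoms = res.sidechain_atoms()
    if not atoms:
        if not res.has_ca:
            raise MeasurementError(f"{res.label()}: no usable atoms for marker")
        return res.atom("CA").coord
    return np.mean([a.coord for a in atoms], axis=0)


def helix_rotation(inactive: StructureModel, active: StructureModel,
                   bw_inactive: BWMap, bw_active: BWMap,
                   annotation: TMAnnotation, helix: str = "TM6",
                   marker_bw: str = "6.29",
                   _superposition: SuperpositionResult | None = None) -> float:
    """Azimuthal change (degrees) of a marker side chain about the helix axis.

    Viewed from the extracellular side, counter-clockwise is positive; the
    result lies in (-180, 180]. Reversing the two states negates the angle.
    """
    sup = _superposition or superpose_by_bw(inactive, active, bw_inactive, bw_active)
    active_s = sup.apply(active)
    matches = _matched_ca(inactive, active_s, bw_inactive, bw_active, helix)
    if len(matches) < 4:
        raise InsufficientDataError(f"{helix}: too few matched CA for an axis")

    # bundle centre per state: all matched CA across all annotated helices
    centre = {"in": [], "ac": []}
    for h in annotation.helices:
        if not h.startswith("TM"):
            continue
        for _l, _n, ca_r, ca_m in _matched_ca(inactive, active_s,
                                              bw_inactive, bw_active, h):
            centre["in"].append(ca_r)
            centre["ac"].append(ca_m)
    centre_in = np.mean(centre["in"], axis=0)
    centre_ac = np.mean(centre["ac"], axis=0)

    num_in = bw_inactive.number_of(marker_bw)
    num_ac = bw_active.number_of(marker_bw)
    res_in = inactive.residue(bw_inactive.chain_id, num_in) if num_in else None
    res_ac = active_s.residue(bw_active.chain_id, num_ac) if num_ac else None
    if res_in is None or res_ac is None:
        raise MeasurementError(f"marker residue {marker_bw} unavailable")

    ec_is_first = annotation.extracellular_end(helix) == "first"

    def azimuth(ca_column: int, marker_res: Residue, bundle_centre) -> float:
        ca = np.asarray([m[ca_column] for m in matches])
        axis = _principal_axis(ca)
        ec_ca = ca[0] if ec_is_first else ca[-1]
        ic_ca = ca[-1] if ec_is_first else ca[0]
        if np.dot(axis, ec_ca - ic_ca) < 0:
            axis = -axis
        point = ca.mean(axis=0)
        ref = bundle_centre - point
        ref -= np.dot(ref, axis) * axis
        v = _sidechain_centroid(marker_res) - point
        v -= np.dot(v, axis) * axis
        if np.linalg.norm(v) < 1e-9 or np.linalg.norm(ref) < 1e-9:
            raise MeasurementError(f"marker {marker_bw} lies on the helix axis")
        return float(np.degrees(np.arctan2(
            np.dot(np.cross(ref, v), axis), np.dot(ref, v))))

    angle = azimuth(3, res_ac, centre_ac) - azimuth(2, res_in, centre_in)
    # fold into (-180, 180]
    angle = (angle + 180.0) % 360.0 - 180.0
    if angle == -180.0:
        angle = 180.0
    return float(angle)
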