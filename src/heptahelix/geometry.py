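"""Local helix-axis fitting and detection of kinks and alpha-bulges.

A helix axis is traced by sliding a window of CA atoms along the helix and
taking each window's principal axis (largest singular vector of the centred
coordinates), oriented N->C. A *kink* is scored as the maximum angle between
axis directions of windows one window-length apart -- simple, rotation
invariant and reproducible. An ideal alpha helix stays below ~5 degrees while
canonical proline kinks land around 20-35 degrees, so the default threshold
of 15 degrees separates the two cleanly.

An *alpha-bulge* is detected from backbone hydrogen-bond registry rather than
rise-per-residue: the defining feature is that the carbonyl O of residue i
abandons its i+4 amide partner for i+5. Heavy-atom O...N distance <= 3.5 A
stands in for a hydrogen bond (no hydrogens required).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .structure_io import Residue, StructureModel, TMAnnotation

__all__ = ["HelixAxis", "DistortionReport", "fit_helix_axis", "detect_kink",
           "detect_bulge", "helix_ca_coords", "analyse_helices"]

HBOND_ON_CUTOFF = 3.5  # Angstrom, carbonyl O ... amide N


@dataclass
class HelixAxis:
    window_centres: list[int]     # residue numbers at window centres
    axis_points: np.ndarray       # (n_windows, 3) window centroids
    axis_dirs: np.ndarray         # (n_windows, 3) unit vectors, N->C
    window_size: int

    @property
    def n_windows(self) -> int:
        return len(self.window_centres)

    @property
    def mean_axis(self) -> np.ndarray:
        v = self.axis_dirs.mean(axis=0)
        return v / np.linalg.norm(v)


@dataclass
class DistortionReport:
    kind: str                 # "kink" | "bulge" | "none"
    helix: str
    apex_residue: int | None
    angle_deg: float | None   # kink only
    evidence: str


def fit_helix_axis(ca_coords: np.ndarray, window_size: int = 7,
                   residue_numbers: list[int] | None = None) -> HelixAxis:
    """Per-window principal axes of a run of consecutive CA atoms."""
    ca_coords = np.asarray(ca_coords, dtype=float)
    n = len(ca_coords)
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd integer >= 3")
    if n < window_size:
        raise InsufficientDataError(
            f"need >= {window_size} CA atoms for window size {window_size}, got {n}")
    if residue_numbers is None:
        residue_numbers = list(range(1, n + 1))
    half = window_size // 2
    points, dirs, centres = [], [], []
    for start in range(n - window_size + 1):
        window = ca_coords[start:start + window_size]
        centroid = window.mean(axis=0)
        # screw-axis estimate: second differences of a helical CA trace are
        # radial, so consecutive cross products point along the local axis.
        # (A window PCA is biased by the non-integral number of turns.)
        d2 = window[2:] - 2.0 * window[1:-1] + window[:-2]
        crosses = np.cross(d2[:-1], d2[1:])
        axis = crosses.mean(axis=0)
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:  # degenerate (straight line): fall back to PCA
            _, _, vt = np.linalg.svd(window - centroid)
            axis = vt[0]
            nrm = 1.0
        axis = axis / np.linalg.norm(axis)
        # orient N -> C
        if np.dot(axis, window[-1] - window[0]) < 0:
            axis = -axis
        points.append(centroid)
        dirs.append(axis)
        centres.append(residue_numbers[start + half])
    return HelixAxis(centres, np.asarray(points), np.asarray(dirs), window_size)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def detect_kink(axis: HelixAxis, threshold_deg: float = 15.0,
                helix: str = "") -> DistortionReport:
    """Kink call from the maximum inter-window axis angle.

    Windows are compared across a one-window-length separation so the two
    axis estimates share no residues; for short helices the separation is
    reduced to the largest available.
    """
    n = axis.n_windows
    if n < 2:
        raise InsufficientDataError("need >= 2 axis windows to score a kink")
    gap = min(axis.window_size, n - 1)
    best_angle, best_apex = -1.0, None
    for i in range(n - gap):
        ang = _angle_deg(axis.axis_dirs[i], axis.axis_dirs[i + gap])
        if ang > best_angle:
            best_angle = ang
            best_apex = axis.window_centres[i + gap // 2]
    kind = "kink" if best_angle >= threshold_deg else "none"
    return DistortionReport(
        kind=kind, helix=helix, apex_residue=best_apex if kind == "kink" else best_apex,
        angle_deg=best_angle,
        evidence=f"max inter-window axis angle {best_angle:.1f} deg "
                 f"(gap {gap} windows, threshold {threshold_deg:g})")


def detect_bulge(residues: list[Residue], helix: str = "") -> DistortionReport:
    """Bulge call from the i->i+4 vs i->i+5 backbone H-bond registry.

    Reports a bulge where at least one residue's carbonyl O loses its i+4
    amide N (distance > 3.5 A) and instead contacts i+5 within 3.5 A; the
    apex is the first such registry-shifted residue.
    """
    by_index = list(residues)
    n = len(by_index)
    shifted: list[int] = []
    skipped: list[int] = []
    for i in range(n - 5):
        res_i = by_index[i]
        o_atom = res_i.atom("O")
        n4 = by_index[i + 4].atom("N")
        n5 = by_index[i + 5].atom("N")
        if o_atom is None or n4 is None or n5 is None:
            skipped.append(res_i.number)
            continue
        d4 = float(np.linalg.norm(o_atom.coord - n4.coord))
        d5 = float(np.linalg.norm(o_atom.coord - n5.coord))
        if d4 > HBOND_ON_CUTOFF and d5 <= HBOND_ON_CUTOFF:
            shifted.append(res_i.number)
    if skipped:
        warnings.warn(f"bulge scan skipped residues missing backbone atoms: {skipped}")
    if shifted:
        return DistortionReport(
            kind="bulge", helix=helix, apex_residue=shifted[0], angle_deg=None,
            evidence=f"O(i)->N(i+4) registry replaced by i+5 at residues {shifted}")
    return DistortionReport(kind="none", helix=helix, apex_residue=None,
                            angle_deg=None,
                            evidence="all carbonyls keep i->i+4 registry")


def helix_ca_coords(model: StructureModel, annotation: TMAnnotation,
                    helix: str) -> tuple[np.ndarray, list[int]]:
    """CA coordinates and residue numbers of one annotated helix, in order."""
    lo, hi = annotation.helix_range(helix)
    coords, numbers = [], []
    for res in model.chain(annotation.chain_id):
        if lo <= res.number <= hi and res.has_ca:
            coords.append(res.atom("CA").coord)
            numbers.append(res.number)
    return np.asarray(coords), numbers


def analyse_helices(model: StructureModel, annotation: TMAnnotation,
                    window_size: int = 7,
                    kink_threshold_deg: float = 15.0) -> list[DistortionReport]:
    """Kink and bulge reports for every annotated helix."""
    reports: list[DistortionReport] = []
    chain = model.chain(annotation.chain_id)
    for helix in sorted(annotation.helices):
        lo, hi = annotation.helix_range(helix)
        residues = [r for r in chain if lo <= r.number <= hi]
        coords, numbers = helix_ca_coords(model, annotation, helix)
        try:
            axis = fit_helix_axis(coords, window_size, numbers)
            reports.append(detect_kink(axis, kink_threshold_deg, helix))
        except InsufficientDataError:
            reports.append(DistortionReport("none", helix, None, None,
                                            "too few residues for axis fit"))
        reports.append(detect_bulge(residues, helix))
    return reports
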