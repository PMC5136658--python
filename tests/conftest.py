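import numpy as np
import pytest

from heptahelix.structure_io import AtomRecord, Residue, StructureModel
from heptahelix.synthetic import (ContactPair, SyntheticBundleSpec,
                                  _ccd_sidechain, build_bundle,
                                  build_ideal_helix)

DATA = "src/heptahelix/data"


def data_path(rel: str) -> str:
    from importlib import resources
    return str(resources.files("heptahelix").joinpath("data").joinpath(rel))


@pytest.fixture(scope="session")
def tshr_sequence():
    from heptahelix.bw import read_sequence
    return read_sequence(data_path("sequences/tshr_tmd_synthetic.fasta"))


@pytest.fixture(scope="session")
def tshr_annotation():
    from heptahelix.structure_io import TMAnnotation
    return TMAnnotation.from_yaml(data_path("sequences/tshr_tm_annotation.yaml"))


@pytest.fixture(scope="session")
def tshr_bwmap(tshr_sequence, tshr_annotation):
    from heptahelix.bw import assign_bw, infer_anchors
    seq, numbers = tshr_sequence
    return assign_bw(tshr_annotation,
                     infer_anchors(seq, numbers, tshr_annotation))


@pytest.fixture(scope="session")
def ideal_helix():
    return build_ideal_helix(31)


@pytest.fixture(scope="session")
def lock_bundle():
    """Seven-helix bundle with one planted Arg3.50-Asp6.30 pair at 3.0 A."""
    spec = SyntheticBundleSpec(
        seed=11, planted_features=(ContactPair("3.50", "ARG", "6.30", "ASP", 3.0),))
    return build_bundle(spec)


def full_residue(name3: str, number: int = 1, chain: str = "A") -> Residue:
    """One residue with ideal full-atom geometry from the component dictionary."""
    frame, side = _ccd_sidechain(name3.upper())
    tmpl = __import__("biotite.structure.info", fromlist=["residue"]).residue(
        name3.upper())
    heavy = tmpl[(tmpl.element != "H") & (tmpl.atom_name != "OXT")]
    atoms = [AtomRecord(str(heavy.atom_name[i]), str(heavy.element[i]),
                        heavy.coord[i]) for i in range(heavy.array_length())]
    return Residue(chain, number, "", name3.upper(), atoms)


def _group_coords(res: Residue, names) -> np.ndarray:
    return res.coords(names=frozenset(names))


def place_pair(name_a: str, name_b: str, group_a, group_b,
               target: float) -> tuple[Residue, Residue]:
    """Two ideal residues oriented group-to-group at a set group distance.

    ``group_*``: atom-name collections whose minimum mutual heavy-atom
    distance is driven to ``target``; the groups face each other so no other
    atoms come closer.
    """
    res_a = full_residue(name_a, 1)
    res_b = full_residue(name_b, 2)

    def orient(res, group, direction):
        ca = res.atom("CA").coord
        centroid = _group_coords(res, group).mean(axis=0)
        v = centroid - ca
        v /= np.linalg.norm(v)
        w = np.asarray(direction, float)
        # rotation taking v onto w
        axis = np.cross(v, w)
        s, c = np.linalg.norm(axis), float(np.dot(v, w))
        if s < 1e-9:
            rot = np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(w, w)
        else:
            k = axis / s
            kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            ang = np.arctan2(s, c)
            rot = np.eye(3) + np.sin(ang) * kx + (1 - np.cos(ang)) * kx @ kx
        for atom in res.atoms:
            atom.coord = rot @ (atom.coord - ca)

    orient(res_a, group_a, (1.0, 0.0, 0.0))
    orient(res_b, group_b, (-1.0, 0.0, 0.0))
    for atom in res_b.atoms:
        atom.coord = atom.coord + np.array([12.0, 0.0, 0.0])
    for _ in range(10):
        ca_coords = _group_coords(res_a, group_a)
        cb_coords = _group_coords(res_b, group_b)
        d = np.linalg.norm(ca_coords[:, None] - cb_coords[None], axis=-1)
        err = float(d.min()) - target
        if abs(err) < 1e-6:
            break
        for atom in res_b.atoms:
            atom.coord = atom.coord - np.array([err, 0.0, 0.0])
    return res_a, res_b


def translate_residues(model: StructureModel, chain: str, lo: int, hi: int,
                       shift) -> StructureModel:
    """Copy of the model with residues lo..hi of a chain translated."""
    shift = np.asarray(shift, float)
    out = model.copy()
    for res in out.chain(chain):
        if lo <= res.number <= hi:
            for atom in res.atoms:
                atom.coord = atom.coord + shift
    return out
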