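import itertools

import numpy as np
import pytest

from heptahelix.chemdata import typing_for
from heptahelix.errors import MeasurementError
from heptahelix.interactions import (Cutoffs, classify_pair, interaction_map,
                                     pair_distance)
from heptahelix.synthetic import (ContactPair, RigidMotion,
                                  SyntheticBundleSpec, build_bundle)

from conftest import full_residue, place_pair, translate_residues

DON_ACC = {"ASN": ("OD1", "ND2"), "ASP": ("OD1", "OD2"), "TYR": ("OH",)}


class TestPairDistance:
    def test_self_distance_zero(self):
        res = full_residue("LEU")
        for mode in ("ca", "min_sidechain_heavy", "min_heavy"):
            assert pair_distance(res, res, mode) == 0.0

    def test_min_heavy_matches_bruteforce(self, lock_bundle):
        model, _ann, _bw = lock_bundle
        chain = model.chain("A")
        rng = np.random.default_rng(0)
        picks = rng.choice(len(chain), size=5, replace=False)
        for i, j in itertools.combinations(picks, 2):
            res_a, res_b = chain[i], chain[j]
            expected = min(
                float(np.linalg.norm(a.coord - b.coord))
                for a in res_a.atoms for b in res_b.atoms
                if a.element != "H" and b.element != "H")
            assert pair_distance(res_a, res_b, "min_heavy") == \
                pytest.approx(expected)

    def test_glycine_sidechain_fallback_warns(self):
        gly = full_residue("GLY")
        leu = full_residue("LEU", 2)
        for atom in leu.atoms:
            atom.coord = atom.coord + np.array([8.0, 0, 0])
        with pytest.warns(UserWarning, match="glycine"):
            d = pair_distance(gly, leu, "min_sidechain_heavy")
        assert d > 0

    def test_named_atoms_and_missing(self):
        a = full_residue("ALA")
        b = full_residue("ILE", 2)
        d = pair_distance(a, b, "named_atoms", atoms=("CB", "CD1"))
        assert d >= 0
        with pytest.raises(MeasurementError):
            pair_distance(a, b, "named_atoms", atoms=("CB", "XX9"))
        with pytest.raises(MeasurementError):
            pair_distance(a, b, "min_heavy_bogus")


class TestClassifyTiers:
    @pytest.mark.parametrize("name_a,name_b,group_a,group_b,target,tier", [
        ("ARG", "ASP", ("NH1", "NH2", "NE"), ("OD1", "OD2"), 3.0, "salt_bridge"),
        ("ASN", "ASP", ("ND2", "OD1"), ("OD1", "OD2"), 3.2, "hbond"),
        ("ASN", "ASP", ("ND2", "OD1"), ("OD1", "OD2"), 3.8, "weak_polar"),
        ("PHE", "PHE", ("CZ", "CE1", "CE2"), ("CZ", "CE1", "CE2"), 2.9, "aromatic"),
        ("LEU", "ILE", ("CD1", "CD2"), ("CD1",), 3.4, "hydrophobic_strong"),
        ("LEU", "ILE", ("CD1", "CD2"), ("CD1",), 4.2, "hydrophobic_weak"),
        ("LEU", "ILE", ("CD1", "CD2"), ("CD1",), 4.9, "none"),
        ("TYR", "TYR", ("OH",), ("OH",), 4.6, "water_mediated_possible"),
        ("SER", "LEU", ("OG",), ("CD1", "CD2"), 4.2, "induced_dipole"),
    ])
    def test_tier_ladder(self, name_a, name_b, group_a, group_b, target, tier):
        res_a, res_b = place_pair(name_a, name_b, group_a, group_b, target)
        rec = classify_pair(res_a, res_b)
        assert rec.tier == tier
        if tier != "none":
            assert rec.distance_A == pytest.approx(target, abs=0.2)

    def test_water_possible_flag_alongside(self):
        res_a, res_b = place_pair("TYR", "TYR", ("OH",), ("OH",), 4.6)
        rec = classify_pair(res_a, res_b)
        assert rec.water_mediated_possible
        assert not rec.is_contact

    @pytest.mark.parametrize("name_a,name_b,group_a,group_b,target", [
        ("ARG", "ASP", ("NH1",), ("OD1",), 3.4),
        ("PHE", "TYR", ("CZ",), ("CZ",), 4.0),
        ("LEU", "MET", ("CD1",), ("CE",), 3.9),
    ])
    def test_symmetry(self, name_a, name_b, group_a, group_b, target):
        res_a, res_b = place_pair(name_a, name_b, group_a, group_b, target)
        assert classify_pair(res_a, res_b).tier == classify_pair(res_b, res_a).tier

    def test_monotone_under_approach(self):
        """Bringing a pair closer never weakens the assigned tier."""
        strength = {"none": 0, "water_mediated_possible": 0,
                    "induced_dipole": 1, "hydrophobic_weak": 1,
                    "hydrophobic_strong": 2, "aromatic": 2, "weak_polar": 2,
                    "hbond": 3, "salt_bridge": 3}
        for name_a, name_b, ga, gb in [
                ("ASN", "ASP", ("ND2", "OD1"), ("OD1", "OD2")),
                ("LEU", "LEU", ("CD1", "CD2"), ("CD1", "CD2"))]:
            last = -1
            for d in (5.5, 4.8, 4.3, 3.8, 3.2):
                res_a, res_b = place_pair(name_a, name_b, ga, gb, d)
                s = strength[classify_pair(res_a, res_b).tier]
                assert s >= last
                last = s


class TestInteractionMap:
    def test_exactly_one_planted_salt_bridge(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        records = interaction_map(model, bwmap)
        bridges = [r for r in records if r.tier == "salt_bridge"]
        assert len(bridges) == 1
        assert {bridges[0].bw_a, bridges[0].bw_b} == {"3.50", "6.30"}
        assert bridges[0].distance_A == pytest.approx(3.0, abs=0.3)
        # sorted by distance
        dists = [r.distance_A for r in records]
        assert dists == sorted(dists)

    def test_separated_pair_loses_contact(self):
        spec = SyntheticBundleSpec(
            seed=3, n_helices=2, bundle_radius=14.0,
            planted_features=(ContactPair("1.50", "ARG", "2.50", "ASP", 3.0),))
        model, _ann, bwmap = build_bundle(spec)
        assert any(r.tier == "salt_bridge" for r in interaction_map(model, bwmap))
        far = translate_residues(model, "A", 201, 231, (60.0, 0.0, 0.0))
        assert interaction_map(far, bwmap) == []

    def test_map_matches_bruteforce(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        records = interaction_map(model, bwmap)
        keyed = {tuple(sorted((r.res_a, r.res_b))): r.tier for r in records}
        chain = model.chain("A")
        expected = {}
        for res_a, res_b in itertools.combinations(chain, 2):
            la, lb = bwmap.label_of(res_a.number), bwmap.label_of(res_b.number)
            if la is None or lb is None:
                continue
            if la.split(".")[0] == lb.split(".")[0] \
                    and abs(res_a.number - res_b.number) <= 4:
                continue
            rec = classify_pair(res_a, res_b, Cutoffs(), la, lb)
            if rec.tier != "none":
                expected[tuple(sorted((rec.res_a, rec.res_b)))] = rec.tier
        assert keyed == expected
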