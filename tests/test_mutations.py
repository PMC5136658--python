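import random

import pytest

from heptahelix.errors import HeptahelixError
from heptahelix.interactions import InteractionRecord as IR
from heptahelix.interactions import interaction_map
from heptahelix.mutations import (ConformationProfiles, PhenotypeRecord,
                                  load_phenotype_tables, lookup_phenotype,
                                  predict_mutation_effect,
                                  wt_interaction_profile)
from heptahelix.synthetic import (ContactPair, SyntheticBundleSpec,
                                  build_bundle)

from conftest import translate_residues


class TestPhenotypeTables:
    def test_row_counts_per_table(self):
        records = load_phenotype_tables()
        by_table = {}
        for rec in records:
            by_table.setdefault(rec.source_table, []).append(rec)
        assert {t: len(v) for t, v in sorted(by_table.items())} == {
            2: 10, 3: 17, 4: 23, 5: 7, 6: 6, 7: 19}

    def test_known_lookups(self):
        d633a = lookup_phenotype("TSHR", "D633A")
        assert d633a.category == "CAM"
        assert d633a.activity_fold_wt == pytest.approx(13.6)
        d460a = lookup_phenotype("TSHR", "D460A")
        assert d460a.category == "silencing"
        assert d460a.activity_fold_wt == pytest.approx(0.28)
        assert lookup_phenotype("TSHR", "Q999X") is None

    def test_record_validation(self):
        with pytest.raises(ValueError):
            PhenotypeRecord("TSHR", "A1B", "1.50", "bogus", "", None, 2)


def _rec(own_bw, tier, d, partner_res, partner_bw):
    return IR("A/XXX0", partner_res, own_bw, partner_bw, tier, d, None, None)


WORKED_CASES = {
    # FSHR M401T: hydrophobic with Ile3.46 inactive; induced dipole with
    # Arg3.50 active, upgradeable to a hydrogen bond by the new Thr
    "M401T": (ConformationProfiles(
        "2.43", "M",
        inactive=[_rec("2.43", "hydrophobic_strong", 3.8, "A/ILE463", "3.46")],
        active=[_rec("2.43", "induced_dipole", 3.9, "A/ARG467", "3.50")]),
        "active"),
    # LHR M398T: two strong + one weak hydrophobic inactive vs two weak active
    "M398T": (ConformationProfiles(
        "2.43", "M",
        inactive=[_rec("2.43", "hydrophobic_strong", 3.6, "A/ILE463", "3.46"),
                  _rec("2.43", "hydrophobic_strong", 3.7, "A/LEU405", "2.50"),
                  _rec("2.43", "hydrophobic_weak", 4.3, "A/VAL402", "2.44")],
        active=[_rec("2.43", "hydrophobic_weak", 4.2, "A/ILE463", "3.46"),
                _rec("2.43", "hydrophobic_weak", 4.3, "A/LEU405", "2.50")]),
        "active"),
    # Leu3.43 -> Arg: new hydrogen bonds to Asn7.45/7.49 in the active state
    "L512R": (ConformationProfiles(
        "3.43", "L",
        inactive=[_rec("3.43", "induced_dipole", 3.5, "A/ASP633", "6.44"),
                  _rec("3.43", "hydrophobic_weak", 4.4, "A/LEU456", "2.46")],
        active=[_rec("3.43", "induced_dipole", 3.5, "A/ASP633", "6.44"),
                _rec("3.43", "hydrophobic_weak", 4.4, "A/LEU456", "2.46"),
                _rec("3.43", "hydrophobic_strong", 3.3, "A/TYR678", "7.53"),
                _rec("3.43", "induced_dipole", 3.9, "A/ASN670", "7.45"),
                _rec("3.43", "induced_dipole", 3.9, "A/ASN674", "7.49")]),
        "active"),
    # L665F: no wild-type contacts; the longer Phe side chain reaches the
    # TM1/TM2 neighbours, which sit closer in the active state
    "L665F": (ConformationProfiles(
        "7.40", "L",
        inactive=[_rec("7.40", "none", 5.4, "A/LEU468", "2.58"),
                  _rec("7.40", "none", 5.7, "A/VAL421", "1.39"),
                  _rec("7.40", "none", 5.8, "A/VAL424", "1.42")],
        active=[_rec("7.40", "none", 4.4, "A/LEU468", "2.58"),
                _rec("7.40", "none", 5.2, "A/VAL421", "1.39"),
                _rec("7.40", "none", 4.8, "A/VAL424", "1.42")]),
        "active"),
    # Phe594/Phe634 aromatic pair: 2.9 A inactive (Ile still reaches),
    # 3.6 A active (Ile too short) -> active state destabilized
    "F594I": (ConformationProfiles(
        "5.51", "F",
        inactive=[_rec("5.51", "aromatic", 2.9, "A/PHE634", "6.45")],
        active=[_rec("5.51", "aromatic", 3.6, "A/PHE634", "6.45")]),
        "inactive"),
    "F634I": (ConformationProfiles(
        "6.45", "F",
        inactive=[_rec("6.45", "aromatic", 2.9, "A/PHE594", "5.51")],
        active=[_rec("6.45", "aromatic", 3.6, "A/PHE594", "5.51")]),
        "inactive"),
    # D633A: breaks the weak polar contact to Asn7.49 that holds the
    # inactive state
    "D633A": (ConformationProfiles(
        "6.44", "D",
        inactive=[_rec("6.44", "weak_polar", 3.8, "A/ASN674", "7.49"),
                  _rec("6.44", "induced_dipole", 3.5, "A/LEU512", "3.43")],
        active=[_rec("6.44", "induced_dipole", 3.5, "A/LEU512", "3.43")]),
        "active"),
    # D460A: breaks the TM2-TM7/TM3 hydrogen-bond network, denser in the
    # active state
    "D460A": (ConformationProfiles(
        "2.50", "D",
        inactive=[_rec("2.50", "hbond", 3.4, "A/ASN674", "7.49"),
                  _rec("2.50", "hbond", 3.4, "A/SER671", "7.46")],
        active=[_rec("2.50", "hbond", 3.0, "A/ASN674", "7.49"),
                _rec("2.50", "hbond", 3.0, "A/SER671", "7.46"),
                _rec("2.50", "hbond", 3.2, "A/SER508", "3.39")]),
        "inactive"),
}


class TestPredictEffect:
    @pytest.mark.parametrize("mutation", sorted(WORKED_CASES))
    def test_worked_cases_direction(self, mutation):
        profiles, expected = WORKED_CASES[mutation]
        effect = predict_mutation_effect(mutation, profiles)
        assert effect.stabilization_call == expected

    def test_consistency_against_phenotypes(self):
        effect = predict_mutation_effect("D633A", WORKED_CASES["D633A"][0],
                                         lookup_phenotype("TSHR", "D633A"))
        assert effect.phenotype_consistency == "consistent"
        effect = predict_mutation_effect("D460A", WORKED_CASES["D460A"][0],
                                         lookup_phenotype("TSHR", "D460A"))
        assert effect.phenotype_consistency == "consistent"
        # a deliberately contradicting phenotype
        effect = predict_mutation_effect("D460A", WORKED_CASES["D460A"][0],
                                         lookup_phenotype("TSHR", "D633A"))
        assert effect.phenotype_consistency == "inconsistent"

    def test_identity_substitution_neutral(self):
        effect = predict_mutation_effect("L512L", WORKED_CASES["L512R"][0])
        assert effect.stabilization_call == "neutral"
        assert effect.phenotype_consistency == "untestable"

    def test_no_contacts_untestable(self):
        effect = predict_mutation_effect(
            "A575V", ConformationProfiles("6.38", "A"))
        assert effect.stabilization_call == "neutral"
        assert effect.phenotype_consistency == "untestable"
        assert any("membrane" in note for note in effect.notes)

    def test_unknown_code_and_bad_format(self):
        with pytest.raises(HeptahelixError):
            predict_mutation_effect("B512R", WORKED_CASES["L512R"][0])
        with pytest.raises(HeptahelixError):
            predict_mutation_effect("512R", WORKED_CASES["L512R"][0])

    def test_order_independence(self):
        profiles, _ = WORKED_CASES["L512R"]
        shuffled = ConformationProfiles(
            profiles.bw_label, profiles.wt_residue,
            inactive=list(reversed(profiles.inactive)),
            active=random.Random(5).sample(profiles.active,
                                           len(profiles.active)))
        a = predict_mutation_effect("L512R", profiles)
        b = predict_mutation_effect("L512R", shuffled)
        assert (a.score_inactive, a.score_active,
                a.stabilization_call) == \
            (b.score_inactive, b.score_active, b.stabilization_call)


@pytest.fixture(scope="module")
def contact_pair_states():
    spec = SyntheticBundleSpec(
        seed=21, scatter=False,
        planted_features=(
            ContactPair("3.50", "ARG", "6.30", "ASP", 3.0),
            ContactPair("3.50", "ARG", "2.50", "ASN", 3.2, orient=False),
        ))
    inactive, _ann, bwmap = build_bundle(spec)
    # "active": both partner helices pushed far away
    active = translate_residues(inactive, "A", 601, 631, (40.0, 0.0, 0.0))
    active = translate_residues(active, "A", 201, 231, (-40.0, 0.0, 0.0))
    return inactive, active, bwmap


class TestProfiles:
    def test_two_contacts_then_none(self, contact_pair_states):
        inactive, active, bwmap = contact_pair_states
        prof = wt_interaction_profile("3.50", inactive, active, bwmap, bwmap)
        inactive_contacts = [r for r in prof.inactive if r.is_contact]
        partners = {r.bw_b if r.bw_a == "3.50" else r.bw_a
                    for r in inactive_contacts}
        assert {"6.30", "2.50"} <= partners
        active_contacts = {r.bw_b if r.bw_a == "3.50" else r.bw_a
                           for r in prof.active if r.is_contact}
        assert not {"6.30", "2.50"} & active_contacts

    def test_profile_matches_map_filter(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        prof = wt_interaction_profile("3.50", model, model, bwmap, bwmap)
        from_map = {(*sorted((r.res_a, r.res_b)), r.tier)
                    for r in interaction_map(model, bwmap)
                    if "3.50" in (r.bw_a, r.bw_b)}
        from_profile = {(*sorted((r.res_a, r.res_b)), r.tier)
                        for r in prof.inactive if r.is_contact}
        assert from_profile == from_map

    def test_one_sided_profile_flagged(self, lock_bundle):
        model, ann, bwmap = lock_bundle
        # active state lacking the 3.50 residue entirely
        import copy
        gutted = model.copy()
        gutted.chains["A"] = [r for r in gutted.chains["A"] if r.number != 323]
        prof = wt_interaction_profile("3.50", model, gutted, bwmap, bwmap)
        assert prof.inactive and not prof.active
        assert any("active" in f for f in prof.flags)
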