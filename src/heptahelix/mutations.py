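"""Rationalization of activating/silencing receptor mutations.

The annotator is explicitly heuristic and qualitative: it compares the
interactions a wild-type residue makes in the inactive and active
conformations and asks which conformation a substitution would stabilize
(or destabilize less), predicting a *direction* -- never a fold change.

Rule set, applied per conformation over all interactions (and near-miss
neighbours) of the wild-type residue:

* every interaction carries a weight (strong tiers 1.0; weak polar, weak
  hydrophobic and induced-dipole 0.5 -- the induced-dipole discount because
  its strength is poorly characterized);
* the substituted residue is given the best interaction it could still make
  with the same partner at the recorded distance: polar/charged capability
  is judged at the recorded distance (a new hydrogen-bond donor "introduced
  near" the partner), while hydrophobic/aromatic capability is judged at a
  reach-adjusted distance (recorded distance corrected by the difference in
  maximum side-chain extension, so shorter side chains lose long contacts
  and longer ones gain them);
* the conformation score is the sum of (new weight - old weight); the
  mutation is called stabilizing for the conformation with the higher score
  (losing less counts as stabilizing), a tie is neutral;
* predictions are checked against the packaged phenotype tables:
  active-stabilizing is consistent with constitutive activation (CAM /
  activating), inactive-stabilizing with silencing / inactivating.

Membrane-exposure arguments (a residue shielded from or exposed to lipid)
are outside the rule set: a residue with no inter-helical interactions and
no near neighbours returns "untestable".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .chemdata import (ACCEPTOR_AA, APOLAR_AA, AROMATIC_AA, DONOR_AA,
                       NEG_CHARGED_AA, POS_CHARGED_AA, SIDECHAIN_REACH,
                       three_to_one)
from .errors import HeptahelixError
from .interactions import Cutoffs, InteractionRecord, classify_pair
from .structure_io import StructureModel
from .bw import BWMap

__all__ = ["PhenotypeRecord", "ConformationProfiles", "MutationEffect",
           "load_phenotype_tables", "lookup_phenotype",
           "wt_interaction_profile", "predict_mutation_effect",
           "TIER_WEIGHTS"]

TIER_WEIGHTS = {
    "salt_bridge": 1.0,
    "hbond": 1.0,
    "aromatic": 1.0,
    "hydrophobic_strong": 1.0,
    "weak_polar": 0.5,
    "hydrophobic_weak": 0.5,
    "induced_dipole": 0.5,   # counted at half weight: strength never quantified
    "water_mediated_possible": 0.0,
    "none": 0.0,
}

_TABLE_FILES = {
    2: ("table2_fshr_activating.tsv", "FSHR"),
    3: ("table3_lhr_activating.tsv", "LHR"),
    4: ("table4_tshr_activating.tsv", "TSHR"),
    5: ("table5_fshr_inactivating.tsv", "FSHR"),
    6: ("table6_lhr_inactivating.tsv", "LHR"),
    7: ("table7_tshr_inactivating.tsv", "TSHR"),
}

_CATEGORY = {"cam": "CAM", "activating": "activating",
             "inactivating": "inactivating", "silencing": "silencing"}


@dataclass(frozen=True)
class PhenotypeRecord:
    receptor: str
    mutation: str
    bw: str
    category: str
    activity: str
    activity_fold_wt: float | None
    source_table: int

    def __post_init__(self):
        if self.category not in _CATEGORY.values():
            raise ValueError(f"unknown category {self.category!r}")
        if self.activity_fold_wt is not None and self.activity_fold_wt < 0:
            raise ValueError("activity fold must be >= 0")


def _parse_fold(activity: str) -> float | None:
    if not isinstance(activity, str):
        return None
    m = re.search(r"cAMP ([\d.]+)-fold WT", activity)
    return float(m.group(1)) if m else None


def load_phenotype_tables() -> list[PhenotypeRecord]:
    """All rows of the packaged receptor mutation-phenotype tables.

    Tables are stored verbatim from their sources and never cross-checked
    against each other (they contain known internal numbering conflicts).
    """
    records: list[PhenotypeRecord] = []
    base = resources.files("heptahelix").joinpath("data/phenotypes")
    for table, (fname, receptor) in _TABLE_FILES.items():
        path = base.joinpath(fname)
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except Exception as exc:
            raise HeptahelixError(f"cannot load phenotype table {fname}: {exc}")
        if list(df.columns) != ["mutation", "bw", "type", "activity"]:
            raise HeptahelixError(f"malformed phenotype table {fname}")
        for _, row in df.iterrows():
            category = _CATEGORY.get(row["type"].strip().lower())
            if category is None:
                raise HeptahelixError(
                    f"{fname}: unknown mutation type {row['type']!r}")
            records.append(PhenotypeRecord(
                receptor=receptor, mutation=row["mutation"].strip(),
                bw=row["bw"].strip(), category=category,
                activity=row["activity"].strip(),
                activity_fold_wt=_parse_fold(row["activity"]),
                source_table=table))
    return records


def lookup_phenotype(receptor: str, mutation: str,
                     records: list[PhenotypeRecord] | None = None
                     ) -> PhenotypeRecord | None:
    records = records if records is not None else load_phenotype_tables()
    for rec in records:
        if rec.receptor == receptor.upper() and rec.mutation == mutation:
            return rec
    return None


# ---------------------------------------------------------------------------
# wild-type interaction profiles


@dataclass
class ConformationProfiles:
    """Interactions (and near-miss neighbours) of one residue per state."""

    bw_label: str
    wt_residue: str                 # one-letter
    inactive: list[InteractionRecord] = field(default_factory=list)
    active: list[InteractionRecord] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def records(self, conformation: str) -> list[InteractionRecord]:
        return getattr(self, conformation)


def _profile_one_state(model: StructureModel, bwmap: BWMap, bw_label: str,
                       cutoffs: Cutoffs, neighbor_cutoff: float
                       ) -> list[InteractionRecord] | None:
    number = bwmap.number_of(bw_label)
    if number is None:
        return None
    res = model.residue(bwmap.chain_id, number)
    if res is None:
        return None
    helix = bw_label.split(".")[0]
    out = []
    for other in model.chain(bwmap.chain_id):
        label = bwmap.label_of(other.number)
        if label is None or other.number == number:
            continue
        if label.split(".")[0] == helix and abs(other.number - number) <= 4:
            continue
        rec = classify_pair(res, other, cutoffs, bw_label, label)
        if rec.tier != "none" or (rec.distance_A <= neighbor_cutoff):
            out.append(rec)
    out.sort(key=lambda r: r.distance_A)
    return out


def wt_interaction_profile(bw_label: str,
                           inactive_model: StructureModel,
                           active_model: StructureModel,
                           bw_inactive: BWMap, bw_active: BWMap,
                           cutoffs: Cutoffs = Cutoffs(),
                           neighbor_cutoff: float = 6.5
                           ) -> ConformationProfiles:
    """Paired interaction lists of the residue at ``bw_label``.

    Near-miss pairs (tier 'none' but within ``neighbor_cutoff`` of the side
    chain) are included so the effect engine can evaluate gained contacts.
    A residue unresolved in one state yields a one-sided profile with a flag.
    """
    number = bw_inactive.number_of(bw_label) or bw_active.number_of(bw_label)
    wt = "X"
    for model, bwmap in ((inactive_model, bw_inactive), (active_model, bw_active)):
        num = bwmap.number_of(bw_label)
        res = model.residue(bwmap.chain_id, num) if num is not None else None
        if res is not None:
            wt = res.one_letter
            break
    prof = ConformationProfiles(bw_label=bw_label, wt_residue=wt)
    for name, model, bwmap in (("inactive", inactive_model, bw_inactive),
                               ("active", active_model, bw_active)):
        records = _profile_one_state(model, bwmap, bw_label, cutoffs,
                                     neighbor_cutoff)
        if records is None:
            prof.flags.append(f"residue {bw_label} unresolved in {name} state")
        else:
            setattr(prof, name, records)
    return prof


# ---------------------------------------------------------------------------
# effect prediction


@dataclass
class MutationEffect:
    mutation: str
    bw_label: str
    score_inactive: float
    score_active: float
    changes: dict[str, list[str]]
    stabilization_call: str          # "active" | "inactive" | "neutral"
    phenotype_consistency: str       # "consistent" | "inconsistent" | "untestable"
    notes: list[str] = field(default_factory=list)


_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def _partner_aa(rec: InteractionRecord, own_label: str) -> tuple[str, str]:
    """(one-letter type, descriptor) of the record's other residue."""
    if rec.bw_a == own_label:
        res_id, bw = rec.res_b, rec.bw_b
    else:
        res_id, bw = rec.res_a, rec.bw_a
    name3 = re.sub(r"\d+.*$", "", res_id.split("/")[-1])
    return three_to_one(name3), f"{res_id}({bw})"


def _is_polar(aa: str) -> bool:
    return aa in DONOR_AA or aa in ACCEPTOR_AA or aa in POS_CHARGED_AA \
        or aa in NEG_CHARGED_AA


def _best_weight(new_aa: str, old_aa: str, partner: str, distance: float,
                 cutoffs: Cutoffs) -> tuple[float, str]:
    """Best interaction the substituted residue can make with the partner.

    Polar capability is judged at the recorded distance; hydrophobic,
    aromatic and induced-dipole capability at the reach-adjusted distance.
    """
    reach_delta = SIDECHAIN_REACH.get(new_aa, 0.0) - SIDECHAIN_REACH.get(old_aa, 0.0)
    d_adj = distance - reach_delta
    options: list[tuple[float, str]] = [(0.0, "none")]
    opposite = (new_aa in POS_CHARGED_AA and partner in NEG_CHARGED_AA) or \
               (new_aa in NEG_CHARGED_AA and partner in POS_CHARGED_AA)
    if opposite and distance <= cutoffs.salt_bridge:
        options.append((1.0, "salt_bridge"))
    if _is_polar(new_aa) and _is_polar(partner) \
            and distance <= cutoffs.weak_polar_upper:
        options.append((1.0, "hbond"))
    if new_aa in AROMATIC_AA and partner in AROMATIC_AA \
            and d_adj <= cutoffs.aromatic:
        options.append((1.0, "aromatic"))
    if new_aa in APOLAR_AA and (partner in APOLAR_AA or partner in AROMATIC_AA):
        if d_adj <= cutoffs.hydrophobic_strong:
            options.append((1.0, "hydrophobic_strong"))
        elif d_adj <= cutoffs.hydrophobic_weak_upper:
            options.append((0.5, "hydrophobic_weak"))
    polar_apolar = (_is_polar(new_aa) and partner in APOLAR_AA) or \
                   (new_aa in APOLAR_AA and _is_polar(partner))
    if polar_apolar and d_adj <= cutoffs.induced_dipole:
        options.append((0.5, "induced_dipole"))
    return max(options, key=lambda t: t[0])


def predict_mutation_effect(mutation: str, profiles: ConformationProfiles,
                            phenotype: PhenotypeRecord | None = None,
                            cutoffs: Cutoffs = Cutoffs()) -> MutationEffect:
    """Direction call for one substitution given wild-type profiles.

    Deterministic and order-independent over the profile lists.
    """
    m = _MUT_RE.match(mutation.strip().upper())
    if not m:
        raise HeptahelixError(f"cannot parse mutation {mutation!r} (e.g. L512R)")
    old_aa, _number, new_aa = m.group(1), m.group(2), m.group(3)
    if old_aa not in SIDECHAIN_REACH or new_aa not in SIDECHAIN_REACH:
        raise HeptahelixError(f"unknown residue code in {mutation!r}")

    notes: list[str] = list(profiles.flags)
    if profiles.wt_residue not in ("X", old_aa):
        notes.append(f"profile wild-type residue is {profiles.wt_residue}, "
                     f"mutation names {old_aa}")

    if new_aa == old_aa:
        return MutationEffect(mutation, profiles.bw_label, 0.0, 0.0,
                              {"inactive": [], "active": []},
                              "neutral", "untestable",
                              notes + ["identity substitution"])

    if not profiles.inactive and not profiles.active:
        return MutationEffect(
            mutation, profiles.bw_label, 0.0, 0.0,
            {"inactive": [], "active": []}, "neutral", "untestable",
            notes + ["no inter-helical interactions or near neighbours; "
                     "possibly membrane-facing (outside the rule set)"])

    scores = {}
    changes: dict[str, list[str]] = {}
    for conformation in ("inactive", "active"):
        total = 0.0
        change_log = []
        for rec in sorted(profiles.records(conformation),
                          key=lambda r: (r.distance_A, r.res_a, r.res_b)):
            if not np_isfinite(rec.distance_A):
                continue
            partner, desc = _partner_aa(rec, profiles.bw_label)
            w_old = TIER_WEIGHTS.get(rec.tier, 0.0)
            w_new, new_tier = _best_weight(new_aa, old_aa, partner,
                                           rec.distance_A, cutoffs)
            delta = w_new - w_old
            total += delta
            if delta:
                verb = "gain" if delta > 0 else "loss"
                change_log.append(
                    f"{verb} {desc}: {rec.tier}({w_old:g}) -> "
                    f"{new_tier}({w_new:g}) at {rec.distance_A:.1f} A")
        scores[conformation] = total
        changes[conformation] = change_log

    if scores["active"] > scores["inactive"]:
        call = "active"
    elif scores["inactive"] > scores["active"]:
        call = "inactive"
    else:
        call = "neutral"

    if phenotype is None or call == "neutral":
        consistency = "untestable"
    elif (call == "active") == (phenotype.category in ("CAM", "activating")):
        consistency = "consistent"
    else:
        consistency = "inconsistent"

    return MutationEffect(mutation, profiles.bw_label,
                          scores["inactive"], scores["active"],
                          changes, call, consistency, notes)


def np_isfinite(x: float) -> bool:
    return x == x and abs(x) != float("inf")
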