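"""Distance measurements on public GPCR crystal structures.

Six entries document how the 7.40/1.39 residue pair tightens on activation
across three receptors solved in both states (rhodopsin 1U19/3PQR, beta2
adrenergic 2RH1/3SN6, M2 muscarinic 3UON/4MQS), plus the Tyr7.53-Tyr5.58
"toggle" distance of metarhodopsin II. Packaged configs map the generic
positions to author residue numbers (derived from the canonical x.50 motif
anchors of each receptor).

Structures are NOT packaged: `measure_crystal_distances` needs either a
directory of previously downloaded files or network access (``fetch=True``).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import HeptahelixError, MeasurementError
from .interactions import pair_distance
from .structure_io import StructureModel, fetch_structure, read_structure

__all__ = ["CRYSTAL_ACCESSIONS", "load_crystal_config",
           "measure_crystal_distances", "measure_all_crystal_distances"]

CRYSTAL_ACCESSIONS = ("1U19", "3PQR", "2RH1", "3SN6", "3UON", "4MQS")


def load_crystal_config(accession: str) -> dict:
    path = resources.files("heptahelix").joinpath(
        f"data/crystal/{accession.lower()}.yaml")
    with path.open() as fh:
        cfg = yaml.safe_load(fh)
    if "chain_id" not in cfg or "positions" not in cfg:
        raise HeptahelixError(f"bad crystal config for {accession}")
    return cfg


def _residue(model: StructureModel, chain_id: str, number: int):
    res = model.residue(chain_id, number)
    if res is None:
        raise MeasurementError(
            f"{model.id}: residue {number} absent from chain {chain_id}")
    return res


def measure_crystal_distances(accession: str, structure_dir,
                              fetch: bool = False) -> dict[str, float]:
    """7.40/1.39 side-chain and CA distances (plus the 7.53/5.58 toggle when
    configured) for one entry, in Angstrom rounded to 0.1."""
    cfg = load_crystal_config(accession)
    structure_dir = Path(structure_dir)
    path = structure_dir / f"{accession.lower()}.pdb"
    if not path.exists():
        alt = structure_dir / f"{accession.lower()}.cif"
        if alt.exists():
            path = alt
        elif fetch:
            path = fetch_structure(accession, structure_dir)
        else:
            raise MeasurementError(
                f"{accession}: no local structure in {structure_dir} "
                "(pass fetch=True to download)")
    model = read_structure(path, id=accession)
    chain = cfg["chain_id"]
    positions = cfg["positions"]
    r740 = _residue(model, chain, int(positions["7.40"]))
    r139 = _residue(model, chain, int(positions["1.39"]))
    out = {
        "sidechain_7.40_1.39_A": round(
            pair_distance(r740, r139, "min_sidechain_heavy"), 1),
        "ca_7.40_1.39_A": round(pair_distance(r740, r139, "ca"), 1),
    }
    if "7.53" in positions and "5.58" in positions:
        r753 = _residue(model, chain, int(positions["7.53"]))
        r558 = _residue(model, chain, int(positions["5.58"]))
        out["sidechain_7.53_5.58_A"] = round(
            pair_distance(r753, r558, "min_sidechain_heavy"), 1)
    return out


def measure_all_crystal_distances(structure_dir, fetch: bool = False
                                  ) -> dict[str, dict[str, float]]:
    return {acc: measure_crystal_distances(acc, structure_dir, fetch=fetch)
            for acc in CRYSTAL_ACCESSIONS}
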