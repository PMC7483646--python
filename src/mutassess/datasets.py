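"""Packaged reference tables for the ULK1 kinase-domain case study.

Two small curated tables ship with the package:

* the TCGA-derived missense mutations of the ULK1 kinase domain (residues
  8-280, UniProt O75385 numbering) with their cancer studies, REVEL scores,
  co-occurring ULK2 kinase-domain mutations, expression calls for the tumour
  type and PTM/SLiM annotations;
* the persistent salt bridges involving charged mutation sites, with their
  persistence (% of frames) in each of the two force-field ensembles.

These are program inputs for the worked examples and the curation stage;
nothing downstream depends on them being the only possible inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ensemble_io import ResidueID
from .genomics import MutationRecord, parse_protein_change
from .psn import InteractionRecord

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _data_path(name: str):
    return resources.files("mutassess").joinpath("data", name)


def ulk1_mutation_table() -> pd.DataFrame:
    """The curated ULK1 kinase-domain missense-mutation table, as shipped."""
    with resources.as_file(_data_path("ulk1_kinase_mutations.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def ulk1_mutations() -> list[MutationRecord]:
    """Curated mutations as :class:`MutationRecord` objects."""
    out = []
    for _, row in ulk1_mutation_table().iterrows():
        wt, pos, mut = parse_protein_change(row["mutation"])
        out.append(
            MutationRecord(
                "ULK1",
                wt,
                pos,
                mut,
                studies=tuple(str(row["studies"]).split(";")),
                revel=float(row["revel"]),
            )
        )
    return out


def ulk1_salt_bridge_table() -> pd.DataFrame:
    with resources.as_file(_data_path("ulk1_salt_bridges.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def ulk1_salt_bridge_records(ensemble: str = "charmm22star", chain: str = "A") -> list[InteractionRecord]:
    """Salt-bridge interaction records for one force-field ensemble.

    The tabulated persistences are reconstructed as occurrence vectors over
    1000 nominal frames so they interoperate with
    :func:`mutassess.stability.saltbridge_loss`.
    """
    import numpy as np

    df = ulk1_salt_bridge_table()
    df = df[df["ensemble"] == ensemble]
    records = []
    seen = set()
    for _, row in df.iterrows():
        a_letter, a_pos = row["site"][0], int(row["site"][1:])
        b_letter, b_pos = row["partner"][0], int(row["partner"][1:])
        key = frozenset({a_pos, b_pos})
        if key in seen:
            continue
        seen.add(key)
        ra = ResidueID(chain, a_pos, ONE_TO_THREE[a_letter])
        rb = ResidueID(chain, b_pos, ONE_TO_THREE[b_letter])
        n_on = int(round(row["persistence"] * 10))  # persistence over 1000 frames
        occ = np.zeros(1000, dtype=bool)
        occ[:n_on] = True
        records.append(InteractionRecord(ra, rb, occ, "salt_bridge"))
    return records
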