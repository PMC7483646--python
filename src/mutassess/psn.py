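"""Persistence-weighted protein structure networks (PSN).

Residues are nodes; an edge joins two residues whose interaction (side-chain
contact, salt bridge or hydrogen bond) occurs in at least a given fraction
of the ensemble frames.  Edge weight is the persistence in % of frames.
Defaults follow the contact-PSN convention: 5 A side-chain center-of-mass
cutoff, 20% persistence, hubs at degree >= 3; salt bridges use a 4.5 A
minimum charged-group atom distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .ensemble_io import ConformationalEnsemble, ResidueID

logger = logging.getLogger(__name__)

#: charged-moiety atom names (the carboxylic, ammonium and guanidinium groups)
ACIDIC_GROUPS = {"ASP": ("OD1", "OD2", "CG"), "GLU": ("OE1", "OE2", "CD")}
BASIC_GROUPS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE", "CZ")}
#: doubly-protonated histidine imidazole, opt-in via include_histidine
HIS_GROUP = {"HIS": ("ND1", "NE2", "CE1")}

#: side-chain hydrogen-bond donors / acceptors by residue type (heavy atoms)
HBOND_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "TRP": ("NE1",), "CYS": ("SG",),
}
HBOND_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "ASN": ("OD1",),
    "GLN": ("OE1",), "HIS": ("ND1", "NE2"), "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"), "MET": ("SD",), "CYS": ("SG",),
}


class PSNGraph(nx.Graph):
    """Undirected residue graph; edge attribute ``persistence`` in (0, 100].

    Graph-level metadata lives in ``self.graph``: ``interaction_type``,
    ``distance_cutoff``, ``persistence_cutoff`` and the frame count used.
    """

    @property
    def interaction_type(self) -> str:
        return self.graph.get("interaction_type", "contact")


@dataclass
class InteractionRecord:
    """Occurrence of one residue-pair interaction across the ensemble."""

    residue_a: ResidueID
    residue_b: ResidueID
    occurrence: np.ndarray  # per-frame booleans
    interaction_type: str = "contact"

    @property
    def persistence(self) -> float:
        occ = np.asarray(self.occurrence, bool)
        return 100.0 * occ.sum() / occ.size

    @property
    def pair(self) -> tuple[ResidueID, ResidueID]:
        return tuple(sorted((self.residue_a, self.residue_b)))


def _check_cutoffs(distance_cutoff: float, persistence_cutoff: float) -> None:
    if distance_cutoff <= 0:
        raise ValueError(f"distance cutoff must be positive, got {distance_cutoff}")
    if not 0 < persistence_cutoff <= 100:
        raise ValueError(f"persistence cutoff must be in (0, 100], got {persistence_cutoff}")


def _new_graph(ensemble, interaction_type, distance_cutoff, persistence_cutoff) -> PSNGraph:
    g = PSNGraph(
        interaction_type=interaction_type,
        distance_cutoff=float(distance_cutoff),
        persistence_cutoff=float(persistence_cutoff),
        n_frames=ensemble.n_frames,
    )
    g.add_nodes_from(ensemble.residues)
    return g


def build_contact_psn(
    ensemble: ConformationalEnsemble,
    distance_cutoff: float = 5.0,
    persistence_cutoff: float = 20.0,
    sequence_exclusion: int = 1,
) -> PSNGraph:
    """Contact PSN from side-chain center-of-mass distances.

    An edge (i, j) is added iff the COM distance is below ``distance_cutoff``
    in at least ``persistence_cutoff`` % of the frames (inclusive threshold)
    and |seq(i) - seq(j)| > ``sequence_exclusion`` for same-chain pairs.
    """
    _check_cutoffs(distance_cutoff, persistence_cutoff)
    g = _new_graph(ensemble, "contact", distance_cutoff, persistence_cutoff)
    res = ensemble.residues
    if len(res) < 2:
        return g
    coms = ensemble.sidechain_com_trajectory()  # (F, R, 3)
    diff = coms[:, :, None, :] - coms[:, None, :, :]
    within = np.linalg.norm(diff, axis=-1) < distance_cutoff  # (F, R, R)
    persistence = 100.0 * within.mean(axis=0)
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            if res[i].chain == res[j].chain and abs(res[i].position - res[j].position) <= sequence_exclusion:
                continue
            if persistence[i, j] >= persistence_cutoff:
                g.add_edge(res[i], res[j], persistence=float(persistence[i, j]))
    return g


def hubs(graph: PSNGraph, min_degree: int = 3) -> dict[ResidueID, int]:
    """Residues with at least ``min_degree`` edges, with their degrees."""
    return {n: d for n, d in graph.degree() if d >= min_degree}


def connected_components(graph: PSNGraph) -> tuple[list[set], list]:
    """Clusters of connected residues.

    Returns (components, singletons): components of size >= 2 sorted by
    descending size, and isolated nodes reported separately.
    """
    comps = [set(c) for c in nx.connected_components(graph)]
    multi = sorted((c for c in comps if len(c) > 1), key=lambda c: (-len(c), sorted(c)[0]))
    single = sorted(n for c in comps if len(c) == 1 for n in c)
    return multi, single


def _group_min_distances(ensemble, groups_a, groups_b):
    """Per-frame minimum atom-atom distance for every (a, b) residue-group pair.

    ``groups_*`` map residue -> atom index list.  Yields (res_a, res_b, dmin)
    with dmin an (n_frames,) array.
    """
    for ra, ia in groups_a.items():
        for rb, ib in groups_b.items():
            if ra == rb:
                continue
            dmin = np.empty(ensemble.n_frames)
            for f in range(ensemble.n_frames):
                dmin[f] = cdist(ensemble.coords[f, ia], ensemble.coords[f, ib]).min()
            yield ra, rb, dmin


def _charged_groups(ensemble, table):
    out = {}
    for r in ensemble.residues:
        names = table.get(r.name.upper())
        if not names:
            continue
        idx = [i for i in ensemble.atom_indices(r) if ensemble.atoms[i].atom_name in names]
        if idx:
            out[r] = idx
    return out


def build_salt_bridge_network(
    ensemble: ConformationalEnsemble,
    distance_cutoff: float = 4.5,
    persistence_cutoff: float = 20.0,
    include_histidine: bool = False,
) -> tuple[PSNGraph, list[InteractionRecord]]:
    """Salt-bridge network between acidic (Asp/Glu) and basic (Lys/Arg) residues.

    A pair interacts in a frame iff any atom of the carboxylate group lies
    closer than ``distance_cutoff`` to any atom of the basic group.  The graph
    keeps pairs at or above the persistence cutoff; the records list every
    pair with persistence > 0.
    """
    _check_cutoffs(distance_cutoff, persistence_cutoff)
    g = _new_graph(ensemble, "salt_bridge", distance_cutoff, persistence_cutoff)
    basic = dict(BASIC_GROUPS)
    if include_histidine:
        basic.update(HIS_GROUP)
    acidic_groups = _charged_groups(ensemble, ACIDIC_GROUPS)
    basic_groups = _charged_groups(ensemble, basic)
    records: list[InteractionRecord] = []
    for ra, rb, dmin in _group_min_distances(ensemble, acidic_groups, basic_groups):
        occ = dmin < distance_cutoff
        if not occ.any():
            continue
        rec = InteractionRecord(ra, rb, occ, "salt_bridge")
        records.append(rec)
        if rec.persistence >= persistence_cutoff:
            g.add_edge(ra, rb, persistence=rec.persistence)
    records.sort(key=lambda r: r.pair)
    return g, records


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition (donor/acceptor heavy atoms)."""

    distance_cutoff: float = 3.5  # donor-acceptor heavy-atom distance, A
    angle_cutoff: float = 120.0  # donor-H-acceptor angle, degrees
    use_angle: bool = True  # falls back to distance-only without hydrogens


def _hbond_atoms(ensemble, table, include_backbone, backbone_name):
    out: dict[ResidueID, list[int]] = {}
    for r in ensemble.residues:
        names = set(table.get(r.name.upper(), ()))
        if include_backbone:
            names.add(backbone_name)
        idx = [i for i in ensemble.atom_indices(r) if ensemble.atoms[i].atom_name in names]
        if idx:
            out[r] = idx
    return out


def build_hbond_network(
    ensemble: ConformationalEnsemble,
    criteria: HBondCriteria | None = None,
    persistence_cutoff: float = 20.0,
    sequence_exclusion: int = 1,
    include_backbone: bool = False,
) -> tuple[PSNGraph, list[InteractionRecord]]:
    """Hydrogen-bond network from donor/acceptor geometry.

    Without hydrogen coordinates (the usual case for heavy-atom ensembles)
    the angle criterion cannot be evaluated; a warning is logged and the
    distance criterion alone applies.
    """
    criteria = criteria or HBondCriteria()
    _check_cutoffs(criteria.distance_cutoff, persistence_cutoff)
    has_h = any(a.is_hydrogen for a in ensemble.atoms)
    if criteria.use_angle and not has_h:
        logger.warning("no hydrogen coordinates: hydrogen-bond angle criterion disabled, using distance only")
    use_angle = criteria.use_angle and has_h

    donors = _hbond_atoms(ensemble, HBOND_DONORS, include_backbone, "N")
    acceptors = _hbond_atoms(ensemble, HBOND_ACCEPTORS, include_backbone, "O")
    g = _new_graph(ensemble, "hbond", criteria.distance_cutoff, persistence_cutoff)
    occ_by_pair: dict[tuple, np.ndarray] = {}
    cos_min = math.cos(math.radians(criteria.angle_cutoff))
    for rd, di in donors.items():
        for ra, ai in acceptors.items():
            if rd == ra:
                continue
            if (
                rd.chain == ra.chain
                and abs(rd.position - ra.position) <= sequence_exclusion
            ):
                continue
            occ = np.zeros(ensemble.n_frames, dtype=bool)
            for f in range(ensemble.n_frames):
                d = cdist(ensemble.coords[f, di], ensemble.coords[f, ai])
                hits = np.argwhere(d < criteria.distance_cutoff)
                if hits.size == 0:
                    continue
                if not use_angle:
                    occ[f] = True
                    continue
                for k, l in hits:
                    if _angle_ok(ensemble, f, di[k], ai[l], cos_min):
                        occ[f] = True
                        break
            if occ.any():
                key = tuple(sorted((rd, ra)))
                occ_by_pair[key] = occ_by_pair.get(key, np.zeros_like(occ)) | occ
    records = [
        InteractionRecord(a, b, occ, "hbond") for (a, b), occ in sorted(occ_by_pair.items())
    ]
    for rec in records:
        if rec.persistence >= persistence_cutoff:
            g.add_edge(rec.residue_a, rec.residue_b, persistence=rec.persistence)
    return g, records


def _angle_ok(ensemble, frame, donor_idx, acceptor_idx, cos_min) -> bool:
    """Donor-H-acceptor angle criterion over hydrogens bonded to the donor."""
    donor_atom = ensemble.atoms[donor_idx]
    d_xyz = ensemble.coords[frame, donor_idx]
    a_xyz = ensemble.coords[frame, acceptor_idx]
    h_idx = [
        i
        for i in ensemble.atom_indices(donor_atom.residue)
        if ensemble.atoms[i].is_hydrogen
        and np.linalg.norm(ensemble.coords[frame, i] - d_xyz) < 1.3
    ]
    if not h_idx:
        return True  # donor has no resolvable hydrogen: distance-only for this donor
    for i in h_idx:
        h = ensemble.coords[frame, i]
        v1, v2 = d_xyz - h, a_xyz - h
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        # angle >= cutoff  <=>  cos(angle) <= cos(cutoff) (cos decreasing on [0, 180])
        if cosang <= cos_min:
            return True
    return False


def cutoff_scan(
    ensemble: ConformationalEnsemble,
    cutoffs: list[float],
    resample_fraction: float = 0.8,
    repetitions: int = 10,
    persistence_cutoff: float = 20.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Jackknife stability of hub and component counts across distance cutoffs.

    For each cutoff and each resample (a random ``resample_fraction`` of the
    frames, without replacement) the contact PSN is rebuilt; the table reports
    mean and standard deviation of hub counts, component counts and edge
    counts.  ``repetitions=1`` with ``resample_fraction=1.0`` reduces to a
    plain :func:`build_contact_psn` per cutoff.
    """
    if len(cutoffs) < 2:
        raise ValueError("cutoff_scan needs at least two cutoffs")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if not 0 < resample_fraction <= 1:
        raise ValueError(f"resample fraction must be in (0, 1], got {resample_fraction}")
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(resample_fraction * ensemble.n_frames)))
    rows = []
    for cutoff in cutoffs:
        stats = {"hubs": [], "components": [], "edges": []}
        for _ in range(repetitions):
            if n_keep == ensemble.n_frames:
                sub = ensemble
            else:
                sub = ensemble.subset_frames(sorted(rng.choice(ensemble.n_frames, n_keep, replace=False)))
            g = build_contact_psn(sub, cutoff, persistence_cutoff)
            stats["hubs"].append(len(hubs(g)))
            stats["components"].append(len(connected_components(g)[0]))
            stats["edges"].append(g.number_of_edges())
        row = {"cutoff": cutoff}
        for k, v in stats.items():
            row[f"{k}_mean"] = float(np.mean(v))
            row[f"{k}_sd"] = float(np.std(v))
        rows.append(row)
    return pd.DataFrame(rows)


# --- export ----------------------------------------------------------------------


def edge_table(graph: PSNGraph) -> pd.DataFrame:
    """Weighted edge list: res_i, res_j, type, persistence."""
    rows = [
        {
            "res_i": a.label,
            "res_j": b.label,
            "type": graph.interaction_type,
            "persistence": round(d["persistence"], 3),
        }
        for a, b, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    return pd.DataFrame(rows, columns=["res_i", "res_j", "type", "persistence"])


def write_graph(graph: PSNGraph, path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        edge_table(graph).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph(**{k: str(v) for k, v in graph.graph.items()})
        for a, b, d in graph.edges(data=True):
            g.add_edge(a.label, b.label, persistence=d["persistence"])
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
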