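"""Synthetic inputs with planted, recoverable structure.

Every input class the pipeline consumes can be generated here with known
ground truth: pseudo-protein ensembles with an exact contact schedule, a
charged pair realizing a chosen salt-bridge persistence, ensembles built
from planted orthonormal displacement modes (with a tunable shared
subspace), saturation ddG scans with planted hotspot sites, and binary
sample x gene mutation matrices with a planted co-occurring pair.

Contact realization is deterministic (the first ceil(p*F/100) frames of a
pair are in contact) so persistence round-trips exactly up to one frame of
rounding; geometry is idealized, not physical.  All generators are
seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import atom_weights

from .ensemble_io import AtomRecord, ConformationalEnsemble, ResidueID
from .genomics import MutationMatrix
from .stability import AA_ONE, DDGRecord


class GenerationError(ValueError):
    pass


def child_seed(master: int, offset: int) -> int:
    """Derive a per-generator seed from one master seed (stays below 2^31)."""
    return (int(master) * 1_000_003 + offset) % (2**31 - 1)


# --- toy residue geometry --------------------------------------------------------

# side-chain heavy atoms as (name, element, offset-from-CB-direction index);
# coordinates are idealized chains extending radially from CA
SIDECHAIN_TEMPLATES = {
    "GLY": [],
    "ALA": [("CB", "C")],
    "SER": [("CB", "C"), ("OG", "O")],
    "ASP": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "LYS": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "ARG": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C"), ("NH1", "N"), ("NH2", "N")],
}

DEFAULT_CYCLE = ("ALA", "ASP", "LYS", "SER", "ARG", "GLY")

BACKBONE_OFFSETS = [("N", "N", (-1.2, 0.4, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
                    ("C", "C", (1.2, 0.4, 0.0)), ("O", "O", (1.4, 1.6, 0.0))]


def _template_coords(name: str) -> list[tuple[str, str, np.ndarray]]:
    """Side-chain atoms as offsets from CA along a 1.4 A-spaced local chain."""
    atoms = []
    for k, (aname, el) in enumerate(SIDECHAIN_TEMPLATES[name]):
        atoms.append((aname, el, np.array([0.0, 0.0, 1.5 + 1.4 * k])))
    return atoms


def _sidechain_com_offset(name: str) -> np.ndarray:
    atoms = _template_coords(name)
    if not atoms:
        return np.zeros(3)
    w = np.array([atom_weights[el] for _, el, _ in atoms])
    xyz = np.stack([off for _, _, off in atoms])
    return np.average(xyz, axis=0, weights=w)


@dataclass
class ContactSchedule:
    """Residue pairs (1-based positions) with target persistence % each."""

    pairs: dict[tuple[int, int], float]
    n_frames: int

    def __post_init__(self) -> None:
        for pair, p in self.pairs.items():
            if not 0 <= p <= 100:
                raise GenerationError(f"persistence {p} for pair {pair} outside [0, 100]")
        used: dict[int, tuple] = {}
        conflicts = []
        for pair in self.pairs:
            for pos in pair:
                if pos in used:
                    conflicts.append((used[pos], pair))
                used[pos] = pair
        if conflicts:
            raise GenerationError(f"conflicting contact pairs share residues: {conflicts}")

    def contact_frames(self, pair: tuple[int, int]) -> int:
        return math.ceil(self.pairs[pair] * self.n_frames / 100.0)


def make_toy_ensemble(
    n_residues: int,
    schedule: ContactSchedule | dict | None = None,
    n_frames: int | None = None,
    seed: int = 0,
    noise: float = 0.0,
    residue_names: list[str] | None = None,
    chain: str = "A",
) -> ConformationalEnsemble:
    """Pseudo-protein ensemble realizing an exact side-chain contact schedule.

    Residues sit on a wide ring (12 A spacing) with short idealized side
    chains pointing outward, so unscheduled side-chain centers of mass are
    > 6 A apart by construction.  For each scheduled pair the two side
    chains are posed 3.5 A apart (COM-COM), on a strut lifted above the
    ring, in exactly the first ceil(p*F/100) frames.  ``noise`` adds a
    seeded uniform jitter (A) without breaking the 4 / 6 A margins as long
    as it stays below ~0.2.
    """
    if n_residues < 2:
        raise GenerationError("need at least two residues")
    if isinstance(schedule, dict):
        if n_frames is None:
            raise GenerationError("n_frames required when schedule is a plain dict")
        schedule = ContactSchedule(schedule, n_frames)
    n_frames = schedule.n_frames if schedule is not None else (n_frames or 1)
    names = list(residue_names) if residue_names else [
        DEFAULT_CYCLE[i % len(DEFAULT_CYCLE)] for i in range(n_residues)
    ]
    if schedule is not None:
        for pair in schedule.pairs:
            for pos in pair:
                if not 1 <= pos <= n_residues:
                    raise GenerationError(f"scheduled position {pos} outside 1..{n_residues}")
                # a scheduled residue needs a posable side chain
                if residue_names is None and names[pos - 1] == "GLY":
                    names[pos - 1] = "ALA"

    spacing = 12.0
    radius = n_residues * spacing / (2 * math.pi)
    rng = np.random.default_rng(seed)

    atoms: list[AtomRecord] = []
    home_xyz: list[np.ndarray] = []  # frame-independent base coordinates
    res_atom_slices: list[slice] = []
    ca_xyz: list[np.ndarray] = []
    radial: list[np.ndarray] = []
    for i in range(n_residues):
        ang = 2 * math.pi * i / n_residues
        u = np.array([math.cos(ang), math.sin(ang), 0.0])
        ca = radius * u
        ca_xyz.append(ca)
        radial.append(u)
        rid = ResidueID(chain, i + 1, names[i])
        start = len(atoms)
        tangent = np.array([-math.sin(ang), math.cos(ang), 0.0])
        down = np.array([0.0, 0.0, -1.0])  # backbone dips below the ring plane
        for aname, el, off in BACKBONE_OFFSETS:
            xyz = ca + off[0] * tangent + off[1] * down
            atoms.append(AtomRecord(rid, aname, el, xyz, atom_weights[el]))
            home_xyz.append(xyz)
        for aname, el, off in _template_coords(names[i]):
            # local +z mapped onto the outward radial direction
            xyz = ca + off[2] * u
            atoms.append(AtomRecord(rid, aname, el, xyz, atom_weights[el]))
            home_xyz.append(xyz)
        res_atom_slices.append(slice(start, len(atoms)))

    base = np.stack(home_xyz)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)

    if schedule is not None:
        for k, (pair, _p) in enumerate(sorted(schedule.pairs.items())):
            i, j = (pair[0] - 1, pair[1] - 1)
            n_on = schedule.contact_frames(pair)
            mid = (ca_xyz[i] + ca_xyz[j]) / 2 + np.array([0.0, 0.0, 9.0 + 7.0 * k])
            axis = ca_xyz[j] - ca_xyz[i]
            axis = axis / np.linalg.norm(axis)
            for res_idx, sign in ((i, -1.0), (j, +1.0)):
                sl = res_atom_slices[res_idx]
                side_local = [
                    a for a in range(sl.start, sl.stop) if atoms[a].atom_name not in ("N", "CA", "C", "O")
                ]
                if not side_local:
                    raise GenerationError(
                        f"scheduled residue {res_idx + 1} ({names[res_idx]}) has no side chain to pose"
                    )
                w = np.array([atoms[a].mass for a in side_local])
                current_com = np.average(base[side_local], axis=0, weights=w)
                target_com = mid + sign * 1.75 * axis
                shift = target_com - current_com
                coords[:n_on, side_local, :] = base[side_local] + shift

    if noise > 0:
        coords = coords + rng.uniform(-noise, noise, size=coords.shape)
    return ConformationalEnsemble(atoms, coords)


def make_charged_pair_ensemble(
    persistence: float, n_frames: int, seed: int = 0, chain: str = "A"
) -> ConformationalEnsemble:
    """Two-residue Asp/Lys ensemble realizing a salt-bridge persistence.

    The minimum carboxylate-ammonium atom distance is 4.0 A in the first
    ceil(p*F/100) frames and 6.5 A otherwise (criterion thresholds 4.5 /
    5.5 A sit strictly between the two poses).
    """
    if not 0 <= persistence <= 100:
        raise GenerationError(f"persistence {persistence} outside [0, 100]")
    asp = ResidueID(chain, 2, "ASP")
    lys = ResidueID(chain, 10, "LYS")
    atoms: list[AtomRecord] = []
    xyz0: list[np.ndarray] = []

    def add(rid, name, el, xyz):
        atoms.append(AtomRecord(rid, name, el, np.asarray(xyz, float), atom_weights[el]))
        xyz0.append(np.asarray(xyz, float))

    # Asp at the origin; carboxylate pointing +x, OD1 the most exposed atom
    add(asp, "N", "N", (-2.4, 1.0, 0.0))
    add(asp, "CA", "C", (-1.5, 0.0, 0.0))
    add(asp, "C", "C", (-2.0, -1.4, 0.0))
    add(asp, "O", "O", (-3.2, -1.6, 0.0))
    add(asp, "CB", "C", (0.0, 0.0, 0.0))
    add(asp, "CG", "C", (1.4, 0.0, 0.0))
    add(asp, "OD1", "O", (2.1, 1.05, 0.0))
    add(asp, "OD2", "O", (2.1, -1.05, 0.0))
    od1 = np.array([2.1, 1.05, 0.0])
    # Lys backbone far away (+x); side chain reaches back toward the carboxylate
    add(lys, "N", "N", (21.0, 1.0, 0.0))
    add(lys, "CA", "C", (20.0, 0.0, 0.0))
    add(lys, "C", "C", (20.5, -1.4, 0.0))
    add(lys, "O", "O", (21.7, -1.6, 0.0))
    for k, (name, el) in enumerate([("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C")]):
        add(lys, name, el, (18.6 - 1.4 * k, 0.0, 0.0))
    nz_home_far = od1 + np.array([6.5, 0.0, 0.0])  # min group distance 6.5 A
    nz_home_near = od1 + np.array([4.0, 0.0, 0.0])  # min group distance 4.0 A
    add(lys, "NZ", "N", nz_home_far)
    nz_idx = len(atoms) - 1

    base = np.stack(xyz0)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    n_on = math.ceil(persistence * n_frames / 100.0)
    coords[:n_on, nz_idx, :] = nz_home_near
    return ConformationalEnsemble(atoms, coords)


# --- planted-mode ensembles ------------------------------------------------------


@dataclass
class PlantedModes:
    """Orthonormal displacement modes over a CA roster, with amplitudes (A)."""

    modes: np.ndarray  # (k, 3N), rows orthonormal
    amplitudes: np.ndarray  # (k,), descending
    noise: float = 0.0

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(self.modes.shape[0]), atol=1e-8):
            raise GenerationError("planted modes are not orthonormal")
        if np.any(np.diff(self.amplitudes) > 1e-12):
            raise GenerationError("amplitudes must be descending")


def _ca_chain(n_atoms: int, chain: str = "A") -> tuple[list[AtomRecord], np.ndarray]:
    """CA trace on an ideal helix (non-collinear, so rigid-body superposition
    of generated frames is well conditioned)."""
    atoms = []
    xyz = []
    turn = 2 * math.pi / 3.6  # residues per helix turn
    for i in range(n_atoms):
        rid = ResidueID(chain, i + 1, "GLY")
        p = np.array([2.3 * math.cos(turn * i), 2.3 * math.sin(turn * i), 1.5 * i])
        atoms.append(AtomRecord(rid, "CA", "C", p, atom_weights["C"]))
        xyz.append(p)
    return atoms, np.stack(xyz)


def _rigid_body_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body displacements of ``base``."""
    n = base.shape[0]
    centered = base - base.mean(axis=0)
    vecs = []
    for ax in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        vecs.append(v.ravel())
    for ax in range(3):  # infinitesimal rotations
        e = np.zeros(3)
        e[ax] = 1.0
        vecs.append(np.cross(e, centered).ravel())
    basis = np.stack(vecs)
    q, _ = np.linalg.qr(basis.T)
    return q.T[: len(vecs)]


def random_orthonormal_modes(
    n_atoms: int, k: int, seed: int = 0, exclude_rigid: bool = True
) -> np.ndarray:
    """k orthonormal (3N,) displacement modes, orthogonal to rigid-body motion.

    Excluding the 6 rigid-body vectors of the straight-chain geometry means
    the planted modes survive least-squares superposition essentially
    unchanged, which is what makes exact subspace-recovery tests possible.
    """
    rng = np.random.default_rng(seed)
    _, base = _ca_chain(n_atoms)
    raw = rng.standard_normal((k, 3 * n_atoms))
    if exclude_rigid:
        rb = _rigid_body_basis(base)
        raw = raw - (raw @ rb.T) @ rb
    q, _ = np.linalg.qr(raw.T)
    return q.T[:k]


def make_mode_ensemble(
    planted: PlantedModes, n_frames: int, seed: int = 0, chain: str = "A"
) -> ConformationalEnsemble:
    """CA-chain ensemble: frames = base + sum_i a_i(t) mode_i + isotropic noise,
    with a_i(t) ~ Normal(0, amplitude_i)."""
    if n_frames < 2:
        raise GenerationError("mode ensembles need at least 2 frames")
    rng = np.random.default_rng(seed)
    n_atoms = planted.modes.shape[1] // 3
    atoms, base = _ca_chain(n_atoms, chain)
    amps = rng.standard_normal((n_frames, len(planted.amplitudes))) * planted.amplitudes
    disp = amps @ planted.modes  # (F, 3N)
    coords = base[None, :, :] + disp.reshape(n_frames, n_atoms, 3)
    if planted.noise > 0:
        coords = coords + planted.noise * rng.standard_normal(coords.shape)
    return ConformationalEnsemble(atoms, coords)


def make_ensemble_pair(
    overlap: float,
    n_atoms: int = 30,
    k: int = 5,
    amplitude: float = 3.0,
    noise: float = 0.05,
    n_frames: int = 500,
    seed: int = 0,
) -> tuple[ConformationalEnsemble, ConformationalEnsemble, int]:
    """Two ensembles whose top-k essential subspaces share a target overlap.

    With m of the k modes shared and the rest mutually orthogonal,
    RMSIP(top-k)^2 ~ m/k; m = round(overlap^2 * k) is planted.  Returns the
    two ensembles and m.
    """
    if not 0 <= overlap <= 1:
        raise GenerationError(f"overlap target {overlap} outside [0, 1]")
    m = int(round(overlap**2 * k))
    pool = random_orthonormal_modes(n_atoms, 2 * k - m, seed=child_seed(seed, 1))
    amps = amplitude * np.linspace(1.0, 0.5, k)
    modes_a = pool[:k]
    modes_b = np.vstack([pool[:m], pool[k : 2 * k - m]])
    ens_a = make_mode_ensemble(PlantedModes(modes_a, amps, noise), n_frames, child_seed(seed, 2))
    ens_b = make_mode_ensemble(PlantedModes(modes_b, amps, noise), n_frames, child_seed(seed, 3))
    return ens_a, ens_b, m


# --- ddG scans -------------------------------------------------------------------


def make_ddg_scan(
    n_sites: int,
    hotspot_sites: list[int],
    effect: float = 8.0,
    noise: float = 0.3,
    neutral_mean: float = 0.5,
    runs: int = 5,
    frames: int = 20,
    seed: int = 0,
) -> list[DDGRecord]:
    """Saturation ddG records with planted hotspot sites.

    Hotspot cells draw from Normal(effect, noise), all others from
    Normal(neutral_mean, noise); one record per (site, substitution, run,
    frame).  Positions are 1..n_sites with a seeded wild-type sequence.
    """
    rng = np.random.default_rng(seed)
    hot = set(hotspot_sites)
    if not hot <= set(range(1, n_sites + 1)):
        raise GenerationError("hotspot sites outside 1..n_sites")
    wt_seq = rng.choice(list(AA_ONE), size=n_sites)
    records = []
    for pos in range(1, n_sites + 1):
        wt = str(wt_seq[pos - 1])
        mu = effect if pos in hot else neutral_mean
        for sub in AA_ONE:
            if sub == wt:
                continue
            for run in range(runs):
                for frame in range(frames):
                    val = mu + noise * rng.standard_normal() if noise > 0 else mu
                    records.append(DDGRecord(pos, wt, sub, float(val), run, str(frame)))
    return records


def write_ddg_tsv(records: list[DDGRecord], path) -> None:
    df = pd.DataFrame(
        {
            "pos": [r.position for r in records],
            "wt": [r.wild_type for r in records],
            "sub": [r.substitution for r in records],
            "run": [r.run for r in records],
            "frame": [r.frame for r in records],
            "ddg": [r.ddg for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_ddg_foldx(records: list[DDGRecord], out_dir, chain: str = "A") -> list:
    """One FoldX-dialect file per run: frame<TAB>token<TAB>ddg."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    runs = sorted({r.run for r in records})
    for run in runs:
        path = out_dir / f"ddg_run{run}.txt"
        with open(path, "w") as fh:
            fh.write("# frame\tmutation\tddg\n")
            for r in records:
                if r.run == run:
                    fh.write(f"{r.frame}\t{r.wild_type}{chain}{r.position}{r.substitution}\t{r.ddg:.6f}\n")
        paths.append(path)
    return paths


# --- mutation matrices -----------------------------------------------------------


def _joint_prob(p_a: float, p_b: float, odds_ratio: float) -> float:
    """P(both mutated) for given marginals and odds ratio."""
    if odds_ratio == 1.0:
        return p_a * p_b
    s = 1.0 + (p_a + p_b) * (odds_ratio - 1.0)
    disc = s**2 - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_a * p_b
    p11 = (s - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    if not max(0.0, p_a + p_b - 1.0) <= p11 <= min(p_a, p_b):
        raise GenerationError("odds ratio incompatible with the marginal rates")
    return p11


def make_mutation_data(
    n_samples: int,
    genes: list[str],
    rates: dict[str, float],
    planted_pair: tuple[str, str] | None = None,
    odds_ratio: float = 1.0,
    seed: int = 0,
    maf_path=None,
) -> MutationMatrix:
    """Boolean sample x gene mutation matrix with one planted co-occurring pair.

    All genes mutate independently with their Bernoulli ``rates`` except the
    planted pair, whose joint distribution matches the requested odds ratio
    exactly in expectation.  Optionally also writes a MAF-dialect file.
    """
    for g, p in rates.items():
        if not 0 <= p < 1:
            raise GenerationError(f"rate for {g} outside [0, 1): {p}")
    rng = np.random.default_rng(seed)
    data = {}
    pair = set(planted_pair) if planted_pair else set()
    for g in genes:
        if g not in pair:
            data[g] = rng.random(n_samples) < rates.get(g, 0.0)
    if planted_pair:
        a, b = planted_pair
        p11 = _joint_prob(rates[a], rates[b], odds_ratio)
        probs = [p11, rates[a] - p11, rates[b] - p11]
        probs.append(1.0 - sum(probs))
        cell = rng.choice(4, size=n_samples, p=probs)
        data[a] = np.isin(cell, (0, 1))
        data[b] = np.isin(cell, (0, 2))
    df = pd.DataFrame(data, index=[f"SAMPLE-{i:04d}" for i in range(n_samples)], columns=genes)
    matrix = MutationMatrix(df)
    if maf_path is not None:
        rows = []
        for gi, g in enumerate(genes):
            for sample in df.index[df[g]]:
                rows.append(
                    {
                        "Hugo_Symbol": g,
                        "Tumor_Sample_Barcode": sample,
                        "Variant_Classification": "Missense_Mutation",
                        "HGVSp_Short": f"p.A{100 + gi}V",
                    }
                )
        pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "HGVSp_Short"]).to_csv(
            maf_path, sep="\t", index=False
        )
    return matrix
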