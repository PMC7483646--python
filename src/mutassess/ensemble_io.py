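"""Conformational-ensemble containers and I/O.

An ensemble is an ordered stack of frames over a fixed atom roster, the
substrate of every network and dynamics stage.  The canonical on-disk form
is a multi-model PDB file (MODEL/ENDMDL records); parsing goes through
Biopython and writing through a plain fixed-column formatter so round trips
preserve coordinates to PDB precision (1e-3 A).

Residue numbering is taken verbatim from the coordinate file — for the ULK1
kinase domain that is UniProt O75385 numbering — and mutation positions are
matched in that numbering without any renumbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio.Data.IUPACData import atom_weights, protein_letters_3to1
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset(
    n.upper() for n in protein_letters_3to1
)  # the 20 standard three-letter codes

#: backbone atom names excluded from side-chain centers of mass
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class EnsembleError(ValueError):
    """Malformed or inconsistent ensemble input."""


class RosterMismatchError(EnsembleError):
    """Models of a multi-model file disagree on the atom roster."""


class MissingAtomsError(EnsembleError):
    """A residue has neither side-chain heavy atoms nor a CA fallback."""


@dataclass(frozen=True, order=True)
class ResidueID:
    """A residue identified by chain, sequence position and 3-letter name."""

    chain: str
    position: int
    name: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise EnsembleError(f"residue position must be >= 1, got {self.position}")
        if self.name.upper() not in STANDARD_RESIDUES:
            logger.warning("non-standard residue name %r at %s%d", self.name, self.chain, self.position)

    @property
    def one_letter(self) -> str:
        return protein_letters_3to1.get(self.name.capitalize(), "X")

    @property
    def label(self) -> str:
        """Compact label such as ``A28`` (one-letter code + position)."""
        return f"{self.one_letter}{self.position}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class AtomRecord:
    residue: ResidueID
    atom_name: str
    element: str
    coordinates: np.ndarray  # (3,) Angstrom, frame-0 position
    mass: float  # amu

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise EnsembleError(f"non-finite coordinates for atom {self.atom_name} of {self.residue}")
        if self.mass <= 0:
            raise EnsembleError(f"non-positive mass for atom {self.atom_name} of {self.residue}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_sidechain_heavy(self) -> bool:
        return (not self.is_hydrogen) and self.atom_name not in BACKBONE_ATOMS


class ConformationalEnsemble:
    """Ordered frames of coordinates over a fixed atom roster."""

    def __init__(self, atoms: Sequence[AtomRecord], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise EnsembleError(f"coords must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise EnsembleError("an ensemble needs at least one frame")
        if coords.shape[1] != len(atoms):
            raise EnsembleError("coordinate array does not match the atom roster")
        if not np.all(np.isfinite(coords)):
            raise EnsembleError("non-finite coordinates in ensemble")
        self.atoms: list[AtomRecord] = list(atoms)
        self.coords = coords
        # ordered unique residues and per-residue atom indices
        self.residues: list[ResidueID] = []
        self._atom_idx: dict[ResidueID, list[int]] = {}
        for i, a in enumerate(self.atoms):
            if a.residue not in self._atom_idx:
                self._atom_idx[a.residue] = []
                self.residues.append(a.residue)
            self._atom_idx[a.residue].append(i)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, residue: ResidueID) -> list[int]:
        try:
            return self._atom_idx[residue]
        except KeyError:
            raise EnsembleError(f"residue {residue} not in ensemble") from None

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset_frames(self, indices: Iterable[int]) -> "ConformationalEnsemble":
        idx = list(indices)
        if not idx:
            raise EnsembleError("frame subset is empty")
        return ConformationalEnsemble(self.atoms, self.coords[idx])

    def equally_spaced_frames(self, n: int) -> "ConformationalEnsemble":
        """Equal-in-time subset of ``n`` frames (default representative-set helper)."""
        if not 1 <= n <= self.n_frames:
            raise EnsembleError(f"cannot take {n} frames from {self.n_frames}")
        idx = np.unique(np.round(np.linspace(0, self.n_frames - 1, n)).astype(int))
        return self.subset_frames(idx)

    # --- convenience selections -------------------------------------------------
    def ca_indices(self) -> list[int]:
        idx = []
        for r in self.residues:
            cas = [i for i in self._atom_idx[r] if self.atoms[i].atom_name == "CA"]
            if not cas:
                raise MissingAtomsError(f"residue {r} has no CA atom")
            idx.append(cas[0])
        return idx

    def ca_coords(self) -> np.ndarray:
        """(n_frames, n_residues, 3) CA coordinates."""
        return self.coords[:, self.ca_indices(), :]

    def _sidechain_selection(self, residue: ResidueID) -> tuple[list[int], np.ndarray]:
        """Indices and masses used for the side-chain COM (CA fallback for Gly)."""
        idx = [i for i in self.atom_indices(residue) if self.atoms[i].is_sidechain_heavy]
        if not idx:
            idx = [i for i in self.atom_indices(residue) if self.atoms[i].atom_name == "CA"]
        if not idx:
            raise MissingAtomsError(f"residue {residue}: no side-chain heavy atoms and no CA")
        return idx, np.array([self.atoms[i].mass for i in idx])

    def sidechain_com_trajectory(self) -> np.ndarray:
        """(n_frames, n_residues, 3) side-chain mass centers, vectorized over frames."""
        out = np.empty((self.n_frames, len(self.residues), 3))
        for j, r in enumerate(self.residues):
            idx, m = self._sidechain_selection(r)
            w = m / m.sum()
            out[:, j, :] = np.einsum("fak,a->fk", self.coords[:, idx, :], w)
        return out


def sidechain_center_of_mass(
    ensemble: ConformationalEnsemble, residue: ResidueID, frame: int = 0
) -> np.ndarray:
    """Mass-weighted mean of the side-chain heavy atoms of ``residue``.

    Hydrogens are excluded; glycine (and any residue with no side-chain heavy
    atoms) falls back to its CA position.
    """
    idx, m = ensemble._sidechain_selection(residue)
    return np.average(ensemble.coords[frame, idx, :], axis=0, weights=m)


# --- PDB I/O ---------------------------------------------------------------------


def _element_of(atom) -> str:
    el = (atom.element or "").strip()
    if not el:
        name = atom.get_name().strip()
        el = "".join(c for c in name if c.isalpha())[:1]
    return el.capitalize()


def read_pdb_ensemble(path: str | Path, model_policy: str = "all") -> ConformationalEnsemble:
    """Read a (multi-model) PDB file into an ensemble, one frame per MODEL.

    ``model_policy='first'`` keeps only the first model.  Alternate locations
    are resolved to the highest-occupancy conformer (Biopython default).
    All models must share the same atom roster and ordering.
    """
    path = Path(path)
    if model_policy not in ("all", "first"):
        raise ValueError(f"model_policy must be 'all' or 'first', got {model_policy!r}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise EnsembleError(f"{path}: no models found")
    if model_policy == "first":
        models = models[:1]

    rosters = []
    frames = []
    for model in models:
        key, coords, atoms = [], [], []
        for chain in model:
            for res in chain:
                het, resseq, _ = res.id
                if het.strip():
                    continue  # skip waters / heteroatoms
                rid = ResidueID(chain.id, resseq, res.get_resname())
                for atom in res:
                    el = _element_of(atom)
                    if el not in atom_weights:
                        raise EnsembleError(f"{path}: unknown element {el!r} for atom {atom.get_name()}")
                    key.append((chain.id, resseq, res.get_resname(), atom.get_name()))
                    coords.append(atom.get_coord())
                    atoms.append(
                        AtomRecord(rid, atom.get_name(), el, np.asarray(atom.get_coord(), float), atom_weights[el])
                    )
        rosters.append((key, atoms))
        frames.append(np.asarray(coords, dtype=float))

    ref_key = rosters[0][0]
    if not ref_key:
        raise EnsembleError(f"{path}: no protein atoms found")
    for i, (key, _) in enumerate(rosters[1:], start=2):
        if key != ref_key:
            raise RosterMismatchError(f"{path}: model {i} atom roster differs from model 1")
    return ConformationalEnsemble(rosters[0][1], np.stack(frames))


def write_pdb_ensemble(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file (fixed 8.3f coordinates)."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            for a, xyz in zip(ensemble.atoms, ensemble.coords[f]):
                name = a.atom_name
                # PDB column rules: 4-char names start in col 13, shorter in col 14
                name_field = name if len(name) == 4 else f" {name:<3s}"
                fh.write(
                    "ATOM  {serial:5d} {name} {res:<3s} {chain:1s}{pos:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=serial,
                        name=name_field,
                        res=a.residue.name.upper(),
                        chain=a.residue.chain[:1] or "A",
                        pos=a.residue.position,
                        x=xyz[0],
                        y=xyz[1],
                        z=xyz[2],
                        occ=1.0,
                        b=0.0,
                        el=a.element.upper(),
                    )
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --- functional annotation -------------------------------------------------------

#: default functional residue classes of the ULK1 kinase domain (O75385 numbering)
ULK1_ANNOTATION: dict = {
    "domain_range": [8, 280],
    "sets": {
        "activity": [46, 63, 62, 180, 162],
        "dfg": list(range(165, 168)),
        "hrd": list(range(136, 139)),
        "ape": list(range(189, 192)),
        "chelix": list(range(55, 66)),
        "cspine": [21, 30, 44, 145, 144, 146, 210, 214],
        "rspine": [203, 136, 166, 67, 78],
        "activation_loop": list(range(165, 175)) + list(range(178, 192)),
    },
}


@dataclass
class FunctionalAnnotation:
    """Named residue sets (by sequence position) plus the domain range."""

    sets: Mapping[str, frozenset] = field(default_factory=dict)
    domain_range: tuple[int, int] = (8, 280)

    def __post_init__(self) -> None:
        lo, hi = self.domain_range
        if lo > hi or lo < 1:
            raise EnsembleError(f"bad domain range {self.domain_range}")
        clean = {}
        for name, positions in self.sets.items():
            pos = frozenset(int(p) for p in positions)
            bad = [p for p in pos if not lo <= p <= hi]
            if bad:
                raise EnsembleError(
                    f"annotation set {name!r}: positions {sorted(bad)} outside domain range {self.domain_range}"
                )
            clean[name] = pos
        self.sets = clean

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def class_names(self) -> list[str]:
        return list(self.sets)


def _expand(entry) -> list[int]:
    """Positions from an int, a list, or a 'start-end' range string."""
    if isinstance(entry, int):
        return [entry]
    if isinstance(entry, str):
        if "-" in entry:
            lo, hi = entry.split("-")
            return list(range(int(lo), int(hi) + 1))
        return [int(entry)]
    out: list[int] = []
    for e in entry:
        out.extend(_expand(e))
    return out


def load_annotation_config(path: str | Path | None = None) -> FunctionalAnnotation:
    """Load a YAML annotation config; fields omitted fall back to ULK1 defaults.

    The config declares ``domain_range: [lo, hi]`` and ``sets:`` mapping set
    names to lists of positions or ``"start-end"`` range strings.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    domain = tuple(data.get("domain_range", ULK1_ANNOTATION["domain_range"]))
    raw_sets = data.get("sets", ULK1_ANNOTATION["sets"])
    sets = {name: frozenset(_expand(entry)) for name, entry in raw_sets.items()}
    return FunctionalAnnotation(sets=sets, domain_range=(int(domain[0]), int(domain[1])))
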