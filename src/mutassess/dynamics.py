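"""Essential dynamics: CA-covariance PCA, subspace comparison and mobile regions.

The covariance matrix of CA fluctuations (after least-squares superposition
onto the mean structure, iterated twice) is eigendecomposed; the leading
eigenvectors span the essential subspace.  Two ensembles are compared with
the root mean square inner product (RMSIP) over their first ``n`` modes,
which is 1 for identical subspaces and 0 for mutually orthogonal ones.
Mobile regions are contiguous stretches whose per-residue weight on a
leading mode exceeds mean + 1 SD of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble_io import ConformationalEnsemble, ResidueID


class PCAError(ValueError):
    pass


@dataclass
class PCAModel:
    """Eigendecomposition of the 3N x 3N CA covariance matrix (units A^2)."""

    mean: np.ndarray  # (N, 3) mean CA conformation after fitting
    eigenvectors: np.ndarray  # (3N, 3N), columns orthonormal, descending variance
    eigenvalues: np.ndarray  # (3N,), A^2, descending, >= 0
    residues: list[ResidueID]

    @property
    def n_atoms(self) -> int:
        return self.mean.shape[0]

    def projections(self, coords: np.ndarray, n_modes: int = 2) -> np.ndarray:
        """(n_frames, n_modes) projections of fitted frames onto the top modes."""
        flat = (coords - self.mean).reshape(coords.shape[0], -1)
        return flat @ self.eigenvectors[:, :n_modes]


def _superpose(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) fit of every frame onto ``reference``; CA only."""
    out = np.empty_like(frames)
    ref = reference - reference.mean(axis=0)
    for f in range(frames.shape[0]):
        x = frames[f] - frames[f].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref, x)
        out[f] = rot.apply(x)
    return out + reference.mean(axis=0)


def fit_pca(*ensembles: ConformationalEnsemble, fit: bool = True) -> PCAModel:
    """PCA of CA fluctuations; several ensembles are concatenated frame-wise.

    Frames are superposed onto their mean (two fitting iterations) before
    the covariance is formed, unless ``fit=False`` (pre-fitted input).
    """
    if not ensembles:
        raise PCAError("at least one ensemble required")
    rosters = [tuple(e.residues) for e in ensembles]
    if any(r != rosters[0] for r in rosters[1:]):
        raise PCAError("ensembles have different residue rosters")
    coords = np.concatenate([e.ca_coords() for e in ensembles], axis=0)
    if coords.shape[0] < 2:
        raise PCAError("PCA needs at least two frames")
    if fit:
        for _ in range(2):  # fit to current mean, recompute mean, fit again
            coords = _superpose(coords, coords.mean(axis=0))
    mean = coords.mean(axis=0)
    flat = (coords - mean).reshape(coords.shape[0], -1)
    cov = np.cov(flat, rowvar=False, bias=True)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    return PCAModel(mean=mean, eigenvectors=vecs, eigenvalues=vals, residues=list(ensembles[0].residues))


def variance_fraction(model: PCAModel, k: int) -> float:
    """Percent of total CA fluctuation captured by the top ``k`` modes."""
    n = model.eigenvalues.size
    if not 1 <= k <= n:
        raise PCAError(f"k must be in [1, {n}], got {k}")
    total = model.eigenvalues.sum()
    if total == 0:
        return 0.0
    return float(100.0 * model.eigenvalues[:k].sum() / total)


def rmsip(model_a: PCAModel, model_b: PCAModel, n_modes: int = 20) -> float:
    """Root mean square inner product of the two leading eigenvector sets.

    sqrt( (1/n) sum_ij (v_i . w_j)^2 ) over the first ``n_modes`` modes of
    each model; 1 for identical essential subspaces.
    """
    if model_a.n_atoms != model_b.n_atoms or model_a.residues != model_b.residues:
        raise PCAError("models were built over different atom rosters")
    n = min(n_modes, model_a.eigenvalues.size)
    va = model_a.eigenvectors[:, :n]
    vb = model_b.eigenvectors[:, :n]
    inner = va.T @ vb
    return float(np.sqrt((inner**2).sum() / n))


def residue_mobility(model: PCAModel, pc: int = 1) -> np.ndarray:
    """Per-residue displacement magnitude of eigenvector ``pc`` (1-based)."""
    if not 1 <= pc <= model.eigenvalues.size:
        raise PCAError(f"pc must be in [1, {model.eigenvalues.size}]")
    v = model.eigenvectors[:, pc - 1].reshape(-1, 3)
    return np.linalg.norm(v, axis=1)


@dataclass
class MobileRegion:
    """Contiguous residue interval with elevated weight on a leading mode."""

    start: int  # first residue position (inclusive)
    end: int  # last residue position (inclusive)
    peak: float  # maximum profile value in the interval
    pc: int

    def contains(self, position: int, halo: int = 0) -> bool:
        return self.start - halo <= position <= self.end + halo


#: mobile regions of the ULK1 kinase domain seen along its first principal
#: component: two closing disordered loops and the loop next to the catalytic
#: lysine
ULK1_MOBILE_REGIONS = [
    MobileRegion(148, 158, float("nan"), 1),
    MobileRegion(172, 183, float("nan"), 1),
    MobileRegion(35, 41, float("nan"), 1),
]


def detect_mobile_regions(
    model: PCAModel,
    pc: int = 1,
    n_sigma: float = 1.0,
    min_length: int = 3,
) -> list[MobileRegion]:
    """Contiguous intervals where the mode-``pc`` profile exceeds mean + n_sigma*SD.

    Runs shorter than ``min_length`` residues are discarded; intervals are
    reported in residue numbering (positions of the model's roster).
    """
    profile = residue_mobility(model, pc)
    threshold = profile.mean() + n_sigma * profile.std()
    positions = [r.position for r in model.residues]
    regions: list[MobileRegion] = []
    run: list[int] = []
    for i, (pos, val) in enumerate(zip(positions, profile)):
        contiguous = run and positions[i - 1] == pos - 1
        if val > threshold and (not run or contiguous):
            run.append(i)
            continue
        if len(run) >= min_length:
            regions.append(_region_from_run(run, positions, profile, pc))
        run = [i] if val > threshold else []
    if len(run) >= min_length:
        regions.append(_region_from_run(run, positions, profile, pc))
    return regions


def _region_from_run(run, positions, profile, pc) -> MobileRegion:
    return MobileRegion(
        start=positions[run[0]],
        end=positions[run[-1]],
        peak=float(profile[run].max()),
        pc=pc,
    )


def mutation_dynamics_overlap(
    sites: list[ResidueID] | list[int],
    regions: list[MobileRegion] | None = None,
    halo: int = 2,
) -> dict[int, MobileRegion | None]:
    """Flag sites lying within (or within ``halo`` residues of) a mobile region.

    Returns position -> matched region (or None).  Defaults to the ULK1
    mobile regions when no detected regions are supplied.
    """
    regions = ULK1_MOBILE_REGIONS if regions is None else regions
    out: dict[int, MobileRegion | None] = {}
    for site in sites:
        pos = site.position if isinstance(site, ResidueID) else int(site)
        out[pos] = next((reg for reg in regions if reg.contains(pos, halo)), None)
    return out
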