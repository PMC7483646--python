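"""Mutation curation, annotation interplay, SASA and co-occurrence statistics.

Missense mutations arrive as MAF-like tables (one row per called variant in
a tumour sample) or as plain curated TSVs; they are filtered to the kinase
domain, classified by REVEL pathogenicity score, and annotated for overlap
with post-translational modification (PTM) sites and short linear motifs
(SLiMs).  Gain-of-phosphosite flags are gated on side-chain solvent
exposure, computed with a Shrake-Rupley surface.  Pairwise mutation
co-occurrence across tumour samples is tested with Fisher's exact test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .ensemble_io import ConformationalEnsemble

logger = logging.getLogger(__name__)

AA_ONE = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_ACCEPTORS = {"S", "T", "Y"}

_PROT_CHANGE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


class MutationParseError(ValueError):
    pass


@dataclass
class MutationRecord:
    """One curated missense mutation with its annotations."""

    gene: str
    wild_type: str
    position: int
    mutant: str
    studies: tuple[str, ...] = ()
    revel: float | None = None
    ptm_abolished: bool | None = None
    ptm_gained: bool | None = None
    ptm_detail: str = ""
    slim_overlap: str | None = None
    in_domain: bool | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        if self.wild_type == self.mutant:
            raise MutationParseError(f"{self.label}: wild type equals mutant")
        for aa in (self.wild_type, self.mutant):
            if aa not in AA_ONE:
                raise MutationParseError(f"{self.label}: unknown residue code {aa!r}")
        if self.revel is not None and not 0 <= self.revel <= 1:
            raise MutationParseError(f"{self.label}: REVEL score {self.revel} outside [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """'S184F' or 'p.S184F' -> ('S', 184, 'F')."""
    m = _PROT_CHANGE.match(text.strip())
    if not m:
        raise MutationParseError(f"malformed protein change {text!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def parse_mutation_table(path, dialect: str = "tsv", gene: str | None = None) -> list[MutationRecord]:
    """Read mutations from a MAF column subset or a curated TSV.

    maf: tab-separated with Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification and HGVSp_Short columns; only Missense_Mutation
    rows (optionally of one gene) are kept, the rest counted and logged.
    tsv: columns ``mutation`` (e.g. S184F) and optionally ``gene``,
    ``studies`` (';'-separated), ``revel``.
    """
    path = Path(path)
    records: list[MutationRecord] = []
    if dialect == "maf":
        df = pd.read_csv(path, sep="\t", comment="#")
        mask = df["Variant_Classification"] == "Missense_Mutation"
        if gene is not None:
            mask &= df["Hugo_Symbol"] == gene
        dropped = int((~mask).sum())
        if dropped:
            logger.info("%s: dropped %d non-missense/other-gene rows", path, dropped)
        for i, row in df[mask].iterrows():
            try:
                wt, pos, mut = parse_protein_change(str(row["HGVSp_Short"]))
            except MutationParseError as exc:
                raise MutationParseError(f"{path} row {i + 2}: {exc}") from exc
            records.append(
                MutationRecord(str(row["Hugo_Symbol"]), wt, pos, mut, sample=str(row["Tumor_Sample_Barcode"]))
            )
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        for i, row in df.iterrows():
            try:
                wt, pos, mut = parse_protein_change(str(row["mutation"]))
            except MutationParseError as exc:
                raise MutationParseError(f"{path} row {i + 2}: {exc}") from exc
            revel = row.get("revel")
            records.append(
                MutationRecord(
                    str(row.get("gene", gene or "")),
                    wt,
                    pos,
                    mut,
                    studies=tuple(str(row["studies"]).split(";")) if "studies" in row and pd.notna(row["studies"]) else (),
                    revel=float(revel) if revel is not None and pd.notna(revel) else None,
                )
            )
    else:
        raise ValueError(f"unknown mutation-table dialect {dialect!r}")
    return records


def filter_domain(records: list[MutationRecord], domain_range: tuple[int, int] = (8, 280)) -> list[MutationRecord]:
    """Keep mutations inside the closed domain interval; sets ``in_domain``."""
    lo, hi = domain_range
    kept = []
    for r in records:
        r.in_domain = lo <= r.position <= hi
        if r.in_domain:
            kept.append(r)
    return kept


def unique_mutations(records: list[MutationRecord]) -> list[str]:
    """Distinct protein-change labels, in order of first appearance."""
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.label, None)
    return list(seen)


def revel_classify(record: MutationRecord | float | None, cutoff: float = 0.4) -> str:
    """'damaging' at score >= cutoff, 'neutral' below, 'unscored' when missing."""
    score = record.revel if isinstance(record, MutationRecord) else record
    if score is None:
        return "unscored"
    return "damaging" if score >= cutoff else "neutral"


def ptm_slim_annotate(
    records: list[MutationRecord],
    ptm_table: pd.DataFrame | None = None,
    slim_table: pd.DataFrame | None = None,
    gain_table: pd.DataFrame | None = None,
    relative_sasa: dict[int, float] | None = None,
    exposure_threshold: float = 0.20,
) -> list[MutationRecord]:
    """Flag PTM abolition, SLiM overlap and predicted PTM gain in place.

    ptm_table: columns ``position, modification`` (validated/predicted PTM
    sites; a mutation at a listed position abolishes it).
    slim_table: columns ``name, start, end`` (motif ranges; overlap is
    position inside the closed range, no halo).
    gain_table: predictor output with columns ``position, residue,
    modification`` — the flag fires when the mutant residue matches, and a
    phosphorylation gain additionally requires relative side-chain SASA >=
    ``exposure_threshold`` at the site (buried sites cannot be
    phosphorylated); without SASA data the gate is waived with a warning.
    """
    for rec in records:
        details = []
        if ptm_table is not None and len(ptm_table):
            hits = ptm_table[ptm_table["position"] == rec.position]
            rec.ptm_abolished = bool(len(hits))
            details += [f"abolishes {h.modification}" for h in hits.itertuples()]
        if slim_table is not None and len(slim_table):
            hit = slim_table[(slim_table["start"] <= rec.position) & (rec.position <= slim_table["end"])]
            # "" marks "evaluated, no overlap"; None stays "not evaluated"
            rec.slim_overlap = str(hit.iloc[0]["name"]) if len(hit) else ""
        if gain_table is not None and len(gain_table):
            hits = gain_table[
                (gain_table["position"] == rec.position) & (gain_table["residue"] == rec.mutant)
            ]
            gained = False
            for h in hits.itertuples():
                if rec.mutant in PHOSPHO_ACCEPTORS and "phos" in str(h.modification).lower():
                    if relative_sasa is None:
                        logger.warning("no SASA data: exposure gate waived for %s", rec.label)
                        exposed = True
                    else:
                        exposed = relative_sasa.get(rec.position, 0.0) >= exposure_threshold
                    if exposed:
                        gained = True
                        details.append(f"introduces {h.modification}")
                else:
                    gained = True
                    details.append(f"introduces {h.modification}")
            rec.ptm_gained = gained
        rec.ptm_detail = "; ".join(details)
    return records


# --- solvent accessibility -------------------------------------------------------

#: van der Waals radii (A) by element, NACCESS-style defaults
VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "H": 1.00}

#: side-chain reference areas (A^2) in an extended Gly-X-Gly context
#: (Miller et al. standard accessibilities; Gly uses its main-chain CA value)
SIDECHAIN_REFERENCE = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "GLY": 47.0, "HIS": 151.0, "ILE": 140.0,
    "LEU": 137.0, "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0,
    "SER": 80.0, "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_sasa(
    ensemble_or_frame,
    frame: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-residue absolute and relative side-chain SASA of one frame.

    Numerical Shrake-Rupley surface: each atom's solvent-accessible sphere
    (vdW + probe radius) is sampled with ``n_points`` test points; a point is
    accessible when outside every other atom's accessible sphere.  Relative
    side-chain exposure divides by the residue type's extended-reference
    area.  Returns a DataFrame indexed by position with columns
    ``residue, sasa_total, sasa_sidechain, relative_sidechain``.
    """
    ens: ConformationalEnsemble = ensemble_or_frame
    coords = ens.coords[frame]
    radii = np.empty(ens.n_atoms)
    for i, a in enumerate(ens.atoms):
        el = a.element.capitalize()
        if el not in VDW_RADII:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii[i] = VDW_RADII[el] + probe_radius
    points = _sphere_points(n_points)
    area_per_atom = np.zeros(ens.n_atoms)
    for i in range(ens.n_atoms):
        test = coords[i] + radii[i] * points
        # neighbours whose accessible spheres can occlude atom i
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.where((d < radii + radii[i]) & (np.arange(ens.n_atoms) != i))[0]
        if nb.size:
            dist = np.linalg.norm(test[:, None, :] - coords[nb][None, :, :], axis=2)
            accessible = np.all(dist >= radii[nb][None, :], axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        area_per_atom[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    rows = []
    for r in ens.residues:
        idx = ens.atom_indices(r)
        side = [i for i in idx if ens.atoms[i].is_sidechain_heavy]
        if not side:  # glycine: CA stands in for the side chain
            side = [i for i in idx if ens.atoms[i].atom_name == "CA"]
        abs_side = float(area_per_atom[side].sum()) if side else 0.0
        ref = SIDECHAIN_REFERENCE.get(r.name.upper())
        rows.append(
            {
                "position": r.position,
                "residue": r.name,
                "sasa_total": float(area_per_atom[idx].sum()),
                "sasa_sidechain": abs_side,
                "relative_sidechain": abs_side / ref if ref else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("position")


# --- co-occurrence and expression ------------------------------------------------


@dataclass
class MutationMatrix:
    """samples x genes boolean incidence of nonsynonymous mutation."""

    data: pd.DataFrame  # index samples, columns genes, dtype bool

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("sample and gene labels must be unique")
        self.data = self.data.astype(bool)

    @property
    def n_samples(self) -> int:
        return len(self.data)


def cooccurrence_fisher(
    matrix: MutationMatrix | pd.DataFrame,
    gene_a: str,
    gene_b: str,
    alternative: str = "greater",
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test for co-occurring mutations of two genes.

    Returns (odds ratio, p-value, 2x2 table) where the table rows are
    gene_a mutated / wild type and columns gene_b mutated / wild type.
    ``alternative='greater'`` tests enrichment of co-occurrence (default);
    'two-sided' and 'less' (mutual exclusivity) are also accepted.
    """
    df = matrix.data if isinstance(matrix, MutationMatrix) else matrix.astype(bool)
    if df.empty:
        raise ValueError("mutation matrix has no samples")
    a, b = df[gene_a].to_numpy(), df[gene_b].to_numpy()
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    odds, p = fisher_exact(table, alternative=alternative)
    return float(odds), float(p), table


@dataclass
class ExpressionChange:
    gene: str
    logfc: float | None
    fdr: float | None
    call: str  # up | down | no_DE
    thresholds: tuple[float, float] = (0.5, 0.05)


def classify_expression(
    rows: pd.DataFrame, logfc_cutoff: float = 0.5, fdr_cutoff: float = 0.05
) -> list[ExpressionChange]:
    """Up/down/no_DE calls from a differential-expression output table.

    Expects columns ``gene, logFC, FDR``; significance requires FDR <=
    ``fdr_cutoff`` and |logFC| >= ``logfc_cutoff``.  A missing FDR yields
    no_DE with a warning.
    """
    out = []
    for _, row in rows.iterrows():
        logfc = row.get("logFC")
        fdr = row.get("FDR")
        if fdr is None or pd.isna(fdr):
            logger.warning("gene %s: missing FDR, calling no_DE", row.get("gene"))
            call = "no_DE"
            fdr = None
        elif pd.isna(logfc):
            call = "no_DE"
        elif logfc >= logfc_cutoff and fdr <= fdr_cutoff:
            call = "up"
        elif logfc <= -logfc_cutoff and fdr <= fdr_cutoff:
            call = "down"
        else:
            call = "no_DE"
        out.append(
            ExpressionChange(
                str(row.get("gene")),
                None if pd.isna(logfc) else float(logfc),
                None if fdr is None else float(fdr),
                call,
                (logfc_cutoff, fdr_cutoff),
            )
        )
    return out
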