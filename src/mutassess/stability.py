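"""Aggregation and classification of saturation free-energy scans.

ddG values (kcal/mol, mutant minus wild type; positive destabilizes) come
from repeated runs of an empirical energy function over an ensemble of
representative conformations.  Aggregation averages runs within each frame
and then frames, so uneven run counts do not bias frames; the reported
dispersion is the SD over frame means.  Classification is threshold-based
and the thresholds are explicit parameters carried into every downstream
report.  Two network criteria complement the energetics: loss of hub
behaviour upon mutation and loss of a persistent salt bridge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_io import ResidueID
from .psn import InteractionRecord, PSNGraph, hubs

logger = logging.getLogger(__name__)

AA_ONE = "ACDEFGHIKLMNPQRSTVWY"

NEGATIVE = {"D", "E"}
POSITIVE = {"K", "R"}


class DDGParseError(ValueError):
    pass


class MissingCellError(KeyError):
    pass


@dataclass
class DDGRecord:
    """One ddG evaluation: a substitution at a site, in one run on one frame."""

    position: int
    wild_type: str  # one-letter code
    substitution: str  # one-letter code, != wild type
    ddg: float  # kcal/mol
    run: int = 0
    frame: str = "0"

    def __post_init__(self) -> None:
        for aa in (self.wild_type, self.substitution):
            if aa not in AA_ONE:
                raise DDGParseError(f"unknown residue code {aa!r}")
        if self.substitution == self.wild_type:
            raise DDGParseError(f"substitution equals wild type at {self.wild_type}{self.position}")
        if not np.isfinite(self.ddg):
            raise DDGParseError(f"non-finite ddG at {self.wild_type}{self.position}{self.substitution}")


@dataclass
class SaturationScan:
    """site x substitution matrices of mean ddG and dispersion (kcal/mol).

    Rows are indexed by ``(position, wild_type)``; columns are the 20
    one-letter codes (the wild-type cell of each row is absent/NaN).
    """

    mean: pd.DataFrame
    dispersion: pd.DataFrame
    source: str = ""

    def cell(self, position: int, wild_type: str, substitution: str) -> float:
        try:
            value = self.mean.at[(position, wild_type), substitution]
        except KeyError:
            raise MissingCellError(f"no ddG data for {wild_type}{position}{substitution}") from None
        if pd.isna(value):
            raise MissingCellError(f"no ddG data for {wild_type}{position}{substitution}")
        return float(value)

    def sites(self) -> list[tuple[int, str]]:
        return list(self.mean.index)


_MUT_TOKEN = re.compile(r"^([A-Y])([A-Za-z]?)(\d+)([A-Y])$")


def parse_ddg_tables(paths, dialect: str = "tsv") -> list[DDGRecord]:
    """Read ddG tables in the plain TSV or the FoldX-style dialect.

    tsv: columns ``pos  wt  sub  run  frame  ddg`` (tab-separated, header).
    foldx: per-run files of ``frame_label<TAB>mutation<TAB>ddg`` rows where
    the mutation token is wild type + optional chain + position +
    substitution (e.g. ``GA12D``); the run index is the file order.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    records: list[DDGRecord] = []
    for run_idx, path in enumerate(paths):
        path = Path(path)
        if dialect == "tsv":
            df = pd.read_csv(path, sep="\t", comment="#")
            if df.empty:
                logger.warning("%s: empty ddG table", path)
                continue
            for i, row in df.iterrows():
                try:
                    records.append(
                        DDGRecord(int(row["pos"]), str(row["wt"]), str(row["sub"]),
                                  float(row["ddg"]), int(row.get("run", run_idx)), str(row.get("frame", "0")))
                    )
                except (DDGParseError, KeyError, ValueError) as exc:
                    raise DDGParseError(f"{path} line {i + 2}: {exc}") from exc
        elif dialect == "foldx":
            with open(path) as fh:
                lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
            if not lines:
                logger.warning("%s: empty ddG table", path)
                continue
            for lineno, line in enumerate(lines, start=1):
                fields = line.split("\t")
                if len(fields) != 3:
                    raise DDGParseError(f"{path} line {lineno}: expected 3 tab-separated fields")
                frame, token, value = fields
                m = _MUT_TOKEN.match(token.strip())
                if not m:
                    raise DDGParseError(f"{path} line {lineno}: bad mutation token {token!r}")
                wt, _chain, pos, sub = m.groups()
                records.append(DDGRecord(int(pos), wt, sub, float(value), run_idx, frame))
        else:
            raise ValueError(f"unknown ddG dialect {dialect!r}")
    return records


def aggregate_scan(records: list[DDGRecord], source: str = "", flat: bool = False) -> SaturationScan:
    """Two-level average: runs within each frame, then frames.

    ``flat=True`` averages all records of a cell directly (identical when
    every frame has the same number of runs).  Dispersion is the SD (ddof=0)
    of the frame means, so a single-frame scan reports 0, not NaN.
    """
    if not records:
        raise DDGParseError("no ddG records to aggregate")
    df = pd.DataFrame(
        {
            "pos": [r.position for r in records],
            "wt": [r.wild_type for r in records],
            "sub": [r.substitution for r in records],
            "frame": [r.frame for r in records],
            "ddg": [r.ddg for r in records],
        }
    )
    if flat:
        mean = df.groupby(["pos", "wt", "sub"])["ddg"].mean()
        disp = df.groupby(["pos", "wt", "sub"])["ddg"].std(ddof=0)
    else:
        frame_means = df.groupby(["pos", "wt", "sub", "frame"])["ddg"].mean().reset_index()
        g = frame_means.groupby(["pos", "wt", "sub"])["ddg"]
        mean, disp = g.mean(), g.std(ddof=0)
    mean_m = mean.unstack("sub")
    disp_m = disp.unstack("sub")
    cols = [a for a in AA_ONE if a in mean_m.columns]
    return SaturationScan(mean=mean_m[cols], dispersion=disp_m[cols], source=source)


def classify_stability(
    scan: SaturationScan,
    position: int,
    wild_type: str,
    substitution: str,
    damaging_threshold: float = 3.0,
    stabilizing_threshold: float = -1.0,
) -> str:
    """'destabilizing' (mean ddG >= damaging threshold), 'stabilizing'
    (<= stabilizing threshold) or 'neutral'; both boundaries inclusive."""
    value = scan.cell(position, wild_type, substitution)
    if value >= damaging_threshold:
        return "destabilizing"
    if value <= stabilizing_threshold:
        return "stabilizing"
    return "neutral"


def find_hotspots(
    scan: SaturationScan, site_fraction: float = 0.5, damaging_threshold: float = 3.0
) -> list[tuple[int, str]]:
    """Sites where more than ``site_fraction`` of the available substitutions
    are destabilizing — general hotspots for structural stability."""
    out = []
    for site in scan.sites():
        row = scan.mean.loc[[site]].iloc[0].dropna()
        if len(row) and (row >= damaging_threshold).mean() > site_fraction:
            out.append(site)
    return out


def hub_loss(
    wt_graph: PSNGraph,
    mut_graph: PSNGraph | None,
    site: ResidueID,
    min_degree: int = 3,
) -> tuple[bool | None, str]:
    """Does the substitution abolish the site's hub behaviour?

    True only when the site is a hub in the wild-type network and not in the
    mutant network.  A site that is no wild-type hub is not-damaging by this
    criterion ("not a wt hub"); without a mutant ensemble the criterion is
    not evaluated (None, never silently False).
    """
    if site not in wt_graph:
        raise KeyError(f"site {site} absent from the wild-type network roster")
    if wt_graph.degree(site) < min_degree:
        return False, "not a wt hub"
    if mut_graph is None:
        return None, "no mutant ensemble supplied"
    mut_degree = mut_graph.degree(site) if site in mut_graph else 0
    if mut_degree < min_degree:
        return True, f"hub lost (wt degree {wt_graph.degree(site)}, mutant degree {mut_degree})"
    return False, "hub conserved"


def saltbridge_loss(
    records: list[InteractionRecord],
    position: int,
    wild_type: str,
    substitution: str,
    persistence_cutoff: float = 20.0,
    asn_rule_partners: frozenset = frozenset({"R", "K"}),
) -> tuple[bool, list[InteractionRecord]]:
    """Does the substitution abolish a persistent salt bridge at the site?

    Charge-compatibility rules: substitutions conserving the charge class
    (D<->E, K<->R) keep the bridge; X->N retains electrostatic capability
    against basic partners (``asn_rule_partners``; the default covers both
    Arg and Lys so that e.g. D->N against a lysine partner is still called
    retained — restrict to {"R"} for a strict guanidinium-only reading);
    everything else destroys the interaction.
    """
    bridges = [
        r
        for r in records
        if r.persistence >= persistence_cutoff
        and position in (r.residue_a.position, r.residue_b.position)
    ]
    if not bridges:
        return False, []
    same_class = (
        (wild_type in NEGATIVE and substitution in NEGATIVE)
        or (wild_type in POSITIVE and substitution in POSITIVE)
    )
    if same_class:
        return False, bridges
    if substitution == "N":
        partners = {
            (r.residue_b if r.residue_a.position == position else r.residue_a).one_letter
            for r in bridges
        }
        if partners <= asn_rule_partners:
            return False, bridges
    return True, bridges


@dataclass
class StabilityCall:
    """Per-mutation stability verdict across the three criteria."""

    position: int
    wild_type: str
    substitution: str
    ddg_damaging: bool | None  # None = not evaluated
    hub_loss: bool | None
    saltbridge_loss: bool | None
    ddg_value: float | None = None
    notes: str = ""

    @property
    def network_loss(self) -> bool | None:
        """Hub loss OR salt-bridge loss (None iff neither was evaluated)."""
        flags = [f for f in (self.hub_loss, self.saltbridge_loss) if f is not None]
        return any(flags) if flags else None

    @property
    def stability_flag(self) -> bool:
        """Damaging for stability by at least one evaluated criterion."""
        return any(f for f in (self.ddg_damaging, self.hub_loss, self.saltbridge_loss) if f)

    @property
    def label(self) -> str:
        return f"{self.wild_type}{self.position}{self.substitution}"


def call_stability(
    position: int,
    wild_type: str,
    substitution: str,
    scan: SaturationScan | None = None,
    wt_graph: PSNGraph | None = None,
    mut_graph: PSNGraph | None = None,
    sb_records: list[InteractionRecord] | None = None,
    damaging_threshold: float = 3.0,
    stabilizing_threshold: float = -1.0,
    min_degree: int = 3,
) -> StabilityCall:
    """Evaluate every available stability criterion for one mutation."""
    notes = []
    ddg_flag = ddg_value = None
    if scan is not None:
        try:
            category = classify_stability(
                scan, position, wild_type, substitution, damaging_threshold, stabilizing_threshold
            )
            ddg_flag = category == "destabilizing"
            ddg_value = scan.cell(position, wild_type, substitution)
            notes.append(f"ddg={ddg_value:.2f} ({category})")
        except MissingCellError:
            notes.append("ddg cell missing")
    hub_flag = None
    if wt_graph is not None:
        site = next((r for r in wt_graph.nodes if r.position == position), None)
        if site is None:
            notes.append("site not in wt network")
        else:
            hub_flag, reason = hub_loss(wt_graph, mut_graph, site, min_degree)
            notes.append(f"hub: {reason}")
    sb_flag = None
    if sb_records is not None:
        sb_flag, bridges = saltbridge_loss(sb_records, position, wild_type, substitution)
        if bridges:
            notes.append("bridges: " + ",".join(f"{b.residue_a.label}-{b.residue_b.label}" for b in bridges))
    return StabilityCall(
        position, wild_type, substitution, ddg_flag, hub_flag, sb_flag, ddg_value, "; ".join(notes)
    )
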