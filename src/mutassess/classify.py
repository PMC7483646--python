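"""Descriptor aggregation into stability (0-2) and function (0-5) scores.

Each mutation carries seven tri-state descriptors (true / false / not
evaluated).  Two account for stability — destabilizing ddG and loss of a
network feature (hub or salt bridge) — and five for function — PTM
abolition, PTM gain, SLiM overlap, overlap with functional mobile regions,
and long-range communication with at least two functional residue classes.
Scores count the true descriptors per group; not-evaluated never counts, so
"no evidence" is distinct from "no effect".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import dynamics as dyn
from . import genomics as gen
from . import paths as paths_mod
from . import psn as psn_mod
from . import stability as stab
from .ensemble_io import FunctionalAnnotation, load_annotation_config, read_pdb_ensemble

logger = logging.getLogger(__name__)

STABILITY_DESCRIPTORS = ("ddg_damaging", "network_loss")
FUNCTION_DESCRIPTORS = (
    "ptm_abolished",
    "ptm_gained",
    "slim_overlap",
    "dynamics_overlap",
    "long_range_paths",
)


class AggregationError(ValueError):
    pass


@dataclass
class DescriptorVector:
    """Tri-state damaging descriptors; ``None`` means not evaluated."""

    ddg_damaging: bool | None = None
    network_loss: bool | None = None
    ptm_abolished: bool | None = None
    ptm_gained: bool | None = None
    slim_overlap: bool | None = None
    dynamics_overlap: bool | None = None
    long_range_paths: bool | None = None

    def as_dict(self) -> dict[str, bool | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def fully_unevaluated(self) -> bool:
        return all(v is None for v in self.as_dict().values())


@dataclass
class AssessmentReport:
    mutation: str
    descriptors: DescriptorVector
    stability_score: int
    function_score: int
    category: str  # stability_only | function_only | both | neutral
    notes: str = ""
    provenance: dict = field(default_factory=dict)


def assemble_descriptors(
    mutation: str,
    stability_call: stab.StabilityCall | None = None,
    n_communicating_classes: int | None = None,
    dynamics_match: bool | None = None,
    annotation_record: gen.MutationRecord | None = None,
    long_range_min_classes: int = 2,
) -> DescriptorVector:
    """Map upstream results onto the descriptor slots; missing -> not evaluated."""
    v = DescriptorVector()
    if stability_call is not None:
        if stability_call.label != mutation:
            raise AggregationError(f"stability call {stability_call.label} does not match {mutation}")
        v.ddg_damaging = stability_call.ddg_damaging
        v.network_loss = stability_call.network_loss
    if n_communicating_classes is not None:
        v.long_range_paths = n_communicating_classes >= long_range_min_classes
    if dynamics_match is not None:
        v.dynamics_overlap = bool(dynamics_match)
    if annotation_record is not None:
        if annotation_record.label != mutation:
            raise AggregationError(f"annotation record {annotation_record.label} does not match {mutation}")
        v.ptm_abolished = annotation_record.ptm_abolished
        v.ptm_gained = annotation_record.ptm_gained
        v.slim_overlap = (
            None if annotation_record.slim_overlap is None else bool(annotation_record.slim_overlap)
        )
    return v


def score_and_categorize(vector: DescriptorVector) -> tuple[int, int, str]:
    """(stability_score 0-2, function_score 0-5, category)."""
    s = sum(bool(getattr(vector, d)) for d in STABILITY_DESCRIPTORS)
    f = sum(bool(getattr(vector, d)) for d in FUNCTION_DESCRIPTORS)
    if s == 0 and f == 0:
        category = "neutral"
    elif f == 0:
        category = "stability_only"
    elif s == 0:
        category = "function_only"
    else:
        category = "both"
    return s, f, category


def make_report(
    mutation: str, vector: DescriptorVector, provenance: dict | None = None
) -> AssessmentReport:
    s, f, category = score_and_categorize(vector)
    notes = "insufficient data" if vector.fully_unevaluated else ""
    return AssessmentReport(mutation, vector, s, f, category, notes, provenance or {})


def rank_report(
    reports: list[AssessmentReport], order: str = "combined"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked table plus heatmap-ready descriptor matrix.

    ``order`` is 'by_function', 'by_stability' or 'combined' (sum of both);
    descending score, ties broken by mutation label.  The descriptor matrix
    holds 1 / 0 / NA for true / false / not evaluated.
    """
    if not reports:
        raise AggregationError("no reports to rank")
    keys = {
        "by_function": lambda r: (-r.function_score, r.mutation),
        "by_stability": lambda r: (-r.stability_score, r.mutation),
        "combined": lambda r: (-(r.stability_score + r.function_score), r.mutation),
    }
    if order not in keys:
        raise ValueError(f"unknown ranking order {order!r}")
    ordered = sorted(reports, key=keys[order])
    table = pd.DataFrame(
        {
            "mutation": [r.mutation for r in ordered],
            "stability_score": [r.stability_score for r in ordered],
            "function_score": [r.function_score for r in ordered],
            "category": [r.category for r in ordered],
            "notes": [r.notes for r in ordered],
        }
    )
    matrix = pd.DataFrame(
        [
            {d: _tri(getattr(r.descriptors, d)) for d in STABILITY_DESCRIPTORS + FUNCTION_DESCRIPTORS}
            for r in ordered
        ],
        index=[r.mutation for r in ordered],
    )
    return table, matrix


def _tri(value: bool | None):
    return pd.NA if value is None else int(value)


# --- pipeline driver -------------------------------------------------------------


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> list[AssessmentReport]:
    """Run every available stage end to end from a config mapping or YAML file.

    Recognized config keys (all paths; optional unless noted):
    ``ensemble`` (required), ``ensemble2``, ``mutations`` (required, curated
    TSV), ``annotation`` (YAML; defaults to the ULK1 sets), ``ddg_tables``
    (list) + ``ddg_dialect``, ``ptm_table``/``slim_table``/``gain_table``
    (TSVs), ``out_dir``, ``parameters`` (threshold overrides), ``seed``.
    Stages with missing inputs leave their descriptors not-evaluated.
    Outputs: report.tsv, descriptor_matrix.tsv and manifest.json.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    params = dict(config.get("parameters", {}))
    p = {
        "distance_cutoff": 5.0,
        "persistence_cutoff": 20.0,
        "sb_cutoff": 4.5,
        "min_degree": 3,
        "damaging_threshold": 3.0,
        "stabilizing_threshold": -1.0,
        "halo": 2,
        "long_range_min_classes": 2,
        "revel_cutoff": 0.4,
        **params,
    }
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    annotation: FunctionalAnnotation = load_annotation_config(config.get("annotation"))

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    ens_a = stage("ensemble_io", lambda: read_pdb_ensemble(config["ensemble"]))
    ens_b = (
        stage("ensemble_io", lambda: read_pdb_ensemble(config["ensemble2"]))
        if config.get("ensemble2")
        else None
    )

    graph_a = stage(
        "psn", lambda: psn_mod.build_contact_psn(ens_a, p["distance_cutoff"], p["persistence_cutoff"])
    )
    sb_records = stage(
        "psn", lambda: psn_mod.build_salt_bridge_network(ens_a, p["sb_cutoff"], p["persistence_cutoff"])[1]
    )

    muts = stage("genomics", lambda: gen.parse_mutation_table(config["mutations"], dialect="tsv"))
    muts = gen.filter_domain(muts, annotation.domain_range)
    if len({m.label for m in muts}) != len(muts):
        raise AggregationError("duplicate mutation rows in input")

    # annotation interplay (tables optional)
    tables = {}
    for key in ("ptm_table", "slim_table", "gain_table"):
        if config.get(key):
            tables[key] = pd.read_csv(config[key], sep="\t")
    if tables:
        sasa = stage("genomics", lambda: gen.shrake_rupley_sasa(ens_a))
        rel = dict(zip(sasa.index, sasa["relative_sidechain"]))
        gen.ptm_slim_annotate(
            muts,
            tables.get("ptm_table"),
            tables.get("slim_table"),
            tables.get("gain_table"),
            relative_sasa=rel,
        )
        annotated = True
    else:
        annotated = False

    # stability
    scan = None
    if config.get("ddg_tables"):
        records = stage(
            "stability",
            lambda: stab.parse_ddg_tables(config["ddg_tables"], config.get("ddg_dialect", "tsv")),
        )
        scan = stab.aggregate_scan(records)

    # dynamics
    model_a = stage("dynamics", lambda: dyn.fit_pca(ens_a)) if ens_a.n_frames >= 2 else None
    regions = dyn.detect_mobile_regions(model_a) if model_a is not None else None
    dyn_flags = (
        dyn.mutation_dynamics_overlap([m.position for m in muts], regions, halo=p["halo"])
        if regions is not None
        else None
    )

    # communication paths (conserved across both ensembles when two given)
    comm_counts: dict[int, int] | None = None
    sources = sorted({n for n in graph_a.nodes if any(m.position == n.position for m in muts)})
    if sources:
        table_a = stage("paths", lambda: paths_mod.class_paths(graph_a, sources, annotation))
        if ens_b is not None:
            graph_b = psn_mod.build_contact_psn(ens_b, p["distance_cutoff"], p["persistence_cutoff"])
            table_b = paths_mod.class_paths(graph_b, sources, annotation)
            conserved = paths_mod.conserved_paths(table_a, table_b)
        else:
            conserved = table_a[table_a.path.notna()]
        summary = paths_mod.communication_summary(conserved, p["long_range_min_classes"])
        comm_counts = {s.position: int(n) for s, n in zip(summary.source, summary.n_classes)}

    reports = []
    provenance = {
        "parameters": p,
        "inputs": {k: str(v) for k, v in config.items() if k != "parameters"},
    }
    provenance["config_sha256"] = hashlib.sha256(
        json.dumps(provenance["inputs"], sort_keys=True).encode()
    ).hexdigest()
    for m in sorted(muts, key=lambda m: (m.position, m.mutant)):
        call = None
        if scan is not None or graph_a is not None or sb_records is not None:
            site_in_graph = any(n.position == m.position for n in graph_a.nodes)
            call = stab.call_stability(
                m.position,
                m.wild_type,
                m.mutant,
                scan=scan,
                wt_graph=graph_a if site_in_graph else None,
                mut_graph=None,
                sb_records=sb_records,
                damaging_threshold=p["damaging_threshold"],
                stabilizing_threshold=p["stabilizing_threshold"],
                min_degree=p["min_degree"],
            )
        vec = assemble_descriptors(
            m.label,
            stability_call=call,
            n_communicating_classes=(comm_counts.get(m.position, 0) if comm_counts is not None else None),
            dynamics_match=(dyn_flags[m.position] is not None if dyn_flags is not None else None),
            annotation_record=m if annotated else None,
            long_range_min_classes=p["long_range_min_classes"],
        )
        reports.append(make_report(m.label, vec, provenance))

    table, matrix = rank_report(reports)
    table.to_csv(out_dir / "report.tsv", sep="\t", index=False)
    matrix.to_csv(out_dir / "descriptor_matrix.tsv", sep="\t")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return reports
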