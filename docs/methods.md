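# Methods

This note documents the models and procedures implemented in `mutassess`,
the parameter defaults and why they were chosen, the numerical choices that
affect results, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Ensembles and interaction centers

A conformational ensemble is an ordered stack of frames over a fixed atom
roster (`ConformationalEnsemble`); the canonical on-disk form is a
multi-model PDB file, read via Biopython and written with a fixed-column
formatter, so round trips preserve coordinates to PDB precision (10⁻³ Å).
Models with inconsistent rosters are an error, not silently reconciled.
Alternate locations resolve to the highest-occupancy conformer. Residue
numbering is taken verbatim from the coordinate file (UniProt O75385
numbering for the ULK1 kinase domain); mutation positions are matched in
that numbering, never renumbered.

The interaction center of a residue is the mass-weighted mean of its
side-chain heavy atoms. Hydrogens are excluded (deposited heavy-atom
ensembles rarely carry them, and this is standard PSN practice). Glycine
has no side chain and falls back to Cα; alanine's center is its lone Cβ.
Frames for reduced-cost analyses (e.g. representative conformations for
ΔΔG scans) are selected by equal spacing in time by default; any
user-chosen subset is accepted, since no single published convention
exists for picking representative frames.

## Persistence networks

An interaction's *persistence* is 100 × (frames where its geometric
criterion holds) / (total frames). An edge is stored iff persistence ≥ the
cutoff; the threshold is inclusive (a 20.0% contact is kept) because
"occurring in 20% of frames" reads naturally as inclusive. Defaults:

| parameter | default | rationale |
|---|---|---|
| contact distance cutoff | 5.0 Å (side-chain COM) | standard contact-PSN choice, validated by the jackknife cutoff scan |
| persistence cutoff | 20% | removes spurious transient contacts |
| sequence exclusion | \|i−j\| ≤ 1 | covalent neighbours are trivially close; configurable (i±2 also seen in practice) |
| hub degree | ≥ 3 | conventional hub definition for residue graphs |
| salt-bridge cutoff | 4.5 Å (min atom–atom) | charged-moiety criterion; 5.0 Å available as a consistency check |
| H-bond | ≤ 3.5 Å donor–acceptor, ≥ 120° D–H–A | standard geometric definition; the angle term disables itself (with a logged warning) when no hydrogens exist |

Charged moieties are explicit atom sets: Asp {OD1, OD2, CG}, Glu {OE1,
OE2, CD}, Lys {NZ}, Arg {NH1, NH2, NE, CZ}. Histidine is excluded from
salt bridges by default (only carboxylate/ammonium/guanidinium groups
qualify); a flag admits doubly-protonated His.

`cutoff_scan` implements a plain frame jackknife (default 10 resamples of
80% of frames per cutoff) reporting mean and SD of hub, component and edge
counts. This is deliberately simpler than full published resampling
pipelines; its only role here is to show how robust the network summary is
to the cutoff choice.

Graph construction and component/degree queries sit on networkx; the
persistence computation itself is vectorized numpy over all frames and
pairs, and is property-tested against an exhaustive per-frame double loop.

## Communication paths

Path search is minimum-hop (breadth-first) on the undirected persistence
graph. Reported "length" is the number of intermediate nodes (a direct
contact has length 0); the edge count is also emitted. Among equally short
paths, ties break by higher mean edge persistence, then lexicographically
on node labels, so results are deterministic and rerun-stable. Direct
(1-hop) contacts are valid paths. A source with no persistent contacts
yields explicit no-path rows rather than errors.

Per functional class (activity residues, DFG, HRD, APE, C-helix, catalytic
spine, regulatory spine — the ULK1 defaults; any named sets can be
configured), only the best path over member targets is kept. "Conserved"
across two ensembles means, by default, that a path exists in both
(existence reading); a strict mode requires identical node sequences.
A site communicating with ≥ 2 classes is flagged as a long-range
communicator. The mean edge persistence is the only weight the graph
carries, and that is what "average weight" denotes in all outputs.

## Essential dynamics

PCA is performed on the 3N × 3N covariance matrix of Cα coordinates after
least-squares (Kabsch) superposition onto the mean structure, iterated
twice (fit to the running mean, recompute, refit) — a conventional choice,
since fitting protocols are rarely stated precisely in the literature.
Eigenvalues are clipped at zero (round-off) and sorted descending;
eigenvectors are orthonormal to 10⁻⁸. Multiple ensembles passed together
are concatenated frame-wise and fitted to a common mean (the joint
essential subspace); cross-ensemble RMSIP uses per-ensemble models, the
standard usage.

RMSIP over n modes: √((1/n) Σᵢⱼ (vᵢ·wⱼ)²); properties (symmetry, [0, 1]
range, unity on identical subspaces, eigenvalue-sum = covariance trace to
10⁻⁶ relative) are tested. Per-residue mobility of a mode is the Euclidean
norm of its three components for that residue. Mobile regions are maximal
contiguous runs (≥ 3 residues) with mobility > mean + 1 SD of the profile —
explicit, configurable thresholds in place of the visual inspection usually
used to call such regions. Proximity of a mutation site to a mobile region
uses a ±2-residue halo by default ("in the area of" a loop motion includes
its hinges). The ULK1 defaults (148–158, 172–183, 35–41) are provided for
use when no ensemble is at hand.

## Stability assessment

ΔΔG tables (kcal/mol, mutant − wild type, positive destabilizes) come from
repeated runs of an empirical energy function over an ensemble of
representative conformations; this package consumes them (plain TSV or a
FoldX-style dialect) and never re-implements the energy function.
Aggregation averages runs within each frame, then frames, so frames with
more runs are not overweighted; a flat mean is available (identical when
run counts are even). Dispersion is the SD over frame means with ddof = 0,
so a single-frame scan reports 0 rather than NaN. Cells with no records
are *missing*, never zero.

Thresholds: destabilizing at mean ΔΔG ≥ 3.0 kcal/mol, stabilizing at
≤ −1.0, both boundaries inclusive, both exposed as parameters and recorded
in every downstream report. The 3.0 figure is consistent with treating
≤ 1.6 kcal/mol as no-effect while keeping hotspot cells (≈ 8 kcal/mol in
the synthetic scans) clearly damaging. A site is a hotspot when more than
half of its available substitutions are destabilizing.

Network criteria: *hub loss* is true only when the site is a wild-type hub
and not a hub in the mutant-ensemble network; a site that was never a hub
is not-damaging-by-this-criterion with an explicit reason, and a missing
mutant ensemble leaves the criterion "not evaluated", never silently
false. *Salt-bridge loss* is true when the site participates in a
persistent bridge and the substitution destroys charge compatibility:
D↔E and K↔R swaps conserve the interaction; substitution to asparagine
retains electrostatic capability against basic partners (both Arg and Lys
by default — the package's reading of the amide-vs-basic-partner
interaction; a strict guanidinium-only mode is available); all other
substitutions at bridged sites lose. The overall stability flag is the OR
of the evaluated criteria, with the composition configurable.

## Genomics layer

Missense mutations are parsed from a MAF column subset (Hugo_Symbol,
Tumor_Sample_Barcode, Variant_Classification, HGVSp_Short) or a curated
TSV; non-missense rows are dropped with a logged count, malformed
protein-change strings fail with row context. Domain filtering uses the
closed interval (default [8, 280]) and is idempotent. REVEL classification
is damaging at score ≥ 0.4 (inclusive — the cutoff statement does not
specify inclusivity, so the boundary case is documented here), neutral
below, unscored when missing.

PTM/SLiM interplay consumes annotation tables (predictor internals are out
of scope): a mutation at a listed PTM position abolishes it; SLiM overlap
is position-inside-the-closed-motif-range with no halo (a mutation at the
first motif position, like D279N against 279–283, is covered); a
predicted-gain row fires when the mutant residue matches, and
phosphorylation gains additionally require relative side-chain solvent
exposure ≥ 20% — buried serines cannot be phosphorylated. Flags are
tri-state: a table that was never supplied leaves its flag "not
evaluated", distinct from "checked, no hit".

SASA is a Shrake–Rupley numerical surface: each atom's accessible sphere
(van der Waals + 1.4 Å probe) is sampled with 960 golden-spiral points and
a point counts when outside every neighbour's accessible sphere. Radii are
element-based NACCESS-style values (C 1.87, N 1.65, O 1.40, S 1.85 Å).
Relative side-chain exposure divides by Miller-style extended-reference
side-chain areas (glycine uses its Cα main-chain value). Accuracy is
quadrature-limited: tests hold it to 2% of a dense-sampling oracle and 1%
under rotation.

Co-occurrence of mutations between two genes across samples is Fisher's
exact test on the 2 × 2 incidence table, one-sided "greater" by default
(co-occurrence enrichment); two-sided and "less" (mutual exclusivity) are
options. No multiple-testing correction is applied by default; callers
testing many pairs should apply BH-FDR across them. Expression calls
require FDR ≤ 0.05 and |logFC| ≥ 0.5 (inclusive); a missing FDR gives
no_DE with a warning.

## Classification and scores

Seven descriptors, each tri-state (true / false / not evaluated):
stability — ΔΔG-damaging, network loss (hub OR salt bridge); function —
PTM abolished, PTM gained, SLiM overlap, mobile-region overlap, long-range
communication (≥ 2 classes). Scores count true descriptors (0–2 and 0–5,
unit weights); categories partition exhaustively: both scores zero →
neutral, only stability positive → stability_only, only function positive
→ function_only, else both. The five function descriptors are the five
function-level analyses the pipeline performs; the mapping is overridable
in configuration for alternative decompositions. "Not evaluated" never
contributes — reports distinguish absence of evidence from evidence of
absence, and a fully unevaluated mutation is reported neutral with an
"insufficient data" note. Ranking sorts by the chosen score descending
with lexicographic tie-break, so reports are byte-stable across reruns.

The pipeline driver (`run_pipeline`) executes ensemble I/O → networks →
paths → dynamics → stability → genomics → classification, skips stages
whose inputs are absent (descriptors become not-evaluated), aborts with
the stage name on failure, and writes the ranked report, the descriptor
matrix and a manifest carrying every parameter and an input-config hash.

## Synthetic generators: what they emulate, and what they don't

The generators produce every input class with planted, recoverable
structure, so the full pipeline is testable without any external data:

- **Contact schedules** place pseudo-residues (backbone + 1–4 side-chain
  heavy atoms, real residue types so charge rules and COM fallbacks are
  exercised) on a wide ring; scheduled pairs are posed 3.5 Å apart in
  exactly the first ⌈p·F/100⌉ frames and > 6 Å apart otherwise, so realized
  persistence is exact up to one frame of rounding. Deterministic frame
  assignment (not Bernoulli sampling) makes persistence tests exact; pairs
  must be residue-disjoint or generation fails naming the conflict.
- **Charged pairs** realize a scheduled salt-bridge persistence with the
  minimum carboxylate–ammonium distance at 4.0 Å (on) / 6.5 Å (off),
  straddling the 4.5 / 5.5 Å criteria with margin.
- **Mode ensembles** draw frames from planted orthonormal displacement
  modes (orthogonalized against rigid-body motion of the helical Cα
  scaffold, so superposition does not distort recovery) plus isotropic
  noise. The ensemble pair shares m = round(o²·k) of k modes to
  approximate a target top-k RMSIP of o (RMSIP² ≈ m/k).
- **ΔΔG scans** draw hotspot cells from Normal(effect, noise) and others
  from Normal(0.5, noise), written in both supported dialects.
- **Mutation matrices** are independent Bernoulli per gene except one
  planted pair whose joint distribution matches a requested odds ratio
  exactly in expectation (closed-form quadratic for P(both)).

All generators are seed-deterministic (one master seed derives child seeds
by fixed offsets) and write byte-identical files for identical seeds.
They emulate the *statistical* structure the analyses measure — contact
persistence, subspace overlap, effect-size separation, co-occurrence — not
physical protein geometry: no torsional realism, no packing, no
force-field energetics, no sequence-realistic mutation signatures.
Passing tests therefore demonstrate that the estimators recover planted
truth under controlled conditions, not that any particular biological
ensemble is well sampled.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run on ensembles up to 18 residues × 50 frames
and graphs up to 30 nodes, where exhaustive enumeration is exact and fast.
Subspace-recovery checks use 30 Cα atoms × 500 frames (with a 20-frame
degradation check); hotspot recovery uses 15 sites × 19 substitutions ×
5 runs × 20 frames; co-occurrence power uses 100 cohorts of 200 samples at
odds ratio 20 and a 400-replicate null for type-I control. These sizes
give stable statistics while keeping the whole suite fast on one CPU.

## Known limitations

- The energy function behind ΔΔG values, coarse-grained mutant-ensemble
  generation, and all annotation predictors (REVEL, phosphosite and
  nitrosylation predictors, motif discovery) are consumed as tables, never
  computed.
- No π-cation/π-stacking/hydrophobic-cluster network classes; no
  energy-weighted network variant; no centrality measures beyond degree;
  no suboptimal-path ensembles.
- PCA is Cα-Cartesian only (no dihedral PCA, no time-lagged analysis); no
  free-energy-landscape estimation.
- mmCIF and binary trajectory formats are not part of the core reader
  contract; inputs are assumed pre-fitted (no PBC unwrapping).
- Hub-loss requires a mutant ensemble; without one the criterion is
  reported not-evaluated, which lowers the stability score relative to a
  study that did model every mutant.
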