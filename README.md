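# mutassess

Structure-ensemble assessment of cancer missense mutations: persistence-based
protein structure networks, communication-path analysis, essential dynamics,
saturation free-energy aggregation, mutation curation/co-occurrence, and a
final stability/function damaging classification.

## Who this is for

Computational structural biologists and cancer-genomics analysts who have
(i) a conformational ensemble of a protein domain (for example from
molecular dynamics), (ii) a list of somatic missense mutations from tumour
cohorts, and optionally (iii) saturation-mutagenesis ΔΔG tables and
annotation tables (REVEL scores, PTM sites, short linear motifs,
differential-expression output), and who want a per-mutation, per-mechanism
verdict: does this substitution plausibly damage the protein's *stability*,
its *function*, both, or neither?

The worked system is the ULK1 kinase domain (UniProt O75385, residues
8–280), the upstream serine/threonine kinase of autophagy initiation; its
functional annotation (catalytic lysine K46, C-helix glutamate E63,
activation-loop phosphosite T180, DFG/HRD/APE motifs, catalytic and
regulatory spines) ships as the default configuration, and the curated
TCGA-derived mutation table of the domain is included as packaged data.
Every stage is generic over any single-domain ensemble.

## The methods at the core

**Persistence networks (PSN).** Residues are nodes; a pair (i, j) is an
edge iff its interaction occurs in at least *p*% of the ensemble frames
(default *p* = 20, inclusive). Contacts use the side-chain center-of-mass
distance with a 5 Å cutoff; salt bridges use the minimum atom distance
between charged moieties (Asp/Glu carboxylate vs Lys ammonium / Arg
guanidinium) with a 4.5 Å cutoff; hydrogen bonds use donor–acceptor
geometry (≤ 3.5 Å, angle ≥ 120° when hydrogens exist). Edge weight is the
persistence in % of frames. Hubs are nodes with degree ≥ 3 — a proxy for
residues critical to structural integrity.

**Communication paths.** Minimum-hop paths connect each mutation site to
five functional residue classes (activity residues, DFG/HRD/APE motifs,
C-helix, catalytic spine, regulatory spine); "length" is the number of
intermediate nodes. Paths conserved across two independent ensembles and
sites reaching ≥ 2 classes mark candidate long-range (allosteric)
communicators.

**Essential dynamics.** PCA of the Cα covariance matrix after least-squares
superposition. Subspace similarity between two ensembles is the root mean
square inner product over the first *n* = 20 modes,

RMSIP = √( (1/n) Σᵢ Σⱼ (vᵢ·wⱼ)² ),

which is 1 for identical essential subspaces. Contiguous residues whose
PC1 weight exceeds mean + 1 SD are mobile regions; mutations inside (or
within ±2 residues of) one may perturb functional motions.

**Stability calls.** ΔΔG records (kcal/mol, mutant − wild type) are
averaged over runs within each frame and then over frames; a mutation is
destabilizing at mean ΔΔG ≥ 3.0, stabilizing at ≤ −1.0. A site where most
substitutions are destabilizing is a stability hotspot. Network criteria
complement the energetics: loss of hub behaviour upon mutation, and loss of
a persistent salt bridge by a charge-destroying substitution (D↔E and K↔R
swaps conserve; X→N retains capability against basic partners).

**Genomics layer.** MAF/TSV mutation parsing, kinase-domain filtering
(closed interval [8, 280]), REVEL classification (damaging at ≥ 0.4),
PTM-abolition / PTM-gain / SLiM-overlap flags (phospho-gain gated on
relative side-chain solvent exposure ≥ 20%, computed with a Shrake–Rupley
surface), expression calls (|logFC| ≥ 0.5, FDR ≤ 0.05), and pairwise
mutation co-occurrence across tumour samples by Fisher's exact test
(one-sided "greater" by default).

**Classification.** Seven tri-state descriptors (true / false / not
evaluated) are counted into a stability score (0–2: ΔΔG, network loss) and
a function score (0–5: PTM abolished, PTM gained, SLiM overlap, mobile-region
overlap, long-range communication), giving the categories `neutral`,
`stability_only`, `function_only`, `both`. "Not evaluated" never counts —
no evidence is not evidence of no effect.

## Worked example

`examples/` holds one short script per capability. For instance:

```sh
$ python examples/04_curation_and_cooccurrence.py
curated kinase-domain missense mutations: 36
REVEL >= 0.4 (predicted damaging): 12/36
  e.g. L78Q, A125T, R137H, R137C, D138N, G167A ...
ULK1 vs PARTNER  : both mutated in 24/200 samples, odds ratio  35.77, one-sided p = 3.20e-15
ULK1 vs BYSTANDER: both mutated in  8/200 samples, odds ratio   2.61, one-sided p = 4.26e-02
```

The curated table yields 36 unique missense mutations inside the kinase
domain, a third of them REVEL-damaging; in the synthetic cohort the planted
co-occurring partner is detected (p ≈ 10⁻¹⁵) while the independent
bystander is not. And end to end:

```sh
$ python examples/05_full_pipeline.py
mutation  stability(0-2)  function(0-5)  category
D2N             1              1        both
K3M             0              0        neutral
A7V             0              1        function_only
```

D2N is destabilizing (ΔΔG 8 kcal/mol) *and* abolishes a PTM site, so it is
damaging on both axes; A7V only overlaps a motif; K3M trips no descriptor.

A thin CLI mirrors the common operations
(`mutassess psn|pca|curate|synth|run --help`).

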