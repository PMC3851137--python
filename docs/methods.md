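# Methods

## Model and assumptions

The package infers *anti-coexpression*: gene pairs whose expression
profiles are consistently negatively correlated.  The working hypothesis is
that a gene G and the genes anti-correlated with it sit in opposing (or
opposingly regulated) functional modules, so that inhibiting G releases its
anti-correlated cluster.  Three assumptions shape the design:

- **Rank-based edge calling.**  An edge is not a correlation threshold but
  a *mutual extremeness* requirement: p₁ must be in the most anti-correlated
  fraction f of p₂'s correlation column and vice versa.  This adapts to
  each probeset's correlation scale, but caps every node's degree at
  k = max(1, ⌊f·(N−1)⌋): a single network can only reveal ~k partners per
  probeset, however strong the signal.
- **Cross-species conservation as a noise filter.**  A reciprocal-rank edge
  in one species is often a sampling artefact; requiring the edge between
  one-to-one orthologs in a second, independently sampled species removes
  the bulk of these (in the synthetic worlds, ~700-edge single-species
  networks shrink to ~40 conserved edges).
- **Union over datasets.**  Because of the degree cap and noise, any single
  dataset pair recovers only part of a module.  Conserved networks from
  many dataset pairs (tissues/conditions) are merged by edge union; module
  recovery approaches completeness as pairs accumulate.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `fraction` | 0.01 | anti-correlation rank fraction f per column (unitless) |
| `min_samples` | 4 | minimum samples for a usable expression matrix |
| `min_overlap` | 4 | minimum pairwise-complete samples per correlation |
| `sim_threshold` | 0.4 | phenotype-similarity bound for pheno-clusters (closed: s ≥ 0.4) |
| `p_threshold` | 1e-4 | Fisher cut for drug–disease associations (primary filter; BH q reported) |
| `fdr` | 0.05 | BH level for perturbation direction tests |
| `n_permutations` | 100 | node-label permutation replicates for the index distribution |

Sidedness: enrichment and association tests are one-sided
(over-representation; the hypergeometric upper tail is what "enrichment"
means), while the perturbation test is deliberately two-sided — a drug
may move a cluster in either direction and the direction is read off the
medians afterwards.  The Fisher/overlap universe is the merged network's
gene set throughout: the merged network is the sampling frame from which
clusters are drawn, and using any larger universe would overstate overlaps.
The BH family for associations is every (target-centred cluster ×
pheno-cluster) pair actually tested; for perturbation it is every
(cluster × instance) test in the run, not per-drug families.  Bonferroni
correction in the centre-keyword concordance summary divides by the number
of sets tested for that cluster.

## Numerical choices

- Correlations use one BLAS pass on complete data and pairwise-complete
  samples otherwise; pairs with fewer than `min_overlap` shared samples are
  undefined (NaN) and ineligible for edges.  Zero-variance probesets are
  excluded before correlating and reported.
- Only strictly negative correlations can form anti-correlation edges, even
  when k would otherwise reach into non-negative values.
- Ties at the k-th most negative value break lexicographically by probeset
  ID, so edge sets are reproducible across runs and platforms.
- Mann–Whitney p-values are exact (null enumeration) when the smaller group
  has ≤ 8 members and there are no ties, and use the normal approximation
  with tie correction otherwise.  The cluster centre is excluded from both
  groups so its own response cannot drive the call; equal medians are
  reported as "tie" and counted in neither direction.
- Degenerate inputs are flagged rather than guessed at: clusters with no
  measured gene are "untestable", centres without phenotype annotations are
  "not applicable", a concordance summary with no significant cluster is
  returned empty and flagged.
- One master seed fans out to stage seeds through `SeedSequence`, keeping
  every derived seed below 2³¹; identical config + seed gives byte-identical
  outputs (file headers carry tool version, config hash and seed, never
  timestamps).

## What the synthetic worlds emulate

`anticoex.fixtures` generates the full input bundle with planted truth.
The expression model is latent-factor: each module m has one latent profile
z per (dataset pair, species); the centre follows +z, members follow ρ·z
(ρ < 0, default −1), background genes follow their own latent profile, and
every probeset adds independent Gaussian probe noise σ (default 0.2).
Defaults emulate the study conditions at desk scale: 300 genes per species,
~2.7 probesets per gene with ~10% of probesets unmapped (Plus-2-like
platform ratios), 40 samples per dataset, six dataset pairs merged into one
conserved network, three modules of ten genes.  Phenotype families are
aligned with modules (within-family similarity drawn ≥ 0.45, between-family
≤ 0.35, so the 0.4 bound separates them); planted drugs are "inhibitors" of
module centres whose perturbation instances redraw module probesets above
the 0.9 quantile before rank transformation; decoy drugs target background
genes and carry no signal.

The generator deliberately omits several features of real data: batch and
platform artefacts, correlated (biological) noise shared across a gene's
probesets, many-to-many orthology, annotation bias toward well-studied
genes, and phenotype similarity derived from text rather than drawn from
disjoint score bands.  Passing tests therefore show that the machinery
detects the structure it is designed for and controls its error rates under
clean nulls — not that real compendia contain that structure at these
strengths.

One consequence of the union-over-datasets design is worth stating
explicitly: with six dataset pairs, planted-module recovery is saturated
(≈100%) for probe noise σ up to ~1.0 and only collapses when noise swamps
the latent signal (σ ≈ 2); noise sweeps in the tests are therefore
non-increasing with ties rather than strictly decreasing in that range.

The enrichment-validation world is generated directly at gene level: a
random 8-regular graph in which every gene is a cluster centre of equal
size, with one neighbourhood-aligned annotation set per gene.  Regularity
matters — label permutation preserves the degree sequence, so real and
permuted index distributions are exchangeable under the misaligned null,
which is exactly what the false-positive check requires.

## Problem sizes

Synthetic worlds are sized so the full pipeline runs in seconds and the
whole validation suite in a few minutes on one CPU: 300-gene two-species
worlds (~900 probesets per species) for network construction and
repositioning, a 200-cluster world with 20 permutation replicates for the
KS machinery, 1000 random tables for the Fisher oracle comparison, and
20 × 100-test pure-null perturbation runs for false-positive control.

## Known limitations

- The degree cap k makes maximum recoverable cluster size scale with the
  probeset count and the number of merged datasets; sparse compendia
  under-recover large modules by construction.
- Annotation sets are used exactly as given (no ontology ancestor closure,
  no evidence-code filtering, no gene-length bias correction).
- Drug action labels are carried through but never filter associations; the
  direction validation is the only mechanism that distinguishes inhibition
  from activation.
- The probeset→gene map is taken as-is; conflicting annotation versions
  must be reconciled upstream.
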