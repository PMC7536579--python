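# Methods

## Scope and data model

`varstrat` stratifies *HNF1A* missense variants using replicate-level,
internal-control-normalized functional measurements. Tables are long/tidy
TSV — one measurement per row keyed by `(variant, lab, assay, replicate)` —
because replicate counts differ between variants and assays. Three
processing levels exist for such data (raw instrument reads, internal-
control-normalized, wild-type-normalized); only the internal-control-
normalized level is accepted for clustering: intra-assay measurements are
harmonized without imposing the wild-type-normalization assumptions, and it
is the level at which multivariate structure is most faithfully retained.
The other two levels can be read and inspected but are rejected by the
polishing step.

Protein HGVS names (`p.Glu508Lys`) are parsed into (ref, residue, alt) with
validation against the 20 standard three-letter codes; non-substitution
constructs (wild-type backgrounds, in-frame deletions) are carried as opaque
labels.

## Polishing

`drop_emsa → aggregate_replicates → position scores → standardize`.

- EMSA/DNA-binding variables are excluded from clustering because they are
  measured for only a subset of variants; `emsa_candidates` reports which
  variants warrant binding follow-up (DNA-binding-domain residue ≤ 287, or
  any transactivation value < 50% of wild-type) without ever feeding EMSA
  into the multivariate analysis.
- Replicates are aggregated by the arithmetic mean by default (median
  available); replicate counts are kept as metadata and never clustered.
- Two ordinal position scores encode established position–phenotype
  correlations. Isoform band (from exon): exons 1–6 → 3, exon 7 → 2, exons
  8–10 → 1; the latter appear only in hepatocyte-dominant isoforms, so
  variants there dilute the beta-cell phenotype. Domain band (from
  residue): 1–287 (dimerization/DNA-binding) → 2, 288–631
  (transactivation, more tolerant to variation) → 1. The numeric values
  are declared conventions — only their ordering (beta-cell-relevant
  positions weighted higher) is meaningful — and are config-overridable.
- Columns are zero-centered and scaled to unit sample variance (ddof = 1,
  matching conventional standardized PCA). Constant columns are rejected
  by name rather than silently producing NaNs.
- The package's residue→exon band map for the 631-aa protein
  (`EXON_LAST_RESIDUE`) is a convention used by the simulator and shipped
  tables; real analyses supply exon as an input column.

## Decomposition

PCA is the eigendecomposition of the sample covariance of the standardized
matrix (equivalent to correlation PCA; standardization lives in polishing
so the decomposition stays pure). Sign convention: each loading vector is
flipped so its largest-magnitude entry is positive, making output
deterministic across platforms. Component count is the smallest *m* whose
cumulative variance share exceeds the threshold (default 0.85). Ties in
eigenvalues are broken by original column order.

Per-component variable contributions are `100 × loading²` (each component
sums to 100). The "overall" contribution pools retained components with
variance-share weights: `Σ_m share_m·100·w_jm² / Σ_m share_m`. This pooled
form is one formalization of the usual qualitative reading of a
contribution chart; the per-component table is exposed alongside because
the pooled ranking between variables of similar communality is sensitive to
which residual directions fall inside the retained set — at panel sizes of
~40 variants, neighbouring variables' pooled contributions can differ by
less than their sampling error (see Limitations).

## Clustering

- k-means: scikit-learn's k-means++/Lloyd with `n_init = 25` restarts,
  best by within-cluster sum of squares, deterministic under the run seed;
  empty clusters are repaired internally by relocating the point farthest
  from its centroid.
- Optimal k: majority vote over five validity indices — silhouette
  (max), Calinski–Harabasz (max), Davies–Bouldin (min), gap statistic
  (uniform bounding-box references, B = 50 draws, one-standard-error rule),
  and Hartigan's rule (smallest k with H(k) = (W_k/W_{k+1} − 1)(n − k − 1)
  ≤ 10, else the k with the weakest evidence for a further split). Ties go
  to the smallest k among the modal set. The index set is pluggable; five
  auditable indices stand in for the large index batteries sometimes used
  for this vote.
- Hierarchical clustering: Ward's minimum-variance criterion in its D2
  form via SciPy (Lance–Williams on Euclidean distances, heights on the
  distance scale), computed on exactly the components retained by the >85%
  rule. Cutting a tree at k removes the k−1 highest merges (height ties
  resolved by merge order); cuts are nested in k.
- `compare_linkages` scores ward/complete/single/average by the Adjusted
  Rand Index of their cut partitions against the wild-type vs MODY-reference
  dichotomy, the criterion by which the Ward.D2 method earns its default
  role.

## Tanglegram and entanglement

Two dendrograms are first restricted to their shared leaves (unary nodes
collapsed, merge heights preserved). Entanglement between the two leaf
orders is `Σ_s |rank_a(s) − rank_b(s)|^L` normalized by the same sum for an
order against its own reversal — the anti-aligned worst case — giving a
coefficient in [0, 1]; L defaults to 1.5, the convention of the tanglegram
method family. Child order is presentation only: the untangling search
swaps children, never topology or heights, so the final coefficient never
exceeds the initial one.

For ≤ 10 shared leaves the search is exact: all 2^(n−1) rotation
configurations per tree are enumerated and the lowest-mask global minimizer
is applied. Beyond that a deterministic greedy search runs: alternating
one-sided post-order swap passes (A side first) accepting strict
improvements, with simultaneous pair swaps (one node per side) tried when
single swaps stall. The exact small-n path exists because one-sided greedy
search alone can stop at rotations more than 20% above the optimum; the
exhaustive minimum is also reported next to the greedy coefficient wherever
the leaf count permits.

## Zones and reclassification

Clusters map to continuum zones via reference membership: only wild-type →
BENIGN; only T2D-reference → INTERMEDIATE_T2D_RISK; only MODY-reference →
DAMAGING_MODY; conflicting roles → MIXED (never silently resolved);
reference-free clusters inherit the zone of the nearest annotated cluster
by centroid distance and are flagged as inherited.

Allele counts are banded with inclusive thresholds exactly as used on the
population-frequency axis for this gene: ≤ 2 (AF < 0.0008%) is compatible
with a rare MODY-causal allele, 3–121 (AF < 0.04%) matches low-frequency
T2D-predisposing alleles, > 121 is above that range.

The rule engine is a declared formalization of an expert curation process —
ordered, first-match, fully traced, every rule overridable:

- R1: class 4/5 call, benign/T2D-risk zone, count above the MODY band →
  propose 3 (BS1-style).
- R2: damaging zone but hepatocyte-dominant exon (8–10) and count above the
  MODY band → downgrade one tier toward benign (4/5 → 3, 3 → 2): impaired
  function in a liver-dominant isoform is unlikely to drive a strong
  beta-cell phenotype. The one-tier form makes the rule meaningful for
  VUS-level originals as well as pathogenic ones.
- R3: co-occurring pathogenic variant with a class 4/5 call → propose 3.
- R4: VUS in benign/T2D-risk zone, count above the MODY band → propose 2.
- R5: damaging zone, beta-cell-relevant exon (≤ 7), MODY-compatible count →
  retain/support the pathogenic call.
- default → retain.

MIXED or unannotated zones abstain (flagged unreviewed). No default rule
upgrades toward pathogenic; this monotone-downgrade safety is property-
tested over randomized inputs. Registry impact is reported as raw and
nearest-integer percentages of the registry total and of the functionally
characterized overlap.

The two shipped registry-overlap tables encode the documented UK (31
variants) and Norwegian (19 variants) re-assessments. Rows flagged
`source=narrative` carry documented attributes (zones, allele counts, exon
bands, co-occurrence); `source=partial`/`constructed` rows are synthetic
placeholders consistent with each variant's retained classification, since
their per-variant attributes were not published.

## Synthetic data generator

The generator emulates a two-laboratory design: each laboratory measures 40
exome-detected variants (7 shared) plus shared benchmark entries (2
wild-type backgrounds, 6 MODY-causal positive controls, 2 T2D risk
modifiers), 3 replicates per assay variable (replicate counts per variant
are not standardized in practice; 3 is the package convention).

Latent classes and default per-assay means (fraction of wild-type):

| class | TA (both) | PE | NUC_LOC | prevalence |
|---|---|---|---|---|
| WT_LIKE | 1.0 | 1.0 | 1.0 | 0.40 |
| INTERMEDIATE | 0.6 | 0.8 | 0.8 | 0.30 |
| DAMAGING | 0.3 | 0.7 | 0.5 | 0.30 |

Transactivation carries the widest separation (anchored to the 30%–110%
activity range such panels show); abundance and localization separate less,
consistent with panels in which most variants — including damaging ones —
retain adequate protein and nuclear entry. Noise is multiplicative
log-normal (assay readouts are ratios, strictly positive): per-replicate
sdlog 0.15 (luciferase-typical ~15% CV) and a per-(lab, assay) batch factor
with sdlog 0.10. Damaging variants draw their residue from the DNA-binding
domain with probability 0.75 (0.50 intermediate, 0.40 wild-type-like),
emulating the positional bias of MODY-causal variants that makes the
position scores informative. One root seed expands into independent
substreams (panel, references, registry) so each module is reproducible on
its own; truth labels are returned separately and never written into the
dataset payload.

What the generator does **not** emulate: assay-specific heteroscedasticity,
missing cells, batch drifts within a laboratory, bimodal within-class
behaviour (e.g. variants with discordant binding vs transactivation), or
correlation between allele frequency and assay noise. Passing recovery
tests therefore demonstrate that the machinery recovers planted structure
under realistic noise — not that real panels are this clean.

## Evaluation harnesses and problem sizes

Every numerical routine is checked against an independent oracle at small
n: Ward.D2 against a direct recomputation of merge costs over all cluster
pairs (100 random fixtures, n ≤ 8, exact merge order and heights); k-means
against the exhaustive set-partition optimum (n ≤ 7, k ≤ 3); PCA against an
explicit covariance eigensolve (1e-8); the rotation search against full
enumeration (n ≤ 8).

Class recovery runs the full polish → PCA → cluster chain per laboratory on
20 generator seeds at the default panel size (40 variants/lab). The
recovery harness clusters the assay signal (position scores excluded):
because the generator's position bands are only weakly class-correlated,
they are nuisance dimensions for recovery by construction, and no method
could recover the planted classes from them. In the full pipeline the
score columns stay in — there the discrete bands legitimately refine the
partition below the three-class level, which is why the pipeline's voted k
on the full matrix typically exceeds 3 while the continuum zones remain
well-formed.

## Limitations

- The pooled contribution ranking between variables of comparable
  communality (e.g. transactivation vs nuclear localization at the default
  separations) has a per-seed flip probability of a few percent at 40
  variants; margins below ~0.5 contribution points should not be
  over-read. The joint statement — the TA pair's combined contribution
  exceeding every other variable — is stable.
- The entanglement coefficient depends on the layout-search internals; two
  implementations agree only where the exact search applies. The package
  therefore reports the exhaustive optimum alongside its own coefficient
  whenever the shared-leaf count permits.
- The rule engine formalizes a documented curation outcome; it is not an
  ACMG/AMP engine and encodes no clinical free-text evidence.
- No imputation and no cross-laboratory batch correction are performed;
  laboratories are analyzed separately by design.
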