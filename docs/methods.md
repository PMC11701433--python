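# Methods

## Scope

`tlscape` quantifies the spatial immune contexture of tumor sections from
*segmented single-cell coordinate tables* — one row per cell, positions in
microns, binary (or thresholdable) marker readouts for a
CD4/CD8/CD20/CD21/CD23/DC-LAMP/GZMB/PD1/TCF1/TIM-3/FoxP3/CXCR5/CD68/CD163/
PanCK/CALR multiplex panel. It does not touch pixels: segmentation, stain
deconvolution and slide registration are upstream of this package. The core
analyses are (i) rule-based detection and maturity classification of
tertiary lymphoid structures (TLS), (ii) per-phenotype densities by tumor /
stroma compartment, (iii) tumor-contact profiles in concentric distance
bins, (iv) metagene signature scoring of a companion expression matrix, and
(v) median-cutoff survival stratification with Kaplan–Meier / log-rank /
univariate Cox statistics. A synthetic tissue-and-cohort generator with
known ground truth drives every test.

## TLS detection model

Cells are nodes of a *contact graph*: an undirected edge joins two cells
whose center-to-center distance is at most `contact_distance_um`. Candidate
aggregates are the connected components of this graph (computed with a
KD-tree plus sparse connected components; singletons are kept and reported
as rejected calls for auditability).

Each component is then filtered **in a fixed order**, recording the first
failed rule as its rejection reason:

1. **size** — at least `min_cells` members (default 51, i.e. strictly more
   than 50 cells);
2. **extent** — Feret diameter (maximum pairwise center distance) at least
   `min_extent_um` (default 250 μm, inclusive);
3. **B-cell majority** — CD20⁺ fraction strictly greater than
   `b_majority_fraction` (default 0.5);
4. **T-cell presence** — at least one CD4⁺ and one CD8⁺ member
   (individually switchable).

Survivors are classified by follicular-dendritic-cell (FDC) content. Under
the default `maturity_rule="follicle"`, an aggregate containing a
CD21⁺CD23⁺ cell carries a secondary follicle (`mTLS_secondary`); one with
CD21⁺ cells but no double positive carries a primary follicle
(`mTLS_primary`); with neither it is an early TLS (`eTLS`). The stricter
alternative `maturity_rule="strict_double_positive"` calls an aggregate
mature only when it holds at least one CD21⁺CD23⁺ cell — field definitions
of maturity differ on exactly this point, so both readings are first-class
and the choice is echoed in every run manifest. A CD23⁺CD21⁻ cell defines
no follicle under either rule and leaves an aggregate early.

### Parameter rationale

| parameter | default | units | why |
|---|---|---|---|
| `contact_distance_um` | 13.0 | μm | "close contact" read as a ≤3 μm membrane-to-membrane gap; with a nominal 5 μm cell radius per side this is 13 μm between centers. A 3 μm *center* distance is impossible for ~10 μm cells, so the center reading is rejected. Exposed as one tunable number. |
| `min_cells` | 51 | cells | strictly more than 50 cells; 50 is rejected, 51 eligible. |
| `min_extent_um` | 250.0 | μm | minimum aggregate size, implemented as the Feret diameter: rotation invariant, scale-like, cheap. Bounding-box or equivalent-circle diameters would be alternatives; Feret is the least orientation-sensitive. |
| `b_majority_fraction` | 0.5 | — | "majority of cells CD20⁺" as a strict inequality; exactly half fails. |

Extent uses the convex hull's vertices for components above 50 cells (the
Feret diameter is attained on the hull), with a dense-pairwise fallback for
collinear degenerate sets.

## Phenotyping

Phenotypes are conjunctions of required-positive / required-negative marker
flags and are **multilabel**: every TCF1⁺PD1⁺CD8⁺ cell is also a PD1⁺CD8⁺
cell and a CD8⁺ cell, and each population is counted independently in
density reports (the subset inclusions are asserted in tests). A single
`primary_label` (lowest priority number wins) exists for human-readable
summaries only. Cells positive for both TCF1 and TIM-3 stay in both exhausted
CD8 subsets — the populations are defined independently and a tie-break
would be invented biology. Gating of continuous intensities is inclusive
(value ≥ cutoff ⇒ positive) for deterministic boundary behavior. The CD8⁺
rule does not exclude CD4⁺CD8⁺ double positives; users who want exclusion
can supply a rule with `require_neg: [CD4]`.

## Densities and contact profiles

Densities are raw counts over areas in cells/mm². With region polygons the
tumor area is the union of tumor polygons; the stroma area is the union of
stroma/tissue polygons minus the tumor union (tumor nests sit inside
stroma, and tumor takes precedence for cells in overlapping regions); the
whole-section area is their sum. Without regions, the whole-section area
falls back to the convex hull of all cells — flagged in the output
(`area_source="hull"`) because hulls overestimate sparse-section area — and
compartment densities are unavailable. Point-on-boundary counts as inside a
region. No edge correction is applied near section borders; densities and
contact counts are raw, which is a deliberate limitation.

Contact profiles count (target, query) cell pairs per distance bin with the
half-open convention [lo, hi), final bin closed, so no pair is ever
double-counted; the default bins are [0, 10), [10, 20), [20, 30] μm around
PanCK⁺ tumor cells. Because it is ambiguous whether such a figure counts
pairs or query cells with ≥1 target in range, both are emitted: per-bin pair
counts and `close_fraction`, the fraction of query cells with at least one
target strictly closer than 10 μm (strict `<`, matching the printed
inequality; a pair at exactly 10.0 μm falls in the second bin and does not
count as close). A cell carrying both the target and query phenotype never
pairs with itself.

## Statistics

* **Two-group comparisons** — two-sided Mann–Whitney U (scipy backend):
  exact enumeration when both groups have fewer than 8 untied values,
  tie-corrected normal approximation otherwise. Two identical constant
  samples carry no evidence and return p = 1 (the tie-corrected variance is
  zero there, so the case is answered before the backend is called).
* **Count tables** — Fisher's exact test, conditional hypergeometric
  two-sided p; odds ratio ad/bc with 0 and ∞ for empty margins.
* **Survival** — median-cutoff stratification (ties to the High group,
  `value ≥ median`, sample median with midpoint convention for even n;
  all-identical values are an error rather than an arbitrary split),
  Kaplan–Meier product-limit curves (events precede censorings at tied
  times), the k-sample log-rank test, and univariate Cox proportional-hazards
  fits with Efron tie handling, Wald p-values and normal-approximation 95%
  CIs. Estimation is delegated to lifelines behind this module's interface;
  constant covariates and monotone partial likelihoods (perfect separation)
  are rejected with errors. Tests verify the curves against hand
  product-limit computations, the log-rank statistic against a hand O−E
  tabulation, and Cox against parameter recovery from the cohort generator.

## Signature scoring

A signature score is the mean over signature genes of the gene's z-score
across samples (sample standard deviation, ddof = 1): scale-free and the
common metagene default; no published scoring formula is claimed to be
reproduced. A one-gene signature score is exactly that gene's z-scored
value. Genes absent from the matrix are dropped and a coverage fraction
reported; constant gene rows are dropped with a warning. Built-ins: the
three-gene ER-stress set (DDIT3, HSPA5, HSP90B1) and the 12-gene
TLS chemokine set (CCL2, CCL3, CCL4, CCL5, CCL8, CCL18, CCL19, CCL21,
CXCL9, CXCL10, CXCL11, CXCL13); arbitrary YAML gene lists (e.g. B-cell
subtype programs) load the same way.

## The synthetic generator

`simulate_slide` composes three point processes on a rectangular field
(Cartesian microns, origin bottom-left, y up):

* homogeneous Poisson background with one intensity (cells/mm²) per
  phenotype;
* tumor nests: Poisson-filled discs of PanCK⁺ cells;
* planted aggregates: `n_cells` packed into a disc by a skeleton of
  jittered radial arms (consecutive points under the packing spacing apart,
  outermost point at the disc edge) plus sequential anchored fill with a
  minimum-separation rejection rule at 0.45 × spacing. The construction
  guarantees each planted aggregate is a single connected component at any
  contact distance ≥ the packing spacing *and* spans the disc diameter, so
  an aggregate intended to pass the extent rule actually does.

Aggregate composition is a fraction map over lymphoid phenotypes converted
to integer counts by largest remainder, with FDC counts forced consistent
with the requested maturity (early: none; mature-primary: ≥1 CD21⁺CD23⁻ and
no CD23⁺; mature-secondary: ≥1 CD21⁺CD23⁺). Marker noise is an independent
symmetric per-cell per-marker flip. Background and nest points within
`clear_margin_um` (default 15 μm) of a planted disc are thinned — planted
follicles displace surrounding tissue, and the margin keeps the planted
membership unambiguous so recovery can be scored exactly. Overlapping
planted discs are rejected at config time (the pair is named) for the same
reason.

`simulate_cohort` draws exponential event times with hazard
h = h₀·exp(Σ xβ) and independent exponential censoring;
`simulate_expression` draws two groups with signature genes shifted by a
known amount. Everything is a pure function of its config including the
seed; identical configs give byte-identical outputs.

**What the generator does not emulate:** real slides have inhomogeneous,
clustered background, irregular (non-disc) follicles with germinal-center
substructure, segmentation errors, intensity (not binary) marker readouts
with spatial autocorrelation, and survival with non-proportional hazards.
Passing the planted-recovery tests therefore demonstrates that the
*detector implements its rules exactly*, not that the rules themselves are
robust on real tissue; the flip-rate robustness curve probes the rules, not
the segmentation.

Default study conditions used by tests and by `scripts/acceptance.py`
(chosen once as plausible for a 1.4 mm field of view; the densities and TLS
size distribution of real sections are not published quantitatively):
lymphoid background totalling ≈ 340 cells/mm², one 160 μm tumor nest at
1200 cells/mm², planted aggregates of 120–260 cells in 135 μm discs at 8 μm
packing spacing with ~57% B cells, 20% CD4⁺, 14% CD8⁺, 4% T_FH and 2% FDC.
Problem sizes: spatial-oracle checks over 20 slides of ≤ 2000 cells;
planted recovery over 200 slides (tests) / 120 slides (acceptance script);
flip-rate curve at {0, 0.05, 0.10} over 50 × 2 aggregates; null calibration
over 2000 (tests) / 500 (script) simulated cohorts of 60–100 patients;
hazard-ratio recovery over 100 cohorts of n = 4000.

## Numerical choices

* Contact threshold, gating cutoffs and the extent rule are **inclusive**
  at the boundary; B-majority and `close_fraction` are **strict**. Each
  boundary is pinned by a unit test.
* Component and call ordering is deterministic (by smallest member index);
  writers sort keys and use full-precision floats, so read∘write is the
  identity and reruns are byte-identical (manifest wall-times aside).
* Degenerate inputs fail loudly: zero region area, collinear hulls,
  all-zero contingency tables, constant covariates, all-identical
  stratification values, no events in a log-rank.

## Known limitations

* No edge correction for cells near section borders.
* The hull fallback overestimates area on sparse sections (flagged).
* Maturity of an aggregate with CD23⁺CD21⁻ cells only is reported as early;
  such cells are biologically unusual and the definitions are silent.
* Wald CIs and p-values are first-order; for very small cohorts a
  likelihood-ratio test would behave better.
* The detector requires gated (binary) markers; thresholding choices made
  upstream dominate everything downstream.
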