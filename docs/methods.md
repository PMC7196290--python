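# Methods

## Single-cell qRT-PCR preprocessing

A Ct value is the PCR cycle at which a transcript's amplification signal
crosses threshold; lower Ct means higher expression, and a failed detection
(single-cell dropout) carries the instrument sentinel 999. The pipeline
order is fixed and enforced through stage tags on the matrix container
(`imputed_ct → delta_ct → relative_expr`, `imputed_ct → zscore`); applying
an operation at the wrong stage raises `StageError`.

* **Quality filter** (defaults quality ≥ 0.65, Ct ≤ 30): entries failing
  either bound are set to the sentinel. Quality scores follow the
  instrument convention that higher is better; the filter is monotone in
  the threshold (raising it can only drop more entries).
* **Imputation**: per gene, every sentinel becomes that gene's highest
  *detected* Ct + 1 — "just below the worst observed expression", which
  gives missing data a balanced weight instead of an extreme one. Genes
  undetected in **all** cells have no per-gene maximum; they fall back to
  the global detected maximum + 1 and are flagged and logged. "Observed" is
  interpreted per analyzed matrix, not across a whole study. Imputation is
  idempotent.
* **ΔCt / relative expression**: ΔCt(g, c) = Ct(g, c) − Ct(GAPDH, c);
  relative expression is 2^−ΔCt. Cells whose reference gene failed QC
  cannot be normalized and are excluded from EMT scoring (logged); a
  reference-free 2^−ΔCt would be meaningless.
* **Z-scores**: per gene across cells, sample SD (ddof = 1). Genes whose SD
  is at float-noise level relative to their own magnitude are treated as
  constant and mapped to z = 0 (flagged) to avoid catastrophic
  cancellation. Z-scores are computed on the imputed-Ct matrix (the
  clustering branch); only EMT scoring uses the ΔCt → 2^−ΔCt branch.
  Whether a study computes Z-scores jointly or per panel is analysis
  dependent; here they are always per analyzed matrix.

Stained events are classified by the immunofluorescence rule: CD45⁺ → WBC
(leukocyte, regardless of other stains); CK-or-EpCAM⁺ ∧ CD45⁻ ∧ DAPI⁺ →
CTC; anything else is excluded.

## EMT scoring

E-sum and M-sum are the per-cell sums of relative expression over the
epithelial panel (EpCAM, KRT7, KRT18, KRT19) and mesenchymal panel (VIM,
CD44); `m_score = 100·m_sum/(e_sum+m_sum)`, `e_score = 100 − m_score`.
The score is scale-invariant (multiplying all of a cell's markers by c > 0
changes nothing) and strictly increasing in any mesenchymal marker.
Undetected markers contribute their imputed tiny 2^−ΔCt value rather than
zero, keeping scores defined; a strict-zero mode is available by scoring a
matrix built without imputation through `EMTScorer` directly. Cells with
zero total signal are flagged undefined.

Labels: m_score below 40 → epithelial, above 60 → mesenchymal, inside the
closed band → hybrid. The band is a package choice — EMT is a continuum
and no consensus numeric cutoffs exist — picked so that the canonical
regimes (≈22% epithelial, ≈50% hybrid, ≈82% mesenchymal) label as their
qualitative descriptions; both edges are configurable. Group summaries are
mean ± sample SD (ddof = 1); single-cell groups report SD as undefined.

## Heterogeneity

Cells are observations. Hierarchical clustering uses Euclidean distance
with complete linkage by default (the common heatmap-tool default; both
configurable) via scipy; ties follow scipy's lowest-index convention so
trees are deterministic, and tests verify equivalence with a naive O(n³)
agglomeration through cophenetic distances. t-SNE (scikit-learn, PCA
initialization, mandatory seed) requires perplexity < (n−1)/3; default
perplexity 10 suits the typical 20–60 cells per analysis. Embeddings are
validated by separation properties (positive silhouette on well-separated
groups), never by coordinate reproduction. Spearman correlation between
cells is computed over gene vectors with two-sided p-values; Bonferroni
multiplies by the number of pairs within the computed matrix (matrices are
computed separately per cell source, so that is the test family).

## Kinetics

`normalize_count` scales a draw to 7.5 mL (a 3 mL draw × 2.5 — which is
why half-integer per-7.5 mL counts arise from integer raw counts).
ΔCTC(%) is the percent change from the day-0 baseline and is
volume-invariant. A zero baseline makes the ratio undefined: the series is
excluded with a logged warning rather than smoothed with a pseudo-count,
which would distort group means. Draws pair to the nearest assessment
within 45 days (scans typically occur every 2–3 treatment cycles), ties to
the earlier scan; unpaired draws are excluded from the group test. The PD
vs PR comparison is the classical pooled-variance Student's t (two-sided);
Welch is available by flag.

## Survival

Kaplan–Meier estimation and the log-log Greenwood median CI come from
lifelines; the median is the first time S(t) ≤ 0.5. The log-rank statistic
is the standard unweighted observed-minus-expected over hypergeometric
variance form (1 df); it is computed with an in-package vectorized
implementation because the cutoff grid and calibration simulations need
thousands of evaluations — tests pin it to lifelines and to a hand-written
closed form. Times are days internally; months divide by 30.44.

The cutoff search scans every distinct baseline count (strictly greater
than the cutoff → CTC-High), skipping cutoffs that leave either group
below 10% of the cohort, and returns the argmin-p cutoff plus the whole
grid. The returned p-value is *exploratory*: minimizing p over cutoffs
inflates significance, the result carries a note saying so, and a test
demonstrates the inflation (null false-positive rate well above 5%). No
correction is applied beyond the flag.

## Mutation concordance

A sample is concordant when CTC and tissue calls agree at every locus of
its row; the rate is over samples (rows), so longitudinal BT/AR pairs count
twice — with per-locus rates reported separately. Emergence requires an
early sample negative in both modalities and a late sample positive in
tissue and/or CTC, with the modality reported; stage labels (BT < AR), not
dates, order the samples. The bundled 15-sample fixture ships as packaged
CSV data.

## Synthetic cohorts

The generator states one world and keeps it:

* **Ct matrices**: each well's Ct is the reference level (20 cycles) plus
  the group's ΔCt signature plus independent N(0, ct_noise_sd = 0.5)
  noise. Default signatures are block-structured: each of 4 groups
  expresses its own round-robin slice of the panel at ΔCt 6 vs 10
  elsewhere (4-cycle separation); the WBC group expresses only the
  leukocyte marker (PTPRC ΔCt 4) with near-zero epithelial expression
  (ΔCt 16). Dropout is a linear-in-Ct hazard,
  clip(base + slope·(Ct − min Ct), 0, 1) — the simplest monotone model for
  the fact that weakly expressed genes drop out more — with defaults
  base 0.05, slope 0.01/cycle; 5% of quality scores fall below 0.65.
* **Trajectories**: 41 patients split 17 PD / 24 PR (the reported
  observation counts); per-draw effects +70.1% (PD) and −43.1% (PR) with
  N(0, 35) percent noise, realized as Poisson counts from a fixed 23-cell
  3 mL baseline (57.5 per 7.5 mL). With noise 0 the exact expected counts
  are returned (so arm means equal the configured effects exactly); the
  Poisson floor at −100% introduces a small (<1 point) upward bias in the
  PR arm, within the Monte-Carlo tolerance tests use.
* **Survival**: Weibull times (shape 1.3, scale 700 days — medians in the
  13–19-month regime of such cohorts), censoring probability 0.5 with the
  censoring time uniform on (0, T); baseline counts log-normal with median
  37/7.5 mL and log-SD 0.7 (placing ≈20% of patients above a 66 cutoff).
  An optional hazard ratio scales the high-count arm by HR^(−1/shape).
* **Mutations**: tissue calls (activating locus always +, T790M + at rate
  0.15) are copied to CTC calls and each locus flips independently with
  probability 1 − target^(1/L), making the expected all-loci sample
  concordance exactly the target. Optional BT/AR pairs insert a concordant
  T790M − → + emergence.

One global seed fans out through fixed `SeedSequence` spawn keys, one
stream per generator, so adding a generator call never perturbs another.

What the generator does **not** emulate: real per-gene Ct distributions
(unpublished), amplification efficiency and plate batch effects, correlated
dropout, informative censoring, RECIST category dynamics beyond a constant
arm label, and allele fractions. A green recovery test therefore
establishes that the estimators invert the stated generative model, not
that they reproduce any particular patient dataset; the patient-level
numbers quoted in the README's scientific context (specific M-scores,
medians, the printed p = 0.011) depend on unpublished raw data and are not
reproduced, only their formulas and regimes are.

## Numerical choices

* Sample SD (ddof = 1) everywhere a spread is reported.
* Zero-variance (relative tolerance 1e−8 of the gene's magnitude) → z = 0.
* Strict ">" defines CTC-High, so boundary counts go Low.
* ΔCTC and concordance are reported in percent; survival months = days /
  30.44.
* All stochastic steps (t-SNE, generators) take explicit seeds;
  per-generator streams use fixed spawn keys.
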