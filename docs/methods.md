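# Methods

## Scope and data model

`sigscreen` analyzes targeted-transcriptomic compound screens: wells ×
probes integer count matrices from multiwell plates, a per-well layout
(plate, well, genotype WT/KO, treatment, compound, imaged cell count) and a
probe panel (gene symbol, pathway category, housekeeping flag, at most one
`target` probe for the knocked-out gene). All tables are tab-delimited
text; raw and normalized matrices are distinct file schemas (the normalized
file carries a `normalized=true` flag) so a matrix can never be normalized
twice by accident.

## Quality control

Two well filters and one probe filter, with strict inequalities:

* **Cell count**: a well is removed if its cell count is below
  `cell_frac` (default 0.40) times the mean cell count of the *untreated*
  wells of the **same plate**, both genotypes pooled. Per-plate
  referencing was chosen because staining and imaging conditions vary by
  plate; the reference population is a configuration choice, not a claim
  about any particular dataset.
* **Total reads**: removed if row sum < `min_total_reads` (default
  100,000).
* **Probe plate total**: after well filtering, a probe whose read total
  over retained wells is < `min_probe_plate_total` (default 2,000) on
  *any* plate is dropped from the combined analysis, keeping the
  cross-plate matrix rectangular. A housekeeping probe failing this filter
  changes the normalization denominator, so it additionally raises a
  warning naming the probe.

Order is fixed (wells, then probes): removing a well cannot change another
well's read total, but it does change probe plate totals. Every removal is
recorded with the measured value and the violated threshold; the report
also counts compounds whose wells were all removed.

## Normalization

value(w, g) = count(w, g) / Σ_h count(w, h) over housekeeping probes h.
No further scale factor is applied — any common constant cancels in the
per-gene z-scoring before distance computation — and no cross-plate batch
correction is performed; plate-wise control wells remain available for
diagnostics. Wells with zero housekeeping counts are removed and reported.

## Signature derivation

Per gene, fold change is the ratio of KO to WT control means of normalized
values. The test is **Welch's two-sample t-test on log2(x + ε)** with
ε = half the smallest positive normalized value in the matrix (a
scale-free guard against log 0). The selection rule is FC > `fc_thresh`
or FC < 1/`fc_thresh` (default 1.5, i.e. 0.667) and raw p < `p_thresh`
(default 0.05); no multiple-testing correction is applied, matching the
screening-stage convention of a raw p cut. The choice of Welch's test on
the log scale is a genuine design decision — the selection rule itself does
not name a test — and is recorded here prominently because it affects which
borderline genes enter the signature. The target-gene probe passes by
construction (it is knocked out) and is force-excluded from the signature
used for scoring; it appears in the per-gene table for audit.

**Control-outlier removal.** Control wells are clustered on per-gene
z-scored signature values (sample sd, n−1 denominator — the convention used
everywhere in this package) with Ward linkage and Euclidean distance, cut
at k = 2. A control well whose genotype is the strict minority of its
cluster is flagged; flagged wells are removed and the signature recomputed
**once** (no iteration — repeated reclustering on screen-sized control sets
tends to chase noise). Genotype ties flag nobody; degenerate identical
rows yield a warning and no flags.

## Scoring and hit calling

Signature genes are standardized to mean 0, sample sd 1. The constants
are fitted by default over **all retained wells** (controls and treated
together), so a gene's spread across the whole screen defines its unit;
fitting over controls only is available as a switch (`fit="controls"`),
and a `zscore=False` switch scores on normalized values directly for
sensitivity analysis. A zero-variance signature gene is a hard error.

The score of well w is the Euclidean distance d(w) = √Σᵢ(qᵢ(w) − pᵢ)²
from its standardized profile q to the WT centroid p (per-gene mean over
WT untreated controls, outliers removed). With d_ref the KO-to-WT centroid
distance, `is_hit ⇔ d < d_ref` (strict), and `relative_score = d − d_ref`
places untreated KO at 0. Ranks ascend with d; exact ties (measure-zero in
practice) break lexicographically by compound id so output is
deterministic. KO wells enter d_ref only through their centroid; per-well
control distances are reported separately for diagnostics.

## Synthetic screen generator

The generator emulates the statistical structure the analysis assumes, not
the assay chemistry (no probes, barcodes or reads are simulated, and no
imaging). Each probe g has an expected per-read weight w_g; WT weights sum
to 1, with housekeeping probes drawn high (log2 weight ~ N(3, 0.5) vs
N(0, 1)) so their sum is a stable denominator. Defaults mirror the
targeted screen layout: 4 × 384-well plates, 1,120 compounds (one well
each), 42 probes with 6 housekeeping and one target probe, 16 WT + 16 KO
untreated controls per plate, 11 programmed signature genes shifted by
±1 log2 unit, library size lognormal with mean 300,000 reads and CV 0.2,
negative-binomial dispersion 0.05 (var = μ + 0.05 μ²; dispersion 0
degenerates to Poisson), 5% rescuer compounds with rescue fraction
ρ ~ U(0.7, 1.0), 5% toxic and 2% low-read compounds. Where the emulated
design does not pin a value (control-well count per plate, library-size
scale, dropout rates), the defaults are ordinary values for a 384-well
transcriptomic screen and are configuration, not claims.

Three constructions deserve explanation:

* **Compositional closure.** Shifting some genes' share of a fixed read
  budget must come from somewhere: KO weights are renormalized to sum to 1
  by rescaling only the "filler" probes (non-housekeeping, non-signature,
  non-target), keeping housekeeping weights genotype-identical and
  signature shifts exact. Shift directions are assigned by greedy weight
  balancing so the closure factor stays near 1 (|log2| < 0.2 at the
  defaults) and filler genes remain non-differential, as the truth table
  asserts.
* **Rescue.** A compound with rescue fraction ρ moves every non-target
  probe of its KO well toward WT in log space:
  log2 w = log2 w_KO + ρ(log2 w_WT − log2 w_KO), so ρ = 1 reproduces the
  WT expectations exactly — a clean recovery oracle. The target probe
  stays silent (expected count ≈ 0, a 2⁻¹² knockdown) in every KO-derived
  well regardless of ρ: the simulated compounds are transcriptional
  mimetics, not target-gene inducers, which lets tests verify the target
  probe is genuinely excluded from scoring.
* **Noiseless mode.** `noiseless=True` emits rounded expected counts.
  This exists because limit-case contracts ("full rescue scores exactly
  0") are unreachable under any sampling noise, including the Poisson
  floor.

Toxic compounds draw cell counts ~ U(0.05, 0.35) of the untreated mean
(safely below the 40% filter given untreated counts ~ N(1, 0.1)); low-read
compounds draw library sizes ~ U(10,000, 80,000), below the 100,000-read
filter. All randomness flows from one seed in a documented draw order, so
identical configurations are byte-identical.

**What passing on synthetic data does not show.** The generator has
genotype-homogeneous expectations, independent wells, no plate gradients or
edge effects, no batch structure beyond library size, and NB noise with a
single shared dispersion. Recovery results therefore validate the
pipeline's logic and implementation, not its robustness to spatial plate
artifacts or dispersion misspecification in real screens.

## Recovery benchmarks and problem sizes

`sigscreen.benchmark` runs two multi-seed experiments, also used by
`scripts/acceptance.py`:

* **Signature recovery** — one plate with 16 controls per genotype,
  ±1 log2 programmed shifts, dispersion 0.05; sensitivity and specificity
  of selection against the generator truth, averaged over 50 seeds.
* **Hit recovery** — the full default screen (1,120 compounds, 5%
  rescuers with ρ ∈ [0.7, 1.0]); AUC of the distance ranking against
  rescuer truth, averaged over 50 seeds, plus screen-level summaries.

Fifty seeds of the full pipeline complete in under a minute on one CPU;
these sizes were chosen so the whole benchmark stays interactive while
keeping Monte-Carlo error on the averaged metrics below a percent.

## Numerical conventions and edge cases

* Sample standard deviation (n−1) everywhere; a "constant" column is
  detected at sd ≤ 1e−12·max(1, |mean|) since floating-point mean
  subtraction leaves rounding-level residues.
* fc with a zero WT mean is reported as an ∞ sentinel and excluded from
  selection; Welch p on two zero-variance groups with equal means is
  treated as 1.
* Writers emit floats at 6 significant digits with stable row and column
  order; identical inputs give byte-identical files.
* Well IDs follow 24-column plate convention ("A01"…"P24"), which sorts
  lexicographically.

## Known limitations

* The hit rule d < d_ref calls ~30% of inert compounds at realistic noise
  (an inert KO well sits at distance ≈ d_ref on average, and noise is
  symmetric), so the hit list is a screening funnel, not a significance
  statement; ranking quality (AUC ≈ 1 at the default conditions) is the
  meaningful recovery metric.
* Outlier detection with Ward k = 2 assumes the controls split primarily
  by genotype; with few controls and strong noise it can occasionally flag
  a genuine borderline well alongside a planted outlier.
* No batch/plate correction beyond housekeeping normalization is
  implemented, by design; screens with strong plate effects need upstream
  correction.
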