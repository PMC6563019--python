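# Methods

`glycoms` re-creates, as an open and testable pipeline, the data-analysis
chain used in untargeted serum glycopeptide profiling for two-class
discrimination (e.g. ovarian-cancer vs benign-gynecologic-disease sera):
centroided LC-MS runs are reduced to chromatographic peaks, aligned into a
feature table, normalized against pooled-QC injections, filtered down to a
reliable feature panel, and modelled with OPLS-DA under Q2
cross-validation, with volcano and heat-map statistics for per-feature
interpretation.  Because no raw study data of this kind are publicly
deposited, the package ships a synthetic-cohort generator with complete
ground truth; every stage is validated against that truth or against
independent numerical oracles.

## Peak extraction

Each run's ions are partitioned into extracted ion chromatograms (EICs) by
1-D m/z clustering: ions sorted by m/z are split wherever consecutive ions
are more than 0.02 Da apart, each trace living on the run's scan grid with
zero fill and carrying the intensity-weighted mean m/z of its members.  We
deliberately use gap clustering rather than fixed-width 0.02 Da bins: a
fixed bin boundary falling inside an ion cloud (which run-level m/z drift
makes routine) splits one feature into two half-intensity traces, and that
single artifact is enough to break one-feature-one-cluster recovery.  Gap
clustering assigns every ion to exactly one trace and only merges species
closer than 0.02 Da — which the later 0.06 Da alignment tolerance could
not separate anyway.

Traces are smoothed with a Savitzky-Golay filter (window 7, polynomial
order 2; both exposed in `PeakParams`).  Peak bounds follow the derivative
sign-change rule: a peak starts where the derivative crosses from zero to
positive, tops where it crosses from positive to negative and ends where
it returns from negative to zero.  Because a sampled derivative is never
exactly zero, "zero" means |d| below 1e-3 of the trace's maximum |d|
(`zero_eps`); the apex is refined to the intensity maximum inside the
span; a valley (negative-to-positive crossing) closes one peak and opens
the next; incomplete triples are discarded.  The area is the trapezoidal
integral of the smoothed trace from start to end.  On a noiseless sampled
Gaussian (0.01 min grid) this recovers the apex to the grid step and the
area to well under 1% of fine-grid quadrature.

S/N is not standardized in vendor software, so the package defines it
robustly: peak height divided by 1.4826 x MAD of the raw-minus-smoothed
residual over scans with nonzero raw signal.  A zero residual (noiseless
data) gives S/N = infinity, which the S/N filter treats as "retained".

## Drift correction and alignment

Five internal-standard anchors (fetuin-like spiked peptides, fixed RT/m/z,
present in every run including blanks) are matched per run and an affine
model (offset + slope) is least-squares fitted separately for RT and m/z;
at least two matches are required, and a degenerate spread falls back to a
pure offset.  Correction moves coordinates only — areas, heights and S/N
are untouched.

Alignment pools all runs' corrected peaks, sorts them canonically
(descending height, then RT, m/z, run id) and greedily grows clusters: a
peak joins the nearest cluster whose centroid is within 0.3 min and
0.06 Da and whose slot for that run is free, else it seeds a new cluster.
The canonical ordering makes the result independent of run order; the
one-peak-per-run rule keeps features well defined.  Cells with no
contributing peak stay missing (NaN) in the stored table and are imputed
as half the feature's minimum observed value only at the modelling stage.

## QC normalization and CVs

Pooled-QC injections (one pool per study arm) interleave the sequence
every ten study samples.  Every area is divided by the feature's mean QC
area, so QC columns have per-feature mean 1 by construction and study
values are unitless ratios; features with a zero or undefined QC mean are
flagged and removed rather than divided.  Inter-assay CV is the percent CV
over all of a pool's QC injections and intra-assay CV the mean of
within-batch CVs; the reported per-feature value takes the maximum over
pools — the conservative reading when a feature must be precise in every
pool.  Whether normalization uses all QCs or batch-local QCs is
configurable (`qc_scope`); the default is all.

## Filter cascade

Four stages in fixed order, with a `FilterReport` that enforces the
accounting identity (stage outputs chain; removals plus survivors equal
the input):

1. **blank**: remove features whose study mean (missing cells counted as
   zero) is below 5x the blank mean.  The 5x ratio is a common untargeted
   default and is configurable.
2. **cv**: remove features with QC CV strictly above 50% ("more than");
   undefined CVs are removed conservatively.
3. **sn**: remove features with representative S/N strictly below 100
   ("less than"); the representative value is the median over contributing
   peaks (per-feature rather than per-peak, configurable in effect through
   the supplied series).
4. **satellite**: remove isotopologues (a more intense co-eluting feature
   exactly one 13C spacing of 1.0033/z below, z in {1, 2}, within 0.01 Da
   and 0.1 min), negative-mode adducts (formate +46.0055, Na-H +21.9819,
   Cl +34.9689 below a more intense co-eluter) and in-source fragments (a
   co-eluting feature with higher m/z and higher intensity whose
   across-sample profile correlates at Pearson r >= 0.95).  The satellite
   tolerances are deliberately tighter than the alignment tolerances so
   true co-eluting features are not deleted.

The cascade order is itself part of the contract: re-ordering stages can
change the outcome (e.g. a satellite whose parent was already removed by
the CV stage survives the satellite stage), and the report records the
order actually applied.

## Discriminant modelling

Feature matrices are unit-variance scaled and mean-centered with
training-set parameters; zero-variance features are dropped with a
warning.  PCA (plain SVD of the scaled matrix, deterministic sign
convention) provides the unsupervised overview that guards against
OPLS-DA over-separation.

OPLS-DA splits X-variation into one predictive component aligned with the
two-class response and `n_ortho` orthogonal components.  Each orthogonal
component is extracted by computing the PLS weight w (proportional to
X'y), its loading p, removing the predictive direction
w_o = p − (w'p/w'w) w, and deflating X by t_o p_o'; the construction makes
every orthogonal score exactly orthogonal to y and to the final predictive
score.  R2Y is the fraction of response variance explained, R2X the
fraction of X sum of squares captured by all components, and
Q2 = 1 − PRESS/TSS comes from 7-fold class-stratified cross-validation
(round-robin assignment after a seeded within-class shuffle; each fold's
model, including its scaling, is fit on the remaining folds).  Seven folds
follow chemometrics convention; `n_ortho` defaults to 1 and can be chosen
by maximizing Q2 over 0..3.  The response is encoded {0, 1} and centered;
class calls threshold the prediction at 0.5.  Q2 > 0.5 is treated as the
reliability bar.  The test suite also surfaces the method's known failure
mode: with permuted labels the fitted R2Y stays high while Q2 centers at
or below zero — separation on the scores plot alone is not evidence.

Train/test splits are class-stratified with per-class training size
round(0.8 x class size); explicit per-class counts can be pinned when a
protocol's printed counts follow different rounding.  Score plots carry a
Hotelling T2 confidence ellipse: critical value
2(n−1)/(n−2) F_{2,n−2}(1−alpha) on the two plotted score columns, which
approaches the chi-square limit (semi-axis 2.448 per unit sd at 95%) for
large n.

## Differential statistics

Per feature, the volcano table holds the case/control ratio of group means
and a Welch (unequal-variance) two-sample t-test p-value — Welch rather
than Student because group variances are not assumed equal; Student is a
switch.  A feature is significant when p < 0.05 and the fold change is
< 0.7 or > 1.5; no multiple-testing correction gates this call, matching
the raw-p convention of this kind of screening analysis, but a
Benjamini-Hochberg FDR column is emitted for information.  The top-n
selection (default 300) takes the smallest p-values, ties broken by larger
|log2 fold| then feature id.  Heat-map matrices divide every sample's
level by the feature's control-group mean and bin the ratio on a
log10-uniform scale: 9 bins spanning [0.1, 10] plus two overflow bins
(< 0.1, > 10), so ratio 1 falls in the central bin and the edges are
symmetric in log10.

## The synthetic cohort

The generator emulates the study design the pipeline targets: 39 cancer
and 45 control sera in randomized injection order, a pooled-QC injection
after every 10 study samples (pools alternate between a cancer pool and a
benign pool, each the mean of ten randomly chosen study samples of that
arm, re-measured with fresh noise so QC CV reflects assay noise only),
and 3 leading blank injections carrying only background features and the
internal standards.  Features are Gaussian in RT (sd 0.05 min, analytic
area available for oracle tests) on a 1–14 min gradient with masses in
1000–3000 Da, single charge by default.  Per-sample true levels combine a
lognormal feature base area (median 1e5 counts.min, log10 sd 0.6), a
planted log2 fold change on a configurable fraction of features (default
10% at mean |log2FC| 1, random sign), and biological variation (log-sd
0.3, i.e. ~30% CV).  Measurement adds a per-injection scale factor
(log-sd 0.1), multiplicative noise (log-sd 0.1, ~10% CV — the QC CV
scale), run-level RT/m/z drift (sd 0.05 min / 0.005 Da, kept inside half
the alignment tolerances so ground-truth matching stays well defined),
per-peak RT jitter (0.01 min), per-ion m/z jitter (0.002 Da) and additive
detector noise (sd 30 counts per scan).

Satellite ions deserve a modelling note: an isotopologue, adduct or
in-source fragment is formed from the parent's ion population, so its
measured area is a fixed fraction of the parent's *measured* area in the
same injection, with only a small (~3%) independent integration error —
not an independent re-draw of the full measurement noise.  This is what
makes the cross-sample correlation rule for fragments effective in real
data, and the generator reproduces it.

What the generator does **not** emulate: profile-mode spectra,
chromatographic tailing or fronting, real glycan mass ladders and their
isotope envelope shapes, charge-state envelopes (multiple charges exist
behind `charge_states` but default to z = 1), ion suppression, or
missingness that correlates with class.  Passing tests therefore
demonstrate that the pipeline's logic is correct under its stated model of
the data, not that any specific clinical separation would replicate; the
published headline metrics of the motivating study (feature counts and
R2/Q2 values) were computed on undeposited patient data and are
deliberately not targets.

## Problem sizes and numerical choices

Raw-run simulations default to 300 monoisotopic features (plus
satellites, background features and standards), which keeps a full
95-injection simulate-to-model run around a minute; table-level
simulations use the full 2281-feature panel size.  All randomness flows
from a single master seed; identical configurations reproduce
byte-identical artifacts.  Degenerate inputs have defined behavior
throughout: zero-variance features are dropped before scaling,
zero-mean denominators flag rather than divide, noiseless traces yield
infinite S/N, incomplete derivative triples yield no peak, and ties in
ranking are broken deterministically (by magnitude, then id).
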