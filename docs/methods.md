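# Methods

## Residue charge model

Side-chain charges at physiological pH (7.4) use a fixed integer/half-integer
scheme: D/E −1, K/R +1, H +0.5, phosphorylated S/T/Y −2 (the charge of a
phosphomonoester dianion), everything else 0. Ambiguity codes (B, Z, X, U, O)
are treated as neutral; stop (`*`) and gap characters are rejected. Terminal
amine/carboxyl charges are deliberately ignored — the model scores side chains
only, so NCPR is a pure composition statistic and the phosphorylation identity
NCPR(k sites) = NCPR(0) − 2k/L holds exactly.

Local charge density is the arithmetic mean of the charges in a sliding
window (default 21 residues, odd by construction). Only full windows are
emitted — no edge padding — enumerated starting at the C-terminus and sliding
toward the N-terminus, each value reported at its 1-based window-center
coordinate. Sequences shorter than the window yield an empty density track
with a warning flag; their NCPR is still valid.

Phosphorylation states: `hypo` (no sites), `observed` (a supplied site list,
e.g. from middle-down MS), `hyper` (all S/T/Y). An optional 1-based inclusive
region restricts the effective sites, because "full phosphorylation" is often
meaningful only within an RS-like domain; whether sites outside such a domain
should count is experiment-specific, so the region is an explicit parameter
rather than a fixed convention.

### Proteome stratification

The S-graph ranks proteins by NCPR (ascending, ties broken by accession) and
labels the extremes beyond mean ± 2 SD. The sample (n−1) standard deviation is
used, the conventional estimator for an observed proteome sample. Strict
inequalities define the low/high groups (a value exactly at a threshold is
"mid"). The default state for the ranking is unmodified (`hypo`): the
stratification characterizes bare sequences before any PTM consideration.
The summary is computed after the minimum-length filter (default 1; use 100
to mimic whole-proteome surveys that exclude very short entries), since the
thresholds should describe the population actually ranked. For reference,
mean NCPR 0.0076 with SD 0.0457 places the cut-points at −0.0838 / +0.0990.

## Label-free quant preprocessing

Input is a MaxQuant-proteinGroups-like TSV: an id column, `LFQ intensity
<sample>` columns matched to the sample design, a razor+unique peptide count
(configurable — some searches report only total peptides), and `+`-flagged
`Reverse` / `Potential contaminant` / `Only identified by site` columns.
Zero intensities are missing (the MaxQuant convention); negative intensities
are a hard error.

Filters run in order, each with an audited removal count:

1. flagged rows (reverse, contaminant, site-only);
2. rows missing in more than `max_missing_fraction` (default 0.5) of **all**
   design samples — with 16 samples, a protein observed in exactly 8 is
   retained;
3. rows with fewer than `min_peptides` (default 2) peptides.

After log2 transform, missing values are imputed per sample column by draws
from N(mean − 1.8·SD, (0.3·SD)²), where mean and SD are the observed moments
of that column, frozen before any imputation (no leakage between columns).
This is the standard left-censored ("MNAR") treatment: undetected proteins
are assumed to sit below the detection limit, so imputations land in the
lower tail of the column's intensity distribution. Each column draws from its
own deterministic substream derived from the root seed and a hash of the
column name, so results are bit-reproducible and independent of column order.

The pipeline imputes before computing the solubility statistic (switch
`impute_before_solubility`); the alternative — computing fraction
insolubility only from observed pairs — is available because the choice is
methodologically open, but imputing first keeps the paired design complete.

## Fraction insolubility and the paired statistic

On the linear scale (de-logged after imputation), FI = pellet/(pellet +
soluble) within each matched (condition, replicate) pair. FI is clamped to
[ε, 1−ε] (ε = 10⁻⁶) before logs so degenerate fractions give large finite
deltas rather than infinities. The per-replicate statistic is

    Δ_r = log2 FI[treated, r] − log2 FI[mock, r]

paired within biological replicate. The per-protein test is the two-tailed
one-sample t of the Δ_r against zero (df = R − 1), algebraically identical to
the paired two-sample t on the condition vectors. Classification requires
both |mean Δ| ≥ log2(2) = 1 and raw p < 0.05; Benjamini–Hochberg q values are
reported alongside but do not gate the class, matching the thresholding
convention of volcano-style solubility screens. Zero-variance delta vectors
are flagged degenerate with p = NaN (an exact p of 0 would be dishonest);
they may optionally be classified by the threshold rule alone.

Charge-group comparisons use Welch (unequal-variance) two-sided t tests over
all group pairs — the robust default when only "unpaired t test" is
specified — with the usual star tiers. Group means average per-protein mean
deltas by default; pooling all per-replicate deltas is available as an
option since either convention appears in practice.

## Enrichment

The "one-dimensional" Fisher's exact test is the upper-tail hypergeometric
probability P(X ≥ k) for overlap k between a hit list (n of N) and a
candidate set (K of N), candidate intersected with the universe first. Odds
ratios come from the 2×2 table with Haldane 0.5 correction when a cell is
empty. BH correction is applied per analysis family: across modules for
module-hit enrichment, and across however many candidate sets one call
tests. Homolog candidate lists are inputs (one id per line, or id/set-name
pairs); sequence searching is out of scope.

## Network modules

Signed adjacency a_ij = ((1 + cor(x_i, x_j))/2)^β with Pearson correlation
and β = 20; anticorrelated pairs get essentially zero edge weight. The
topological overlap matrix is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with connectivity k_i = Σ_{u≠i} a_iu. Proteins are clustered by average
linkage on 1 − TOM and cut statically at a configurable height (default
0.995); clusters below the minimum size (default 15) stay unassigned
(label 0, "grey"), and surviving modules are labelled M1, M2, … by
decreasing size.

This stage is an intentionally simplified variant of WGCNA's
`blockwiseModules`: dynamic hybrid tree cutting, deep splitting, medoid
partitioning and significance-based reassignment are not reproduced. The
simplification makes the stage fully deterministic and testable, at the cost
of fidelity — module counts on real data will differ from a WGCNA run, and
on strongly globally-correlated data (e.g. the default synthetic fixture,
where the fraction split drives most covariance) the static cut can yield a
single large module. This is a documented fidelity gap, not a target.

Eigenproteins are the first principal component of the member × sample
matrix after per-protein standardization (z-score, ddof 1), unit-normed over
samples, sign-oriented so the mean member correlation is positive (ties
toward a positive first-sample loading). kME is every protein's Pearson
correlation with every eigenprotein; module hubs are the top own-kME
members. Modules whose eigenproteins satisfy 1 − cor < merge height
(default 0.07) are merged iteratively — closest pair first, eigenproteins
recomputed after each merge — to a fixpoint, then relabelled by size.

## Synthetic-data generator

The generator emulates the downstream structure of a solubility
fractionation LFQ study with a dephosphorylation perturbation. Defaults are
the study conditions exercised by the test suite and acceptance script:

| parameter | default | rationale |
|---|---|---|
| classes (rs_like / acidic / background) | 50 / 50 / 400 | extremes are rare against a typical background |
| sequence length | uniform 150–450 | typical protein-length window |
| rs_like composition | R 27%, S 25%, Y 7.5%, K 5%, acidics 2% | RS-dipeptide-rich, expected NCPR ≈ +0.30 |
| acidic composition | D 17%, E 17%, basics 4% | expected NCPR ≈ −0.30 |
| background composition | typical proteome frequencies | expected NCPR ≈ 0 |
| true log2 FI shift | +2 / −0.5 / 0 | strong planted insolubility gain for RS-like; mild solubilization for acidic; null background |
| baseline FI | log-uniform: 0.10–0.22 / 0.20–0.50 / 0.03–0.60 | FI is a scale quantity; RS-like anchored to densitometry of phosphorylated SR protein (~0.3 insoluble in mock) and bounded so FI × 2² < 1 |
| replicates | 4 | biological quadruplicate design |
| base abundance | log2 ~ N(26, 1.5), replicate SD 0.25 | LFQ-like intensity range |
| measurement noise | CV 0.2, mean-one lognormal per measurement | moderate LFQ noise |
| detection | logistic in log2 intensity, midpoint 21.5, slope 0.15 | sharp detection limit; overall missingness ≈ 10%, dropout consistent across replicates |
| decoys | 5 reverse + 5 contaminant rows | exercises the flag filter |

Phosphosites are assigned per class occupancy (each S/T/Y independently;
defaults 0.5 / 0.1 / 0.1). The class shift is assigned by class, **not** as a
function of NCPR, so the charge–insolubility association is a recoverable
statistical signal rather than a built-in identity. Dropout applies after
measurement noise, at the intensity level (detection-limit semantics), which
makes missingness concentrate in the pellet signal of highly soluble
proteins — the same cells that are left-censored in real data.

The detection slope matters more than it looks: a diffuse detection curve
scatters partial missingness across replicates of borderline proteins, and
global-column downshifted imputation then corrupts their paired deltas. A
sharp limit (slope 0.15) pushes proteins to be either consistently observed
or consistently censored, which is both closer to a physical detection limit
and the regime in which downshifted imputation behaves as intended.

What the generator does **not** emulate: peptide-level evidence,
between-sample normalization artefacts, correlated co-regulation beyond the
fraction/condition structure, match-between-runs, isoforms, or real
phosphosite biology. Passing recovery tests therefore demonstrate that the
pipeline's statistics recover planted signals of realistic magnitude under
MNAR missingness — not that any particular real dataset will behave the
same way.

## Orchestration and reproducibility

A single YAML config (unknown keys rejected, all violations reported at
once) drives simulate-or-ingest → preprocess → charge → solubility →
enrichment → network → report. One root seed feeds every random stage
(generator substreams and per-column imputation substreams are derived
deterministically), so a fixed config + seed reproduces the full report byte
for byte. The JSON summary carries the per-stage row counts (the filter
audit trail), parameter echo, and — on simulated runs — recovery scores
against ground truth. Failures abort with the stage name; partial outputs
are retained next to a `FAILED` marker.

## Numerical notes and limitations

* Window densities are computed by convolution with an integer kernel then
  divided once, so they equal brute-force window means to 1e−12.
* The hypergeometric upper tail uses the survival function at k − 1; it
  matches exact rational pmf summation to 1e−12 for all tested N ≤ 200. The
  discrete test is conservative: its attainable null level is below the
  nominal 5%, and the null-calibration tests check against the exact level.
* Eigenprotein extraction uses SVD of the standardized member matrix;
  sign orientation can flip between numerically near-tied solutions only in
  the measure-zero case of an exactly zero mean member correlation.
* The acceptance fixtures run at 500 proteins / 16 samples; statistics at
  this size complete in seconds while leaving the planted-signal recovery
  well away from small-sample artefacts.
* Quantities that depend on a specific deposited dataset (absolute protein
  counts, module counts, group means of a real proteome) are dataset
  properties, not package invariants, and are intentionally not asserted
  anywhere.
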