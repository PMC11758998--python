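# Methods

## Scope and data model

The package post-processes a nontarget-screening (NTS) LC-HRMS feature
table from a dated ice core. Upstream steps — peak picking, alignment,
formula assignment from isotope patterns — are assumed done by the
vendor tool; the pipeline starts from profiles (id, *m/z*, RT, formula,
per-sample intensities, blank intensities, peak rating, group CV,
background flag) and dated sample metadata (depth, calendar year,
enrichment factor). All tabular I/O is delimited text.

## Molecular descriptors

For a formula with C, H, N, O, S and halogen counts:

- **DBE** = C − (H + halogens)/2 + N/2 + 1. Halogens substitute for H
  and are counted with it. DBE is an integer when H + halogens + N is
  even, otherwise a half-integer; no clamping is applied.
- **Aromaticity equivalent** χc = [3·d − 2]/d with
  d = DBE − (m·O + n·S). The π-bond fractions default to m = n = 0.5,
  appropriate for the carboxylic acids and esters that dominate
  negative-mode ESI response; both are configurable in [0, 1]. The
  published definition clamps negative values to 0; we extend the clamp
  to d ≤ 0 (degenerate denominator) so that χc is total and always
  ≥ 0. χc ≥ 2.5 (configurable) counts as aromatic. χc is known to be a
  conservative aromaticity measure — e.g. C8H8O3 scores 2.4 although
  plausible structures are aromatic — and no second aromaticity index
  is provided.
- **Average carbon oxidation state** OSc = 2·O/C − H/C; undefined
  without carbon.
- **Compound classes**: CHO, CHNO, CHNOS, CHOS are exact element-set
  matches (all members present); everything else — halogenated or
  phosphorus-bearing formulas, CHN, CHNS, oxygen-free compositions — is
  `other`. Elements beyond CHNOS affect only DBE (via halogens) and
  class membership; they do not enter χc or OSc.
- **Region annotations**: Van Krevelen aliphatic iff H/C ≥ 1.5; Kroll
  OSc bands monoterpene-oxidation [−1, −0.5], isoprene-OH [−0.8, −0.2],
  SVOC [−0.5, 0], LVOC [0, 0.9], hydrocarbon-like [−1.7, −1.6]. Bands
  overlap by construction; membership is reported as a set, and shared
  boundary points belong to both neighbours.

Descriptors are stored at full precision; rounding to 1–2 decimals is
left to display code.

## QC filter

A profile is kept iff all six predicates pass, evaluated in order:
(i) background flag false, (ii) peak rating ≥ 7.0, (iii) group CV
≤ 15 %, (iv) formula present, (v) maximum sample intensity ≥ 5·10⁶,
(vi) sample-to-blank ratio ≥ 3. Rejections are tallied against the
first failing predicate, so kept + Σtally equals the input count and
the filter is idempotent and monotone in its thresholds.

The sample-to-blank ratio is max(sample intensities)/max(blank
intensities); the aggregation is not standardised anywhere, and max/max
is the conservative reading. An all-zero blank passes (ratio = +∞).
Missing intensity cells are read as 0 (below detection), not errors.
The group CV is consumed as a vendor-computed column; a helper recomputes
it from replicate intensities when those are available instead.

## Homolog series

Two formulas are homologs iff they differ by an integer number of CH2
units, i.e. they share H − 2C and every non-CH element count — the key
includes halogen/phosphorus counts, not only O, N, S, otherwise e.g. a
chlorinated formula would key with its Cl-free analog. Series with at
least `min_members` distinct formulas are reported (default 3: real
series in these records run 5–7 members, while 3 suppresses accidental
pairs without hiding short series). Gaps in the carbon number are
allowed. Within a series DBE and compound class are constant by
arithmetic. Retention-time coherence (RT increasing with nC) is
reported as a diagnostic, never enforced, since no RT criterion for
series membership is standardised.

## Binning and time-series inference

- **Bins** are half-open [start, start + width) calendar windows,
  width 5 years by default, anchored at the record start (1800). A
  sample dated exactly on an edge joins the later bin. Bin values are
  arithmetic means of the sample intensities inside the window; bins
  without samples are missing (NaN), never zero. 5-year averaging
  smooths year-to-year variability of transport and snow preservation.
- **Class series** sum binned intensities per compound class;
  per-bin shares form a probability vector (×100).
- **Weighted descriptor records** are Σ(Iᵢ·xᵢ)/Σ(Iᵢ) per bin over a
  molecule subset with positive weight; bins with zero total weight are
  missing. For oxidation-state records the purely industrial subcluster
  (1B) is excluded, restricting to molecules that also have a biogenic
  source (clusters 1A ∪ 2), so that the record reflects atmospheric
  processing rather than source switching. The value is invariant to
  rescaling a bin's intensities by a positive constant and always lies
  within the descriptor range of the contributing molecules.
- **Change points**: the single best mean shift is found by evaluating
  *every* split of the non-missing bins into two contiguous segments
  and minimising total within-segment SSE (computed with cumulative
  sums; an O(n²) scan gives identical results and is used as a test
  oracle). The change year is reported as the start year of the first
  post-change bin; published change years state no convention, and this
  one is used consistently for planted and detected changes. A zero SSE
  drop flags a change point without support. Optional recursive binary
  segmentation (`detect_change_points`) splits while the SSE drop
  exceeds `penalty` × segment variance, for series with more than one
  change; the default record plants exactly one change per series.
- **Fold change** = mean(post bins)/mean(pre bins) with the windows
  (record start → change year) and (change year → record end). A
  non-positive pre mean makes the ratio undefined (NaN).
- **Trend test**: OLS of value on bin year; two-sided p from the t
  distribution with n − 2 df; significance threshold 0.05. Degenerate
  (constant) series return slope 0 with p = NaN.
- **Proxy correlation**: the proxy is linearly interpolated onto the
  series' bin years (not vice versa — proxies are typically smoother
  and regularly gridded) over the overlapping span; Pearson r with ≥ 3
  overlapping bins.
- **Group comparison**: Welch (unequal-variance) two-sided t-test on
  per-molecule descriptor values; "t test" alone does not pin the
  variant, and Welch is the safer default for unequal cluster sizes.

## Clustering

Each molecule's binned record is z-transformed (mean 0, SD 1 across its
non-missing bins, sample SD with ddof = 1 — the convention is not
standardised and ddof = 1 matches the default of the usual statistical
toolboxes). Rows with (numerically) zero SD are set to zero, excluded
from clustering and reported separately. Bins empty for the whole
record are dropped; any remaining per-row missing bins enter the
distance as 0 (the row mean after standardisation).

Agglomerative clustering uses Euclidean distance and Ward linkage. The
tree is cut at k = 2; the *anthropogenic* branch is identified
proxy-free as the cluster whose mean z-score series correlates more
positively with a monotone ramp (identification via change point or
proxy correlation would be downstream of labelling and circular). The
anthropogenic node's own two children give the subclusters; 1B is the
child with the lower mean z-score over the first third of the record
(purely industrial molecules are absent, hence maximally depressed,
early). Whether published subclusters derive from a fixed-height cut or
visual selection is not stated; cutting the branch at its own root is
one consistent, deterministic choice.

Cluster summaries report member count, class tally and unweighted
mean ± SD (ddof = 1) of O/C, OSc, DBE, χc, nC over members. Cluster
intensity shares are per-bin percentages over the labelled molecules.

## Identification levels

Five confidence tiers: 5 = no formula (exact mass only), 4 = formula
assigned, 3 = several library candidates above the score threshold
(ambiguous structures), 2 = a unique candidate above threshold,
1 = reference-standard confirmation, requiring an identical formula and
|ΔRT| ≤ 0.1 min. A standard match confirms level 1 regardless of
spectral-library uniqueness — the in-house-standard route is
independent evidence. The level-2/3 boundary ("unambiguous") has no
numeric criterion in common use; unique-above-threshold vs
multiple-above-threshold is this package's convention. The library
score threshold defaults to 0.6 (commercial library matches down to
~60 on a 0–100 scale are accepted in practice) and the peak-pairing
tolerance to 0.01 Da (Orbitrap-class accuracy); both are configurable.
Spectral similarity is a greedy cosine: candidate peak pairs within the
m/z tolerance are matched by ascending m/z difference, each peak used
once, and the cosine is computed on square-root-scaled intensities (the
sqrt compresses the dynamic range so base peaks do not dominate).
Proprietary vendor match scores in input tables are annotations only
and are never recomputed.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed and
not tuned per run.

- **Roster**: 398 molecules; class counts by largest-remainder quota at
  proportions CHO/CHNO/CHNOS/CHOS/other = 75/18/3/2/2 % (quota rather
  than multinomial keeps counts within rounding of expectation at this
  n); within each class a quota split over clusters 2/1A/1B mirroring
  the composition of a biogenic-dominated record with an industrial
  overlay (e.g. CHO mostly natural, CHNO evenly split, CHNOS mostly
  purely industrial).
- **Formulas** are drawn per class and cluster: nC between 4 and 20
  (1A skewed lower); target O/C and OSc normal around cluster-specific
  means (1A more oxidised than 2, 1B least oxidised), H derived from
  the OSc target, clamped to 1 ≤ H ≤ 2C + 2 + N with H + N parity
  enforced (integer DBE ≥ 0). This reproduces the observed contrasts —
  higher O/C and OSc and lower nC in 1A than 2 — that drive the
  weighted-descriptor signals.
- **Time templates** (noiseless, multiplicative): cluster 2 declines
  linearly by ~11 % over the record (−6·10⁻⁴ per year); 1A is flat at 1
  until 1925 then ramps linearly to 1.4 by 1980; 1B is 0 before its
  onset (1950; 1960 for CHNOS members) and 1 after.
- **Intensity budgets**: each class's record-total share is fixed
  (CHO 95 %, CHNO 4 %, CHNOS 0.4 %, CHOS 0.3 %, other 0.3 %). The 1B
  budget of CHNO and CHNOS is solved analytically so the aggregated
  class record steps by exactly ×1.4 (1950) and ×1.9 (1960) in the
  noiseless construction; the CHO natural/1A split is solved (Brent's
  method) so cluster 1A carries 41 % of pre-1950 intensity, from which
  the post-onset share rise (~+6 pp) follows. Within groups, molecule
  weights are lognormal (σ = 0.7). All planted values, including the
  realised share shift, are recorded in `SyntheticTruth`.
- **Noise**: per-sample lognormal factors with CV 0.15,
  mean-corrected to 1 (ESI intensities vary multiplicatively); planted
  zeros stay exactly zero.
- **Record**: 53 unevenly spaced dated samples over 1800–1980 (ends
  included), monotone depth scale, enrichment factors ~N(92, 3²);
  3 procedural blanks per molecule at ~5 % of peak intensity; vendor QC
  columns drawn in the passing range; a configurable set of extra rows
  (default 36, six per predicate) constructed to fail the QC filter.
- **Proxies** (nitrate, sulfate, ozone, OH) are built at 5-year
  resolution from the realised anthropogenic-cluster mean z-score plus
  Gaussian noise sized to hit a target Pearson r (0.70/0.72/0.66/0.30);
  the realised construction r is stored as the planted value, and
  values are affinely mapped to concentration-like magnitudes.

What the generator does **not** emulate: mass accuracy and isotope
structure (m/z is exact [M−H]⁻), chromatographic drift, censoring at
the detection limit, correlated noise between co-eluting compounds,
dating uncertainty, and the long-tailed intensity distributions of real
ESI data beyond the lognormal. Passing recovery tests therefore shows
the *inference machinery* is correct under the assumed statistical
structure — not that the structure itself matches any particular
glacier.

## Pipeline and reproducibility

`run_all` executes simulate/load → filter → descriptors → homologs →
bin → cluster → trends → identify → report. The run is deterministic
under its seed; the report embeds a SHA-256 hash of the scientific
configuration (output paths and rendering switches excluded). Stage
failures abort with the stage name and preserve a partial report.

Problem sizes used by the validation suite: the default record
(398 molecules × 53 samples × 37 bins) for end-to-end recovery; 200
replicates for change-point recovery and the statistical-calibration
checks; 100 replicates for cluster recovery; 1,000 random formulas for
the descriptor invariants. The change-point noise condition is SD =
0.3 × step on 37 bins.

## Known limitations

- Single change point per series by default; gradual (non-step)
  transitions are attributed to the best single split.
- The anthropogenic-branch heuristic (ramp correlation) assumes the
  anthropogenic signal rises within the record span; a declining
  anthropogenic cluster would be mislabelled.
- Filtering attributes each rejection to the first failing predicate
  only; rows failing several predicates are counted once.
- Weighted-mean uncertainties are reported as the SD across bins within
  the window (± values elsewhere may be SDs or SEs; this package
  labels its choice).
- The published record's dataset-specific numbers (its exact cluster
  sizes, weighted O/C levels, proxy correlations) depend on an
  unreleased feature table; the synthetic generator targets their
  statistical structure, not their values.
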