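# Methods

## Measurement model

A MeRIP two-channel array splits each sample's transcript pool by anti-m6A
immunoprecipitation.  For a transcript with total linear abundance `E` and
methylated fraction `π`, the IP channel measures `E·π·κ` (κ = capture
efficiency of the pulldown, default 1) and the supernatant channel measures
`E·(1−π)`.  Observed raw intensities multiply these true amounts by a
per-sample-per-channel scale factor (labelling/hybridization efficiency) and
multiplicative measurement noise.  All analysis operates on log2 intensities.

## Spike-in normalization

Exogenous spike-in control RNAs of fixed amount are present in every
sample-channel and share its scale factor.  With `s` the mean log2 intensity
of the spike-in probes in a sample-channel, a probe with raw intensity `x` is
normalized to `log2(x) − s`.  Because the scale factor shifts every log2
intensity (spike-ins included) by the same constant, the subtraction removes
it exactly: the normalized output is invariant under any per-sample-channel
rescaling of the raw data (a property tested to 1e−12).  An optional
re-centering adds back the grand mean of `s`, purely for readability; it
breaks exact scale invariance and is off by default.  Raw intensities must be
strictly positive; no pseudocount is applied (an explicit offset for exports
containing zeros would be the caller's responsibility), because a pseudocount
silently biases low-intensity probes.

QC filtering precedes normalization statistics: a probe enters the "all
targets" set when its Agilent-style flag is Present (P) or Marginal (M) in
all (default) or any sample-channels; unknown flag symbols are rejected, not
coerced.  Spike-ins are always retained.  Both channels are filtered to the
same probe set.

## Per-transcript statistics

From normalized log2 intensities `ip` and `sup`:

| statistic | definition | rationale |
|---|---|---|
| methylation level (%) | `100·2^ip/(2^ip+2^sup)` | fraction of molecules captured by the pulldown; depends only on the IP:Sup ratio |
| m6A quantity | `2^ip` | absolute methylated amount, IP channel alone |
| expression | `2^ip + 2^sup` | total abundance; the sum is taken on the linear scale (adding log2 values would be a product, not a sum) |

These satisfy `level·expression = 100·quantity` identically, which the tests
assert as an algebraic invariant.  The level is computed through the logistic
form `100/(1+2^(sup−ip))` for overflow safety and exact shift invariance.

## Differential calling

Per transcript the M-over-V contrast is the difference of group means of log2
values (= log2 ratio of geometric means).  Significance comes from a
two-sided Welch (unequal-variance) t-test on log2 values — the standard
choice for a 3-vs-3 two-color array comparison; an exact count-based test is
undefined for continuous intensities, so Fisher's exact test is reserved for
the enrichment stage where 2×2 count tables actually arise.  Degenerate
conventions: both groups constant and equal → p = 1; constant but unequal →
smallest positive float (p stays in (0, 1]).  BH step-up FDR is applied
across transcripts (statsmodels implementation; an O(m²) literal step-up
serves as the test oracle).

Differential **methylation** fold change is computed on the m6A *quantity*.
The percent methylation level is bounded in [0, 100] and cannot produce
fold changes of 8–9× (log2FC > 3) that methylation contrasts commonly reach,
so the quantity is the axis on which FC thresholds operate; the mean
level difference in percentage points (`delta_level`) is reported alongside.
Calls: hyper/up iff FC ≥ `fc_up` (default 1.5) and significant; hypo/down iff
FC ≤ `fc_down` (default 0.7) and significant; else ns.  The significance
metric is a switch between raw p and FDR (default FDR < 0.05; the raw-p
variant matches how per-transcript tables are usually printed).  A
`Thresholds.fig5_mode()` preset applies |log2FC| > 0.5 with p < 0.05, the
convention joint four-quadrant plots often use.

Hierarchical clustering of transcripts and samples uses per-row z-scoring
(constant rows map to zero), Euclidean distance and average linkage (UPGMA);
SciPy's tie-breaking by lowest cluster index makes it deterministic.

## Chromosomal landscape

Differential peaks are counted per chromosome and direction.  The
homogeneity chi-square test `Σ(O−E)²/E` (df = k−1) compares observed counts
to a null that by default distributes peaks proportionally to the number of
probed transcripts per chromosome — the array, not the genome, defines the
sampling frame; chromosome-length and uniform nulls are available since the
choice is genuinely open.  Chromosomes with zero expectation are excluded
with a warning and the df reduced.  Region overlap (e.g. against the packaged
CAKUT-associated CNV loci 4p16.3, 16p11.2, 17q12, 22q11.2, given at
approximate GRCh37 cytoband coordinates) counts a peak toward every region it
intersects by ≥ 1 bp; all intervals are 0-based half-open internally, with
1-based inclusive annotation coordinates converted at the I/O boundary only.

## RBP overlap and enrichment

RBP binding sites (genomic BED, RMBase-style) are intersected with
differential peaks via per-chromosome interval trees; multiple sites of one
RBP in one peak collapse to a single (RBP, peak) pair.  Binding rates divide
bound peaks by total peaks per direction; bound peaks are additionally binned
by fold-change magnitude (default breakpoints 1, 1.5, 2, 3 on the linear FC
axis; a log2FC axis is available because published axis conventions vary).

Gene-set enrichment is flat per term: hypergeometric upper tail
`P(X ≥ k)` with fold enrichment `(k/n)/(K/N)` and BH across terms.  The
universe defaults to all non-spike-in genes on the panel, again because the
array defines the sampling frame; fold-enrichment magnitudes depend directly
on this choice.  Ontology hierarchies and elimination-style pruning are
deliberately out of scope — they are database content, not part of the
statistic.

## Synthetic data

The generator reproduces the measurement model above with planted effects:

- 2000 genes (one probe each), 30 spike-ins (a 2^6–2^14 geometric ladder),
  3 samples per group; baseline log2 abundance ~ N(8, 1.5²); methylated
  fraction π ~ Beta(4, 4).
- Sample-channel scale factors log-normal with 0.3 log2-sd; i.i.d.
  measurement noise with 0.25 log2-sd (≈ 19% CV, typical array repeatability).
- Planted fractions 5% hyper / 2% hypo (methylation axis) and 5% up / 2% down
  (expression axis), disjoint within an axis, independent across axes.
  Hyper/hypo genes have their methylation **odds** `π/(1−π)` multiplied or
  divided by 2 in group M, which keeps π in (0, 1) and gives the closed-form
  quantity fold change `FC = m/(1+(m−1)π)` at fixed expression.  Up/down
  genes have `E` multiplied/divided by 2.  A coupling coefficient β adds
  `β·(methylation log2FC)` to the expression log2FC, planting a
  methylation–expression correlation (default β = 0).
- QC flags default to all-Present; absent/marginal flag rates are available
  to exercise the filtering path.
- The random stream is consumed in a fixed order (gene truth → panel
  geometry → noise → flags → scale factors), so runs differing only in noise
  or scale parameters share the same planted truth, and the same seed is
  bit-reproducible.

What the generator does *not* emulate: spatial array artifacts, saturation,
intensity-dependent (heteroscedastic) noise, intensity-dependent QC flags,
probe-sequence effects, and correlated transcript programs.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to real-array artifacts.

### Power under the default conditions

The default planted methylation effect (odds multiplier 2 with π ~ Beta(4,4))
yields a median true quantity log2FC of ≈ 0.42, while the per-gene standard
error of a 3-vs-3 Welch contrast at 0.25 log2-sd noise is ≈ 0.20.  Individual
effects therefore sit near t ≈ 2 (p ≈ 0.1), and after BH correction across
2000 transcripts (~7% non-null) essentially no single gene reaches FDR < 0.05;
at raw p < 0.05 sensitivity is ≈ 0.35.  The *median* estimated log2FC over
planted genes remains unbiased (|error| well under 0.1), and the false-call
rate among doubly-null genes stays at or below the nominal level.  This is an
honest property of the design, reported as-is by `scripts/acceptance.py`
(`recovery_sensitivity_fdr_0.05`): per-gene discovery at n = 3 requires
substantially larger effects than a 2-fold odds shift.  For the false-call
rate, "null genes" means genes null on *both* axes — an expression-planted
gene's methylated amount `E·π` genuinely changes, so calling it is not an
error.

## Numerical and design notes

- Coordinates: 1-based inclusive on disk for annotation tables (matching the
  published table convention), BED kept native, 0-based half-open everywhere
  in memory; conversions only at I/O.  Width = end − start is preserved by
  round-trips.
- Result tables are TSV with floats at 6 significant digits and deterministic
  row order; re-reading a written table reproduces regulation calls exactly.
- Sample→group mapping comes from an explicit `# group:` line or run config,
  never guessed from sample names.
- The chromosome homogeneity example `O=[10,0]` against equal weights gives
  χ² = 10 (each cell contributes 25/5); the asymptotic tail is cross-checked
  against a multinomial Monte-Carlo null in the tests.
- Problem sizes in the test suite (2000-gene simulations, ≤ 200-instance
  oracle sweeps, 2·10⁴ Monte-Carlo draws) were chosen to keep the full suite
  in the tens of seconds while leaving every statistical assertion several
  standard errors away from its threshold.
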