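# Methods

## Model and procedure

The pipeline is membership-based throughout: a gene either belongs to a set
or it does not.  There are no ranked statistics, no expression values, no
permutation nulls — the unit of evidence is an overlap count between two sets
restricted to a common universe.

**Representativity.** For catalog set *T* (size *K* in the universe), query
set *S* (size *n*), universe of size *N* and overlap *k*, representativity is
r = k/n and the background rate is p₀ = K/N.  Both sets are always restricted
to the universe first, so adding genes undetectable in the assay to either
set changes nothing.  An empty restricted query is an error (never a silent
zero); an empty overlap is a valid result with r = 0.

**Over-representation test.** One-sample proportion z-test,
z = (k/n − p₀)/√(p₀(1−p₀)/n), one-sided over-representation by default,
α = 1 − confidence with confidence defaulting to 0.95.  A Yates-style
continuity correction is available but off by default; no multiple-testing
adjustment is applied by default (Benjamini–Hochberg is available behind a
flag).  Alongside every z-test the exact hypergeometric tail probability is
computed.  When the approximation and the oracle differ by more than 0.01 on
a cell whose expected counts are at least 5, the cell is *flagged*, not
silently accepted.

A caveat worth stating plainly: the uncorrected z-test p-value differs from
the exact over-tail P(X ≥ k) by about half the probability mass at k.  Near
the null mode of cells with expected counts around 5 this is ~0.02–0.06, and
it only falls below 0.01 deep in the tails or when n·p₀(1−p₀) is large
(roughly ≥ 400).  The z-test is retained as the primary statistic because it
is the field's convention for these tables; the exact p-value is always
reported next to it and the disagreement flag makes the approximation's
limits visible per cell rather than hiding them.

**Annotation coverage.** The fraction of a restricted query set covered by
the union of all sets in a catalog — the "n (%)" style columns of annotation
summary tables.

**Differential representativity.** The same catalog set's conditional rates
in two contexts, k₁/n₁ and k₂/n₂, are compared with the pooled two-proportion
z-test, z = (p̂₂ − p̂₁)/√(p̂(1−p̂)(1/n₁+1/n₂)), two-sided by default.  Each
context keeps its own universe, because the two query sets typically derive
from different experiments with different detected-gene backgrounds.  Genes
shared between contexts are not paired: the contexts are treated as
independent samples, since no pairing information exists in list-based
inputs.  Classification: unchanged if p ≥ α, else increased/reduced by the
sign of r₂ − r₁.  Results are ordered by |z| descending with lexicographic
tie-break, so output is deterministic.

**Network assembly.** Significant matrix cells become edges of a typed
multigraph (node types: pathway, tf, condition, phenotype; at most one edge
per source/target/tail-direction).  Exports (SIF, versioned JSON, long TSV)
are lexicographically ordered and contain no timestamps, so identical inputs
give byte-identical files.

**Nested overlap summaries.** Reproduces nested-Venn figure captions: the
first set is the background, the second the focal query (shown as a
percentage of the background), and every later set is a crossing of the
query, shown as a percentage of the query.  The plain consecutive-parent
reading would report the third-level overlap against the second-level one;
the figures this summarises report *all* crossings against the focal query,
so that is the implemented convention.

**Percent rendering.** One shared formatter: values ≥ 10% to the nearest
integer ("56%"), below 10% to one decimal ("5.4%", "0.6%") — so summary
tables and figure-style captions cannot diverge in style.

## RTCA metrics

Cell index (CI) is the dimensionless impedance readout; all derived measures
follow the standard conventions of the instrument's analysis:

- **Normalized CI**: CI(t)/CI(t₀) with t₀ the treatment time; exactly 1 at
  t₀.  If t₀ falls between samples, the divisor is linearly interpolated.
  Normalization is idempotent.  CI(t₀) ≤ 0 is an error.
- **Slope**: ordinary least-squares slope of CI against time over a
  user-chosen closed window (CI/h).  There is deliberately no default
  window — the informative window depends on the assay, so it is a required
  parameter.
- **4PL dose–response**: response(d) = bottom + (top − bottom)/(1 +
  (d/IC50)^hill), fitted by nonlinear least squares on log₁₀ dose with
  deterministic initialization from data quantiles (asymptotes from the 5th
  and 95th response percentiles, IC50 from the median log dose, hill sign
  from the dose–response rank correlation).  After fitting the parameters
  are canonicalized to bottom ≤ top with the response direction carried by
  the hill sign.  The reported IC50 is the *relative* IC50 (midpoint of the
  fitted asymptotes).  Non-convergence, flat responses, and IC50s outside
  the tested dose range never raise: they return `fit_ok=False` with a
  diagnostic, and extrapolated IC50s are excluded from any averaging.
- **Time-dependent IC50**: at each evaluation time the per-dose response
  (normalized CI by default, windowed slope as an option) is fitted and the
  mean IC50 is taken arithmetically on the molar scale over successful fits;
  a geometric-mean option exists because IC50s are log-normally distributed
  in practice.  Replicate wells are averaged after normalization, with SEM
  propagated.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the reference study design:
a genome universe of 31 524 symbols, 48 pathway-target and 52 TF-target
sets, condition sets of 447 (pan-human context) and 129 (cell-line context)
genes, a 364-gene shared differential core of which 213 genes agree in
direction, and drug potencies spanning 10⁻⁷–10⁻³ M.

- **Catalog sets** are drawn uniformly without replacement, sizes uniform in
  (30, 1200).  This range makes the expected catalog-union coverage of the
  genome ≈ 61%, inside the 30–75% band real annotation catalogs show.  Sets
  overlap only by chance; real pathway/TF target catalogs share hub genes
  and overlap much more.  This is the generator's main infidelity: passing
  tests show the statistics behave correctly under independent catalogs, not
  that correlated catalogs cannot produce correlated significance calls.
- **Planted enrichment** is specified as a *conditional rate* — the expected
  fraction of condition genes inside a chosen catalog set — because the
  statistics of interest are all conditional rates.  The realized overlap is
  Binomial(n, rate), so planted signals carry natural sampling spread; the
  realized rate is recorded in a machine-readable truth file.  A separate
  noiseless fixture plants exact counts (enriched sets at round(r·n), null
  sets at their null expectation) for tests that need an exact significant-set
  count.
- **Paired signed sets** share a core with exactly round(concordance·core)
  sign-agreeing genes.  Fold-change magnitudes are threshold · e^|N(0,σ)|
  (σ = 0.5), guaranteeing consistency between sign and fold change and, when
  requested, that every gene clears the 1.4-fold symmetric threshold —
  emulating pre-filtered differential lists.
- **Growth curves** are logistic, L(t) = capacity/(1 + (capacity/ci0 − 1)
  e^(−rate·t)), with the drug factor 1 − emax·d^hill/(d^hill + IC50^hill)
  applied from the treatment time t₀ onward.  Applying it to the whole trace
  would cancel exactly under t₀-normalization, leaving no dose signal — so
  treatment starts at t₀, and the post-treatment normalized CI is an exact
  4PL in dose, enabling round-trip recovery tests.  Noise is multiplicative
  log-normal, ci·e^(σε), which keeps CI positive.  The generator does not
  simulate attachment transients, well edge effects, media changes, or
  drift; a linear-in-log IC50 drift option exists for testing the
  time-dependent estimator.
- **Determinism**: all randomness flows through one `numpy.random.Generator`;
  a fixed seed gives byte-identical GMT/CSV/JSON outputs.

No attempt is made to simulate microarray intensities or probe-level data:
condition sets arrive as gene lists, which is also the pipeline's input
contract.

## Numerical and design choices

- Identifiers are upper-cased HGNC-style symbols; alias resolution only via
  a user-supplied local table (no network access, ever).  Symbols absent
  from a non-empty alias map pass through with a once-per-symbol warning.
- Fold-change dialects: linear ratio (values < 1 = downregulation) and log₂,
  with the linear 1.4-fold symmetric threshold as default.
- Degenerate statistics (background rate 0 or 1, pooled proportion 0 or 1)
  are flagged per cell and never abort a matrix or profile.
- Ties in differential ordering break lexicographically; matrix rows and
  columns keep input order; exports sort lexicographically.
- Problem sizes in the test suite and acceptance script (500 differential
  replicates, 2000 null cells, 200 noisy IC50 replicates, 500-cell oracle
  grid) were chosen to give stable Monte-Carlo estimates at interactive
  runtimes.

## Known limitations

- The z-test/exact-test disagreement near the null mode (see above) is
  intrinsic to the uncorrected normal approximation; users needing exact
  calibration on small expected counts should read `p_exact`.
- Independent-draw catalogs understate between-set correlation; differential
  classifications on heavily overlapping real catalogs will be correlated
  across sets in ways the synthetic power estimates do not capture.
- The two-proportion context comparison assumes independent samples; if the
  two condition sets derive from the same experiment, the test is
  conservative or anticonservative depending on the induced correlation.
- RTCA metrics assume a shared sampling grid per dose series (interpolation
  is linear); impedance-to-cell-number calibration is out of scope.
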