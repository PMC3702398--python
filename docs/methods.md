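# Methods

## Problem setting

K somatic mutation callers evaluate N candidate positions across a cohort
of tumor/normal pairs; position i yields the observed detection pattern
Y_i ∈ {0,1}^K. A "site" is specific to one patient: identity is
(patient, chromosome, position, alternate allele), SNVs only. A caller's
final call set contains the sites it reported as somatic and passing all
of its filters; sites absent from a caller's VCF are treated as "not
called" (presence in the raw, pre-filter VCF is tracked separately as a
descriptive diagnostic, since "never scanned" and "scanned but filtered"
are different failure modes).

The pattern-count table over all 2^K cells is the sufficient statistic for
the model-based analysis. The all-zero cell (screened but called by
nobody) cannot be derived from the call sets and must be supplied
explicitly; the bundled 76-gene fixture includes it (4,301 of 4,439
sites).

## Latent class models

With latent true status D_i (prevalence η) and conditional independence of
callers given D, the cell probability factorizes over callers with
per-caller false-positive rate fp_k = P(Y_k=1 | D=0) and false-negative
rate fn_k = P(Y_k=0 | D=1); the model has 1+2K free parameters and
residual df = 2^K − 1 − (2K+1).

**Fitting.** EM on the multinomial cell counts: the E-step computes the
posterior responsibility P(D=1 | Y=y) per cell, the M-step has closed-form
updates for η, sensitivities, and FP rates. The log-likelihood is
non-decreasing by construction (asserted in tests via the per-iteration
trace). Defaults: 20 restarts (one data-driven start — prevalence from the
all-positive cell, rates from the margins — plus stratified random starts
alternating low/high prevalence), tolerance 1e-8 on the log-likelihood,
5,000 iterations cap, probability floor 1e-12 inside logs. Both mixture
labelings fit identically; the returned solution is always oriented so the
class-1 mean detection probability exceeds the class-0 mean (class 1 =
somatic). K = 3 is allowed but saturated (df = 0); K < 3 raises.

**Random-effects extension.** A shared standard-normal site effect b with
loading σ ≥ 0 enters a probit link: P(Y_k=1 | D=d, b) = Φ(a_{d,k} + σb),
with a single σ shared between the somatic and non-somatic classes (one
parameter beyond conditional independence; df = 2^K − 1 − (2K+2)).
Marginalization over b uses Gauss–Hermite quadrature (40 nodes by default;
cell probabilities sum to 1 within 1e-8, cross-checked against adaptive
quadrature at 1e-6). The likelihood is maximized by L-BFGS-B on
(logit η, a_0, a_1, σ) with σ bounded below by 0, started from the CI
solution (σ = 0.1) plus perturbed restarts — so the CI model is nested at
the boundary and the RE log-likelihood dominates the CI one up to
optimizer tolerance. Marginal rates use the closed form
Φ(a_{d,k}/√(1+σ²)).

**Goodness of fit.** Pearson χ² between observed and fitted counts over
all cells (df with no boundary adjustment). Because pooling conventions
vary, a pooled variant (cells with expected count < 0.5 merged into a
remainder cell, df reduced accordingly) is reported alongside; on the
bundled fixture the smallest fitted cell is ≈0.7, so the two coincide.

**Standard errors.** Observed-information covariance via a central
finite-difference Hessian of the multinomial log-likelihood at the MLE,
pseudo-inverted for near-boundary robustness. Wald comparisons for rates
should be made on the probit scale: near-zero rates have flat likelihood
tails where rate-scale Wald intervals are unreliable.

## Validation schemes

All comparisons are strict (>, <) so threshold ties fall to the negative
side; a vaf at zero depth is undefined and propagates as `not_evaluable`,
never as a silent pass or a zero.

* **Gold standard** (independent deep sequencing, ~3× exome coverage):
  somatic iff deep tumor vaf > 10% and deep normal vaf < 2%; among
  non-somatic sites, wildtype iff both < 2%. An alternative criterion uses
  signed quality scores (tumor > 200 and normal < −100); sites where the
  two criteria disagree are labeled ambiguous and excluded rather than
  adjudicated. Evaluation sets are built by requiring deep tumor depth
  ≥ 100x and exome tumor/normal depth ≥ 10x before labeling.
* **Signed-quality pseudo-validation:** per-sample genotyper quality with
  the sign flipped when no variant allele was found (large negative =
  confident reference). Pseudo-positive iff tumor score > q_t and normal
  score < q_n; defaults q_t = 200, q_n = −50.
* **RNA-seq validation:** positive iff tumor RNA vaf > f_t (default 10%)
  and normal exome vaf < f_n (default 2%), restricted to RNA depth ≥ 10x
  (a 5x display variant is configurable).
* **Strand-bias filters:** a variant allele is strand-extreme when > 95%
  or < 5% of its reads are on the forward strand. The exome filter removes
  sites whose variant allele is extreme while the reference allele is not
  (its forward fraction inside (0.30, 0.70) — the published phrasing
  "less than 70% or larger than 30%" is vacuous as written, so it is
  implemented as "reference not itself extreme", which matches the
  filter's purpose; the interval is configurable). The RNA filter requires
  extremity in both the tumor exome and the RNA assay, because
  strand-bias correspondence between variant and reference alleles is
  weak in RNA even for genuine variants. Filters only remove positives;
  they can never convert a negative into a positive.

Performance sweeps report the true positive rate against the false
*discovery* rate: on an ascertained candidate universe only relative
false-positive rates are meaningful, and FDR has an interpretable scale.
FP rates are additionally rescaled to a common reference prevalence
(default 3% of the evaluated universe truly somatic): the rescaled rate is
the FP count divided by the implied negative count
n_true · (1−p)/p. This rescaling is this package's concrete rendering of a
one-sentence verbal description; it is monotone, so caller rankings are
preserved, and the reference prevalence is a parameter. An ascertainment
diagnostic cross-tabulates detection pattern against validation group and
flags a caller when ≥ 99% (configurable) of attempted-validation sites
carry its bit — labels ascertained on one caller's calls must not be used
to score the other callers.

## Synthetic cohort generator

The generator draws exactly the structure the analysis assumes, so
parameter-recovery tests are meaningful:

* **Latent status:** somatic with probability η (default 0.03, the
  approximate somatic share of screened candidate sites in the target
  setting); the remainder split among germline (0.25), germline-like
  wildtype artifact (0.12, set from the 76-gene description where 787 of
  6,692 candidate sites were germline-like — illustrative, not a claim
  about whole exomes), and clean wildtype.
* **Calls:** Y_k ~ Bernoulli(Φ(a_{d,k} + σb)), b ~ N(0,1) per site, with
  intercepts solved from the configured *marginal* rates via the
  Φ(a/√(1+σ²)) identity — at σ = 0 calls are independent Bernoulli at
  exactly the configured fp/fn. Default rates (fp 0.001–0.003,
  fn 0.1–0.3) give one stringent caller and three comparable ones.
* **Allele fractions:** somatic tumor vaf = purity · c/2 with clonal
  fraction c ~ U(0.2, 1) and purity 0.8; normal vaf 0. Germline vafs are
  N(0.45, 0.05) in both samples — centred below 50% to mimic alignment
  bias toward the reference allele. Artifact sites get matched
  low-but-nonzero vafs (base U(0.05, 0.30) plus noise) in tumor and
  normal, mimicking germline-like sequencing artifacts; the deep-seq
  assays are modeled as cleaner and omit the artifact allele, so the gold
  standard classifies these sites as wildtype.
* **Evidence:** depths are negative-binomial (exome mean 80x, deep 240x —
  three-fold higher, dispersion 5); RNA depth is strongly overdispersed
  (mean 12, dispersion 0.35, including zeros) so that roughly a third of
  sites reach 10x, matching the evaluable share seen in practice. Alt
  counts are Binomial(depth, vaf·(1−e)+e) with base error e = 0.001.
  Forward-strand alt counts are Binomial(alt, s) with s = 0.5 for genuine
  variants; with probability `strand_artifact_prob` (default 0.5, from
  the ~50% strand-extreme share among germline-like sites in the 76-gene
  description) an artifact site draws s ∈ {0.002, 0.998}, i.e. virtually
  all variant reads on one strand.
* **Signed quality scores:** ten times the log10 Bayes factor of a
  heterozygous-variant model against a reference-with-error model,
  10·[alt·log10(0.5/e) + (depth−alt)·log10(0.5/(1−e))] — monotone in the
  allele evidence, negative when no variant allele is present, and on the
  few-hundred scale the default thresholds assume.
* **Reproducibility:** one global seed; truth, calls, and evidence use
  deterministic substreams (`SeedSequence.spawn`), and `write_cohort`
  output is byte-identical for identical configurations. Each uncalled
  site appears in a caller's raw VCF with probability
  1 − `raw_missing_prob` (default 0.6 missing, echoing the observed
  "never scanned" share for a stringent caller).

**What the simulator does not model:** read-level error processes, indels,
mapping artifacts with positional structure, inter-patient heterogeneity
in purity or error rates, caller-specific filter logic, and linkage
between neighboring sites. Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed generative model, not
caller performance on real data.

## Problem sizes and numerical choices

Recovery tests use pattern tables of N = 1e5 sites (20 replicate seeds for
the conditional-independence model, one σ = 1.5 cohort for the
random-effects model) — large enough for asymptotic standard errors to be
meaningful while keeping the full suite fast. The brute-force oracle for
the EM uses a shared-rate parameter grid in steps of 0.02 on K = 3 tables;
quadrature cross-checks run at 60 nodes against adaptive integration.
Degenerate inputs are handled explicitly: empty cohorts produce valid
empty outputs, all-zero pattern tables fit (to a boundary), zero-depth
assays yield undefined vafs, and duplicate caller records with conflicting
filter status raise rather than guess.

## Known limitations

* The conditional-independence fit is saturated at K = 3 and unavailable
  below; the random-effects model needs K ≥ 4.
* Boundary estimates (σ̂ = 0, rates near 0) make rate-scale Wald intervals
  unreliable; use the probit scale or bootstrap.
* The FP rescaling to a common prevalence is a definition, not an
  estimate; cross-scheme FP comparisons inherit its assumption that the
  evaluated universes share the reference somatic share.
* VCF ingestion supports the documented dialect (somatic status in a
  configurable INFO key, PASS-based filter status, TUMOR/NORMAL samples
  with DP/AD) plus a column-mapping configuration — not every historical
  center-specific flavor.
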