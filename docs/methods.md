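# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that matter for
reproducing results.

## Rhythmicity score and its null

A profile x over sampling times tᵢ (hours) is standardized to mean 0 and
population sd 1 (ddof = 0; any fixed scaling convention gives identical
permutation p-values, so the choice is cosmetic). The Fourier score

F = √[(Σᵢ xᵢ cos(2π tᵢ/T))² + (Σᵢ xᵢ sin(2π tᵢ/T))²]

is the unnormalized magnitude of the T = 24 h frequency component; we do
not divide by N, again because every downstream decision is made on
permutation ranks, which are invariant to rescaling. For a standardized
pure cosine sampled hourly over two full cycles, F = 24·√2.

Significance: the observed profile is compared with randomly permuted
versions of itself. p = (1 + #{F_perm ≥ F_obs}) / (B + 1) with B
permutations (add-one convention, so p ∈ (0, 1] and is exact under
exchangeability). Constant profiles carry no testable rhythm and are
flagged `NonTestableProfileError` / `testable = False` rather than treated
as numeric failures; profiles with missing values are excluded and
reported, not imputed.

**Pooled backgrounds.** Standardized profiles are exchangeable under the
null, so for matrix-wide analyses the permuted scores of all G testable
profiles are pooled, giving G·B null draws and p/q resolution fine enough
for thresholds like 10⁻⁵ with only B ≈ 100–200 permutation rounds. A
per-profile mode exists for diagnostics. Whether pooling matches the
original study's implementation is unknowable from the published text;
both modes are exposed.

**Empirical FDR.** At score threshold s, q(s) = (expected null count ≥ s
per permutation round) / (observed count ≥ s), clipped to [0, 1]. Each
observation then takes the minimum raw q over all thresholds that include
it (the standard q-value monotonization), so q is non-increasing in the
score.

**Phase.** α = argmax over a shift grid (default step 0.1 h) of
Σᵢ xᵢ cos(2π(tᵢ − α)/T), ties broken toward the smallest α. On noiseless
periodic input this agrees with the closed-form atan2 phase of the 24-h
Fourier component to within half a grid step.

## Complex abundance and dynamic edges

The complex of interacting proteins P1, P2 is assumed proportional to the
product of the partners' abundances: A_C(tᵢ) = E_P1(tᵢ)·E_P2(tᵢ),
computed on the **raw, non-negative** profiles. This matters: for
zero-mean (pre-standardized) sinusoids the product contains only the 12-h
harmonic, whereas raw profiles b(1 + a·cos(...)) yield a 24-h component
whose phasor is the amplitude-weighted sum of the partners' phasors — for
baseline- and amplitude-matched partners the complex phase is the circular
midpoint of the two peak phases, and its amplitude shrinks monotonically
as the offset grows toward antiphase. Multiplying standardized profiles
instead is available behind `standardize_inputs=True` for sensitivity
analysis. Only the *product* is standardized before scoring.

Edges are scored exactly like single genes, with backgrounds pooled
across all testable edges. The default call threshold is an empirical FDR
of 10⁻⁵; small synthetic runs use a relaxed threshold (0.01–0.05) simply
because a few hundred edges cannot estimate tails of 10⁻⁵ — the threshold
is a parameter everywhere. Undirected duplicates and self-loops in input
edge lists are collapsed/dropped with logged counts. Edges with an
endpoint missing from the expression matrix are reported as `unmapped`;
edges with a constant endpoint or a constant product as `untestable`.

A note on ground truth in simulations: the product of a rhythmic and a
flat profile is a scaled copy of the rhythmic one, hence genuinely
rhythmic. In recovery experiments the planted co-phase edges measure
recall, while false calls are counted among edges with **no** rhythmic
endpoint — the only edges whose complex is truly non-rhythmic.

## Network topology

Path statistics average shortest-path lengths over unordered reachable
pairs within the largest connected component (disconnected graphs are
noted; the convention is configurable). Per-node clustering is
Cₙ = 2eₙ/(kₙ(kₙ−1)); nodes of degree < 2 contribute 0 to the global mean
but are excluded from the degree-averaged clustering curve. The
topological coefficient is Tₙ = mean over nodes m sharing at least one
neighbor with n of |shared neighbors(n, m)|/kₙ. The scale-free slope is an
ordinary least-squares line on log₁₀(count) vs log₁₀(degree).

The topology null model is double-edge-swap rewiring: swaps that would
create self-loops or multi-edges are rejected, so the degree sequence is
preserved exactly. Defaults: 10·|E| swaps per replicate, 100 replicates
for ensembles (20 in the CLI's quick summary). Graphs admitting no legal
swap (e.g. a triangle) are returned unchanged with a warning.

## Co-expression and party/date hubs

Pair co-expression is the Pearson correlation of the two raw profiles
over matched timepoints; constant profiles are flagged and excluded from
fractions. Enrichment of co-expressed pairs (strictly PCC > 0.5) among
interactions uses a 2×2 chi-squared against ≥1000 random pairs drawn
uniformly from profiled genes excluding the true interacting pairs.

A hub's partners' mean PCC with the hub is compared with random partner
sets of equal size (default 1000 sets); empirical FDRs (add-one) for
"higher than chance" and "lower than chance" yield *party* (fdr_high <
0.01) or *date* (fdr_low < 0.01) labels, at most one per hub. The
"partially random" background — keep a uniformly chosen half of the true
partners, resample the rest — is this package's own construction (the
original figure does not define its recipe) and is optional; the fully
random background is the default for classification.

Degree–rhythmicity association uses (a) a Wilcoxon rank-sum test of
degree between rhythmic and non-rhythmic proteins and (b) a chi-squared
test of the rhythmic fraction between degree strata cut at the median
degree (configurable).

## Process coupling

An edge contributes to category pair (A, B) iff one endpoint carries A
and the other carries B; multi-annotated endpoints contribute to every
qualifying pair (including A = A self-links), each edge counted once per
pair. The null redistributes the dynamic labels uniformly over all edges,
preserving only the global dynamic count — the most literal reading of
"randomized versions of the dynamic interactome"; per-node dynamic-degree
preservation is deliberately not imposed (documented choice). p_perm is
the fraction of random networks with a strictly larger dynamic count;
pairs with p_perm ≤ 10/n_networks (default 10 of 1000) are displayed.
Because pair counts are small integers, ties at the observed count are
common and the realized null display rate sits slightly above the naive
≈1.1% (typically 1.5–3% in calibration runs) — a property of the display
rule itself, not of the implementation.

Category-level node enrichment is a hypergeometric upper tail for genes
with ≥1 dynamic interaction, Benjamini–Hochberg corrected across
categories.

## Reporter phenotyping

Traces are detrended by subtracting a centered running mean whose window
(default 24 h) uses trapezoidal weights — the two window endpoints count
half — so that a full-period cosine averages to exactly zero and a linear
ramp to its center value; edge windows shrink. A running mean is a linear
time-invariant filter, so in the interior it rescales a damped cosine
without changing its period or damping; the fit therefore uses only the
interior where the window was complete.

The oscillation model is A·e^(−λt)·cos(2π(t−φ)/τ), fitted by bounded
nonlinear least squares from 8 starting periods spanning the search
window (default 18–32 h), phase initialized by cosine-shift overlap.
Amplitude is canonicalized positive with φ ∈ [0, τ). Rhythmicity is
r ≥ 0.8, where r is the Pearson correlation between fit and detrended
data; both the model family and the cutoff stand in for an unpublished
analysis tool and are configurable, with the settings stamped into
outputs. Non-convergence yields `rhythmic = False` plus a diagnostic
message rather than an exception.

Period deviation is Δ = τ̂ − mean(τ_controls) (≥2 rhythmic controls
required; sem over sample replicates when n ≥ 2); arrhythmic samples
carry the flag instead of a Δ.

**Phenotypic score** (per gene, this package's explicit default rule set
— the original scoring rules are not published in the text available):
per perturbation direction, 0 if |Δ| < 0.5 h and no flags; 1 if
0.5 ≤ |Δ| < 2 h or any amplitude/damping/magnitude flag; 2 if |Δ| ≥ 2 h;
3 if arrhythmic; the gene score sums the knockdown and overexpression
directions. When two constructs of one direction disagree by more than
0.5 h the weaker (smaller) construct score is used. The magnitude flag
means mean raw counts below 20% of the control mean. All thresholds live
in `ScoreRules`. The score is monotone: worsening any input never lowers
it. Scores are compared between genes with ≥5 and <5 dynamic interactions
by two-sided Welch t and Mann–Whitney U tests.

## Synthetic data: what it emulates, what it does not

Expression: x_g(t) = b_g(1 + a_g cos(2π(t−φ_g)/24)) + ε with log-normal
baselines (log-mean 5, log-sd 1), relative amplitudes uniform in
[0.2, 0.6], phases uniform on [0, 24), Gaussian noise as a fraction of
baseline (default 0.05), hourly sampling over 48 h, positivity enforced
by truncation at 0.01·b_g. Exactly round(n·frac_rhythmic) genes are
rhythmic (default fraction 0.3, a liver-like order of magnitude).
Networks: Barabási–Albert preferential attachment (m = 3) with planted
co-phase edges (phase offset ≤ 2 h) between rhythmic genes. Reporter
traces: damped cosine + polynomial trend + Gaussian noise, 30-min
sampling over 144 h. Annotations: uniform random category membership with
possible multi-annotation.

Not emulated: probe/platform effects, tissue-specific rhythmicity,
protein-level kinetics and delays between transcript and protein peak,
interaction competition or stoichiometry, non-Gaussian counting noise,
and realistic GO topology. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated generative
model, not biological validity on real tissue data.

Recovery experiments use a 500-node / ~1540-edge network with 50 planted
edges, amplitude/noise ratio 10, and a 1000-gene null matrix — sizes
chosen so every check runs in seconds while leaving tail estimates
(binomial bands, FDR fractions) statistically meaningful.

## Numerical conventions

- All times in hours; phases in circadian hours on [0, 24); TSV with '.'
  decimal separator, UTF-8.
- One integer seed per run; child seeds are derived with
  `numpy.random.SeedSequence` and stay below 2³¹.
- Phase grid step 0.1 h; ties toward the smallest phase.
- Add-one conventions for permutation p-values and empirical FDRs, so
  reported significance can never be exactly zero for p while q may reach
  0 when no null draw matches an observation.
- Degenerate inputs: constant profiles → non-testable flags; empty
  backgrounds, empty strata and too-short traces raise `ValueError` with
  a message naming the problem.

## Known limitations

- Transcript abundance proxies protein abundance; the complex-abundance
  product inherits that assumption squared.
- The pooled permutation null assumes profiles are exchangeable after
  standardization; strong autocorrelation shared across genes would make
  the pooled null slightly optimistic.
- The damped-cosine fit assumes a single dominant period within the
  search window; multi-periodic or strongly nonstationary traces will be
  classified arrhythmic rather than decomposed.
- The process-network null preserves only the global dynamic count, not
  per-node dynamic degree; hub-concentrated dynamic edges can therefore
  appear (correctly, under this null) as widespread process coupling.
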