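# Methods

This note documents the models, the numerical choices, the defaults, and
what the synthetic-data generator does and does not emulate. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and conventions

All generative and inferential machinery works on the **mutation time
scale**: times are expected substitutions per site, diversity is
Θ = 4N_eμ per site, and migration is M = m/μ, the mutation-scaled
immigration rate in the **receiving convention** — `mig[s, d]` is
M_{s→d}, the rate at which (backwards in time) a lineage currently in
deme d jumps to deme s. Keeping simulator, coalescent density and
sequence likelihood on one clock removes a whole class of unit bugs;
calendar years and N_e enter only in `paleodemo.calibrate`.

Site coordinates are 0-based half-open internally and 1-based in emitted
reports. Deme labels are 1-based in alignments, 0-based internally.

## Sequence input and filtering

Alignments must be pre-aligned and equal length. Any column containing a
gap (`-`) or missing base (`N`) in **any** row is removed before
analysis (list-wise deletion). IUPAC ambiguity codes other than N are
mapped to N (with a warning) and therefore also removed by the column
filter: an alignment column with partial information contributes
unequal evidence across sequences, and the classical statistics below
assume complete columns. Pairwise-complete handling would retain more
sites but make S and π depend on the pair — list-wise was chosen and is
applied uniformly.

Per-deme subsampling caps sample sizes (default cap 250) by uniform
draws without replacement; the `equalize` flag reduces all demes to the
smallest deme size to avoid uneven-sample-size bias. Both are
deterministic for a fixed seed.

## Diversity and neutrality statistics

For n sequences and L retained sites: S is the count of columns with
more than one residue (tri-allelic columns count once); h is the number
of distinct rows; H = n/(n−1)·(1 − Σp_i²) (Nei's unbiased haplotype
diversity); π is the mean pairwise **proportion** of differing sites
(no multiple-hit correction — matching the convention of the classical
software this mirrors); Watterson's θ_w = S/(a₁L) with
a₁ = Σ_{i<n} 1/i.

Tajima's D uses the 1989 constants
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ from n) and
D = (π_locus − S/a₁)/√(e₁S + e₂S(S−1)). Fu's Fs uses the Ewens
distribution of the number of alleles:
P(K = k) = |s(n,k)|θᵏ/θ₍ₙ₎ with unsigned Stirling numbers of the first
kind computed **exactly** (big-integer recurrence, n ≤ 250) and θ set to
the mean pairwise difference count; Fs = ln(S′/(1−S′)) with
S′ = P(K ≥ h_obs), evaluated in log space. Statistics that are
undefined at S = 0 propagate as NaN sentinels, never as 0; an S′ that
underflows yields signed infinity with a warning.

## The synthetic-data generator

`simulate_genealogy` draws from exactly the model the estimator assumes:
piecewise-constant Θ per deme and M per direction, coalescence rate
k_d(k_d−1)/Θ_d, per-lineage emigration rate Σ_s M_{s→d}, epoch
boundaries truncating the exponential waiting times. It is validated
distributionally against msprime (TMRCA mean and variance on a matched
two-deme scenario) in the test suite. Zero-rate dead ends (all rates
zero with more than one lineage and no further epoch) raise an
"absorbing state" error rather than looping.

`mutate` evolves a root sequence drawn from the stationary base
frequencies down the genealogy under HKY (default κ = 2, equal base
frequencies; κ = 1 is Jukes–Cantor). Substitutions follow the exact
finite-sites Markov process — transition matrices from the symmetrized
eigendecomposition — which is distributionally identical to placing
Poisson substitution events along branches and cheaper. Because the
model is finite-sites, pairwise diversity saturates slightly below Θ
(≈ 1.3% at Θ = 0.01); the calibration checks therefore use
Monte-Carlo standard errors rather than exact equalities.

`simulate_folded_sfs` draws Poisson counts around L × the analytic
expected folded SFS (below). `simulate_temperature` produces a
deglacial-warming sigmoid (default amplitude 15 °C, the magnitude of
the Pleistocene–Holocene transition; midpoint 9.5 kya, width 800 y)
with optional AR(1) noise and an optional brief cold spike emulating an
8.2-kya-type event.

**What the generator does not emulate:** recombination, selection,
more than two demes, sequencing error, alignment error, and
genotype-likelihood uncertainty (nuclear inputs are hard calls with a
missingness filter). Passing tests therefore demonstrate correctness of
the estimators **under their own model assumptions**, not robustness to
the artifacts of real data.

## Structured-coalescent MCMC (the skyline estimator)

State: (Θ per deme per epoch, M per direction per epoch, genealogy with
per-branch migration paths). Priors are uniform with user-set bounds; a
helper (`suggest_prior_bounds`) brackets Watterson's estimate by
(0.1×, 10×) and an F_ST-based migration estimate likewise, mirroring
the practice of setting priors from quick preliminary runs. The
likelihood is Felsenstein pruning over compressed site patterns with
per-node rescaling.

The coalescent density splits inter-event intervals at epoch boundaries
and looks parameters up at sub-interval midpoints, which makes the
midpoint lookup exact and the density the literal inverse of the
simulator. Deme-inconsistent states have density −∞.

Moves:

1. **Parameter update** — one Θ or M entry via (i) a log-scale
   multiplier, (ii) a reflected uniform window, or (iii) an
   independence draw from the prior, each with the proper Hastings
   term. The independence draw decorrelates prior-dominated parameters.
1b. **Conditional (Gibbs) update** — because the sequence likelihood
   does not depend on Θ or M, their full conditionals given the
   genealogy are available in closed form from per-deme, per-epoch
   sufficient statistics (coalescence counts and the integrals
   ∫k(k−1)dt and ∫k dt): M_{s→d} | genealogy is Gamma(n_events + 1,
   ∫k_d dt) and 1/Θ_d is Gamma(n_coal − 1, ∫k_d(k_d−1)dt), each
   truncated to the uniform prior bounds. The same sufficient
   statistics, cached per chain, make the coalescent density an O(D²E)
   expression, so parameter moves are cheap.
2. **Node-time slide** — uniform within the window bounded by child
   times, adjacent migration events, and the parent time; the root gets
   an exponential tail proposal whose rate depends only on the fixed
   window edge (reversibility across epochs).
3. **Regraft with path re-simulation** — detach a lineage, re-simulate
   its migration path and coalescence against the remaining forest under
   the *current* parameters (above the forest root, the forest-root
   lineage's own continuation path is co-simulated). The proposal
   density cancels the coalescent-prior factor exactly, so acceptance is
   the sequence-likelihood ratio alone; with the likelihood disabled the
   move is Gibbs. The factorization requires the detached lineage to
   start at or below the forest root; the one configuration violating
   this (the detached node is the root's upper child) is rejected, and
   the rejection is symmetric because the criterion depends only on the
   forest and the detached node's time, which forward and reverse moves
   share. Pathological excursions with vanishing rates are cut off by an
   event-count cap so remote that the affected proposal mass is
   negligible. This move is the component that the prior-recovery
   validation stresses hardest — a deliberately sharp test, since any
   unaccounted proposal density shows up as a biased uniform marginal.
4. **Joint scale** — multiply all Θ entries, node times and migration
   event times by a common factor (Hastings cᵏ). This breaks the strong
   Θ–tree-length posterior coupling that otherwise dominates the
   autocorrelation time.

Metropolis coupling follows the static-heating scheme (temperatures
start at 1.0 and are non-decreasing; the full-scale preset uses
1.0, 1.5, 3.0, 10⁶). Heating powers the **sequence likelihood only**;
the coalescent prior stays at full strength so heated-chain genealogies
remain proper even at the near-infinite top temperature. Adjacent
chains swap states by the standard exchange ratio.

**Scale presets.** The desk default is 200k steps, half burn-in, thin
50, one chain, ESS floor 200 (flagged, never silently dropped); the
full-scale preset (`paper_scale_config()`) is 16M steps, 8M burn-in,
thin 200, four heated chains, ESS floor 10,000. The validation
experiments in the test suite and acceptance script use 15k–305k steps
chosen per experiment so the whole suite runs on one CPU in minutes;
each experiment's size is stated in its code.

**Skyline construction.** The reporting grid is a fixed user-supplied
set of bins (default 30, to a configurable horizon) rather than
genealogy-determined change points, which makes replicate pooling
trivial. For each recorded state, every genealogy inter-event interval
contributes one draw of each parameter (the epoch value at the
intersection midpoint) to every bin it overlaps; per bin the median, SD
and draw count n are reported. One "MCMC datapoint" is thus one
recorded-state interval overlapping the bin. Deep bins are only
informed by states whose genealogies reach them, which couples
long-genealogy states with high-Θ draws; read deep bins with a support
floor (the validation experiments require n ≥ 5% of the per-run
maximum). Ties in medians follow numpy's lower-median convention.

**Validation hierarchy** (all recomputed by the suite): exact
closed-form checks of the density and likelihood; equality with naive
re-implementations on random states; n = 2 posterior vs 1-D quadrature
(max CDF deviation < 0.02); prior recovery of all Θ and M marginals
with the likelihood disabled (KS against the uniform priors at 5000
thinned draws); 95% credible-interval coverage over 20 replicates at
n = 30, L = 400, Θ = 0.01; and recovery of a 10-fold expansion as a
monotone median skyline. For the expansion experiment the change point
is placed at 0.002 mutation units so that roughly ten lineages survive
into the ancient epoch — with a much deeper change point the ancient
epoch carries only 2–4 coalescences and its Θ is prior-dominated, an
information limit of single-locus data rather than a sampler defect.

## Folded-SFS demography

Genotype input is hard diploid calls {0, 1, 2, missing}; sites called
in fewer than 80% of individuals (the default) are dropped, matching a
standard genotyping filter; monomorphic sites count toward L but not
toward the spectrum. Minor-allele counts are tallied as observed (no
hypergeometric projection).

The expected folded SFS of a piecewise-constant history is analytic:
E[ξ_i] = Σ_k k·P_k(i)·E[T_k], with subtending probabilities
P_k(i) = C(n−i−1, k−2)/C(n−1, k−1) and per-epoch expected times with k
lineages obtained by integrating the lineage-count law of the pure-death
ancestral process through the Θ-rescaled clock. The law is an
alternating exponential series, numerically unstable beyond n ≈ 200
chromosomes; larger samples must be projected down (enforced with an
error). Folding is η_i = ξ_i + ξ_{n−i} with a single term at i = n/2.

The stairway-style fit maximizes the Poisson composite log likelihood
Σ_i [η_i log λ_i − λ_i], λ_i = L·E[η_i | Θ], over per-epoch log-Θ
(L-BFGS-B, seeded multi-start). Epoch boundaries are fixed at
pairwise-coalescence quantiles of the constant-Θ Watterson model
(boundary_e = −(θ̂_w/2)·ln(1 − e/K)); models are fitted sequentially
with warm starts so the maximized likelihood is non-decreasing in the
number of epochs. A one-epoch fit reduces analytically to Watterson's
estimator. **Identifiability caveat:** with a free or mis-placed change
point, (boundary, ancient Θ) lie on a nearly flat likelihood ridge —
profiling shows ~0.5 log-units across a two-fold range of ancient Θ at
n = 40, L = 10⁵ — so recovery experiments place the true change point
at the fitter's boundary rule. Composite likelihood assumes site
independence (no linkage modeling), and no bootstrap confidence bands
are produced.

## Pooling, calibration, window

Replicates are pooled per bin: m_p = Σnᵢmᵢ/Σnᵢ and
SD_p = √(Σ(nᵢ−1)SDᵢ²/(Σnᵢ−k)); bins with Σnᵢ = 0 are emitted as
missing. The 95% CI is m_p ± 1.96·SD_p/√(Σnᵢ) by default — the printed
form of this interval in the source analyses is typographically
ambiguous about the divisor, so it is exposed as a config option
(`sqrt_total_n` or `total_n`).

Calibration constants ship as defaults and are overridable per species:
control region 1.125×10⁻⁶ /site/generation, other mtDNA 3.4×10⁻⁷
/site/generation, nuclear 1.07×10⁻⁹ /site/year; generation times 21.2 y
(common minke whale), 32.5 y (fin whale), 27.6 y (southern right
whale). N_e = Θ/(4μ_generational) is applied uniformly to all markers;
for mitochondrial data this is the conventional reporting scale rather
than the inheritance-corrected 2N_fμ scale, so mitochondrial N_e values
are comparable within the analysis but not across ploidy conventions.
Ages scale as years = t/μ_per_year (mitochondrial rates are divided by
the generation time first). Calibrated trajectories are clipped to the
1–30 kya analysis window by default (bins wholly outside dropped,
partial bins clipped); fold changes ΔΘ = Θ(1 kya)/Θ(21 kya) are
computed on the unclipped trajectory so both endpoints are interior.

## Synchrony statistics

Trajectories are linearly interpolated at their bin midpoints onto
1000/2000/5000-year grids, never extrapolated. Correlations are
pairwise-complete Pearson r with two-sided t-distribution p-values;
cells with fewer than 3 joint points are undefined. p-values are raw —
no multiple-testing correction, matching the reporting convention of
the analyses this package mirrors; treat borderline cells accordingly.

Mann–Whitney U is min(U_a, U_b) with midrank ties; for n_a + n_b ≤ 12
the two-sided p is exact by enumeration over all C(n_a+n_b, n_a)
labelings, otherwise the normal approximation with tie correction.
Note that a two-sided exact test of U = 3 at 5 vs 5 gives
p = 14/252 ≈ 0.056; only the one-sided tail (7/252) clears 5%.

## Pipeline

`run_pipeline` executes diversity → skyline (× replicates) → pooling →
calibration → optional SFS fits → trend analysis from one YAML
manifest. One master seed fans out to per-stage, per-item child seeds
via SHA-256 of `(master, stage, item)` — every stage is independently
reproducible, and a re-run of an identical manifest is byte-identical
(provenance blocks record input checksums, seeds and parameters, and
deliberately no timestamps). A failing stage halts the run, leaves a
`FAILED` marker naming the stage, and keeps partial outputs.

The demo (`paleodemo demo`) generates a miniature two-ocean analogue:
five taxa (three whale-like, two prey-like), each a two-deme alignment
whose southern deme expands 8-fold toward the present and whose
northern deme changes mildly, a shared warming forcing with an
8.2-kya-like cold spike, and one nuclear folded SFS. Its MCMC preset
(6000 steps, 2 replicates) is deliberately tiny: the demo illustrates
the plumbing and the direction of effects, not publication-grade
posteriors.

## Known limitations

- Single-locus inference: no multi-locus joint estimation.
- Two demes maximum; the between-ocean analyses are pairwise.
- The skyline's deep-time bins are biased by the long-genealogy/high-Θ
  selection effect described above; use the reported n per bin.
- Fixed substitution model per run (HKY with configurable κ); no
  model selection.
- No recombination or selection anywhere in the chain.
- Desk-scale MCMC presets trade Monte-Carlo error for runtime; the
  full-scale preset exists but takes correspondingly long.
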