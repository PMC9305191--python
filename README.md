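# paleodemo

Reconstructing temporal changes in genetic diversity (Θ) and migration
(M) from DNA sequence data, at the scale of post-glacial demographic
history. The package implements the full analysis chain used in
comparative marine phylogeography: single-locus diversity and neutrality
statistics, a structured-coalescent MCMC "skyline" estimator of Θ(t) per
deme and M(t) per direction, a folded-site-frequency-spectrum estimator
of piecewise-constant N_e(t) for genome-wide SNP data, pooling of
replicate MCMC estimates, calibration to calendar years, and cross-taxon
synchrony statistics (Pearson correlations against a temperature series,
ΔΘ fold changes, Mann–Whitney comparisons between ocean basins). A
first-class synthetic-data module generates two-deme structured
coalescent genealogies, finite-sites alignments, folded SFS draws and
temperature-like forcing series for testing and calibration.

## Who this is for

Population geneticists who want a desk-scale, fully scriptable and
testable version of the MIGRATE-N / Stairway-Plot style analysis:
estimate mutation-scaled diversity Θ = 4N_eμ per deme through time from
a single locus (e.g., a mitochondrial control-region alignment with
samples from two ocean basins), or from a folded SFS over 10⁴–10⁵
nuclear sites, then ask whether several taxa changed in synchrony.

## The model

**Structured coalescent.** Backwards in time, while k_d lineages are in
deme d, pairs coalesce at rate k_d(k_d−1)/Θ_d and each lineage in d
migrates to deme s at rate M_{s→d} (mutation-scaled immigration,
receiving convention). Time is measured in expected substitutions per
site, so the estimator and the sequence likelihood (HKY/JC via
Felsenstein pruning) share one clock; conversion to years happens only
at calibration, via per-site mutation rates and generation times.

**MCMC.** Metropolis-coupled sampling over (Θ-epochs, M-epochs,
genealogy with migration paths) under uniform priors, with four move
families: single-parameter updates, node-time slides constrained by the
migration paths, a joint (Θ, node-times) scale move, and a lineage
detach/re-attach move whose migration path is re-simulated from the
structured-coalescent conditional — its Hastings ratio reduces to the
sequence-likelihood ratio. The skyline output reports per-time-bin
medians, SDs and MCMC datapoint counts.

**Pooling and calibration.** Replicate estimates are pooled per time bin
by datapoint-weighted medians, m_p = Σnᵢmᵢ/Σnᵢ, with pooled SD
SD_p = √(Σ(nᵢ−1)SDᵢ²/(Σnᵢ−k)) and a normal 95% CI. Effective size is
N_e = Θ/(4μ) and ages scale to years through μ and the generation time.
Trajectories are clipped to an analysis window (default 1–30 kya).

**SFS demography.** The expected folded SFS of any piecewise-constant
history is computed analytically (lineage-count law of the coalescent ×
combinatorial subtending weights), and a stairway-style Poisson
composite likelihood is maximized over per-epoch Θ.

## Worked example

```python
import numpy as np
from paleodemo import (DemographicScenario, McmcConfig, run_mcmc,
                       simulate_dataset, summarize)

# simulate one "species": one deme, theta = 0.01, 30 sequences, 400 bp
scenario = DemographicScenario.constant(0.01)
sim = simulate_dataset(scenario, n_per_deme=[30], L=400, seed=100)

print(summarize(sim.alignment))
# DiversitySummary(n=30, L=400, S=20, h=11, H=0.8482758620689655,
#                  pi=0.012367816091954023, theta_w=0.012620991776326777,
#                  tajima_D=-0.06989548237343905, fu_Fs=-0.30202778114538864)

cfg = McmcConfig(steps=18_000, burn_in=6_000, thin=12,
                 theta_bounds=(1e-3, 0.1), n_time_bins=10,
                 time_horizon=0.05, seed=0, kappa=1.0)
result = run_mcmc(sim.alignment, cfg)
theta = result.trace["theta_1_e0"]
print(round(theta.median(), 4), np.round(np.quantile(theta, [0.025, 0.975]), 4))
# 0.0145 [0.0075 0.0266]
```

The summary reports 20 segregating sites and nucleotide diversity
π ≈ 0.0124 per site — within coalescent noise of the simulated
Θ = 0.01 — and the posterior 95% credible interval for Θ
(0.0075–0.0266) covers the truth. A two-deme alignment instead yields
posteriors for Θ₁, Θ₂ and the two immigration rates, plus a per-bin
skyline table.

The same flow is available from the shell:

```bash
paleodemo demo --outdir demo_run --seed 1     # miniature two-ocean study
paleodemo diversity --fasta aln.fasta --deme-map demes.tsv
paleodemo skyline --fasta aln.fasta --deme-map demes.tsv --seed 1
paleodemo run --manifest manifest.yaml        # full pipeline
```

## Layout

| module | contents |
| --- | --- |
| `paleodemo.alignment` | FASTA I/O, gap/missing-site filtering, subsampling, series input |
| `paleodemo.diversity` | S, h, H, π, Watterson's θ, Tajima's D, Fu's Fs |
| `paleodemo.simulate` | structured-coalescent simulator, finite-sites mutation, SFS and temperature generators |
| `paleodemo.skyline` | coalescent density, pruning likelihood, the MCMC sampler (`SkylineSampler`) |
| `paleodemo.sfs` | folded SFS from genotypes, expected SFS, stairway fit (`StairwayEstimator`) |
| `paleodemo.calibrate` | replicate pooling, N_e = Θ/4μ, year scaling, window clipping |
| `paleodemo.trend` | gridded trend tables, correlations, ΔΘ, group summaries, Mann–Whitney |
| `paleodemo.pipeline` / `paleodemo.cli` | manifest-driven orchestration and the `paleodemo` command |

See `docs/methods.md` for the model details, parameter defaults, and
known limitations.
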