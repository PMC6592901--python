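# sensorydrive

Tools for testing **sensory drive** in mammal vocal communication: do species
in acoustically cluttered forest habitats hear — and produce — relatively more
high-frequency sound than species of open habitats, and do hearing and call
structure co-evolve?

The package implements the three ingredients such a comparative analysis
needs, end to end and fully testable on synthetic data:

1. **Audiogram indices** (`sensorydrive.audiogram_metrics`).  From a species'
   audiogram (threshold in dB against tone frequency) it computes peak
   sensitivity (PS, the frequency of the threshold minimum, ties averaged),
   band mean thresholds with log2-frequency interpolation at unmeasured band
   edges, and **relative high-frequency hearing sensitivity**
   (relHFHS = mean threshold over 0–20 kHz − mean threshold over 10–20 kHz;
   higher = relatively better high-frequency hearing, invariant to
   between-study offsets), plus cross-species composite audiograms.

2. **Spectral slopes of calls** (`sensorydrive.spectral_acoustics`).
   Recordings are anti-alias down-sampled to 40 kHz (20 kHz Nyquist, matching
   the hearing band), set to a common 60 dB mean intensity, and summarised by
   the **spectral slope** (SS): an OLS line fitted to the per-100-Hz-bin
   amplitude peaks of the whole-call spectrum, in dB/kHz.  Shallower (less
   negative) slopes mean relatively more high-frequency energy.

3. **Bayesian phylogenetic mixed models** (`sensorydrive.phylo_pglmm`).  A
   Gaussian PGLMM ("animal model" at the species level)

   y = Xβ + a + Z_u u + e,  a ~ N(0, σ²ₐ A),  u ~ N(0, σ²ᵤ I),  e ~ N(0, σ²ₑ I)

   with A the phylogenetic correlation matrix derived from a Newick tree,
   fitted by a conjugate Gibbs sampler under diffuse N(0, 10¹⁰) priors on the
   fixed effects and inverse-Gamma(0.001, 0.001) priors on variances.
   Posterior summaries report means, 95% HPD intervals, pMCMC (twice the
   smaller posterior sign tail, floored at 2/N), phylogenetic heritability
   H² = σ²ₐ/(σ²ₐ+σ²ₑ), and the classical convergence toolkit (Gelman–Rubin
   PSRF, Heidelberger–Welch stationarity, autocorrelation-based ESS).

A synthetic-data module (`sensorydrive.synthetic_data`) generates ultrametric
Yule trees, trait tables with controlled fixed effects and phylogenetic
variance, U-shaped audiograms, and harmonic source–filter calls with a
controlled source spectral slope, so every stage can be validated without any
downloads.  The `sensorydrive.pipeline` module binds the three analyses
(hearing vs habitat, slope vs habitat, slope vs hearing within forest
species) as presets.

## Worked example

Simulate a comparative dataset with a strong habitat effect
(β_habitat = −5, σ²ₐ = 3, σ²ₑ = 1 on a 25-taxon tree) and fit the
hearing-vs-habitat preset:

```bash
sensorydrive simulate traits --n-taxa 25 --seed 3 --out demo/
# bind the simulated columns to the preset's names
python - <<'PY'
import pandas as pd
df = pd.read_csv("demo/species.csv").rename(columns={
    "covariate": "log10_head_size", "response": "peak_sensitivity_khz"})
df.to_csv("demo/species.csv", index=False)
PY
sensorydrive run --preset hearing_vs_habitat --table demo/species.csv \
    --tree demo/tree.nwk --settings test --seed 1 --out demo/report
```

which prints (abridged):

```
intercept: mean=-0.3733 HPD=[-2.701, 2.123] pMCMC=0.7213
beta_habitat: mean=-5.123 HPD=[-6.499, -3.828] pMCMC=0.0006667
beta_log10_head_size: mean=0.8452 HPD=[0.1568, 1.489] pMCMC=0.018
sigma2_a: mean=6.366 HPD=[0.0007737, 12.85]
sigma2_e: mean=0.8092 HPD=[0.000269, 3.054]
h2: mean=0.8343 HPD=[0.2853, 1]
```

The habitat coefficient is the other-minus-forest contrast (forest is the
reference level), so the simulated −5 effect — forest species five units
higher — is recovered with a 95% HPD excluding zero and pMCMC at its 2/N
floor.  With only 25 species the variance components are, as expected, only
weakly identified (wide HPDs).  `demo/report/report.json` holds the full
summaries (H², ESS, PSRF, Heidelberger results, seeds, input hashes);
`demo/report/chains.csv` the retained posterior draws.

Spectral slopes from synthesized calls, through the same preprocessing a real
recording would get:

```bash
sensorydrive simulate calls --seed 2 --out calls/
sensorydrive slope --manifest calls/calls.csv --out calls/slopes.csv
```

recovers the five source slopes {−8, −6, −4, −2, 0} dB/kHz with bias below
0.1 dB/kHz (`calls/slopes.csv`: −7.96, −5.94, −4.02, −2.02, −0.02).

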