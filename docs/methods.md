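# Methods

## The generative model

`metabarsim` treats an amplicon (metabarcoding) read-count dataset as the
outcome of a chain of sampling and amplification processes acting on
individual DNA molecules. For a community of `I` species with template
concentrations `lambda_i` (copies/µL) and per-cycle amplification
efficiencies `a_i ∈ (0, 1]`, one technical replicate `j` is generated as

| step | process | distribution |
|---|---|---|
| 1 | template subsampling into the PCR tube | `W_ij ~ Poisson(lambda_i · V)` |
| 2 | target PCR (`Npcr1` cycles) | `X1_ij ~ Poisson(W_ij · (1 + a_i)^Npcr1)` |
| 3 | bead cleanup / carry-over | `X2_ij ~ Binomial(X1_ij, π)` |
| 4 | indexing PCR (`Npcr2` cycles, shared efficiency) | `X3_ij ~ Poisson(X2_ij · 1.9^Npcr2)` |
| 5 | sequencing | `Y_j ~ Multinomial(N_reads,j, p_j)`, `p_ij = X3_ij / Σ_i X3_ij` |

Step 2 is a Poisson whose mean is itself a random (Poisson) count scaled by
geometric growth — a Poisson-stopped-sum (Neyman Type A) construction that
produces the overdispersion and zero inflation characteristic of real
amplicon data. Zeros propagate structurally: `W_i = 0` forces `Y_i = 0`, so
the overall non-detection probability decomposes exactly as

```
p(Y=0) = p(W=0) + p(Y=0 | W>0) · (1 − p(W=0)),     p(Y=0 | W=0) = 1.
```

The first term is rarity (no template molecule made it into the tube, with
closed form `exp(−lambda·V)`); the second is amplification/sequencing loss.
Separating the two is the point of the simulator.

### Default protocol parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `volume_uL` (V) | template volume pipetted into the PCR | 1 | µL |
| `n_pcr1` | target-PCR cycles | 35 | cycles |
| `n_pcr2` | indexing-PCR cycles | 10 | cycles |
| `cleanup_fraction` (π) | fraction of first-PCR product carried forward | 0.20 | — |
| `index_efficiency` | shared per-cycle efficiency of the indexing PCR | 0.9 | — |
| depth rule | sequencing depth per replicate | discrete uniform 60,000–140,000 | reads |

These defaults are the standard two-step library protocol the model is
parameterized for; all are overridable per call or via the YAML config.

## Scenario engine

The factorial design crosses community richness (default 4, 10, 30, 50),
a shared concentration level (default 18 log-spaced levels from 0.5 to
10,000 copies/µL) and an efficiency-variation parameter `gamma`
(default 5, 10, 20, 100, 1000, 10^6), i.e. 432 scenarios. Efficiencies are
drawn `a ~ Beta(0.7·gamma, 0.3·gamma)`: mean 0.7 at every `gamma`, variance
`0.21 / (gamma + 1)`, so `gamma = 5` is strong among-species amplification
bias and `gamma = 10^6` effectively none.

Design choices where the design was genuinely open:

- **Efficiency redraw scope.** The efficiency vector is redrawn every
  realization (default), so realized `a_i` values trace the whole Beta
  distribution and records can be binned by efficiency; a
  `redraw_efficiencies=False` switch fixes one vector per scenario instead.
- **Concentration spacing.** Levels are log-spaced because the interesting
  transitions (template zeros below ~10 copies/µL; amplification-driven
  zeros above) span four orders of magnitude; explicit level lists are
  accepted everywhere.
- **Uneven communities.** An abundance profile supplies raw weights which
  are normalized by their mean (`lambda_i = level · w_i / mean(w)`), so the
  level keeps its meaning as the community-average concentration whether or
  not the raw weights sum to 1.
- **Realization count.** Defaults to 2,000 per scenario — with 50 taxa this
  already gives ≥ 10^5 records per scenario cell, enough to estimate the
  pooled non-detection fractions reported by `scripts/acceptance.py` to
  about ±0.005; the full design at 50,000 realizations is a configuration
  change, not a code change.

## Numerical choices

- **Large means.** `(1 + a)^35` reaches ~10^8, so post-PCR counts reach
  10^12–10^15. Poisson and binomial draws are exact (integer) for means up
  to 10^7 and switch to a rounded Gaussian with matched mean and variance
  (clamped at 0) above; at the switch point the coefficient of variation is
  ~3·10^-4, far below any quantity the package reports.
- **Proportions.** `p = X3 / ΣX3` is computed via logs shifted by the
  maximum when any count exceeds 10^15, preserving ratios without overflow.
- **Efficiency bound.** `a` is accepted on the half-open interval (0, 1] so
  the perfect-doubling case `a = 1` is expressible.
- **Degenerate replicates.** If every `X3_i = 0` the replicate is recorded
  with all-zero reads and a `degenerate` flag rather than raised: such a
  library would still be sequenced (yielding only off-target reads), and
  non-detection tallies must include it. The read-conservation invariant
  `ΣY = N_reads` therefore applies to non-degenerate replicates only.
- **Determinism.** Every stochastic operation takes an explicit
  `numpy.random.Generator`; the grid assigns each scenario a spawned child
  of the master seed, so results are reproducible and order-independent.

## Efficiency calibration

Read counts are compositional, so absolute efficiencies are not
identifiable; the package estimates the log-scale per-cycle efficiency of
species `i` relative to a reference `R`:

```
alpha_i = log((1 + a_i) / (1 + a_R))
```

`alpha_R = 0` by construction, `alpha < 0` means worse-than-reference
amplification, and multiplying every species' per-cycle growth `(1 + a)` by
a common factor leaves every `alpha` unchanged (tested). A raw-ratio
accessor `a_i / a_R` is provided as a secondary scale. Given a mock
community with known inputs `lambda_i`, the moment estimator inverts the
expected read ratio per replicate,

```
alpha_hat_i = (1/Npcr) · [log(Y_i / Y_R) − log(lambda_i / lambda_R)],
```

and averages over replicates, reporting the between-replicate standard
error. Zero-read observations are dropped rather than pseudocounted — a
pseudocount biases `alpha` for precisely the low-efficiency species of
interest (a `pseudocount` flag exists for sensitivity analysis). Species
never observed get an undefined (NaN) `alpha`, never 0. The `auto`
reference is the species observed in every replicate with the highest mean
read count. Species with `alpha` strictly below −0.07 are labelled the
low-efficiency group; this threshold separates species whose expected reads
per input molecule differ by roughly an order of magnitude.

Mass-to-copies conversion for fluorometric (Qubit) quantifications uses
`copies/µL = conc[ng/µL] · N_A / (length_bp · 650 g mol⁻¹ bp⁻¹ · 10^9 ng/g)`.

## Replicate QC

Technical replicates are filtered in two passes: depth strictly below
30,000 reads (first), then mean pairwise Bray–Curtis dissimilarity to
depth-passing sister replicates of the same sample strictly above 0.7.
Bray–Curtis is computed on depth-normalized relative abundances by default
(depth varies ~30× across real libraries; a raw-count mode is available),
over the zero-filled union of the sisters' species. Samples reduced to a
single replicate skip the dissimilarity rule. Each pass evaluates all
replicates simultaneously; a one-pass rule is not formally idempotent for
adversarial inputs (removing a replicate changes its sisters' means), but
is on realistic tables, and matches how such filters are applied in
practice. Non-detections are tallied strictly within samples: a replicate
counts as a non-detection for a species only if a sister replicate of the
same sample detected that species, so true absences contribute nothing.

## What the synthetic fixtures do and do not show

The fixture generator drives the generative core itself (it is not an
independent model): it emulates a mock community — known species at known
concentrations, several technical replicates, optionally a sabotaged
shallow replicate — and writes the generating truth alongside. Passing
parameter-recovery tests therefore show that the estimator correctly
inverts *this* generative process at realistic depths and replicate counts.
They do not show that real libraries obey the model: real data add
off-target amplification, chimeras, index hopping, tag jumping, polymerase
errors and cycle-to-cycle efficiency drift, none of which are modeled
(deliberately — see the module docstrings). Calibrating against real mock
communities requires real sequencing data and an upstream bioinformatics
pipeline, both outside this package's scope.

## Known limitations

- Only the two-step (target + indexing) library protocol is modeled.
- Amplification efficiency is constant across cycles and templates; no
  plateau-phase saturation.
- The full Bayesian hierarchical calibration of amplification efficiencies
  is out of scope; the moment estimator here is simpler, unbiased in the
  tested regimes, but has no pooling across species and no posterior.
- At 20 target-PCR cycles the pooled non-detection fraction for taxa with
  `a < 0.3` computed over the default concentration grid sits just below
  0.5 (~0.45): with fewer cycles the efficiency spread compresses, and taxa
  just under the cutoff are detected often at high concentrations. The
  fraction exceeds 0.5 only for lower cutoffs or rarer templates.
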