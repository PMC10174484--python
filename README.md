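# metabarsim

Mechanistic simulation and calibration of metabarcoding read counts.

Metabarcoding (amplicon sequencing of a conserved marker gene) routinely
shows *non-detections*: a species with thousands of reads in one technical
PCR replicate and zero in a sister replicate of the same DNA extract. Are
those zeros caused by rarity — too few template molecules pipetted into the
tube — or by poor species-specific PCR amplification? `metabarsim` answers
that question by simulating the laboratory process that generates the data,
for eDNA, microbiome and diet-analysis practitioners who need to decide
which zeros in their tables are informative.

## The model

One technical replicate `j` of an `I`-species community is generated by a
chain of linked stochastic processes:

```
W_ij  ~ Poisson(lambda_i · V)                      template subsampling
X1_ij ~ Poisson(W_ij · (1 + a_i)^Npcr1)            target PCR (species-biased)
X2_ij ~ Binomial(X1_ij, pi)                        cleanup carry-over
X3_ij ~ Poisson(X2_ij · (1 + 0.9)^Npcr2)           indexing PCR (species-neutral)
Y_j   ~ Multinomial(N_reads,j , p_j),   p_ij = X3_ij / sum_i X3_ij
```

`lambda_i` is the template concentration (copies/µL), `V` the pipetted
volume, and `a_i ∈ (0, 1]` the per-cycle amplification efficiency
(`a = 1` doubles the pool each cycle). Because `W = 0` forces `Y = 0`, the
non-detection probability decomposes exactly into a rarity term and an
amplification term:

```
p(Y=0) = p(W=0) + p(Y=0 | W>0) · (1 − p(W=0)),   p(W=0) = exp(−lambda·V)
```

The package provides:

- `metabarsim.core` — the per-replicate generative chain;
- `metabarsim.scenarios` — a factorial scenario engine (richness ×
  concentration × efficiency variation, `a ~ Beta(0.7γ, 0.3γ)`) with
  non-detection and read-count summaries;
- `metabarsim.efficiency` — mock-community calibration of log-scale
  relative amplification efficiencies `alpha_i = log((1+a_i)/(1+a_R))`,
  low/high efficiency grouping, and ng/µL → copies/µL conversion;
- `metabarsim.qc` — read-table I/O, depth and Bray–Curtis replicate
  filters, and within-sample non-detection tallies;
- a `metabarsim` CLI (`simulate`, `estimate`, `qc`, `fixture`).

## Worked example

Simulate 50-taxon communities with strong among-species efficiency
variation (`gamma = 5`) at a rare (1 copy/µL) and an abundant
(100 copies/µL) concentration, 2,000 replicates each:

```python
from metabarsim.scenarios import build_scenario_grid, run_grid, summarize_nondetection

grid = build_scenario_grid(richness_levels=[50], lambda_levels=[1.0, 100.0],
                           gamma_levels=[5.0], n_realizations=2000, master_seed=7)
records = run_grid(grid)
print(summarize_nondetection(records)[
    ["lambda_level", "n", "p_Y0", "p_W0", "p_Y0_given_Wpos"]].to_string(index=False))

low = records[records.efficiency < 0.4]
print("pooled p(Y=0 | a<0.4) =", round(float((low.Y == 0).mean()), 3))
```

```
 lambda_level      n    p_Y0    p_W0  p_Y0_given_Wpos
          1.0 100000 0.44658 0.36776         0.124668
        100.0 100000 0.13809 0.00000         0.138090
pooled p(Y=0 | a<0.4) = 0.974
```

Reading this: at 1 copy/µL almost all non-detection (0.447) is rarity —
0.368 of records had no template molecule in the tube at all
(`exp(−1) ≈ 0.37`). At 100 copies/µL template zeros vanish entirely, yet
13.8% of records are still zeros: those are amplification-driven, and they
concentrate in the low-efficiency tail — a taxon whose realized efficiency
fell below 0.4 was missing from 97% of the records it appears in. Zeros at
high concentration are a signature of amplification bias, not absence.

Calibrating efficiencies from a mock community and QC-ing replicates from
the shell:

```sh
metabarsim fixture --out-dir demo --seed 4 --shallow rep2:5000
metabarsim qc demo/fixture_reads.csv --out-dir demo/qc
metabarsim estimate demo/fixture_reads.csv demo/fixture_inputs.csv --out demo/eff.csv
```

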