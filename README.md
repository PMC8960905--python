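# rankdyn

Dynamics of ranking lists: a displacement–replacement model of how fixed-size
rankings (top-N0 lists embedded in an N-element system) evolve, together with
the empirical observables and fitting machinery that connect the model to
longitudinal ranking data.

What it does:

* **Measure** rank flux `F_t`/`F`, rank turnover `o_t`/`ȯ`, per-rank change
  probability `C(R)`, and empirical displacement histograms `P_{x,t}` (with
  optional Savitzky–Golay smoothing) on any long-format ranking table.
* **Simulate** the stochastic model: per micro-step of length `1/N`, a random
  element jumps to a uniformly random rank with probability `τ` (displacing
  the elements in between) and a random element is replaced in place by a
  brand-new one with probability `ν`. A fast vectorized tracker follows the
  exact marginal dynamics of a tagged element over many realizations.
* **Evaluate the theory**: `P_{x,t} = e^{-νt}(L_t + D_{x,t})` with the flat
  jump term `L_t = (1-e^{-τt})/N` and a genetic-drift-type diffusion kernel
  `D_{x,t}` (Gaussian approximation or an implicit, mass-conserving
  finite-difference solver for the degenerate diffusion
  `∂D/∂t = αx(1-x)∂²D/∂x²`, `α = τ/N`), closed forms for mean flux and mean
  turnover rate, per-step regime weights, and survival probabilities.
* **Fit and classify**: invert the flux/turnover equations for `(τ̂, ν̂)` from
  measured `(F, ȯ, p)` by bracketed root finding, rescale onto the plane
  where open systems collapse onto the universal curve `τ_r·ν_r = 1`,
  classify the dominant regime (Lévy / diffusion / replacement), run
  subsampling analyses, and bootstrap-test the distance to the curve.

## Command line

All commands write a `<output>.provenance.json` sidecar (resolved options,
package version, seed) so stochastic runs are reproducible bit-for-bit. A
YAML config file can supply per-command defaults (`rankdyn --config cfg.yaml
...`); explicit flags win.

```sh
# simulate the model and write the observed top-N0 table
rankdyn simulate --n 100 --n0 80 --tau 0.1 --nu 0.2 --t 50 --seed 7 -o sim.tsv

# measure flux, turnover, rank change, displacement histograms
rankdyn measure sim.tsv --out summary.json --change --pxt 1 --pxt 5

# closed-form displacement kernel on the model grid
rankdyn theory pxt --tau 0.1 --nu 0.2 --n 100 --r 0.5 --t 1 --t 5 \
    --backend gaussian -o kernel.tsv

# fit (tau, nu), rescale, classify the regime
rankdyn fit sim.tsv -o fit.json

# subsampling and universal-curve bootstrap test
rankdyn subsample sim.tsv --k 1 --k 2 --k 4 --k 8 -o sub.tsv
rankdyn curve-test sim.tsv --n-boot 200 --seed 1 -o test.json

# convert a raw score table to ranks; emit preset fixtures
rankdyn convert --scores scores.tsv --n0 100 -o ranks.tsv
rankdyn fixtures --preset open-diffusive -o fixture.tsv
```

Rank tables are long-format TSV/CSV with header columns
`time, rank, element[, score]`: ranks `1..N0` contiguous per observation,
rank 1 best, UTF-8, scores non-increasing in rank.

## Notes on approximations

The closed-form flux and turnover expressions are continuum / first-order
approximations of the discrete dynamics. Measured turnover on simulated data
falls below the closed form by a factor approaching `(1-e^{-ν})/ν` as `ν`
grows, which propagates into a positive bias of `τ̂` (and a smaller negative
bias of `ν̂`) when inverting at large per-observation replacement rates; the
Gaussian displacement kernel likewise carries a small systematic
discreteness error near its peak at short lags. The test suite documents
both effects quantitatively.
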