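# modalage

Old-age mortality disparities measured with the **modal age at death** — the
adult age *M* at which the life-table age-at-death distribution peaks — instead
of indicators tied to a fixed "old" age threshold such as life expectancy at 65.

`modalage` is aimed at demographers and epidemiologists who monitor
socioeconomic mortality differences from stratified death-count and exposure
tables (register extracts, Human Mortality Database files). It provides:

* **P-spline hazard smoothing.** Death counts `D(x,t)` with person-years of
  exposure `E(x,t)` are modelled as `D ~ Poisson(E·μ)`, with `log μ` expanded
  on an equally-spaced cubic B-spline basis over age — and, in the
  two-dimensional variant, a tensor-product basis over age × calendar year.
  An order-2 difference penalty on adjacent coefficients controls smoothness;
  its weight λ (one per dimension, one set per stratum) is chosen by
  minimizing `BIC = deviance + log(n)·ED`, where `ED` is the trace of the
  influence matrix.
* **Life-table indicators from the smooth hazard.** On a 0.01-year grid the
  fitted hazard gives survival `S(x) = exp(−∫μ)` (radix 1 at the first
  observed age, 31) and the age-at-death density `f = μ·S`, from which the
  package extracts: the modal age at death *M* (argmax of `f` above a floor,
  refined by quadratic interpolation), the compression measure SD(M+)
  (root-mean-square deviation of deaths above *M*, measured from *M*),
  conditional life expectancies on the attained-age convention
  `e_x = x + ∫ₓS/S(x)`, proportions surviving from 31 to *M*/65/75, and ages
  at given survival quantiles.
* **A synthetic-data generator with closed-form ground truth.**
  Gompertz–Makeham hazards `μ(x,t) = c + a(1−r)^t e^{bx}` per stratum, with
  Poisson sampling given exposures. For `c = 0` the true mode is
  `(1/b)·ln(b/a)`, so every downstream stage is testable without restricted
  register data.
* **Robustness analyses**: sensitivity of *M* to left-truncating the age
  range (start ages 31/35/40), and a comparison of *M*-trends from 2D
  smoothing versus year-by-year 1D smoothing (roughness = mean squared second
  difference).

## Worked example

Run the full pipeline on the built-in six-stratum scenario (3 occupational
classes × 2 sexes, ages 31–110, 45 years, improving Gompertz mortality):

```python
from modalage import PipelineConfig, run_full

res = run_full(PipelineConfig(seed=1, verbosity=0))
male = res.table[res.table.stratum.str.startswith("male")]
print(male[male.year.isin([1971, 2015])][
    ["stratum", "year", "M", "e65", "p_surv_M", "p_surv_65", "p_surv_75"]
].round(3).to_string(index=False))
```

```
             stratum  year      M    e65  p_surv_M  p_surv_65  p_surv_75
male:lower_nonmanual  1971 74.990 75.969     0.372      0.700      0.372
male:lower_nonmanual  2015 81.639 80.320     0.370      0.833      0.601
         male:manual  1971 73.507 75.100     0.373      0.662      0.318
         male:manual  2015 80.123 79.263     0.371      0.808      0.553
male:upper_nonmanual  1971 76.982 77.192     0.371      0.746      0.444
male:upper_nonmanual  2015 83.675 81.791     0.370      0.862      0.661
```

Reading the numbers: the modal age at death rises by ~6.7 years in every
class while the class hierarchy (upper non-manual highest) persists; the
proportion surviving from 31 to the fixed ages 65 and 75 climbs steeply and
differs across classes, yet the proportion surviving to the *moving* target
*M* stays pinned just below 40 % (here ≈ 0.37) in every class and year — the
property that makes *M* compare like with like across time and strata.

The same analyses are available from the shell:

```sh
modalage simulate --seed 1 ds.csv          # write a synthetic dataset
modalage full --input-path ds.csv --outdir out/
modalage sensitivity --seed 1              # left-truncation robustness of M
modalage compare-smoothers --seed 1        # 2D vs yearly-1D M-trend roughness
modalage indicators --seed 1 --plot trends.png
```

User-supplied data (e.g. HMD deaths/exposures) are ingested from the same
long-format CSV (`stratum,sex,class,age,year,deaths,exposure`).

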