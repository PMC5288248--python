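# tssprev

Prevalence dependence of the true skill statistic (TSS) in
presence/absence model evaluation.

## The problem

Species distribution models (and binary classifiers generally) are often
scored with the true skill statistic

```
TSS = TPR + TNR − 1,      TPR = TP/(TP+FN),  TNR = TN/(TN+FP)
```

also known as the Youden index or Peirce/Kuipers skill score.  TSS is
widely believed to be independent of prevalence π = P/N (the fraction of
presence observations), which would make it safe for comparing models of
different species or of the same species on different datasets.  That
belief rests on two shaky legs:

1. **A circular fixed-rate argument.**  Holding TPR and TNR constant while
   varying prevalence necessarily keeps TSS = TPR + TNR − 1 constant — the
   design cannot detect a prevalence effect.  Any residual wiggle in such
   a sweep is just the constraint that confusion-matrix cells are integers.
2. **Idealized observations.**  TSS is prevalence independent in the
   binary case only if species occupy exactly the suitable sites.  Under
   realistic observation errors — missed presences, fallacious absences
   (suitable but vacant sites), fallacious presences (sink populations) —
   closed-form TSS contains π explicitly.

Moreover, the dominant practice scores a continuous prediction by the
*maximum* TSS over a grid of probability cutoffs.  Because the cutoff is
chosen from the data, the mean of the maxima over-estimates the
theoretical value E[TSS](x_c) = F₀(x_c) − F₁(x_c) (where F₁, F₀ are the
score distributions conditional on presence/absence), and the inflation is
U-shaped in prevalence at small samples: rare or very common species look
better than they are.

This package implements all of those pieces as a tested library with a
CLI: confusion-matrix metrics, the closed-form error-scenario TSS, a
beta-distribution simulator of predicted probabilities, the factorial
maximum-TSS Monte Carlo experiment, and the theoretical optima.

## Worked example

Theoretical optima of the four discrimination-quality scenarios (beta
score densities f₁ ~ Beta(α,1) for presences, mirrored for absences):

```
$ tssprev theory
scenario,cutoff_star,tss_star
quadratic,0.5,0.75
linear,0.5,0.5
square_root,0.5,0.2928932188
p16,0.5,0.0423967193
```

Every scenario's densities cross at 0.5, so an oracle who knew the curves
would cut there; `tss_star` is the best TSS the model can truly deliver.
Now compare that with what the data-driven maximum-TSS rule reports:

```python
from tssprev import SimulationConfig, run_experiment, bias_table

cfg = SimulationConfig(scenarios=("square_root",),
                       sample_sizes=(100, 1000, 10000),
                       prevalence_grid=(0.05, 0.5), n_reps=200, seed=1)
print(bias_table(run_experiment(cfg)).round(4).to_string(index=False))
```

```
   scenario  n_total  prevalence  mean_max_tss  tss_star   bias
square_root      100        0.05        0.4675    0.2929 0.1746
square_root      100        0.50        0.3364    0.2929 0.0435
square_root     1000        0.05        0.3339    0.2929 0.0410
square_root     1000        0.50        0.3029    0.2929 0.0100
square_root    10000        0.05        0.2985    0.2929 0.0056
square_root    10000        0.50        0.2943    0.2929 0.0014
```

A weakly discriminating model whose true skill is 0.29 is reported as 0.47
when it is fit to 100 sites of which 5 are presences — a +0.17 artifact of
prevalence and sample size alone, which fades as N grows.

Other entry points: `tssprev simulate` (full factorial study, results CSV
plus a JSON manifest), `tssprev closed-form` (error-scenario TSS tables,
including both variants of the fallacious-presence formula), `tssprev
allouche` (the fixed-rate sweep, real vs integer cells), `tssprev report`
(pivot/bias summaries of a results file), `tssprev fixtures` (small test
datasets).

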