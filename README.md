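# netmetareg

Network meta-regression (NMR) for trial-level contrast data, with per-trial
**contribution matrices** and the diagnostic graphs that show which studies —
and which covariate values — each NMR result actually rests on.

## The problem

Network meta-analysis combines direct and indirect randomised evidence on
several treatments. Adding a study-level covariate (a meta-regression) lets
the treatment effects vary with, say, average patient age or randomisation
year. But an NMR result for one comparison is assembled from evidence flowing
through the whole network, so it is far from obvious which trials — and which
covariate values — drive it. A result may be quietly interpolated across a
covariate range where no contributing trial sits, or extrapolated beyond the
range entirely. This package is for systematic reviewers and methodologists
who need to see that before drawing clinical conclusions.

## The model

For trial *i* with arms *k* = 1..*A*ᵢ, treatments *t*ᵢₖ ∈ {1..*T*}, observed
contrasts *y*ᵢₖ (arm *k* vs arm 1) with variances *v*ᵢₖ and study covariate
*c*ᵢ:

    y_ik ~ N(θ_ik, v_ik),    θ_ik = δ_ik + β_{t_i1, t_ik} c_i

with consistency relations d_{t_i1,t_ik} = d_{1,t_ik} − d_{1,t_i1} and
β_{t_i1,t_ik} = β_{1,t_ik} − β_{1,t_i1}. Fixed-effect models set
δ_ik = d_{t_i1,t_ik}; random-effects models draw δ_ik around it with common
between-trial variance σ² (σ²/2 covariance within multi-arm trials). The
basic interaction coefficients β_{1t} may be **independent**, **exchangeable**
(β_{1t} ~ N(B, υ²)) or **common** (β_{1t} = β, functional coefficients zero).

Estimation is generalised least squares given the variance components: σ² by
REML or, on the Bayesian path, a Gibbs sampler on the marginal likelihood
with vague N(0, 100000) priors, a Uniform(0, 10) prior on σ, and DIC
(D̄ + p_D) for model comparison.

**Contributions.** Every NMR result — an effect at the covariate centre or a
coefficient, for any comparison — is c′θ̂ = w′y with
w′ = c′(X′V⁻¹X)⁻¹X′V⁻¹, so data row *j* (one observed contrast, or one prior
pseudo-row) contributes 100·|wⱼ|/Σ|w| percent. Rows sum to 100%; summing
within studies or covariate bins gives the study-level and heat-plot views.
The package also implements the variance-decomposition study weights of
Riley et al. (100·[S Fᵢ S]ₚₚ/Sₚₚ with Fᵢ the study's Fisher information) and
a comparison between the two methods.

**Graphs.** Five diagnostic graph types: the network covariate distribution
diagram, covariate-contribution plot, heat plot, contribution-NMR plot and
heat-NMR plot.

## Worked example

A built-in deterministic 3-treatment network (6 studies, one of them
three-arm, with a covariate gap between 5 and 25):

```python
import netmetareg as nm

ds = nm.center_covariate(nm.triangle_fixture(), "mean")
dsys = nm.build_design(ds, nm.ModelSpec(effects="fixed", interactions="independent"))
fit = nm.fit_gls(dsys)
print(fit.params.round(3))
# d(B)       0.622
# d(C)       0.002
# beta(B)    0.012
# beta(C)    0.012

study = nm.aggregate_contributions(nm.contribution_table(dsys), "study")
print(study.values.round(2))
#                    t01    t02    t03    t04    t05    t06
# d:B_vs_A@center  26.88  23.83   0.82  17.85  12.81  17.81
# d:C_vs_A@center   2.11  11.30  24.06  35.66   9.86  17.01
# d:C_vs_B@center  18.84  10.09  17.51  11.53  16.61  25.41
# beta:B_vs_A      28.97  23.71   5.78  18.57  13.68   9.30
# beta:C_vs_A       5.23  13.33  26.17  26.07  12.47  16.73
# beta:C_vs_B      18.55   6.75  19.69   9.25  22.66  23.09

binned = nm.aggregate_contributions(study, "bin", nm.BinSpec((0., 10., 20., 35.)))
print(binned.values.round(1))
#                  0–10  10–20  20–35
# d:B_vs_A@center  45.5    0.0   54.5
# d:C_vs_A@center  43.2    0.0   56.8
# d:C_vs_B@center  61.8    0.0   38.2
# beta:B_vs_A      44.0    0.0   56.0
# beta:C_vs_A      48.1    0.0   51.9
# beta:C_vs_B      61.3    0.0   38.7

est, (lo, hi) = nm.predict_effect(fit, ("B", "A"), 30.0)
print(f"B vs A at covariate 30: {est:.3f} (95% CI {lo:.3f} to {hi:.3f})")
# B vs A at covariate 30: 0.780 (95% CI 0.319 to 1.241)
```

Reading the output: every contribution row sums to 100% across studies; the
study t06 (the three-arm trial) contributes to every result; and the middle
bin 10–20 is exactly zero for every result — each NMR result is interpolated
across that covariate range, which is precisely what the heat plot shades.

The same workflow is available from the shell:

```sh
netmetareg simulate --out sim.csv --seed 4 --studies 50
netmetareg fit --config analysis.yaml --out results/
netmetareg contribute --config analysis.yaml --out results/ --method both
netmetareg plot --config analysis.yaml --out results/ --kind all
```

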