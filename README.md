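# longiv

Instrumental-variable estimation of **time-varying treatment effects** from
longitudinal patient-level data.

Observational comparative-effectiveness studies of sustained treatments (e.g.
staying on one biologic drug versus another for 18 months) must deal with
confounders that evolve with treatment, and usually with confounders nobody
measured. A time-varying instrument — a variable like a physician's current
prescribing preference that predicts the treatment actually taken at each
follow-up period but affects the outcome only through treatment — offers a
route around unmeasured confounding, giving as many instruments as there are
treatment decision points.

`longiv` implements two estimators of the average treatment effect
ATE = E[Y(1,…,1) − Y(0,…,0)] of sustained treatment for panels with a binary
treatment A_t, binary instrument Z_t and confounders L_t at periods
t = 1..K and a continuous end-of-study outcome Y:

- **IV g-estimation of a structural nested mean model (SNMM).** The model
  E[Y(ā_t, 0) − Y(ā_{t−1}, 0) | …] = β_t a_t asserts that treatment at t
  shifts the counterfactual outcome mean by β_t. G-estimation finds the β at
  which the de-treated outcome H₁ = Y − Σ_t β_t A_t is uncorrelated with the
  residualised instruments Z_t − E[Z_t | M_t], where M_t = (Ā_{t−1}, Z̄_{t−1})
  is the conditioning history. The estimating equations are linear in β and
  solved in closed form: β̂ = Yᵀ(Z − Ê(Z)) (Aᵀ(Z − Ê(Z)))⁻¹; the ATE is Σ_t β_t.
- **Inverse probability of IV weighting (IV-W) of a marginal structural model
  (MSM).** The MSM E[Y(a)] = β₀ + Σ_t β_t a_t is fitted by weighted least
  squares with signed subject weights W̄ = Π_t (−1)^{1−Z_t} P(Z_t|M_t) Δ_t,
  where Δ_t is the compliance difference — the shift in the treatment pmf
  when the instrument flips from 0 to 1. Standard and "delta" weight
  stabilisers and Tukey-fence weight trimming are included.

Around the estimators the package provides: the longitudinal panel data model
with wide/long CSV I/O; QALY outcome construction from per-phase EQ-5D
utilities; preference-based instrument construction from prescription records
(proportion-above-median, modal-drug and last-prescription definitions);
nonparametric subject-level bootstrap with percentile confidence intervals;
weak-instrument diagnostics (per-period Z–A correlation and the
Sanderson–Windmeijer conditional F-statistic); a fully specified simulation
mechanism with analytic and interventional Monte-Carlo truths; and a
Monte-Carlo scenario runner reporting bias, RMSE, Monte-Carlo error and CI
coverage.

## Worked example

```python
import longiv as lv

# a panel of 5000 subjects, 3 treatment periods, strong instrument
panel = lv.simulate(lv.DGMParams(alpha=0.5), n=5000, seed=11)

est = lv.estimate_iv_g(panel)
print("per-period effects:", est.beta.round(3), " ATE:", round(est.ate, 3))

boot = lv.bootstrap(panel, lv.iv_g_estimator(), b=500, seed=11)
print("95% CI:", [round(v, 3) for v in lv.percentile_ci(boot.draws)])

print("conditional F:", lv.conditional_f(panel).round(1))
```

prints

```
per-period effects: [2.069 1.92  0.987]  ATE: 4.975
95% CI: [4.791, 5.161]
conditional F: [4267.1 4028.3 4268.4]
```

The simulated mechanism has true per-period effects (2, 2, 1) — each period's
direct effect plus its path through the next period's confounder — so the
true ATE is 5; the g-estimate lands close, its percentile interval covers the
truth, and conditional F-statistics far above 10 confirm the instruments are
strong. The same panel can be analysed by weighting:

```python
msm = lv.fit_iv_w(panel, lv.HistorySpec(confounder_subset=(0,)),
                  stabiliser="standard")
print("IV-W ATE:", round(msm.ate, 3))   # IV-W ATE: 4.883
```

A command-line interface mirrors the library:

```sh
longiv simulate --n 1000 --alpha 0.5 --seed 1 --out panel.csv
longiv estimate -i panel.csv --method iv_g --b 500 -o report.json
longiv diagnose -i panel.csv
longiv simstudy --n 1000 --alpha 0.5 --method iv_w --stabiliser standard --m 200
```

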