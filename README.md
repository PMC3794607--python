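# trmbdyn

Dynamic perturbation analysis of a transcription-factor-driven metabolic
gene regulatory network.

## The problem

Steady-state measurements of gene expression and promoter occupancy are
poor at separating direct regulation from secondary effects: the
equilibrium level of a transcript reflects every regulator acting on it.
A cleaner experiment perturbs the system — here, a nutrient pulse that
makes a sugar-responsive transcription factor (TF) such as TrmB in the
haloarchaeon *Halobacterium salinarum* release its target promoters
within minutes — and follows both TF–promoter occupancy (ChIP-qPCR fold
enrichment, `B(t)`) and mRNA levels (`m(t)`) over time in a parent
strain and a TF-knockout strain.

`trmbdyn` implements the full downstream analysis of such an experiment:

1. **Decay constants.** Per-gene first-order degradation rates
   `K_deg` are fitted to transcription-shut-off time courses
   (`m(t) = e^{-K_deg t}` after normalisation to *t* = 0), with
   standard errors.
2. **Synthesis rates.** The production–degradation balance
   `S(t_i) = dm/dt(t_i) + K_deg · m(t_i)` deconvolves degradation from a
   measured trace; derivatives on the nonuniform grid use
   opposite-interval-weighted secants (exact for quadratics).
3. **Binding-driven ODE.** Each gene is modelled as
   `dm/dt = K_basal + K_eff · B(t)^n − K_deg · m`, with `n = +1`
   (activation) or `−1` (repression). `K_basal` and `K_eff` are solved
   exactly from the flanking steady states (means of the first/last
   three time points, right-hand side set to 0); trajectories are
   integrated by explicit 1-minute Euler steps; the knockout is the
   `B ≡ 1` (no-binding) limit.
4. **Residual classification.** Per-gene synthesis-rate residuals
   (actual − model) are clustered (k-means, Euclidean, k = 5): genes the
   single TF explains leave flat residuals; TF-independent impulse genes
   leave an immediate excursion shared by both strains; targets of a
   delayed TF-dependent second regulator leave a positive excursion in
   the 20–45 min window.
5. **Feed-forward-loop (FFL) logic.** A three-node logic approximation
   (step activation at 0.5 on unit-scaled traces, OR gate) tests whether
   a delayed excursion is consistent with the TF driving the target both
   directly and through an intermediate effector; the two decay rates
   `(k_Y, k_Z)` are fitted by bounded multi-start least squares at the
   4 early evaluation times {5, 10, 20, 45} min. `ln 2 / k` converts a
   rate into a response time.
6. **Clustering & enrichment.** Expression profiles are standardised
   and clustered with a Pearson-distance k-means (k = 8 in the original
   design); clusters are scored for COG-category enrichment with the
   upper-tail hypergeometric test. A one-sided Welch test decides
   whether a gene changed by at least 1.5-fold across the perturbation.

A first-class synthetic-data module generates binding curves, decay
experiments and complete two-strain panels with planted ground truth, so
the whole pipeline is testable without any external data.

## Worked example

```python
import numpy as np
import trmbdyn as td

# simulate the study: binding curve + 100-gene two-strain panel
panel = td.simulate_panel(td.PanelConfig(seed=0))
binding = panel.binding

# fit the FFL logic model to the cobalamin-like target cluster
x = td.scale_unit(binding.times, binding.enrichment)
target = np.mean([panel.by_gene(g, "parent").mean_trace()
                  for g in panel.genes("ffl_target")], axis=0)
u = td.scale_unit(td.DESIGN_GRID, target)
fit = td.fit_ffl(td.FflModel(), x, u.times, u.values)
print(f"effector decay  k_Y = {fit.k_y:.4f}/min "
      f"(response time {td.response_time(fit.k_y):.1f} min)")
print(f"target mRNA     k_Z = {fit.k_z:.4f}/min "
      f"(half-life {fit.half_life_z:.1f} min)")
```

prints

```
effector decay  k_Y = 0.0293/min (response time 23.7 min)
target mRNA     k_Z = 0.1585/min (half-life 4.4 min)
```

i.e. the effector needs ~20–25 minutes to cross its activation threshold
after the TF leaves the DNA — which is why the residual excursion of the
target cluster sits in the 20–45 min window — and the target mRNA turns
over with a ~6 min half-life.

The same stages are available from the shell:

```sh
trmbdyn simulate --seed 0 --out-prefix sim
trmbdyn fit-deg --decay-table decay.tsv --out deg.tsv
trmbdyn cluster --table sim_panel.tsv --kind expression --out clusters.tsv
trmbdyn enrich --cluster-table clusters.tsv --annotation-table cogs.tsv --out enrich.tsv
trmbdyn ffl-fit --binding-table sim_binding.tsv --target-table cluster_mean.tsv --out ffl.json
```

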