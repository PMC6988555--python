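# overlapshift

Joint spatial models for coupled marine species on survey lattices, and
metrics for the ecological cost of a changing climate.

Marine predators and their prey (seals, seabirds, porpoises; sandeels and
herring) are surveyed as densities on regular grids — nominally 7 × 7 km
cells over a shelf sea — alongside modelled biophysical fields such as
bottom temperature, chlorophyll-a, net primary production, potential energy
anomaly (stratification) and current speed, available for both a present
climatology and a projected mid-century scenario.  Two questions follow:
*where do a predator and its prey overlap beyond what the environment
explains*, and *how much does that overlap move or shrink under the future
climate*?

`overlapshift` answers both with Besag–York–Mollié (BYM) models.  For
species *s* at cell *i*,

    eta_si = alpha_s + sum_k f_k(x_ki) + delta_s z_i + v_si

with shared binned random-walk smooths `f_k`, a shared intrinsic-CAR
spatial field `z` (the **common spatial trend** — its significantly
positive cells are the pair's joint high-density areas), per-species
loading `delta_s` (`delta_1 = 1`), and iid heterogeneity `v_s`.  Densities
are Gamma with mean `exp(eta)`; species with excess zeros add a logistic
occupancy hurdle.  Candidate covariate subsets are screened at |r| ≤ 0.5
and ranked by DIC; future densities come from the missing-response
convention; and present/future surfaces are compared with four
ecological-cost metrics (relative population change, the thirds-rule
overall percentage difference, Getis–Ord G* hot/cold-spot transitions and
significant sign changes of the common trend, and weighted-centroid
displacement with haversine distance and compass bearing) plus RMSE and
the Bhattacharyya distance.  Inference is an empirical-Bayes Laplace
backend with a third-order skewness correction, exact for Gaussian
likelihoods; everything is seed-deterministic.  A synthetic-data module
generates covariate fields and coupled species from the model itself, so
the whole pipeline runs against known ground truth.

See `docs/methods.md` for the model, inference scheme, metric conventions
and limitations.

## Worked example

Fit the joint model to a simulated predator–prey pair and read off the
common spatial trend (`examples/03_joint_fit_common_trend.py`):

```python
import overlapshift as o
from overlapshift.inference import InferenceConfig

grid = o.build_grid(15, 15)
present = {f.name: f for f in o.simulate_covariates(grid, ["PEA", "NPP"], seed=1)}
truth = o.default_truth(grid, ("PEA", "NPP"), seed=2)
species = o.simulate_joint_species(grid, present, truth, seed=3)

spec = o.ModelSpec(species=("predator", "prey"), covariates=("PEA", "NPP"),
                   family={"predator": "gamma", "prey": "hurdle-gamma"})
fit = o.fit(spec, species, present,
            InferenceConfig(seed=0, max_opt_evals=120, n_samples=100))
cst = o.extract_common_trend(fit)
```

Output:

```
converged: True   DIC: 1701.1 (pD 93.5)
delta_2 (prey loading on shared trend): 0.92 (generative truth 1.0)
gamma shapes: predator 3.03, prey 2.40
common trend: 21 significantly positive cells of 225; corr with generative z: 0.79
```

`delta_2` is the prey's loading on the shared spatial field: 0.92 means the
pair co-varies spatially nearly one-for-one after the covariate effects,
as simulated.  The 21 significantly positive trend cells are the estimated
joint habitat; their 0.79 correlation with the generative field shows the
overlap structure being recovered.  Projecting the same fit under shifted
covariates and pricing the change
(`examples/04_project_and_costs.py`) prints:

```
predator: population change -26.2%, 44% of cells beyond the one-third change (fairly different), centroid moved 2.2 km
prey: population change -29.9%, 59% of cells beyond the one-third change (fairly different), centroid moved 2.3 km
```

— the populations decline under the warmer, more stratified scenario
because stratification acts negatively in the generative habitat model,
and the thirds-rule category says roughly half the map changed materially.

The other scripts in `examples/` cover grid construction and depth masking
(01) and scenario simulation (02).  The same workflow is available from the
shell:

```bash
overlapshift run --seed 1 --out results_dir        # full pipeline
overlapshift simulate --seed 1 --out data_dir      # synthetic grids + truth
```

`run` writes the selection tables (single and joint), predicted density
surfaces, present/future common-trend surfaces, the cost tables, a
deviance-explained table, and a reproducibility manifest.

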