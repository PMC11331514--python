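# dielsat

Monte Carlo simulation of primitive-model electrolytes with **local
dielectric saturation**, for studying ion clustering, electrostatic
screening and electric double layers in concentrated 1:1 salts.

## The problem

Concentrated aqueous electrolytes (≳1 M) show surprisingly long-ranged
correlations between charged surfaces ("anomalous underscreening"), which
the classical restricted primitive model (RPM) — charged hard spheres of
diameter d in a uniform dielectric continuum ε_r — cannot reproduce.
Water in the hydration shell of an ion is rotationally constrained, so its
dielectric response is locally *saturated*.  `dielsat` implements an RPM
variant in which the permittivity depends on the ion–ion separation r:

    ε_r(r) = ε_c + (ε_b − ε_c)·clamp((r − d)/Δ, 0, 1)

ramping linearly from a saturated contact value ε_c = 23 at r = d to the
bulk value ε_b = 78.3 over a solvent layer Δ = 3 Å, with

    βu_ij(r) = z_i z_j l_B(ε_r(r)) / r,    l_B(ε) = βe₀²/(4πε₀ε),

and a hard core at r < d.  The extra short-ranged attraction between
unlike ions drives strong cluster formation; because the enhancement is
local, like-charge repulsion within clusters is not amplified, so clusters
grow much larger than in a uniform low-ε RPM — with visible consequences
for screening lengths and double-layer profiles.

The package provides:

* canonical Metropolis MC for **bulk** (cubic, minimum-image) and **slit**
  (charged hard walls, charged-sheet electrostatics) geometries, with
  single-particle and rigid-cluster moves (merge-rejection guard for
  detailed balance), incremental energy bookkeeping with O(N²)
  reconciliation, and bitwise-reproducible seeded runs with checkpoints;
* observables: species-resolved g(r), the density–density/charge–charge
  combinations g_nn and g_cc, cluster decomposition and P_ion(N_c) under
  the δ = d + 0.5 Å criterion, Yukawa tail fits, a phase-separation
  diagnostic, slit density profiles n±(z) and Δn(z);
* a ghost test-charge-pair (Widom) estimator of the effective
  electrostatic screening length λ, with bootstrap uncertainties;
* analytic reference lengths (Bjerrum, Debye), deterministic test
  fixtures, YAML run configurations and a CLI.

## Worked example

A 0.25 M bulk run of the saturation model, then the screening length from
ghost-pair insertions (a reduced linear-response probe charge; the decay
length is probe-independent while the insertion average stays
light-tailed):

```python
import numpy as np
from dielsat import (DielectricRampModel, MoveSchedule, BulkBox,
                     initialize_configuration, run, debye_length,
                     WidomSettings, pair_insertion_free_energy,
                     effective_screening_length)
from dielsat.observables import FrameRecorder, RDFObserver

model = DielectricRampModel()            # eps_c=23, eps_b=78.3, d=3, Δ=3
box = BulkBox(L=87.36)                   # 100 ion pairs at 0.25 M
state = initialize_configuration(100, 100, box, seed=7, model=model)
frames, rdf = FrameRecorder(), RDFObserver(box, bin_width=0.25)
run(state, MoveSchedule(equilibration=5000, production=40000, stride=100,
                        max_step=4.0), observers=(frames, rdf))

lam_d = debye_length(0.25)               # 6.07 Å
seps = tuple(np.linspace(1.5 * lam_d, 5.0 * lam_d, 8))
table = pair_insertion_free_energy(
    frames, WidomSettings(separations=seps, insertions=800,
                          test_charge=0.3, seed=7), model=model)
est = effective_screening_length(table)
print(f"lambda = {est.lam:.2f} A  (lambda_D = {lam_d:.2f} A)")
```

which prints, for this seed,

```
lambda = 9.83 A  (lambda_D = 6.07 A)
```

i.e. at 0.25 M the fitted decay length of the test-charge potential of
mean force exceeds the Debye length — the mild underscreening
characteristic of the clustered regime (at 0.05 M the same estimator
reproduces λ_D to within ~15%).

The same run from the shell:

```bash
dielsat debye --c 0.25                   # 6.0748
dielsat simulate-bulk run.yaml --out out/     # rdf.tsv, clusters.tsv, ...
dielsat screening out/trajectory.npz --method widom --insertions 800
```

with `run.yaml`:

```yaml
thermo:   {concentration: 0.25}
geometry: {type: bulk, L: 87.36}
schedule: {equilibration: 5000, production: 40000, stride: 100}
seed: 7
```

A slit run uses `geometry: {type: slit, L: 35, H: 50,
sigma_inv_A2_per_e: 70}` and `dielsat simulate-slit`, producing
`profile.tsv` with n₊(z), n₋(z) and Δn(z).

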