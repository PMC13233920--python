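# pyloricnet

A workbench for studying when local activity-dependent homeostatic
regulation can maintain a circuit-level property — the triphasic "pyloric"
burst order — in a three-neuron continuous-time recurrent neural network
(CTRNN).

The package provides:

- **`ctrnn`** — the three-neuron leaky-integrator network (neurons labeled
  LP, PY, PD), fixed-step RK4 integration (numba-accelerated), limit-set
  classification.
- **`rhythm`** — burst parsing at a 0.5 output threshold, period detection,
  LP-anchored folding of the six burst-boundary events into one of 120
  orderings, the three pyloric criteria, duty cycles / phases, cycle
  averages.
- **`fitness`** — the staged pyloricness score `P_b` (0.05 per satisfied
  requirement, 0.3 = pyloric), the timing-similarity bonus `P_t`
  (inverse summed |z| against reference duty/phase statistics), the total
  `P`, and the regulator score `A` (mean of `P + 25·[pyloric]` over a
  perturbation grid and two checkpoints).
- **`adhp`** — slow homeostatic dynamics on neuronal biases: sliding-window
  average of each regulated neuron's own output drives a dead-zone
  controller `rho` with range `[LB, UB]`; biases clip to `[-16, 16]`;
  outcome classification (interior/boundary endpoints, parametric limit
  cycles) and per-cycle balance measurement at endpoints.
- **`evolution`** — a steady-state microbial GA over unit-interval genomes
  for both circuits (15 genes) and regulators (4 genes per regulated bias),
  plus the extended 6×6 robustness grid and meta-parameter census.
- **`prediction`** — grid scans of regulated-bias subspaces (2D or 3D),
  cycle-averaged flow fields and nullclines, endpoint prediction with
  stability and anomaly flags (boundary pinning, bifurcation flip-flop
  risk), the 0.01-bin separability verdict (fully / partially /
  unregulatable), generalization across circuit pairs, and
  prediction-vs-simulation agreement tables.
- **`fixtures`** — deterministic test fixtures: an analytic zero-weight
  circuit, square-wave rhythm generators for all ten pyloric orderings, and
  three certified archetype oscillators (separable, 2D-inseparable,
  pyloric-unstable) found with the package's own GA.
- **`io` / `cli`** — flat-JSON circuit and mechanism records, database
  files, scan bundles with content hashes, CSV export, and a `pyloricnet`
  command-line front end.

## CLI

```sh
pyloricnet simulate --circuit circuit.json --duration 50 --out traj.csv
pyloricnet analyze --circuit circuit.json
pyloricnet fitness --circuit circuit.json [--timing-stats stats.json]
pyloricnet evolve-circuits --mode base --n-runs 10 --seed 0 --out db.json
pyloricnet evolve-adhp --circuit-db db.json --per-circuit 5 --out mech.json
pyloricnet recover --circuit c.json --mechanism m.json --perturb 9,-9 --out run.csv
pyloricnet scan --circuit c.json --axes LP,PD --step 0.25 --out scan/
pyloricnet predict --scan scan/ --mechanism m.json
pyloricnet compare --circuit c.json --scan scan/ --out agreement.json
pyloricnet generalize --scan-a a/ --scan-b b/
pyloricnet fixtures --seed 0
```

A circuit JSON is a flat object with keys `tau_LP…`, `theta_LP…`,
`w_LP_to_PY…` (9 weights, source→target). Timing statistics files supply
`duty_mean/duty_sd` per neuron and `phase_mean/phase_sd` for LP and PY;
only the duty-cycle means (0.264 / 0.348 / 0.385) have package defaults —
the remaining reference statistics must be provided by the user.

## Notes on scale

Desk-scale defaults are deliberately smaller than the largest published
analyses of this model class: subspace scans default to a 0.25–1.0 bias
step (the binning resolution of 0.01 is unchanged), and long regulation
runs support an early exit once biases settle. All scales are exposed as
parameters.
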