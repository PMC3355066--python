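# mechinverse

Infer the mechanical state of a two-dimensional epithelial cell sheet
from its geometry alone.

Epithelial mechanics at the apical surface is dominated by actomyosin
cortices and adhesion at the cell–cell interfaces. If the tissue is
close to quasi-static force balance, the observed polygonal geometry of
the cell array strongly constrains the relative interfacial tensions
`T_ab` and intracellular (2-D) pressures `P_a`: at every tricellular
junction the interface forces

    F = T_ab t̂ + (P_a − P_b)/2 · J u        (J = clockwise 90° rotation)

must sum to zero. These conditions are linear in `(T, P)`, so the
geometry defines a rectangular linear system whose pseudo-inverse —
the *Mechanical Inverse* — recovers the mechanical state up to a small
number of undetermined constants (4 for a closed array of threefold
vertices; the overall scale is fixed by constraining the mean tension
to one). Reduced parameterizations (all pressures equal, or per-cell
cortical tensions) make the system overdetermined and strongly suppress
the noise sensitivity of the full problem.

The package provides:

- `cell_array` — the polygonal data model (closed / open / toroidal
  arrays, rosettes allowed), geometry, validation, JSON and CSV I/O,
  and the zero-mode counting rules;
- `vertex_model` — interface forces, the tension/pressure energy,
  quasi-static relaxation, and the synthetic-tissue generator and
  vertex-noise protocol used for in-silico validation;
- `inverse` — assembly and pseudo-inverse solution of the force-balance
  system in full, constant-pressure, and cortical parameterizations,
  including a non-negative-tension variant (quadratic programming);
- `sensitivity` — the analytic error-response operator and its singular
  spectra, plus the empirical noise-vs-recovery benchmark;
- `validation` — intercellular traction (shear) forces, the
  Young–Laplace cross-check against measured interface curvatures,
  orientation-anisotropy statistics, and recovery scatter metrics;
- `cli` — a `mechinverse` command with `simulate`, `corrupt`, `infer`,
  `sensitivity`, `traction`, `laplace`, `anisotropy` and `benchmark`
  subcommands.

Intended users: quantitative biologists and biophysicists with
segmented apical views of epithelia (vertex coordinates and cell
adjacency) who want relative tension/pressure maps and their
reliability, and modellers who need a reproducible benchmark for force
inference.

## Worked example

```python
import mechinverse as mi

# a relaxed 64-cell synthetic tissue with known tensions
cfg = mi.SimulationConfig(n_cells=64, seed=3)
array, truth = mi.generate_voronoi_tissue(cfg)

# corrupt the vertex positions at 5% of the mean edge length,
# then run the constant-pressure Mechanical Inverse
noisy = mi.corrupt_vertices(array, 0.05, seed=1)
solution = mi.solve(mi.assemble(noisy, "constant_pressure"))
r, pairs = mi.recovery_scatter(truth, solution.state)
print(f"recovered {len(pairs)} tensions, Pearson r = {r:.3f}")
print(f"mean inferred tension = "
      f"{solution.state.tension_vector(noisy).mean():.6f}")
```

prints

```
recovered 192 tensions, Pearson r = 0.819
mean inferred tension = 1.000000
```

The correlation of 0.82 says that on a 64-cell tissue with 5% vertex
noise the partial inverse recovers the true interface tensions well;
the mean tension is exactly one because the overall scale is not
observable and is pinned by convention. On noiseless geometry the same
call returns r = 1.000000; at 10% noise on a 400-cell tissue it falls
to roughly 0.5–0.7, the practical limit of the method. Equivalent CLI
pipeline:

```
mechinverse simulate --n-cells 64 --seed 3 -o run/
mechinverse corrupt run/array.json --rms 0.05 --seed 1 -o run/noisy.json
mechinverse infer run/noisy.json --mode constant-pressure -o run/out/
```

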