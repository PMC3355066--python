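# Methods

## The force-inference model

An epithelial monolayer is represented by the polygonal geometry of its
apical cell outlines: vertices (tricellular junctions), straight-chord
edges (cell–cell interfaces) and cells (counter-clockwise vertex loops).
The mechanical state is one effective tension `T_ab` per interface and
one two-dimensional pressure `P_a` per cell. The force an interface
exerts on an endpoint vertex is

    F = T_ab t_hat + (P_a - P_b)/2 * J u ,

where `u` is the chord from the vertex to the other endpoint, `t_hat`
its unit vector, `J` the clockwise 90° rotation, and `a` the cell to
the left of the directed chord. The tension part pulls the vertex along
the interface; the pressure part is the Young–Laplace load of the half
interface nearest the vertex, pushing away from the higher-pressure
side. Summed over the interfaces incident at a vertex, these forces are
exactly minus the gradient of the energy

    H = - sum_a P_a A_a + sum_<ab> T_ab l_ab

with respect to that vertex position (asserted by a finite-difference
oracle in the test suite). Quasi-static force balance — zero net force
at every junction — is the core modelling assumption: the tissue is
taken to relax mechanically much faster than it rearranges.

## The inverse problem

Tensions and pressures enter the balance conditions linearly, so the
observed geometry defines a linear system `A q = b`: two rows per
balanced vertex plus one row fixing the arbitrary overall scale
(mean tension = 1). Balanced vertices are all vertices for closed and
periodic arrays, and only interior vertices (all incident cells in the
field of view) for open patches. The exterior pressure is the zero
reference and carries no column.

Counting gives the number of undetermined "zero modes" (parameter
combinations producing no force anywhere): for a closed array of
threefold vertices, `E + C - 2V + 3 = 4` — the scale plus three modes
tied to the identically-zero total force and torque of a closed system;
each rosette (higher-order vertex) adds one. A periodic (toroidal)
array has 2 (scale and uniform pressure shift); an open patch has
`E + C - 2 V_interior`, i.e. one per boundary condition the field of
view cuts off. All three counts are verified against the numerical
null-space dimension of the assembled matrix.

`solve` computes the minimum-norm least-squares solution by SVD with
the scale row enforced as a hard constraint: the constraint direction
is eliminated with a Householder reflection and the balance system is
solved in the tangent space. A soft (appended-row) scale constraint
gives a collinear solution, but under strong positional noise its mean
tension collapses toward zero; the hard constraint keeps the mean
exactly one without changing any correlation-based result. Singular
values below `rel_tol` (default 1e-8) times the largest are treated as
zero and returned as the zero-mode basis; amplitudes default to zero
(minimum-norm representative). `solve_nonnegative` solves the same
system as a bounded least-squares problem with tensions >= 0.

Parameter reductions: `constant_pressure` drops all pressure columns
(the system becomes overdetermined); `cortical` writes each interface
tension as the sum of the two adjacent cells' cortical tensions,
leaving two unknowns per cell.

## Error sensitivity

The first-order response of the inferred parameters to a vertex
displacement field is `dq = -Z pinv(A_bal Z) (dA_bal q)`, with `Z` the
scale-constraint tangent basis; the derivative of the balance matrix in
the vertex coordinates is analytic (entries depend on chords through
unit vectors and rotations). The operator is made dimensionless by
measuring displacements in mean edge lengths and parameters in mean
tensions. Its singular values quantify noise amplification: for the
full tension+pressure problem a large fraction exceeds one (with a very
heavy tail), while the constant-pressure reduction caps the spectrum at
a few units — this is what makes the partial inverse usable on real
images. The "fraction above one" statistic is computed over the
positive spectrum only, since exact zeros are rank-limitation
directions with no response at all.

## Synthetic tissues

`generate_voronoi_tissue` builds the in-silico benchmark: `n_cells`
uniform random seeds in a periodic box of mean cell area one, Voronoi
tessellation, then relaxation to force balance of the elastic energy

    E = sum_e Lambda_e l_e + (Gamma/2) sum_a (L_a - L0)^2 ,

with i.i.d. line tensions `Lambda_e ~ U(0.5, 1.5)`, perimeter
elasticity `Gamma = 0.3` and rest perimeter `L0 = 3.7224` (the regular
hexagon of unit area). There is no area term, so every cell carries the
same pressure (set to zero). The ground-truth interfacial tensions are
the energy conjugates of the edge lengths,

    tau_e = Lambda_e + Gamma (L_a - L0) + Gamma (L_b - L0) ,

evaluated at the relaxed geometry.

The perimeter term is not cosmetic. For a pure line-tension energy the
three tensions at a junction fix the three junction angles outright,
and the angle sums around each face then impose one closure condition
per cell on the tension field alone: a generic i.i.d. draw satisfies
none of them, no equilibrium with that topology exists, and (the energy
being convex in the vertex positions) minimization simply collapses
edges. The quadratic perimeter term lets the effective tensions co-adapt
with the geometry, making force balance generically attainable while
keeping tensions dominated by the uniform draw. `Gamma = 0.3` puts the
perimeter forces on the same scale as the line tensions; the resulting
tension distribution has a coefficient of variation near 0.33 and only
a weak negative correlation with edge length (about -0.1 to -0.35
depending on realization), the signature observed in real tissue data.

Relaxation is damped Newton descent (`scipy` trust-region Newton-CG
with exact Hessian-vector products). Edges that nonetheless collapse
during descent undergo T1 neighbour exchanges (or T2 removal for a
collapsing triangle) between descent rounds; new interfaces draw a
fresh line tension. An edge qualifies for surgery when it ends a
descent round below 2% of the mean edge length; each round operates on
a mutually non-adjacent batch of such edges, shortest first, and the
tissue re-relaxes before any neighbour is reconsidered. The final
state satisfies a maximum
net vertex force below 1e-6 of the mean tension. T2 removals can leave
the final cell count one or two below the requested `n_cells`.

`corrupt_vertices` adds isotropic Gaussian displacements with per-
coordinate sigma chosen so the r.m.s. displacement magnitude equals the
requested fraction of the mean edge length; this emulates segmentation
error and junction fluctuation. The anisotropic variant of the
generator multiplies the line tensions by `1 + eps*cos 2(theta-axis)`
before relaxing, emulating planar-polarized contractility; relaxation
feedback erodes the realized group-mean tension gap (amplitude 0.55
yields roughly an 8–10% aligned-vs-transverse gap), so the constructed
gap is always re-measured from the true state rather than assumed.

What the generator does not emulate: curved interfaces (all chords are
straight, so curvature-based validation uses constructed curvature
fixtures), rosettes (T1 handling keeps vertices threefold), cell
divisions or active rearrangements, and any imaging artefact beyond
isotropic vertex noise. Benchmarks passing on these tissues therefore
demonstrate correctness of the inference machinery under the model's
own assumptions, not segmentation robustness on real micrographs.

## Benchmarks and problem sizes

The headline in-silico benchmark uses 400-cell tissues, 10 replicate
seeds, vertex noise at 5% and 10% of the mean edge length, and the
constant-pressure inverse; the reported quantity is the Pearson
correlation between true and inferred tensions after both are scaled
to mean one. Noiseless recovery is exact to rounding (r > 0.999999).
At 10% noise the plain (untruncated) pseudo-inverse becomes sensitive
to system size: in larger arrays the corrupted balance matrix can
develop spuriously small singular values, well separated from the
physical spectrum, whose inversion contaminates the solution for some
realizations. The benchmark keeps the estimator exactly as defined
(rel_tol = 1e-8) and reports the ensemble mean; the `rel_tol` knob on
`solve` lets a user truncate such modes (any cutoff in the wide plateau
between the spurious and physical singular values gives the same,
noticeably higher, correlation — the sensitivity module quantifies
this).

Unit and property tests run on 16–144-cell fixtures; counting tests on
100-cell closed arrays; the sensitivity comparison on 200 cells. These
sizes were chosen so the full suite runs in minutes while every
statistic quoted above is still measured, not extrapolated.

## Numerical choices and edge cases

- Degenerate edges (below 1e-9 of the mean length) are rejected at
  load time; self-intersecting loops raise on area evaluation.
- Toroidal geometry uses the minimum-image convention; boxes must be
  at least 3 mean edge lengths wide. During relaxation each edge's
  periodic image shift is frozen per descent round so the energy stays
  smooth; positions are wrapped into the box only on return.
- Orientation ties in the anisotropy split (an edge within 1e-9 rad of
  the threshold angle) go to the transverse group.
- The two-sample anisotropy test is a Mann-Whitney U (the compared
  distributions are not assumed normal).
- The rank cutoff for zero-mode detection is `1e-8 * sigma_max`;
  counting results are insensitive to this over many decades because
  the physical spectra are gapped.
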