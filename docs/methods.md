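# Methods

## The model

`gastrusim` simulates a 2D tissue of N cells with the Cellular Potts
(Glazier–Graner–Hogeweg) model.  The lattice Λ carries a spin field
σ(x) ∈ {0, 1, …, N}; cell s is the set of sites with σ = s, spin 0 is
the medium M.  The energy is

    H = Σ_{adjacent pairs} J(τ, τ′) (1 − δ_{σ,σ′})
      + Σ_cells [ λ₁ (A(s) − A_T)² + λ₂ (L(s) − L_T)² ],

with Moore (8-site) adjacency, interfacial energies J per unit boundary
length indexed by cell type τ, an area constraint around the target
area A_T and a length constraint around the target length L_T.  A
Monte Carlo attempt copies the spin of a random boundary neighbor onto
a site and is accepted with the Metropolis rule P = 1 for ΔH ≤ 0 and
exp(−ΔH/T) otherwise; the temperature T sets cell motility.  Surface
tensions γ(τ, τ′) = J(τ, τ′) − (J(τ,τ) + J(τ′,τ′))/2 summarize the
adhesion table: γ(c, M) > 0 keeps the tissue compact, the sign of
γ(1, 2) decides sorting versus mixing.

Cells are not required to stay connected and may disappear; a cell
reaching zero area is retired (its filopodia are dropped; its constant
constraint energy no longer affects any ΔH).

**Cell length.** The model needs a scalar length L(s).  We use the
covariance-based major-axis estimate L = 4·√λ_max of the cell's site
coordinates, which equals the diameter of a filled disc — consistent
with A_T = 100 and L_T = 10 making cells close to round.  The raw
coordinate moments (Σx, Σy, Σx², Σy², Σxy) are maintained incrementally
(exactly, in double precision) and can be validated against a
from-scratch scan at any time.

## Edge-list sampling

Conventionally one MCS is |Λ| random site-pair proposals, almost all of
which fall inside cells and do nothing.  The simulator instead tracks
the set E of directed boundary pairs (site, neighbor with unequal spin)
in two mutually indexing arrays: `edge_of_index[i]` maps the flattened
(site, neighbor-slot) index i = (y·W + x)·8 + slot to an edge number or
−1, and `index_of_edge[k]` holds, for k < |E|, the pair index.  This
1-to-1 relationship gives O(1) uniform sampling and O(1) updates: a
removed edge is back-filled with the edge at |E| − 1, so the dense
prefix never needs defragmentation.  One MCS is ⌈|E|/8⌉ attempts (|E|
re-read as it changes), which matches the expected number of boundary
proposals of the conventional sampler; a dedicated test shows the two
samplers produce statistically indistinguishable area statistics at
matched effective attempts.  The lattice has a one-site frame that is
permanently medium and excluded from all neighborhoods; no periodic
boundaries.

## Convergent extension by filopodial tension

Each cell carries a polarization angle P(s), initialized uniformly in
[0, 2π).  Every t_interval MCS each cell discards its filopodia and
attaches up to n_max new ones, drawn uniformly among the cells whose
centers of mass lie inside a double cone of half-angle θ_max and radius
r_max·L_T around the line ±P(s) (filopodia grow parallel to the
polarization axis).  A proposed copy changes the centers of mass of the
two affected cells in closed form; the filopodial term adds

    ΔH_pull = λ_F Σ_i (R_i,after − R_i,before)

over all links touching an affected cell (all others cancel), so links
act as contractile center-to-center springs.  At each refresh the
polarization is first updated by a memory-weighted, noise-free
circular blend with the polarizations of the currently linked cells:
P_avg = arg Σ e^{iP(s_j)}, P_new = arg(w·e^{iP} + (1 − w)·e^{iP_avg}).
No global axis is imposed; local alignment (and hence a self-organized
elongation axis) emerges.  The alternative location-based rule
(`repolarization_mode = "belmonte"`) steers toward the mean
displacement to the linked centers instead, approximating the original
filopodial-tension model's repolarization; it is used only for the
mechanism comparison.  Ordering within a refresh: repolarize from the
existing links, then rebuild the links.  Ties (no links, zero-magnitude
circular sum) leave P unchanged.

Filopodia persist unchanged between refreshes even if a target drifts
out of the cone; turnover is governed entirely by t_interval.  Links to
cells that die are skipped.  With λ_F = 0 the trajectories are bitwise
identical to the plain CPM at equal seeds (tested).

## Model presets

* `diff_adhesion`: 10 cell types on the linear gradient
  J(τ, τ′) = O + |τ − τ′|·S with J(τ, M) = 25, so γ(τ, τ′) = |τ − τ′|·S
  and γ(c, M) = 25 − O/2.  Types are prearranged in 10 contiguous
  x-ordered bands (the band axis is arbitrary by isotropy).
* `ce_one_type`: the filopodial-tension model with a single type.
* `ce_same_type`, `ce_all_all`, `ce_yellow_all`, `ce_yellow_yellow`:
  two types (type 2 is "yellow"), assigned independently with
  probability ½ each (configurable), with the pulling permission
  restricted by the variant's (τ_source, τ_target) predicate.

## Default parameters

| name | meaning | default |
|---|---|---|
| temperature | Metropolis temperature T | 50 |
| target_area | A_T (sites) | 100 |
| target_length | L_T (sites) | 10 |
| lambda_area, lambda_length | constraint strengths λ₁, λ₂ | 5, 5 |
| mcs | run length | 100,000 |
| n_cells | cells N | 200 |
| theta_max | filopodium cone half-angle (deg) | 45 |
| r_max | cone radius (multiples of L_T) | 2 |
| n_max | filopodia per cell | 3 |
| t_interval | refresh cadence (MCS) | 20 |
| w | polarization memory | 0.99 |
| J(c, M), J(c, c) | interfacial energies | 10, 10 |
| lambda_f | pulling force λ_F | 15 |

The lattice is square, 400×400 for 200 cells of area 100, scaled with
√(N·A_T) otherwise; a warning is emitted if the tissue touches the
frame.  Initialization seeds N single-site cells uniformly in a
center disc of radius ≈ 1.07·√(N·A_T/π) and grows them for 100 MCS with
the area and adhesion terms only, yielding a compact blob of
near-target-area cells.  Repeat seeds in campaigns are
base_seed + repeat_index.

## Shape quantification (LOCO-EFA)

The tissue mask (all cell sites) is contoured by marching squares at
the 0.5 level of a σ = 1-blurred indicator (the blur removes the
staircase-perimeter bias without moving the boundary by more than
about half a pixel).  The closed polygon, traversed counterclockwise
and parameterized by arc length, has the complex Fourier expansion
z(t) = a₀ + Σ_{n≥1} [a_n e^{inωt} + b_n e^{−inωt}]; the coefficients of
a polygon are computed in closed form.  A shape with l lobes excites
exactly the prograde harmonic l+1 and the retrograde harmonic l−1, so
after normalizing starting point and orientation on the first
harmonic's ellipse, the l-lobed mode amplitude is the peak radial
modulation

    L_l = √( |a_{l+1}|² + |b_{l−1}|² + 2|a_{l+1}||b_{l−1}| cos(ζ⁺_{l+1} + ζ⁻_{l−1}) ),

and L₁ = |a₁| is the linear size.  The scaled coefficients L_n/L₁
(n ≥ 2) are invariant under translation, rotation, uniform scaling and
the choice of starting point (exactly, by the covariance of the
normalization; verified to 1e−6 on fuzzed shapes).  Analysis uses modes
2–3: higher modes are increasingly sensitive to the lattice scale and
simulation noise, while modes 2–3 agree within 5% between a continuous
contour and its rasterized mask.  Note that because the
parameterization is arc length, the classical identities for eccentric
ellipses hold only approximately (L₂/L₁ = 0.509 rather than 0.5 for a
3:1 ellipse); this is inherent to elliptic Fourier analysis, not an
implementation artifact.

## Statistics

`ks2d` implements the Fasano–Franceschini two-sample 2D KS test: for
origins at the data points of each sample, D is the maximum absolute
difference of the two samples' quadrant fractions, averaged over the
two origin passes.  Quadrants are strict (open); the origin and points
on the dividing lines count toward no quadrant; fractions use the full
sample size.  With this convention identical samples give exactly
D = 0 and samples confined to opposite quadrants give exactly D = 1
(take the origin at a Pareto-extreme point).  p-values come from the
asymptotic Kolmogorov distribution with the Press-style correlation
correction (effective n = n₁n₂/(n₁+n₂)) or, authoritatively for small
samples, from label permutation of the pooled points (seeded).  The
permutation p is calibrated (≈ U(0,1) under the null; tested).
`brown_forsythe` is the median-centered Levene test
(scipy.stats.levene, center="median").

## Segmentation and trajectories

The wide-field pipeline is fixed-parameter and deterministic: Gaussian
blur (σ = 5 px) → Otsu threshold on the blurred image → dilation then
opening (disc radius 10) → Euclidean distance transform → local maxima
≥ 70 px apart as markers (+ background) → Scharr gradient elevation →
marker watershed → drop objects < 1000 px or touching the border.
Time-lapse frames use a 51×51 blur (σ = 8), a fixed fractional
threshold (default 40/255, overridable per frame), then 40 iterations
of 5×5 dilation followed by 40 of erosion; already-binary simulated
frames use 4 erosion + 4 dilation iterations instead.

Trajectory analysis fits an ellipse (least squares on the mask
boundary) per frame, disambiguates the orientation across frames
(ellipse fitters report θ modulo π/2 swaps; the representative closest
to the previous frame is chosen), subtracts the center (drift) and
rotates by −θ (rotation).  Net movements along the long/short axis are
normalized by the axis lengths (v_l/L, v_s/S); cells are labeled
inward/outward/crossing relative to the long axis.  Relative positions
of points in a mask are principal-axis projections min-max scaled by
the mask extent.  All reported quantities are rigid-motion invariant
(tested by composing a rotation + drift onto a stretch flow).

## Synthetic data

`fixtures` generates (a) wide-field-like images: hard discs blurred
with a Gaussian (soft edges) plus additive Gaussian sensor-like noise,
16-bit, with ground-truth masks; (b) analytic shape families — circle,
ellipse, n-lobed flower r = R(1 + ε·cos nθ), and "snowman" (union of a
disc and a smaller overlapping head disc; the unequal lobes carry both
2- and 3-lobe content) — whose lobe content is known in closed form;
(c) tracks advected by the incompressible stretch flow
(x, y) → (k x, y/k), optionally composed with rigid motion and jitter.
These emulate geometry and noise, not microscope optics: no PSF
anisotropy, no structured background, no segmentation-confusing
debris.  Passing tests therefore validate the algorithms' contracts,
not robustness to every real-imaging artifact.

## Desk-scale study conditions

The full-scale conditions (200 cells, 100,000 MCS, 100 repeats per
parameter set) take minutes per run; the shipped test suite and
acceptance script run everything at desk scale chosen so the
phenomenology is preserved while a whole campaign fits in minutes:

* pulling/variance campaigns: 36 cells, 20,000 MCS, λ_F = 20,
  γ(c, M) = 15, 25 runs (tests) or 12 runs (acceptance script);
* phase windows: elongation past L₂/L₁ = 0.25 happens around MCS 5–8k
  at this tissue size (vs ≈ 50k at 200 cells), so the "initial phase"
  is the first 5,000 MCS and the "final phase" the last 10,000;
* repolarization comparison: 12,000 MCS, 30 + 30 runs (tests) or
  15 + 15 (script);
* differential adhesion: 30 cells, 15,000 MCS, slopes {1, 2.5, 4}.

At this scale the model reproduces the qualitative and statistical
signatures: tissues elongate from L₂/L₁ ≈ 0.1 to 0.6–0.8 with roughly
one run in six failing to elongate; mean L₂/L₁ grows with the adhesion
slope while L₃/L₁ stays flat; differential adhesion never reaches the
crawling model's elongation; pulling inflates run-to-run shape
variance; and the two repolarization rules produce significantly
different shape distributions.  Absolute MCS timescales and the exact
phase fractions are size-dependent and should not be compared
numerically with full-scale values.

## Numerical notes and limitations

* ΔH is computed locally and equals the full-Hamiltonian difference to
  < 1e−9 (tested over fuzzed proposals); per-cell moment bookkeeping is
  exact in double precision.
* The RNG inside the compiled kernel is xorshift128+, seeded via
  splitmix64 from the run seed; Python-level randomness (seeding,
  filopodium choice) uses numpy's PCG64 from the same seed.  Equal
  seed + config give bitwise-equal runs.
* Cells may fragment at extreme parameters (connectivity is not
  enforced); tissues can split at large λ_F.
* 3D simulation, cell growth/division, chemotaxis and junction-
  contraction convergent extension are out of scope.
* The location-based repolarization rule is an approximation of the
  original model's (which also assumed a global axis, removed here).
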