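# Methods

This note documents the models and procedures implemented in `bmcpore`, the
parameters that matter, the numerical choices behind them, and what the
synthetic-data validation does and does not demonstrate about real
molecular-dynamics data.

## Scope and data model

The package analyses protein structures and trajectories of BMC shell-protein
tiles; it does not run simulations. Structures are fixed-column PDB
(HETATM waters accepted; alternate locations other than blank or 'A' dropped,
giving a deterministic single-conformer model; models beyond the first
ignored with a warning). Trajectories are multi-model PDB, or binary DCD
behind a thin MDAnalysis adapter so the core stays format-agnostic. Units are
Angstrom and nanoseconds throughout; residue ids keep the 1-based author
numbering so residue labels such as M7 or Y41 match published structures.
Boxes are orthorhombic only.

Van der Waals radii come from a Bondi-style element table by default
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å, …), with atom-name entries taking
precedence and plain-text two-column radius files supported. Absolute pore
radii are radius-set dependent — the classic HOLE program ships a different
native set — so the radius table is an explicit, swappable input rather than
a constant, and quantitative agreement with any published absolute bottleneck
value should only be expected once the same radius set is used.

The atom-selection mini-language (`chain A and resid 5 to 10`, `name CA`,
`water`, `protein`, `element O`, with `and`/`or`/`not` and parentheses) is a
small recursive-descent parser evaluating to sorted atom-index arrays. It is
deliberately minimal: its operators obey exact set algebra, which the tests
verify against brute-force filters.

## Pore profiling

The pore radius in a plane perpendicular to the channel axis is

    r(z) = max_p  min_i ( ||p − x_i|| − R_i ),

the radius of the largest sphere centred in the plane that overlaps no
inflated atom (distances to atoms are 3D, so neighbouring planes' atoms
constrain the sphere). The maximiser is an improvement-only Monte-Carlo
search: proposals are uniform in a disc whose radius starts at
`mc_initial_step` (0.5 Å) and decays geometrically (factor 0.9) over 40
levels, about 1000 proposals in total, so the final step (~0.008 Å) resolves
well below the 0.05 Å validation tolerance. Three deterministic restarts are
run and the best result kept — a cheap guard against a walk stalling on a
shallow ridge. All randomness flows from an integer seed; results are
bit-reproducible.

Profiles march from a seed point (default: the selection's geometric centre)
in ±axis directions in `z_step` (0.25 Å) increments, seeding each plane's
search from the previous plane's centre so bent channels are followed. A
radius above `max_radius` (15 Å, chosen below typical half-box sizes) marks
the pore mouth and stops the march in that direction; a non-positive best
clearance marks a closed plane. Per-trajectory statistics are per-z mean,
median, min, and max across frames (missing planes beyond a frame's escape
point are excluded), plus a per-frame bottleneck time series. When comparing
with diameters quoted elsewhere, report 2× the bottleneck radius.

No periodic imaging is applied in the pore search: the pore interior of a
shell tile never crosses the box in the intended systems. This is a
documented limitation, not an oversight.

Validation: on stacked-ring fixtures the exact answer is
`ring_radius − vdw` at each ring plane (for an on-axis optimum); on random
50-atom cages the search is compared against an exhaustive 0.02 Å dense-grid
maximisation of the same clearance function. The acceptance suite requires
agreement within 0.05 Å everywhere.

## Stability metrics

RMSD uses Kabsch superposition (SVD with reflection correction) of a fit
selection onto a reference structure matched atom-by-atom on
(chain, resid, name); the metric is then evaluated over the analysis
selection. Whole-assembly and per-tile modes are separate calls: per-tile
fits each tile independently to its own reference, which distinguishes
internal tile deformation from inter-tile rearrangement. Smoothing is a
trailing 5-frame rolling mean (prefix frames average what is available), so
no future frames leak into a plotted point.

RMSF masks frames before an explicit equilibration cut, superposes every
retained frame onto the initial frame, and reports per-atom RMS deviation
about the time-mean position — hence invariance to global rigid motion. The
equilibration cut is a configuration input (defaults 200 ns for shell-like
and 500 ns for sheet-like conditions, matching how such cuts are typically
judged by inspecting the RMSD curve); no automatic change-point detection is
attempted.

## Solvation analysis

SASA is Shrake–Rupley: per atom, test points on a Fibonacci sphere of radius
`r_vdw + probe` are classified against all other inflated atoms
(KD-tree-pruned), and the accessible fraction scales the sphere area.
Defaults are probe 1.4 Å and 960 points — standard practice; both are
configurable. Residue values are sums over their atoms, so per-residue areas
partition the total exactly. Waters are excluded both as surface and as
occluders. At 960 points the isolated-sphere and two-sphere-cap closed forms
are reproduced well within 2% (observed ≲ 0.5%).

Water contacts count, per frame, water molecules with at least one atom
within 5 Å (minimum-image convention) of at least one residue atom, then
average over masked frames — matching per-frame pairwise-contact semantics. A
cumulative distinct-water count is available behind a flag because "unique
waters within 5 Å" is ambiguous between the two readings. Distances are
atom–atom minima over all residue atoms × all water atoms; a heavy-atoms-only
mode exists.

Residence times use the two-threshold hysteresis rule: an event starts at the
first frame a water is within the 5 Å contact cutoff, persists while it stays
within the 8 Å release cutoff, and ends the frame before it exceeds 8 Å;
re-entry opens a new event. Events still open at the last analysed frame are
closed there and flagged censored. Durations are `(end − start + 1) × dt`
with dt the (uniform) frame spacing. Per-residue means average over events,
censored included by default (a sensitivity flag excludes them): with few
trapped waters, per-water maxima would be noisier and censoring-dominated.
Wider release cutoffs can only lengthen an event that starts at the same
frame (monotonicity, tested).

Monomer segmentation classifies each non-trimer protein chain as
"buried-interface" if any heavy atom lies within 5 Å of a trimer heavy atom,
else "exposed" — buried-interface monomers emulate the assembled-shell
environment, exposed monomers emulate dilute tiles in solution. Class
averages report mean and SEM (sd/√n over monomer copies).

## XFMS dose–response

Fraction unmodified is `a_u / (a_u + Σ a_m)` from integrated peak areas. The
dose–response fit is unweighted nonlinear least squares of
`f(t) = A·exp(−k t)`; by default A is fixed at 1 because the fraction at zero
dose is 1 by construction, with a free-amplitude mode (A ∈ (0, 1.1]) for real
data that does not pass exactly through 1 and a weighted mode behind a flag.
Standard errors come from the fit covariance. Identically constant fractions
return k = 0 with a boundary flag; non-convergence raises. The fit is exactly
scale-equivariant in time (dilating exposures by c divides k̂ by c).

k-ratios propagate uncertainty to first order:
`σ_r = r √((σ_a/k_a)² + (σ_b/k_b)²)`; a zero denominator yields a flagged
undefined ratio rather than an exception. Ratio-vs-ratio comparison uses
ordinary least squares and the Pearson coefficient, with undefined simulated
ratios (e.g. zero SASA for buried residues) excluded and reported by site —
dropping them silently would bias the comparison invisibly.

The bundled experimental k table (six hexamer sites, solution and shell
conditions) ships as input data; dividing its printed rates reproduces the
published ratios to 2 d.p. for three sites, and within 1% for the other three
whose published ratios were evidently computed from unrounded fits. Grouped
sites ("M16, M23"; "P77, P79, P88") are single entities keyed by their
printed label; when mapped to structure metrics the metric is averaged over
the listed residues.

For the parameter-recovery study the simulated truth is k = 2.42 × 10⁻⁴ s⁻¹ —
the most prominent experimental rate (M7 in solution) — at the experimental
exposure schedule {0, 100, 250, 500, 750, 1000, 2000} s with 2% Gaussian
noise on fractions. Under these conditions 200-replicate median relative
error is ~3.5% and ±2·SE coverage ≥ 85%. Slower rates (≲10⁻⁴ s⁻¹) are
intrinsically less identifiable on this schedule; the bias study across
k ∈ {10⁻⁵, 10⁻⁴, 5×10⁻⁴} confirms estimates converge to truth as noise → 0.

## Rigid-body geometry

`superpose` is standard Kabsch (weighted, reflection-excluded); degenerate
collinear inputs are rejected. An independent quaternion (Horn) oracle in the
tests agrees to 10⁻⁸ Å. `tile_normal` is the right-hand-rule cross product of
two edge vectors from three monomer reference points; the sign convention is
exposed (swap or flip) since outward orientation is a modelling choice.

Assembly flattening rotates each tile rigidly about its centroid so its pore
normal aligns with the target axis, then translates the centroid into the
z = 0 plane. The per-tile normal is the least-squares plane normal of the
tile's atoms (tiles are thin, roughly planar multimers), sign-oriented toward
the target axis; this avoids having to designate specific reference atoms per
tile, and reduces to the exact normal for the symmetric synthetic tiles. The
operation is idempotent and preserves intra-tile distance matrices to
10⁻⁹ Å. Flexible (density-driven) relaxation after rigid placement is out of
scope; the output is the rigid arrangement that would serve as a fitting
target.

Synthetic density maps place a unit-integral isotropic Gaussian on each atom
with σ = resolution / (2√(2 ln 2)), i.e. FWHM equals the nominal resolution —
a documented convention choice, since blurring kernels vary between tools —
on a grid padded 3.5σ beyond the atom extent, written in OpenDX text format.

## Synthetic data: what it does and does not show

Every generator returns the data **and** its ground truth, computed directly
from the generating script (ring algebra, the scripted distance series, the
closed-form exponential) with no code shared with the analysis modules.
Scripted waters are 3-site (O plus two hydrogens offset perpendicular to the
placement ray) so "any water atom" contact logic is genuinely exercised while
the oxygen remains the nearest atom and the scripted distance stays exact.
Random-walk distance scripts are reflected Gaussian walks in [0.5, 20] Å with
0.8 Å steps — chosen to cross both thresholds frequently so event bookkeeping
(entries, rattling, exits, re-entries, censoring) is stressed.

Passing these tests establishes that the geometric and statistical machinery
is correct: the pore search finds true inscribed-sphere radii, the residence
state machine implements its rule exactly, SASA matches closed forms, fits
recover known rates. It does **not** establish anything about force fields,
sampling adequacy, or the biology of real shells: synthetic waters do not
diffuse physically, synthetic tiles have no side chains, and the demo systems
are orders of magnitude smaller than the microsecond-scale assemblies the
pipeline is designed to digest. Headline simulation observables (bottleneck
diameters, tens-of-ns retention at specific residues) require those real
trajectories as input.

## Pipeline and reproducibility

The end-to-end run is configured by one YAML file; unknown keys anywhere are
errors (no silent typos), defaults that mirror literature conventions
(5/8 Å cutoffs, 5-frame window, 200/500 ns cuts) are annotated in the echoed
config, and conditions are restricted to the labels {shell, sheet} while
remaining agnostic to what the coordinates actually are. Outputs are TSV/CSV
tables plus a manifest (package version, seed, config hash, file list); any
stage failure aborts with the stage name and removes partial outputs. A fixed
config and seed give byte-identical tables. Problem sizes in the test suite
and acceptance script (20 random cages × 3 planes for the grid oracle, 100
waters × 500 frames for the residence check, 200 fit replicates, 12-frame
demo systems) were chosen as the smallest sizes that still exercise every
code path and statistical claim.
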