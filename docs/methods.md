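# Methods

## Scope and units

`lipoarm` analyzes trajectories of the protein H–protein T interaction that
releases the aminomethyl lipoate arm from its protected cavity. It does not
run molecular dynamics: structural inputs are either user-supplied
(multi-model PDB / XYZ / internal CSV) or generated by the synthetic
subpackage. Units are fixed package-wide: coordinates in Å, structural time
in ns, Langevin time in ps, energies in kJ/mol, temperature in K, with
k_BT = R·T and R = 8.314×10⁻³ kJ/mol/K.

## Hydrogen-bond detection

A bond is recorded for every (donor, bonded hydrogen, acceptor) triple with
donor–acceptor distance ≤ r_DA and H–donor–acceptor angle ≤ θ_HDA. Defaults
r_DA = 3.5 Å, θ_HDA = 30° follow the conventional geometric criterion of the
gmx-hbond tool family; since published analyses rarely print their cutoffs,
both are config-exposed and should be logged with results. A bond is
*charged* when donor or acceptor carries nonzero formal charge; an optional
residue-group toggle extends this to net residue charge so carboxylates
annotated on the other oxygen still qualify. Detection is vectorized but
exhaustively equivalent to a triple loop (enforced by an oracle test).

π–sulfur contacts (e.g. S15 with the His-13 imidazole) use a pure
centroid-distance criterion, sulfur-to-ring-centroid ≤ 5.5 Å; angular
refinements are out of scope.

Note on residue naming: some descriptions of the release interchange
Asp-68 and Asp-69 as the State-III partner. The package treats **Asp-68**
as canonical (it is the residue used consistently in the state narrative);
Asp-69 should be read as an alias.

## State segmentation

Hallmarks: I = N17↔Glu-12/Glu-14, II = N17↔Ser-67, III = N17↔Asp-68,
IV = N17↔Tyr-70, V = N6↔Leu-35; a frame with no arm–cavity bond is
*released*; arm–cavity bonds matching no hallmark give *none*. When several
hallmarks co-occur, the later state wins — the release is a forward
progression, so ambiguity is resolved forward.

Raw labels are smoothed by a centered sliding majority vote (default window
11 frames = 1.1 ns at the default frame spacing — large against single-frame
flicker, small against the shortest ~20 ns dwell). Ties break toward the
later state; both raw and smoothed tracks are emitted because it is
generally unknowable whether published dwell times came from smoothed or
raw inspection.

The step report applies a furthest-state-reached convention (a frame below
the running maximum keeps the maximum), preventing transient back-flickers
from resetting dwell clocks and making the reported sequence non-decreasing.
Entry into state k is the first smoothed frame at or above k; step n =
entry(n+1) − entry(n); a state traversed with no frame of its own gets zero
duration and a skipped flag. Release time = entry(State V), the point at
which the arm has completely left the cavity; an alternative definition
(first fully bond-free frame) is available behind a flag. By construction
the traversed step durations sum exactly to the release time when State I
starts at t = 0. A trajectory that never leaves State I reports an explicit
null sentinel, not an error.

## Reaction coordinate, RMSD, clustering

The release coordinate is the distance between arm atom N17 and the center
of mass of all atoms of Glu-12 and Glu-14. COM weighting defaults to unit
masses (the toy atoms carry no meaningful elements); element masses can be
passed explicitly. RMSD uses Kabsch least-squares superposition (proper
rotation enforced; ≥ 3 non-collinear atoms required) with the first frame
as reference; the atom subset (e.g. backbone heavy atoms) is a required,
logged choice because published RMSD traces rarely pin it down.

Clustering is the neighbor-count algorithm: the frame with the most
neighbors within the RMSD cutoff seeds a cluster of itself and its
neighbors, members are removed, repeat. Default cutoff 1.0 Å suits the toy
systems and must be re-chosen for real ones. The representative structure is
the member of the largest cluster with the smallest average RMSD to the
rest of that cluster — the centroid-most-member reading of "smallest average
RMSD from the centroid of the largest population", which mixes two idioms;
we implement the member-based reading and note it as an interpretation. All
ties break toward the lowest frame index.

## Umbrella sampling and WHAM

Windows carry harmonic biases w_j(d) = k_j (d − d0_j)²/2. WHAM iterates

    P(x)   = Σ_i n_i(x) / Σ_j N_j f_j exp(−β w_j(x))
    f_j⁻¹  = Σ_x P(x) exp(−β w_j(x))

to self-consistency, measured as max |Δ ln f_j| < 10⁻⁶ (dimensionless;
published analyses report no tolerance, so this is a package default), with
at most 10⁵ iterations and a converged flag. F(x) = −k_BT ln P(x), anchored
to minimum zero over occupied bins. Default bin width 0.1 Å; empty bins are
masked, never interpolated or regularized. Samples are treated as
independent — no autocorrelation correction, matching the level of detail
of typical published workflows — with a subsampling stride exposed for
correlated input. An overlap diagnostic counts shared occupied bins for
adjacent window pairs and flags empty intersections. The main barrier is
max F over a peak interval minus min F over a preceding valley interval
(defaults [14.5, 16.5] Å and [7, 9] Å, bracketing stationary points F and C).

## Synthetic data: what it emulates, what it does not

**Reference landscape.** A monotone PCHIP interpolant through ten knots
traces the characteristic four-upward-step PMF with stationary points A–H.
The one hard constraint is F(15.5 Å) − C(8.0 Å) = 14.6 kJ/mol, the main
release barrier; the other knot values are package defaults chosen to
reproduce the qualitative shape, and are overridable. A boundary knot at
(3.75 Å, 0.5 kJ/mol) closes the evaluable range [3.75, 21.12] Å on the left
while keeping A(4.0 Å) the protected-state minimum.

**Langevin sampler.** Euler–Maruyama overdamped dynamics,
d ← d − (D/k_BT)·U′(d)·Δt + √(2DΔt)·ξ, with reflecting boundaries at the
landscape range edges. Defaults D = 0.05 Å²/ps, Δt = 0.2 ps, T = 300 K: at
the default umbrella spring (10 kJ/mol/Å²) the discrete-time stationary
variance then overshoots k_BT/k by ~2%, negligible against the 1 kJ/mol
barrier tolerance, and one 55 000-step window runs in well under a second.
Forces come from a dense (10⁻³ Å) precomputed derivative table with linear
interpolation. Umbrella defaults: 34 windows evenly spaced on
3.75–21.12 Å inclusive, spring 10 kJ/mol/Å², 50 000 production + 5 000
equilibration steps per window, per-window seeds derived deterministically
from the top-level seed.

**State schedules.** WT: I 0–40, II 40–240, III 240–260, IV 260–280 ns,
released at 280 (steps 40/200/20/20). S67Q: Step 2 stretched to 300 ns,
release at 380. S67Y is assigned the S67Q schedule, since the two mutants
behave alike (π-cation trapping in Step 2 with the same 300 ns dwell).
S67V and S67P skip State II entirely, reaching State III at 100 ns; their
totals are fixed at 200 and 150 ns, and the splits of steps 3/4 inside
those totals (75/25 and 30/20 ns) are package choices — only the totals and
the 100 ns I→III times are externally constrained. Each schedule ends with
20 ns of post-release frames.

**Toy trajectories.** An abstract cavity (chain A) places the hallmark
acceptor sites 6 Å apart along a release path, with Glu-12/Glu-14 flanking
the origin so that the bonded State-I N17 position is 2.75 Å from the
Glu-12 carboxylate oxygen and 2.77 Å from COM(Glu-12, Glu-14) — inside the
2.5–3.0 Å protected band. His-13 contributes a five-membered ring within
π–sulfur range of the State-I S15 position. Frame by frame, the scheduled
state's hallmark bond is realized exactly (2.75 Å, 0°); a construction-time
checker brute-forces every other arm↔cavity donor–H–acceptor triple in
every noiseless layout and requires it to violate the criteria by ≥ 0.5 Å
or ≥ 15°, so exactly one hallmark exists per frame by construction.
Per-coordinate Gaussian noise (σ = 0.05 Å) and hallmark flicker (p = 0.02:
the donor is displaced to 4.0 Å for one frame) exercise the smoothing;
both are small enough that planted-schedule recovery stays unambiguous at
the default frame spacing (0.1 ns).

What the toy data does **not** emulate: real side-chain chemistry and
sterics, solvent, competing non-hallmark interactions, gradual transitions
between states (switches are instantaneous), back-transitions, or
force-field energetics. Passing the recovery tests therefore demonstrates
the correctness of the detection/segmentation/WHAM machinery on planted
truth, not the reproduction of all-atom MD observables on real proteins.

## Activities and correlation

Enzyme activities are experimental inputs (CSV: variant, activity, unit);
the package never computes them. The packaged example table encodes the
qualitative pattern only — fast-releasing mutants (S67P, S67V) above wild
type, slow ones (S67Q, S67Y) below — with clearly illustrative numbers.
Pearson's r (two-sided p from the t transform on n−2 degrees of freedom)
matches the linear trend the release-time/activity comparison presents;
Spearman is available behind a flag. The correlation requires ≥ 3 matched
variants, rejects constant inputs explicitly, and the wild type anchors
relative activities in the run report.

## Problem sizes and determinism

Default analysis runs use 1 700–4 000 frames per variant (0.1 ns spacing)
and 1.7×10⁶ umbrella samples; the full acceptance run completes in a few
seconds on one CPU. Every stochastic component takes an explicit seed;
regeneration under the same seed is bitwise identical, and derived
sub-seeds stay below 2³¹.

## Known limitations

* No MBAR, no bootstrap error bars on the PMF, no 2D coordinates.
* No hidden-Markov state estimation; labeling is rule-based by design.
* No periodic-boundary handling or compressed binary trajectory formats.
* The gap between toy geometry and real structural ensembles (above) means
  thresholds tuned here (clustering cutoff, smoothing window) must be
  revisited for real trajectories.
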