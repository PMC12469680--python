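# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators emulate (and what they do
not), and the numerical choices that matter for reproducibility.

## Scientific setting

Antithrombin (AT) is a serpin whose reactivity toward factor Xa is controlled
allosterically: the native protein sits almost entirely in a repressed (R)
conformation, and binding of the heparin pentasaccharide at a site opposite
the reactive center loop (RCL) shifts it to an activated (AH) conformation
whose second-order association rate constant toward factor Xa is roughly
three orders of magnitude higher. The residues that hold the R state locked —
an allosteric communication network spanning helices D and E, β-sheet A and
the RCL hinge — can be nominated structurally (they move the most between the
two crystal forms) and interrogated functionally (mutating them activates the
native protein, destabilizes it thermally, and changes its tryptophan
fluorescence). The package implements the desk side of that whole program.

## Conformer comparison (`structio`, `confdiff`)

**Superposition.** Two conformers are paired residue-by-residue using residue
number + insertion code (both antithrombin entries use mature numbering, so
no sequence alignment is needed). The backbone atom set is N, CA, C — the
minimal unambiguous reading of "backbone atoms"; O can be added via the
`atoms` argument. Each cycle is a closed-form Kabsch fit followed by
rejection of atom pairs deviating more than `trim_sigma` (default 2.0)
standard deviations of the current deviation distribution, for at most
`max_cycles` (default 5) cycles. Both knobs are exposed because published
overlay endpoints depend on the trimming schedule; the retained pair set,
cycle count and final RMSD are all reported so the schedule is auditable.

**Distal side-chain carbon.** Each residue is represented by its most distal
side-chain *carbon*: the carbon with the largest bond-graph distance from CA,
computed by breadth-first search over the side-chain covalent topology
(heteroatoms are traversed but never selected — ARG ends at CZ, LYS at CE,
MET at CE through the sulfur). Ties at equal bond distance (LEU CD1/CD2, VAL
CG1/CG2) are broken by the larger Euclidean distance from CA in the conformer
at hand, then lexicographically, which is deterministic and conformer-aware.
PRO is traversed from CA through CB, giving CD. Glycine has no side-chain
carbon and is skipped by the scan. If the top-ranked carbon is missing from
the model the next rank is used and the record is flagged. Because the His
convention (CE1 vs CD2) is not universal, the table accepts per-residue-type
overrides.

**Displacement scan and pair distances.** After mapping the mobile conformer
into the reference frame, the per-residue displacement is the distance
between the two distal carbons; records are ranked largest-first. "Core
residue" is taken as *every* shared residue — ranking makes a burial filter
unnecessary. Intra-structure pair distances are plain Euclidean distances
between two distal carbons of one model, with no superposition involved.

**Deviation maps.** Per-atom deviations between two matched-roster models,
aggregated per residue as the RMS of its atoms. Values are clipped to the
colour scale (default 0–5 Å) only in the rendering channel, never in the
numeric output, and maps subtract to signed difference maps (mutant − WT).
Mismatched atom rosters are an error rather than a silent intersection.

## Inhibition kinetics (`kinfit`)

Progress curves measured under pseudo-first-order conditions (inhibitor at
≥ 10-fold excess over protease; flagged on the input object) are fitted to
A(t) = A0·exp(−k_obs·t) with the endpoint fixed at zero, matching how
serpin inhibition reactions are driven to completion. The fit is unweighted
ordinary least squares (relative weighting is available behind a flag), with
initial values from a log-linear regression. A floating-endpoint variant
exists but is off by default. Curves without a genuine decay (terminal
activity above 90% of the initial level, or a non-positive fitted rate)
raise a distinct "no inhibition detected" error.

The second-order rate constant is k2 = k_obs·SI/[inhibitor]: the
stoichiometry of inhibition SI (moles of inhibitor consumed per mole of
protease inhibited) corrects the effective inhibitor concentration for
turnover through the substrate pathway. SI itself comes from the abscissa
intercept of a linear regression of residual activity on inhibitor:protease
ratio; points below 5% of the uninhibited activity (the post-equivalence
plateau) are excluded before fitting, and a total decline of less than 5% is
rejected as "no titration".

**Activation arithmetic.** Fold activation is k2_variant/k2_native_wt, and
percent activation maps the fold onto the native→activated window as
100·(fold−1)/(window−1), so the unactivated native protein reads 0% and the
fully activated form 100%. The alternative fold/window definition differs
by under half a percentage point anywhere in the window of interest; the
convention used is recorded in the result object. The window itself (e.g.
360-fold) is an input, never recomputed from other printed rates, because
reported windows and reported endpoint rates are generally rounded
independently.

**Two-state partition.** Observed native reactivity is modelled as the
population-weighted average of the R and A rates,
k_obs = f_R·k_R + f_A·k_A, giving f_A = (k_obs−k_R)/(k_A−k_R). With
k_obs = 4×10³, k_R = 7.5×10² (midpoint of the 0.5–1×10³ bracket for the
immobilized-hinge R form) and k_A = 1×10⁶ M⁻¹s⁻¹, the native equilibrium is
≈ 99.7% R.

## Mutant-cycle coupling (`mutcycle`)

For mutations a, b over a background set bg, the coupling index is
CI = (k_{bg+a}·k_{bg+b})/(k_bg·k_{bg+a+b}). Additive (multiplicative-on-rate)
effects give CI = 1; a double mutant that gains *less* than the
multiplicative prediction gives CI > 1, the signature of a shared,
cooperative function. The orientation was chosen so that "CI > 1 =
cooperation" holds for exactly that sub-multiplicative pattern; the
reciprocal convention is available behind a flag and the convention used is
stamped into every result. The interaction free energy is dG = R·T·ln CI
with R = 1.987×10⁻³ kcal·mol⁻¹K⁻¹ and T defaulting to 298.15 K (assays at
25 °C). When standard errors accompany the rates, the CI error is propagated
to first order in log space. The conditional cycle over a third mutation
exposes the three-body term dG(a,b|c) − dG(a,b), which is identically zero
for tables generated without three-body energies — the quantity that drops
to zero when a third network residue gates a pairwise linkage.

Numeric CI values for the real mutants live in a bar plot and an appendix
rather than printed text, so the coupling stage is verified by an exact
synthetic round trip: tables built from arbitrary single energies plus
prescribed pairwise interaction energies return each interaction energy to
10⁻⁶ kcal/mol.

## Thermal denaturation and fluorescence (`thermflr`)

Melting curves (tryptophan fluorescence vs temperature, 20–85 °C scans at
2–5 °C steps) are fitted to a two-state van't Hoff model with *linear*
pre- and post-transition baselines — tryptophan fluorescence drifts with
temperature, and flat baselines are the degenerate special case:

F(T) = [F_n(T) + F_u(T)·K(T)]/[1+K(T)],
K(T) = exp[−(ΔH_vH/R)·(1/T − 1/Tm)].

Temperatures are converted to Kelvin for fitting and reported in °C. At the
fitted Tm the folded fraction is exactly 0.5 by construction. The fit uses
variable projection: the four baseline parameters are linear given (Tm,
ΔH_vH) and are profiled out by linear least squares, leaving a
two-parameter nonlinear problem solved with an analytic (Kaufman) Jacobian
and finished with plain Gauss–Newton steps. This keeps the problem well
conditioned and makes the fitted Tm invariant under affine rescaling of the
fluorescence axis to ~10⁻¹³ °C; a naive six-parameter fit with
finite-difference gradients reproduces Tm only to ~10⁻⁸ °C across such
rescalings. Tm is initialized at the steepest point of the curve; a Tm at a
scan boundary sets a warning flag rather than failing. Curves without a
detectable transition (signal range under 3× the local point-to-point noise,
or indistinguishable from a straight line) are rejected. Aggregation
artifacts above a user cutoff can be masked.

Baseline fluorescence is the OLS slope of buffer/volume-corrected
fluorescence against protein concentration; the correction dialect is
F_corr = (F_raw − F_buffer)·(V_total/V_initial), applied at parse time.
The pentasaccharide-induced gain is 100·(F_sat − F_base)/F_base, with the
wild-type protein gaining about 40%.

## Trajectory dynamics (`trajdyn`)

Trajectories (multi-model PDB or a plain text frames × 3N matrix) are
reduced to Cα atoms and every frame is Kabsch-aligned onto a reference frame
— by default frame 0 of the *full* trajectory, so windowing never changes
the anchor. The analysis window keeps the trailing ceil(fraction·n_frames)
frames (15% of a 50,000-frame, 1 µs run is 7,500 frames from index 42,500).

**PCA.** The flattened, per-window mean-centered coordinate matrix is
decomposed by SVD; variance ratios are fractions of the total variance, so
they match eigenvalue ratios of the brute-force sample covariance to
≤ 10⁻⁹. Component signs are fixed (largest-magnitude element positive) so
projections are reproducible across runs and libraries. Drift in the
(PC1, PC2) plane is the distance between the mean projection of the first
and last 5% of frames (both fractions configurable), a scalar summary of
whether a run walked somewhere or dithered in place.

**Correlation maps.** The default residue–residue map is the standard DCCM,
ρ_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), with Δr the deviation from the
time-mean position. A frames × 3N flattening would natively give a 3N × 3N
matrix; since the target object is residue × residue, the vector correlation
is the default and a per-coordinate-averaged Pearson variant sits behind a
flag, with the mode stamped into the output. Zero-variance residues yield
NaN rows plus a warning rather than silent zeros. Differential maps are the
direct subtraction Δρ = target − reference; entries with |Δρ| below the
threshold (default 0.5) are zeroed only in the visualization copy, and the
most positive / most negative upper-triangle pairs are ranked.

## Synthetic data (`synthgen`)

Each generator draws from the exact model its analysis fits and echoes the
generating parameters as truth. All randomness comes from seeded numpy
generators, so identical parameters give bit-identical fixtures. Noise is
Gaussian throughout: multiplicative for activities and fluorescence
(instrument-like), additive and isotropic for coordinates.

Defaults mirror the study conditions: progress curves encode
k2 = 4×10³ M⁻¹s⁻¹ at 0.5 µM inhibitor with 2% noise over 12 points spanning
three decay times; titrations decline linearly to zero at the true SI;
melting curves use Tm = 63 °C, ΔH_vH = 150 kcal/mol on a 20–85 °C grid;
the wild-type fluorescence preset steps up by 40% with 1% noise; conformer
pairs are idealized poly-alanine chains in which only the prescribed distal
carbons move (plus an optional global rigid motion), since the scan contract
needs nothing else.

Trajectories are built as base + Σ aᵢ(t)·vᵢ + ε over orthonormalized mode
vectors with isotropic noise. Mode amplitudes are standardized to exact
sample moments (zero mean, stated variance, zero cross-correlation) so the
analytic variance ratios hold exactly at zero noise rather than only in
expectation. The injected-coupling fixture adds one shared in-phase mode
confined to two residue blocks whose amplitude std is set analytically from
the target block correlation ρ as noise_std·√(3ρ/(1−ρ)); the base noise and
mode streams use sub-seeds independent of the coupling option, so the
coupled trajectory and its uncoupled twin share every other displacement
bit-for-bit — the cleanest possible null for differential-correlation
ranking.

**What the generators do not emulate:** real side-chain geometry, crystal
packing, correlated (non-isotropic) instrument noise, irreversible
aggregation in melts, slow-binding inhibition, and force-field dynamics.
Passing the synthetic suite therefore demonstrates correctness of the
estimators on their own model classes and their noise robustness at realistic
levels — not robustness to model misspecification in real data.

## Problem sizes

The regression suite uses 500 progress curves for the rate-recovery sweep,
200 replicates at the 2%-noise reference condition, 100 melting curves at 1%
noise, 50 seeds × 1,000 frames × 40 residues for the correlation null, and
2,000-frame, 60-residue trajectories for the PCA oracle and
injected-coupling checks — sizes at which every stochastic tolerance in the
suite was comfortably stable across seeds while the whole suite stays fast
on a single CPU.

## Real-structure checks

The distance and overlay checks against the two antithrombin crystal forms
need the PDB entries 1T1F (native R form) and 1EO3 (pentasaccharide-bound
form) on disk under `data/structures/`; `scripts/fetch_structures.py`
downloads them once. Which chain of each multi-copy asymmetric unit the
published distances refer to is not stated anywhere; `chain="auto"` picks
the first chain containing residue 393 (the P1 position), and the chain plus
trimming schedule are recorded in the outputs rather than guessed at.

## Known limitations

* PDB input only (no mmCIF), no hydrogens, no structure repair.
* Cross-conformer residue pairing is strictly by number + insertion code.
* The kinetics module does not model slow-binding or substrate-competition
  mechanisms; the melt module is van't Hoff only (no calorimetric ΔCp).
* Compressed MD formats are out of scope; convert to multi-model PDB or a
  coordinate matrix first.
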