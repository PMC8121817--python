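# Methods

## Scope and model

The package estimates mean backbone (Cβ–Cβ) distances in tetrameric ion
channels from transition-metal-ion FRET quenching measurements, and turns
them into harmonic restraints for structural refinement. The chain is:

1. per-patch unquenched fractions F from background-subtracted ROI
   intensities before/after metal application;
2. site-specific FRET efficiency by the nonspecific-quenching correction;
3. a Förster-Convolved-Gaussian (FCG) standard curve — the Förster
   efficiency averaged over a Gaussian distance distribution — calibrated
   by a single shared width σ;
4. inversion of the calibrated curve, with Monte-Carlo propagation of the
   measurement s.e.m.s;
5. symmetry-classified distance predictions from tetramer structures and
   constraint-file export.

## Quenching model and the correction formula

FRET to the engineered acceptor and nonspecific quenching (solution
quenching, off-target labeling) are treated as independent de-excitation
pathways, so their rates add. Writing each pathway's strength as the odds
x = 1/F − 1 of a photon being lost, the with-site and no-site constructs
satisfy 1/F_site − 1/F_no_site = E/(1−E), which rearranges to the corrected
efficiency

E = (F_no_site − F_site) / (F_site·F_no_site + F_no_site − F_site).

Under this rate-additive model the correction is *exact*, and the synthetic
generator draws with-site fractions as
F_site = F_ns(1−E) / ((1−E) + E·F_ns) so that a zero-noise cohort closes
the loop identically. A multiplicative model (F_site = F_ns·(1−E)) would
be inconsistent with the correction — at F_ns = 0.9 the recovered
efficiency would be biased by ≈ 5% — which is why the generator does not
use it.

Per-patch efficiencies use each patch's own F_site with the *averaged*
F_no_site of all control patches under the same condition. Statistics
(mean, s.e.m. = sd/√n over independent patches) are computed on unclipped
values; reported point values outside [0, 1] are clipped with a warning.
Donor brightness is environment-sensitive and changes with voltage, so F is
always formed within one voltage, never across voltages.

## FCG relation

fcg_efficiency(r̄; R0, σ) = ∫ N(r; r̄, σ²) · 1/(1+(r/R0)⁶) dr over
r ∈ [r_min, r̄+6σ], with the truncated Gaussian renormalized to unit mass.

- **Truncation** r_min = 2 Å (hard-sphere floor): keeps the density proper
  without perturbing σ = 5 Å cases at r̄ > 10 Å (the truncated mass there
  is < 0.06%).
- **Quadrature**: trapezoidal at a fixed step (default 0.05 Å, required to
  be ≤ σ/5), with an automatic step-halving check; a change > 1e−6 raises
  a numerical error rather than returning a silently coarse value.
- **Inversion**: the curve is strictly decreasing, so a Brent root find on
  the default [2, 80] Å bracket converges to 0.01 Å; requests outside the
  attainable efficiency range raise an error naming the attainable
  interval. Batch inversion (used by the Monte-Carlo propagation)
  interpolates a 0.02 Å-step monotone grid, which agrees with the scalar
  root finder to well below the 0.01 Å tolerance.

**Calibration.** σ is fit globally — one shared width across all
calibration pairs — by bounded scalar least squares on
Σ(Eᵢ − FCG(dᵢ; R0ᵢ, σ))², deterministic given the pairs. Distances enter
in r/R0 units in the fitted reporting curve, so pairs measured with
different donor Förster radii share one relation; a per-pair σ mode is
deliberately excluded (one measurement per pair cannot constrain it). Both
"fit σ" and "fix σ" usage are supported; the pipeline and CLI default to a
fixed σ = 5 Å, the width that describes transmembrane-to-C-linker pairs.
Fits landing within 1% of a search bound are flagged with a warning.

## Spectra and Förster radius

J = ∫f_D(λ)ε_A(λ)λ⁴dλ / ∫f_D(λ)dλ with the donor emission area-normalized:
J is invariant to donor amplitude and linear in acceptor extinction.
Spectra are linearly interpolated to a common 1 nm grid over the union of
supports (zero outside each spectrum's own support); disjoint supports give
J = 0 with a warning rather than an error. R0 = C(J·Q·η⁻⁴·κ²)^(1/6) with
η = 1.33 (aqueous saline), κ² = 2/3 (transition-metal acceptors have
multiple transition dipoles, so the isotropic value is appropriate), and
C = 0.211 for J in M⁻¹cm⁻¹nm⁴ and R0 in Å — the standard constant for this
unit convention, which the package treats as declared configuration.
Relative quantum yields come from through-origin least-squares slopes of
donor vs. YFP intensity (expression tracking), scaled by a reference
yield and the measured brightness ratio between voltages; no absolute
donor quantum yield is hard-coded.

## Structure distances

Tetramers are read with gemmi (PDB or mmCIF; first model, altloc A,
occupancy ignored — the single-model cryo-EM convention). Protein chains
sharing a sequence form the ring; their centers of mass lie on a circle
about the pore axis, recovered as the best-fit plane normal (SVD), and
angular order defines adjacency. Distances are donor Cβ on one reference
chain to acceptor Cβ on all four chains (Cα fallback for glycine), labeled
same / adjacent_1 / adjacent_2 / diagonal. The single "adjacent" summary is
the minimum of the two neighbors (the two are generally unequal because the
donor and acceptor rings are phase-offset); both raw values stay in the
table. Rate shares per relation pool the two adjacent chains and are
independent of R0 (the (R0)⁶ factor cancels in the normalization).

Residue numbering between homologous channels is mapped by global pairwise
alignment (BLOSUM62, affine gaps, via Bio.Align); positions in gap columns
raise an unmapped-position error. No curated mapping table for any
specific channel pair ships with the package; mappings are built from
user-supplied sequences.

Constraint files are plain text, one
`AtomPair CB <res><chain> CB <res><chain> HARMONIC <distance> <sd>` record
per line, with the refinement weighting scheme (coordinate weight 1,
atom-pair weight 2, atom-pair cutoff 6 Å, experimental weight
40 kcal/mol/Å²) in header comments, and byte-stable output. The harmonic sd
defaults to the Monte-Carlo-propagated distance s.e.m.

## Boltzmann G-V fitting

G/Gmax = 1/(1+exp[(V−V1/2)/Vs]); Vs > 0 gives activation by
hyperpolarization. Tail currents are fit directly with free Gmax
(normalization by fitted Gmax is more robust than max-point normalization
when the most hyperpolarized pulse reaches only partial activation; a
max-normalization mode exists). Initial guesses: V1/2 from the half-range
crossing, |Vs| = 10 mV with sign from the direction of activation, Gmax
from the largest-magnitude current. Inward (negative) tail currents are
handled by a sign convention that keeps Gmax > 0.

## Monte-Carlo uncertainty propagation

Inputs are sampled from normal distributions at their measured mean and
s.e.m., truncated to the physical F interval (0, 1.2] (tolerating noise
slightly above 1). Each draw is pushed through the exact correction and the
FCG inversion; the reported value and s.e.m. are the mean and standard
deviation of the propagated distribution. Draws producing a non-positive
correction denominator, or efficiencies outside the attainable FCG range,
are rejected and counted (warnings above 1% and 5% respectively). Default
10⁵ draws; zero-s.e.m. inputs short-circuit to the deterministic value.
Seeds are required in the CLI and threaded through every stage, so
identical configuration and seed give byte-identical outputs.

## Synthetic-data generator

The generator stands in for undeposited raw measurements and defines the
conditions under which the pipeline is validated:

- Förster radii 13.3 Å (0 mV) and 13.0 Å (−100 mV) — donor photophysics
  differ slightly between voltages;
- true state distances 24 / 20 / 21 / 18 Å for resting-cAMP / resting-apo /
  activated / inactivated, spanning the 15–25 Å tmFRET working range with
  the expected ordering (ligand-free closer than ligand-bound, shorter at
  −100 mV);
- distance heterogeneity σ = 5 Å; nonspecific unquenched fraction
  F_ns = 0.9; donor brightness ×1.26 at −100 mV;
- lognormal patch-to-patch expression scaling (sd 0.4 in log space) applied
  identically to donor and YFP intensities — this is what makes the
  donor-vs-YFP slope a yield estimator;
- background offsets (50 a.u. on a 1000 a.u. donor signal) and 3% Gaussian
  noise on every recorded intensity, matching few-percent s.e.m.s at
  n = 3–7 patches;
- 5 patches per condition per construct by default.

Calibration-pair, spectra (Gaussian emission × flat extinction, with
closed-form J = ε(μ⁴+6μ²s²+3s⁴) and, on request, the Q that makes the
Förster-radius equation hit a target R0 exactly), G-V, and structure
generators follow the same pure-function-of-(parameters, seed) contract.
Structure fixtures are exactly C4-symmetric poly-alanine chains with probe
Cβ atoms at analytic ring positions; a two-ring solver reconstructs a
geometry consistent with any given (same, adjacent, diagonal) distance
triple, which is how reference distance sets are realized as synthetic
stand-in structures (labelled as such — they are constructed geometries,
not deposited coordinates).

**What the generator does not emulate**, and hence what passing tests do
not show about real data: photon-level camera noise, bleaching and
time-resolved fluorescence, probe rotamer clouds (distances are treated as
backbone-to-backbone), imperfect labeling stoichiometry, correlated
background drift within a patch, and any deviation from the rate-additive
quenching model. Recovery performance on real patches depends on those
factors; the closed-loop tests certify the *analysis*, not the assay.

## Problem sizes in the validation suite

Monte-Carlo studies use 200 replicates for σ recovery (noise sd 0.03 on
eight pairs), 100 replicates for Boltzmann recovery (noise sd 0.03 on 12
voltages), 10⁵ draws for uncertainty propagation, and 8 cohorts × 4 states
for end-to-end coverage — sizes at which medians and coverage fractions
are stable to well within the asserted tolerances. The end-to-end
"within 2 propagated s.e.m." check is asserted as ≥ 28/32 recoveries
within 2 s.e.m. (and all within 4), since a 2-s.e.m. band is a ~95%
coverage statement, not a per-realization guarantee.

## Known limitations

- κ² is a scalar; orientation distributions are out of scope.
- The FCG assumes one shared σ across sites and states.
- Efficiencies near the flat tail of the FCG curve (E ≲ 0.05 at r̄ ≫ R0)
  invert with large, skewed distance uncertainties; the Monte-Carlo s.e.m.
  reflects the spread but the mean of a strongly skewed draw distribution
  can sit above the deterministic inversion.
- Ring ordering assumes an approximately symmetric tetramer; heavily
  asymmetric assemblies would need explicit chain assignment.
- Constraint export records the refinement weighting scheme; running the
  refinement itself is downstream of this package.
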