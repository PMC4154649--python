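# Methods

## Model and assumptions

pepflux works on carbon-transition metabolic networks: each internal reaction
carries an atom mapping (one lowercase letter per carbon, a bijection between
reactant and product sides), and the culture is assumed to be at both
metabolic and isotopic steady state.  Fluxes are dimensionless, normalized so
that substrate uptake equals one.  Reversible reactions are split into an
irreversible forward/backward pair with the inverse mapping; the backward
flux is capped at a configurable multiple of the uptake (default 10).  A
metabolite is *balanced* (receives a stoichiometric-matrix row) iff it has at
least one producing and one consuming flux; terminal sinks and substrate
pools are exchange pools.  Substrate labeling is given either per carbon
position (independent ¹³C purity per position; positions not covered default
to natural abundance 0.0107, configurable) or as explicit MDVs for individual
substrate fragments — the latter form is how correlated labeling (e.g. a
mixture of fully labeled and unlabeled molecules, or a predicted
exchange-metabolite labeling) enters.

## Labeling simulation (EMU cascade)

Target fragments are traced backward through the atom mappings.  The
resulting elementary-metabolite-unit graph is acyclic across fragment sizes:
a size-k fragment depends only on fragments of size ≤ k, and a reaction that
assembles a product fragment from two or more reactant fragments introduces a
combined node whose MDV is the convolution of its (strictly smaller)
constituents.  Per size stratum the steady-state balance

    (Σ_producing v_j) · X_e = Σ_producing v_j · X_source(j,e)

is one sparse linear system, solved with a direct LU factorization in
increasing size order.  Fragments with numerically zero production are either
flagged (`DeadEMUError`) or, inside an optimizer where a flux may touch zero,
pinned to the unlabeled MDV — they carry no material downstream, so the
convention does not affect the objective.

The **isotopomer oracle** is an independent check: it solves the complete
2^C positional-isotopomer balance per metabolite.  Without condensation this
is a single linear solve; condensation couples reactant distributions
bilinearly and is handled by fixed-point iteration of exact linear solves
(sup-norm tolerance 1e-13).  It is exponential in carbon count (per-metabolite
cap 12 carbons) and exists purely to validate the EMU cascade, which the test
suite does to 1e-8 over hundreds of random feasible flux profiles.

## Natural-abundance correction

Observed MDVs include mass shifts from heavy isotopes of atoms that are not
traced carbons.  A correction matrix is lower-triangular with every column
holding the molecular shift distribution — the convolution of per-atom
binomials with standard abundances (²H 0.000115, ¹³C 0.0107, ¹⁵N 0.00364,
¹⁷O 0.00038, ¹⁸O 0.00205, ³³S 0.0075, ³⁴S 0.0421) — truncated at a
configurable window (default +4 mass units; truncated columns sum to < 1 and
the corrected MDV is renormalized).  Free-amino-acid formulas are bundled for
all twenty residues; the padding residue X uses the identity.  Corrections
are applied **per residue before convolution** (the per-amino-acid form);
applying one peptide-level matrix built from the summed formula is
mathematically equivalent for the carbon-independent heteroatom part and is
not separately implemented.  The bundled synthetic pipeline leaves
corrections off by default so that closure tests are exact; they are an
opt-in argument wherever residue MDVs are consumed.

## Peptide labeling

A peptide's MDV is the left-fold of convolutions of its residue MDVs —
equivalent to multiplying the residues' generating polynomials, hence
order-independent and mean-mass additive.  Panels therefore keep one peptide
per composition multiset.  Panel selection sorts candidates by (length,
sequence), shuffles with a seeded generator, and takes greedily subject to
composition distinctness; in community mode a peptide present in more than
one supplied proteome is excluded (string-level uniqueness, not an MS
detectability model).  Digestion is trypsin by default: cleave C-terminal to
K/R except before P, configurable missed cleavages.  Peptide MDVs are kept
full-length internally; comparisons against measurements use the overlapping
mass range, so windowed (e.g. first 10 shifts) experimental tables are
accepted as-is.

## Flux fitting

The fit minimizes Σ_targets Σ_m ((MDV_sim − MDV_obs)/σ)² over the polytope
{S·v = 0, lb ≤ v ≤ ub, measured fluxes fixed}.  Equalities are eliminated by
optimizing over v(θ) = v₀ + N·θ with N an orthonormal null-space basis of the
stacked stoichiometry/equality system and v₀ a maximum-slack interior point
(LP); bound constraints map to linear inequalities in θ.  The solver is
SLSQP with finite-difference gradients, multi-start (default 10 starts: the
interior point plus seeded hit-and-run samples); all starts are logged and
the best converged start is returned.  σ is the per-element measurement error
bound, with 0.01 substituted where the table gives none.  Objective tolerance
1e-9.

**Confidence ranges** follow flux variability under labeling constraints: for
each flux, minimize and maximize it subject to the simulated labeling staying
elementwise within the error bounds (the bounds are used verbatim — a zero
bound collapses the range onto the best fit).  These are 2·|J| local NLPs
warm-started from the best fit; a failed subproblem is recorded per flux and
the best-fit value stands in.  Fluxes pinned by the equalities (null-space
row ≈ 0) are reported with zero width without optimization.

## Flux information content

FIC = −k · ln Π_j max(width_j, ε) with k = 1 and floor ε = 0.01 on every
range; the product is the enveloping-box approximation of the compatible
flux-space volume.  FIC curves add panel peptides cumulatively in the
deterministic selection order and report the smallest size whose FIC reaches
the amino-acid reference (strict ≥ up to 1e-6); the reference is computed
from the same underlying amino-acid MDVs with the same error bound.
Averaging over random panel orders is available by re-running with different
selection seeds.

Two properties of this box-level construction are worth stating plainly.
First, with a *shared elementwise* error bound the peptide FIC can overshoot
the amino-acid FIC past the crossing: a peptide containing k copies of one
residue has MDV elements up to k-fold more sensitive to a flux than the
residue itself, so individual peptide constraints can be tighter than the
amino-acid ones.  Second, in a mode-limited regime (ranges above the ε floor
in both modes) the peptide widths converge to a constant multiple (~1.2–1.3×
on the bundled central-carbon fixture) of the amino-acid widths, and strict
crossing may never occur.  The bundled crossing experiment therefore runs at
σ = 0.002, which places well-determined fluxes below the ε floor in both
modes — the regime in which the reference amino-acid analysis itself
operates (confidence intervals limited by network position, identical across
modes), and in which the crossing is finite and robust to the sampled ground
truth.  Elsewhere the default σ stays 0.01.

## Noise model

Measurement noise is multiplicative-relative uniform, MDV′(m) =
MDV(m)·(1 + Δ·r), r ~ U(−1, 1) independently per element, at amplitudes
Δ ∈ {0.05, 0.08, 0.10} for the degradation studies.  The noisy vector is
clamped at zero and renormalized to sum one so it remains a valid MDV;
renormalization can be disabled (the raw form is exactly mean-preserving).
The error bound attached to noisy data is Δ itself, overridable to study
lack of fit at fixed instrument precision.

## Community solving

With species-unique peptide panels and an acyclic exchange graph, species are
fitted in topological order; each downstream species receives, as substrate
labeling, the MDVs of *every sub-fragment* of each exchanged metabolite
predicted from the upstream best fit (a whole-molecule MDV alone would not
determine the fragment MDVs the downstream cascade needs).  Cyclic exchange
topologies raise a clear error rather than iterating silently; upstream
non-convergence marks dependents as blocked.  Species biomass fractions
enter only the bulk-mixture construction Σ_s x_s·f_s used to demonstrate why
fitting species-blind averaged labeling does not return the average flux
profile (the flux-to-labeling map is nonlinear); the community solver itself
never needs them because peptides are species-resolved.  A metabolite a
consumer does not incorporate into the measured products simply has no route
from its pool to the targets, which encodes "passed through, not assimilated".

## Synthetic study systems

The generator emulates: defined positional substrate labeling, steady-state
labeling of amino-acid precursor fragments (a residue → fragment map plays
the role of biosynthetic precursor assignments), tryptic peptide supply from
a proteome, measured uptake/secretion rates, and instrument noise of the
stated form.  It does **not** emulate GC-MS fragmentation of derivatized
amino acids, peptide detectability/ionization, retention behaviour,
isotopic-envelope deconvolution, or non-steady-state labeling — so passing
tests show correctness of the inference machinery under the stated model,
not robustness to those instrument effects.  Fixture sizes: the two-route
splitter has 6 fluxes / 1 free; the condensation variant 8 / 2; the reduced
central-carbon model 14 fluxes / 1 free after fixing uptake, secretion and
the biomass-like drain (all extracellular rates measured, as in a real
experiment — leaving the drain free gives a second, weakly determined
direction in which the pure-15-mer group plateaus just below the amino-acid
FIC; see above); the two-species chain has one free flux per species.  Toy
proteomes are built from composition-distinct tryptic "words" (40 per length
class per fixture) over alphabets restricted to mapped residues.  Flux
profiles are sampled uniformly by hit-and-run on the null-space polytope
(1000 burn-in steps, seeded).

## Numerical choices and degenerate inputs

Sparse LU per EMU stratum; MDV unit-sum checked to 1e-9 in strict mode and
renormalized silently inside optimizers (an SLSQP line search may probe
slightly infeasible profiles); measurement tables renormalize only when the
deviation is ≤ 1e-6, else error; zero-production fragments as above; panels
reject anagrams at construction; ties in panel selection are broken by the
sorted order before shuffling, making every pipeline output reproducible
from its seed.  Interior-point search failure (empty polytope) and
all-starts non-convergence are distinct, named errors.

## Limitations

- Local NLP only: no global-optimality certificate, no Monte Carlo posterior.
- The enveloping box overestimates the compatible volume of correlated flux
  ranges; FIC values are comparable within a network, not across networks.
- The strict FIC crossing is only well-posed in the floor-saturated regime
  (see above); in mode-limited regimes the peptide curve can plateau below
  the amino-acid reference.
- Community topologies with labeling feedback (cyclic exchange) are out of
  scope by construction.
- Raw-spectrum processing and peptide identification are upstream of this
  package: inputs are MDV tables, not spectra.
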