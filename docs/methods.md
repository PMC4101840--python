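# Methods

## Elastic network mechanics

Proteins are represented at C-alpha resolution. A spring network over a
trace of N sites defines the potential
`V(r) = 1/2 Σ_{i<j} k_ij (d_ij − d⁰_ij)²` with rest lengths `d⁰_ij` equal
to the equilibrium distances, so the native conformation is the exact
minimum with V = 0. Two force-constant schemes are built in: pfANM
(`k_ij = 1/(d⁰_ij)²`, all pairs) and ANM (`k_ij = 1` within a cutoff,
boundary inclusive, default `R_cut = 13 Å`; contacts at exactly the
cutoff are included, a measure-zero choice in practice).

The Hessian is assembled analytically from the standard ENM 3×3 blocks
`H_ij = −(k_ij/(d⁰_ij)²) r_ij r_ijᵀ`; a central-finite-difference
evaluation of V is retained purely as a test oracle. The covariance of
thermal fluctuations is the Moore–Penrose pseudo-inverse of H, computed
by dense eigendecomposition (the package targets desk-scale chains,
N ≲ 1500). Eigenvalues below `1e-8 · λ_max` are treated as rigid-body
modes; exactly six must be found for a connected, non-collinear network,
and any other count raises rather than silently inverting a degenerate
matrix (an `expected_zero_modes` parameter accommodates analytically
degenerate fixtures such as a two-site dumbbell, which has five). The
per-site mean-square fluctuation is `MSF_i = Tr(C_ii)/β`.

Energies are in units of k_BT. The inverse temperature β and the
mutation variance α² (defaults: 1 and 1 Å²) enter only as overall scales;
every headline analysis operates on per-protein z-scores, which are
invariant to both — an invariance the test suite asserts rather than
assumes.

## Mutational stress

A mutation at site *i* perturbs the rest lengths of the springs incident
to *i* by independent draws with zero mean and variance α². Only the
site-local interpretation makes the closed-form mean stress
`MLmS_i = 1/2 α² k_i` exact, which is why it is adopted. The default
perturbation distribution is Gaussian, which admits an exact acceptance
rate `⟨e^{−βΔV}⟩ = Π_j (1 + βα² k_ij)^{−1/2}` used as the Monte-Carlo
oracle; a uniform option demonstrates that the MLmS identity depends
only on the variance. The linearized acceptance rate `1 − β·MLmS` is
deliberately not clipped when it goes negative: the breakdown of the
weak-selection approximation is informative, and z-scoring removes the
issue downstream. Each Monte-Carlo routine takes an explicit seed and is
bitwise reproducible; the mutation sampler computes the energy cost by
two independent routes (local sum vs full network re-evaluation) and
raises if they disagree beyond 1e-10 relative.

## z-scores and predictors

z-scores use the population standard deviation,
`x̃ = (x − ⟨x⟩)/√(⟨x²⟩ − ⟨x⟩²)`, computed within each protein. With this
convention `z(MLmS)` is *identical* (to rounding) to the z-scored local
packing density — WCN (`Σ_j 1/d_ij²`) for pfANM, CN (contacts within the
cutoff) for ANM — while `z(MSF)` only approximates `z(1/k_i)`. The site
table joins predictors to rates on author residue numbering plus
insertion code; rate rows without a structural site are dropped (never
imputed) with a logged count, proteins with fewer than 3 matched sites
are excluded, and constant or missing B-factor columns simply disable
the B-factor flexibility variant for that protein.

## Model comparison

Both models are ordinary least-squares fits of z-scored rates on one
z-scored predictor. AIC uses the full Gaussian maximum log-likelihood
`−(n/2)(ln(2π·rss/n) + 1)` and k = 3 parameters (intercept, slope,
residual variance) — the convention of mainstream statistical packages
for a simple linear model; AIC weights are `exp(−ΔAIC/2)` normalized
over the compared pair. Comparisons are pairwise within a potential
(pfANM stress vs pfANM flexibility, likewise ANM), with a B-factor
flexibility variant when B-factors are available. Partial correlations
use the first-order formula from the three pairwise correlations.
Binned profiles rank sites by the predictor and split them into 20
equal-count bins (remainder to the first bins, ties kept in stable input
order); each bin reports mean predictor, mean rate, and a 99% normal
confidence half-width `2.5758·SD/√n`. Curvature of a profile is
quantified by an F-test of a quadratic term against the linear fit. A
perfect fit (rss < 1e-12) raises rather than reporting an unbounded
likelihood.

## Synthetic study conditions

The self-contained validation set emulates a batch of small monomeric
enzymes: 20 self-avoiding compact chains of 120 sites each, bond length
3.8 Å, minimum inter-site separation 3.5 Å, confined to a sphere of
radius `3.0·N^(1/3)` Å (globular mean density). Rates are generated as
`−z(MLmS|pfANM) + N(0, 0.8)` and re-z-scored; the 0.8 noise SD places
the comparison in a regime where the generating model wins decisively
without being trivial. An ideal helix (radius 2.3 Å, rise 1.5 Å, 100°
twist) provides a deterministic fixture with known geometry.

What the synthetic set does not emulate: real side-chain packing
heterogeneity, secondary-structure regularity, crystallographic noise in
B-factors, phylogenetic error in inferred rates, and the across-protein
size and shape variation of curated structure datasets. Passing tests
therefore demonstrate the correctness of the mechanics, the identities
and the statistical machinery, and the recoverability of a known
generative model — not the empirical adequacy of either model on real
proteins, which requires real structures plus rate estimates (consumed
as input; rate inference itself is out of scope).

## Numerical choices and limitations

- Dense `eigh` on the 3N×3N Hessian; no sparse path.
- Globule growth is stochastic with bounded restarts; it fails loudly
  with advice to enlarge the radius rather than loosening the
  excluded-volume constraint.
- Problem sizes in tests and in `scripts/acceptance.py` (N = 120,
  20 proteins, 10⁴ Monte-Carlo samples per site) were chosen so the
  statistical assertions have comfortable margins while the whole suite
  completes in seconds on one CPU.
- Monte-Carlo assertions use 4-standard-error bands; with the seeded
  streams the expected spurious-failure rate is far below 1e-3 per site.
- Only PDB-format input is supported (first model of multi-model files;
  mmCIF and non-protein polymers are out of scope). Structures whose ANM
  graph is disconnected at the chosen cutoff get NaN ANM columns rather
  than fabricated values.
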