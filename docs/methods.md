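# Methods

This note records the statistical models, numerical choices and known
limitations behind `coevokit`. It is the place to look when a default needs
justifying or a result needs interpreting.

## Alignment handling

Alignments are integer-encoded over the 20 canonical residues plus gap
(q = 21; gap is the last state). Ambiguous residue codes (B, Z, X, J, U, O)
carry almost no information at the resolution of a Potts model and map to
gap by default; a strict mode refuses them instead. A2M insert states
(lowercase, `.`) are unaligned by definition and are removed before
encoding.

Trimming is two-pass and deterministic: first drop columns that are gapped
in the query or have a gap fraction above 30%, then drop sequences whose
non-gap fraction over the *retained* columns is below 50%. Running columns
before rows makes the two thresholds composable (row coverage is measured
on exactly the columns that survive) and renders the operation idempotent.
The query row is never removed, so positions always index the target
protein.

Redundancy reweighting is the standard inverse-cluster-size rule: a
sequence's weight is 1 over the number of sequences (itself included) at
identity ≥ 0.8, with gap–gap counted as a match. 0.8 is the conventional
choice in the coupling-analysis literature; it is configurable. The sum of
weights, Neff, is the effective sample size that normalises all frequency
estimates.

## Frequencies and positional conservation

Single-site frequencies `f_i(A)` and joint frequencies `f_ij(A, B)` are
weighted counts normalised by Neff, then smoothed against the uniform
distribution with mixing weight `c = λ/(λ + Neff)` (default λ = 0.5, a
Jeffreys-style pseudocount; λ is per estimate, so smoothing vanishes as the
alignment grows). The joint gets `c/q²` so that its marginals equal the
smoothed single-site frequencies identically, not just at λ = 0.

Positional conservation is the binary Kullback–Leibler relative entropy

    D_i(A) = f ln(f/p) + (1−f) ln((1−f)/(1−p)),  f = f_i(A),  p = p(A)

with 0·ln 0 = 0. It is non-negative, zero exactly at f = p, and convex in
f. Three backgrounds are supported; the default is the alignment-wide mean
composition (`msa_mean`), which keeps the package self-contained — no
external residue-frequency table. Uniform and user-supplied vectors are
available where cross-family comparability matters.

The scalar per-position profile `D_pos[i]` is D evaluated at the query's
own residue — the natural choice for a target-specific energy, since the
filtered energy below asks "is the residue the target actually has at this
position conserved?". Max- and sum-over-residues aggregations are available
behind a flag. The conservation threshold σ defaults to the median of
`D_pos`: no value is canonical, and the median keeps the filtered energy
non-degenerate in both directions (half the positions pass, half do not).

## Potts model and pseudolikelihood inference

The sequence model is the maximum-entropy distribution matching one- and
two-site marginals:

    P(A_1..A_L) ∝ exp( Σ_{i<j} e_ij(A_i, A_j) + Σ_i h_i(A_i) ).

Fitting maximises the regularised pseudolikelihood: each site's conditional
distribution given the rest of its sequence is a multinomial logistic
regression on one-hot encodings of the other columns, solved by L-BFGS with
analytic gradients (mean weighted negative log-likelihood plus ridge
penalties). The two directed estimates of each coupling block are averaged,
`e_ij ← (e_ij + e_jiᵀ)/2`, and the model is shifted to the zero-sum gauge
(fields and couplings sum to zero over states). The gauge shift moves only
the additive constant; all score differences are invariant, which is what
every downstream use consumes. The partition constant Z is never computed.

Ridge defaults are `reg_h = 0.01`, `reg_e = 0.05` on the mean-likelihood
scale. The heavier coupling penalty was calibrated on the null model: an
i.i.d. uniform alignment of 5000 sequences (L = 6, q = 4) must come back
with mean pair coupling norms below 0.05, i.e. visibly empty, while planted
contacts at realistic strength remain fully recoverable (top-12 precision
1.0, true-vs-inferred norm correlation ≈ 0.97 on the L = 25 fixture). Gap
is a full 21st state during inference but is excluded from contact norms,
since gap couplings reflect alignment coverage rather than structure.

**Sign convention.** The exponent is a log-probability, so a HIGHER score
means a fitter sequence everywhere in this package: mutation scans report
`Δ = score(mutant) − score(wild type)` (negative = predicted deleterious),
and design *maximises* the score. Reports state this in their headers.

**Conserved-coupling energy.** The σ-filtered energy keeps field terms only
at positions with `D_pos > σ` and coupling terms only where *both*
endpoints pass (the stricter of the two defensible readings; an
either-endpoint mode is a flag). At σ = −∞ it equals the full score
exactly; above the maximum conservation it is exactly zero.

**Contact scores.** Raw scores are Frobenius norms of the 20×20 non-gap
coupling blocks; the average-product correction subtracts
`mean_i · mean_j / mean_all` to remove background row/column signal.
Rankings exclude |i−j| < 5 by default.

**Gibbs sampler.** Synthetic alignments are drawn by systematic-sweep Gibbs
sampling, run as independent vectorised chains — one chain per requested
sequence, each burned in, so returned rows are independent draws. Each site
update draws from the exact conditional via inverse-CDF sampling.
Correctness is pinned by enumeration: on a 2×2 model the sampled joint is
within total variation 0.02 of the exact Boltzmann distribution at
n = 20 000. The planted-fixture generator uses 200 burn-in sweeps; the
sparse, weak, zero-field models it samples mix in far fewer, and the
marginal agreement is property-tested rather than assumed.

## Residue blocks

The coupling-norm matrix is eigendecomposed; significance is assessed
against a randomised null. The default (fast) null shuffles the
off-diagonal entries symmetrically and takes the 95th percentile of the
null's maximum eigenvalue over 100 shuffles; a data-level null that
column-shuffles the alignment and re-runs inference at reduced settings is
available when the alignment is at hand.

The significant eigenvectors are rotated to independent components by a
closed-form kurtosis-maximising Jacobi rotation: for each pair of
components the planar angle maximising the sum of fourth powers of the
loadings is solved exactly (the objective is a pure 4θ harmonic, so three
evaluations determine it). Maximum kurtosis is the correct independence
criterion for sparse block-indicator sources, and the Jacobi scheme has no
learning rate, no random start, and — critically — cannot stall when two
blocks of similar strength make the leading eigenvalues degenerate and the
incoming eigenvectors an arbitrary mixture. Gradient (Infomax) and
fixed-point (FastICA) rotations were both tried first and both failed
intermittently on exactly that degeneracy.

Block membership: |loading| above 2 robust standard deviations
(median absolute deviation × 1.4826) of its component; positions claimed by
several components go to the one with the largest |loading|, making blocks
disjoint. A structureless (numerically zero) matrix yields empty blocks by
construction. The default input is the *raw* coupling-norm matrix, not the
APC-corrected one — block structure is partly what APC removes.

## Sequence design

`mutation_scan` computes every single-substitution Δscore incrementally
from the local coupling field (`O(Lq)` per position rather than full
rescoring) and is tested to equal full rescoring to 1e-10 — the module's
core correctness gate.

The stability score is `E = E_s + α·E_c`, the site-bias and coupling sums
with the coupling weighted by α. α is calibrated by grid search (default
−2…2 in steps of 0.01) maximising the absolute Pearson correlation with a
measured quantity such as a transition temperature; ties break toward
smaller |α|. With independent component energies this grid maximum is a
consistent estimator of a planted α, which the fixtures verify, including
at the operating point α = −0.43 under 10% noise. Per-family
mesophilic/thermophilic comparison reports the mean score difference and
whether its sign matches the configured expectation (default: thermophilic
higher, matching the fixture construction where the measured quantity
increases with the score).

Dead-end elimination uses the Goldstein singles criterion under
maximisation: candidate A at position i dies when some B beats it by a
margin that survives the worst case over all other positions' candidate
sets, iterated to a fixed point. Singles-only is provably sound (the global
optimum always survives — tested exhaustively on 200 random instances) and
sufficient at this problem scale.

Metropolis design proposes a uniform random substitution at a uniform
random mutable position and accepts with `min(1, exp(Δ/T))`; T defaults to
1.0, with an optional geometric annealing schedule. The trial count is a
free parameter (default 500) and trials are independently seeded from the
master seed. On enumerable instances (L = 5, q = 4) 50 trials × 2000
iterations find the exhaustive optimum in ≥ 95% of cases; the sampler's
stationary distribution is verified against the two-state closed form.

## Folding

The chain model is deliberately minimal: per-residue (φ, ψ) with ω fixed at
180°, ideal backbone bond lengths and angles, and only the Cα trace kept.
Under this geometry the virtual Cα–Cα bond is a constant 3.804 Å whatever
the torsions — asserted after every rebuild. The energy is a sum of three
non-negative terms: flat-bottom contact restraints `Σ w·max(0, d−d₀)²`
(d₀ = 8 Å), quadratic penalties outside square (φ, ψ) windows of half-width
25°, and a soft-core clash term below 4 Å between non-adjacent residues.
The torsion-term weight defaults to 0.01 because degrees² and Å² differ by
about two orders of magnitude. This energy is a documented stand-in chosen
so the *protocol* — not a particular knowledge-based potential — is what
the module implements and tests.

Each trajectory starts from the fully extended chain and anneals
geometrically from T = 2.0 to 0.2 over its moves (default 500 per
trajectory, sized for the ~15-residue systems the fixtures use); moves
perturb one residue's (φ, ψ) by Gaussian noise of 30° or, when torsion
windows exist, resample inside the window half the time. The iterative
protocol runs 500 independent trajectories per round, keeps the best 20%
(elite size exactly 100), averages their contact maps, and feeds consensus
contacts seen in ≥ 50% of the elite back as restraints for the next round.
Per-round records report the elite's median restraint energy both against
the current restraint set and against the *initial* set — only the latter
is comparable across rounds, since the restraint set itself grows.
Round-wise torsion-window re-estimation (circular mean of the elite) exists
behind a flag but is off by default; no principled update rule stands out,
and re-centring windows on a misfolded elite can lock in errors.

## Synthetic fixtures

Every test input is generated, with its ground truth, from a seed:

* **Coupled alignments** — sparse couplings (i.i.d. normal blocks on the
  non-gap states) on 12 random pairs at separation ≥ 5 in L = 25, zero
  fields, 5000 Gibbs samples. This emulates the *statistical* structure
  coupling inference must detect; it deliberately omits phylogeny, so
  reweighting is nearly inert here and passing recovery tests says nothing
  about tree-correlated noise.
* **Stability tables** — measured = `E_s + α·E_c + N(0, sd)` with unit
  component spread; labels split each family at its median measured value.
  Real calorimetry has family-level systematics this ignores.
* **Toy folds** — a canonical helix, or a hairpin built from two extended
  strands around a type-II′-like turn, with native contacts sampled from
  the built coordinates. Fifteen residues exercise the protocol, not the
  physics of real folding.

One caveat worth stating: with 288 of 300 pair norms exactly zero in the
planted truth, rank correlations are floored by ties (Spearman tops out
near 0.34 even for perfect recovery), so recovery is quantified by top-k
precision and the Pearson correlation of norms; the Spearman value is
reported alongside for transparency.

## Known limitations

* Pseudolikelihood needs Neff comfortably above q; below that the ridge
  dominates and couplings shrink toward zero (a warning fires).
* The folding energy is not a transferable potential; predictions on real
  proteins would additionally need calibrated statistical potentials and
  torsion predictions, which enter only as input files here.
* Mean-field, Boltzmann-machine and exact-Z inference are out of scope, as
  is any all-atom or rotamer-level modelling.
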