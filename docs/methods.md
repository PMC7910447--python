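# Methods

## The accuracy model

For a single-chain model with n residues, accuracy is described per residue
pair (i, j) by the signed CB–CB distance error e_ij = d_model − d_native
(CA substitutes for CB at glycine). Three objects carry the prediction:

- **Estogram** — a categorical distribution of e_ij over 15 bins with
  boundaries −20, −15, −10, −4, −2, −1, −0.5, 0.5, 1, 2, 4, 10, 15, 20 Å.
  Interior bin centers are interval midpoints; the two overflow bins are
  assigned ±20 Å, which is also the convention for expected-error maps.
- **Mask** — the probability that the *native* CB distance is below 15 Å.
  Only masked pairs are informative for local accuracy.
- **CB l-DDT** — per residue i, the mask-weighted mean probability that
  |e_ij| falls within 0.5/1/2/4 Å, averaged over the four cutoffs and
  normalized by the mean mask weight:
  lddt_i = 0.25·(p̄0+p̄1+p̄2+p̄3)/p̄4. The global score is the mean over
  defined residues. Residues whose mask weight sums below 1e−9 are
  undefined (NaN) and excluded from the global mean.

Bin edges are assigned half-open on the positive side ([lower, upper)) and
half-closed on the negative side ((lower, upper]), with the central bin
(−0.5, 0.5) open at both edges. Under this convention the cutoff sets
|e| ≤ 0.5/1/2/4 coincide exactly with the unions of 1/3/5/7 central bins,
so the l-DDT reconstruction applied to the one-hot true estogram and binary
true mask reproduces the directly computed CB l-DDT to ~1e−16 for errors
off the bin boundaries (asserted at 1e−9 in tests). Exactly at a boundary
the reconstruction and the inclusive direct computation can disagree by one
category; synthetic tests avoid exact boundaries.

**Sign convention.** e = d_model − d_native throughout, so the native
distance implied by error category k is d0 − center_k (d0 = current model
distance). P_cen is the probability mass in the three central bins
(|e| < 1 Å); P_contact sums the categories whose implied native distance is
below 10 Å.

The corrected l-DDT variant zeroes mask entries with sequence separation
|i−j| ≤ 11 before reconstruction, removing the short-range contacts that
make helical regions look uniformly accurate. Profiles are smoothed with a
9-residue uniform window that truncates and renormalizes at the termini;
NaN entries are excluded from each window.

## Featurization

All features are exactly invariant to global rigid motions of the model.

- **Voxel grids** — per residue, heavy atoms (C/N/O/S) within a G³ cube
  (default G = 24 at 1.0 Å spacing) are splatted by trilinear interpolation
  into 4 element channels plus an own-residue flag channel, in the local
  frame with origin at CA, x along CA→N, z along x×(CA→C). Grid size,
  spacing and channels are configurable; tests use G = 8–12 grids at wider
  spacing for speed.
- **1D features** (width 40) — amino-acid one-hot (20), the Meiler
  7-descriptor physicochemical table, sin/cos of φ/ψ/ω with presence flags
  (undefined at termini → 0), a 3-state secondary-structure one-hot from
  φ/ψ windows (helix: φ ∈ (−120, −30), ψ ∈ (−80, 0); strand:
  φ ∈ [−180, −60), ψ > 60 or ψ < −150; else coil), and a zero-filled slot
  reserved for externally computed intraresidue energy terms.
- **2D features** (width 10 + extras) — CB distance map scaled by 1/10 for
  conditioning, inter-residue orientation angles (symmetric ω dihedral,
  asymmetric θ dihedral and φ angle) as sin/cos with a validity flag that is
  0 for glycine pairs, log(1+|i−j|) sequence separation, a zero-filled
  inter-residue energy slot, and any externally supplied n×n×K channels
  (e.g. predicted distance distributions or sequence embeddings) appended
  verbatim.
- **Tiling** — pair (i, j) receives [1D features of i | 1D features of j |
  2D features], width 2(F1+E)+F2, where E is the learned per-residue
  embedding width from the voxel encoder.

## Network

A shared 3D-convolutional encoder (two 3³ conv + ELU stages with 2×
average pooling, global spatial mean, dense projection) embeds each
residue's voxel grid; the embedding joins the 1D features, is tiled onto the
pair grid with the 2D features, projected by a 1×1 convolution to the trunk
width, and processed by a residual trunk of 20 blocks of 3×3 convolutions
with dilation rates cycling 1, 2, 4, 8. Two arms of 4 residual blocks emit
per-ordered-pair estogram logits (n×n×15) and a mask logit (n×n). Softmax /
sigmoid outputs are symmetrized by ordered-pair averaging, and the l-DDT
head is computed from them by the reconstruction formula — it costs no
parameters and stays consistent with the estogram and mask heads by
construction.

The loss is `estogram cross-entropy + 10·(l-DDT MSE) + 0.25·(mask BCE)`,
optimized with ADAM at lr 5e-4 decaying 0.98 per epoch. The network, its
convolutions and the differentiable l-DDT reconstruction are implemented on
a small in-package reverse-mode autodiff engine (numpy), with gradients
verified against finite differences. Residual-branch weights are initialized
at 1/√(depth) scale and output heads at 0.1 scale so the deep trunk is
near-identity at initialization and initial logits are moderate. Channel
widths default to CPU-friendly values (trunk 32, encoder 8/16, embedding
16) and are configuration-exposed; the toy training demonstration uses
trunk width 8 on 20-residue decoys and softens the lr decay to 0.995 per
epoch, because a 5-example toy "epoch" is orders of magnitude smaller than
a real training epoch. Weight files (.npz) store an architecture
fingerprint and are rejected on configuration mismatch. A utility averages
estogram/mask probabilities over an ensemble of networks.

## Oracle estimator

The oracle emits the one-hot true estogram and binary true mask computed
from a known native, optionally corrupted by a Gaussian blur across error
categories (renormalized) and seeded symmetric Bernoulli mask flips. It
exists so every downstream stage (restraints, region selection, pool
scheduling) can be exercised and tested without trained weights; the
corruption model is a controllable surrogate and makes no claim about real
network error statistics.

## Restraints

Pairs are classified by P_cen at the current distance d0:

| class | condition | potential (coarse / all-atom) | (s, tol) |
|---|---|---|---|
| high | d0 ≤ 20 Å, P_cen > 0.8 | bounded / sigmoid | (1, 1) |
| moderate | d0 ≤ 20 Å, P_cen > 0.7 | bounded / sigmoid | (2, 2) |
| nonpreserving | d0 < 40 Å | estogram spline; contact form in iterative stages when P_contact > 0.8 | — |
| excluded | d0 ≥ 40 Å | none | — |

The bounded form is flat within ±tol of d0, quadratic over width s, linear
beyond; the sigmoid form is an inverted well of two logistic functions
bounded by the all-atom weight w_fa (default 1.0; the aggressive parameter
set uses w_fa = 0.2 with thresholds {p_moderate 0.8, p_high 0.9}, read in
that order to keep p_high ≥ p_moderate). The estogram spline potential
tabulates −log(P_k/P_bg) at the distances d0 − center_k implied by each
category and interpolates with a **monotone cubic Hermite (PCHIP) spline**:
near-one-hot estograms create deep isolated wells, and an unconstrained
cubic spline rings around them, producing spurious minima that actively
misguide minimization — PCHIP cannot overshoot, so the potential's minimum
stays at the best-supported distance. Probabilities are floored at 1e−4
before the log. The background defaults to uniform; `recompute_background`
rebuilds a (sequence separation × d0)-stratified background table from any
decoy collection at desk scale.

Restraints serialize to Rosetta-style `AtomPair` constraint text (BOUNDED
with lb/ub/sd, a SUMFUNC encoding for the sigmoid pair, SPLINE with inline
knot tables, 1-based residue numbering) and round-trip through the bundled
parser. External per-residue EMA scores can be converted to pair weights
P_ij = exp(−λ/L_i)·exp(−λ/L_j), normalized by the 70th-percentile value and
capped at 1 (λ = 1.4 default, 2.0 alternative).

## Refinement protocol support

- **Unreliable regions** — corrected, smoothed l-DDT profile; the k
  lowest-scoring residues with k = 15% of n (static; the midpoint of the
  10–20% window) or the midpoint of [f_dyn, f_dyn+10]% (dynamic), with
  f_dyn = 20 + 20·(0.55 − Q)/30 capped to [20, 40]% and Q the mean corrected
  accuracy on the 0–1 scale, exactly as the formula is stated. On that scale
  the formula moves f_dyn by well under one percentage point, so the lower
  cap of 20 dominates; a percent-scale Q can be supplied via `q_scale`.
  Ties break toward the lower index; residues with undefined corrected
  scores inherit the lowest defined value, making contact-poor regions
  eligible for rebuilding.
- **Toy sampler** — seeded Gaussian perturbation of CA/CB coordinates
  (default 1–3 Å in the selected regions, 0.05 Å elsewhere) followed by
  adaptive-step gradient descent on the vectorized restraint energy plus
  chain harmonics (force constant 10; targets are the input model's own
  CA–CA and CA–CB bond lengths, so an unperturbed model is at the chain-term
  minimum). It is a documented stand-in for fragment-based rebuilding: it
  samples in Cartesian space, keeps the chain connected, and lets pair
  restraints pull toward the estogram-implied native distances, but does not
  model backbone torsion statistics or side chains.
- **Pool scheduling** — per iteration, 10 seeds (greedy by predicted global
  l-DDT, skipping members with S-score > 0.9 to an already selected one)
  each generate 12 children through the sampler; the next pool of 50 is
  selected from 50 parents + 120 children by the same greedy-with-diversity
  rule, backfilled by score if the diversity cap leaves it underfull. Failed
  sampler calls are logged and skipped.
- **Recombination** — every fifth iteration, each pool member takes its 4
  most complementary partners (complementarity = Σ_i max(0, L_partner,i −
  L_seed,i) on smoothed per-residue l-DDT), CA-superposes the partner onto
  the seed and substitutes coordinates where the partner is better, with the
  acceptance threshold set so coverage lands in [20, 50]% of residues
  (50 × 4 = 200 hybrids). The per-pair restraint source map marks a pair as
  partner-derived if either residue lies in a substituted region. Identical
  profiles yield zero coverage and are skipped.
- **Final selection** — the final-pool member with the highest predicted
  global l-DDT anchors the result; all trajectory members with S-score > 0.8
  to it are CA-aligned and coordinate-averaged. The average is returned
  without geometry re-regularization (noted in the output metadata).
- **Demo protocol** — diversification (40 sampler runs split between static
  and dynamic region definitions), then 10 iterations on a 16-member pool
  with recombination at every fifth, run under both the default and
  aggressive restraint sets with the higher-predicted trajectory kept.
  Full-protocol counts (pool 50, 10×12 children, 4 partners) are the
  configuration defaults and are what the conservation tests assert.

## Molecular-replacement preparation

u_i = 1.5·exp[4·(0.7 − lddt_i)] Å and B_i = 8π²u_i²/3 Å², written into the
PDB B column. Terminal residues are iteratively trimmed when they have no
heavy-atom contact within 4.5 Å to any residue ≥ 4 apart in sequence
(both thresholds configurable); trimming is idempotent and refuses to
consume the whole chain.

## Synthetic data

Toy natives are built from ideal backbone geometry (N–CA 1.458, CA–C 1.525,
C–N 1.329 Å; trans peptides; canonical φ/ψ per topology: helix −57/−47,
strand −120/120, seeded coil) with CB placed by the standard tetrahedral
construction and carbonyl O in the peptide plane. Topologies: helix bundle
(helical segments joined by seeded turns), sheet-like, coil. Decoys perturb
φ/ψ with Gaussian noise of a chosen magnitude inside 1–3 random contiguous
segments covering ~30% of the chain and rebuild coordinates, so larger
magnitudes give lower l-DDT/GDT-TS; magnitude 0 reproduces the native
bit-exactly. A stratified generator buckets decoys into GDT-TS bins
(50–90, width 10). Default chains contain no glycine so every residue
carries a CB; glycine handling is tested with explicit sequences.

What the generator does **not** emulate: side chains beyond CB, non-ideal
local geometry, homology-modeling or folding-derived error correlations,
multi-chain context, and relaxed (energy-minimized) decoys. Passing tests
therefore demonstrate the correctness of the metrics, reconstruction
algebra, featurization, restraint construction and protocol logic — not
performance on real decoys, which requires trained weights and a physical
sampler.

## Numerical choices and problem sizes

- GDT-TS uses a deterministic seed-window search (every contiguous CA window
  of lengths 3/5/7 plus the full-length fit, each iteratively trimmed per
  cutoff, max 10 rounds) — an approximation to the exhaustive superposition
  search, cross-checked against an independent brute-force implementation.
- S-score uses d0 = 5.0 Å (configurable); the Kabsch superposition enforces
  a proper rotation (det = +1).
- PDB I/O resolves altlocs by highest occupancy, drops residues missing
  N/CA/C with a warning, rejects insertion codes, and substitutes CA for a
  missing CB on non-glycine residues with a warning.
- Tests and the demo use 20–60-residue chains, 8–12³ voxel grids, trunk
  width 8, 150–250 training epochs, and 20-decoy comparisons; all
  generator and protocol defaults are the package's standing study
  conditions and are seeded for reproducibility.

## Known limitations

- The spline potential's resolution is the bin width: its minimum matches
  the native distance only to within the containing error bin, and overflow
  bins (|e| > 20 Å) pull to the ±20 Å boundary. Long minimization against
  exact-oracle restraints can therefore trade small l-DDT losses in
  already-accurate regions for global RMSD gains.
- The dynamic region formula as printed barely responds to Q on the 0–1
  l-DDT scale (the 20% cap dominates); the `q_scale` parameter exposes a
  percent-scale reading.
- The l-DDT reconstruction differs from the direct computation for errors
  exactly on bin boundaries (measure-zero off synthetic grids).
- Multi-chain complexes, ligands, nucleic acids and mmCIF input are out of
  scope; all-atom l-DDT is not computed (CB only).
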