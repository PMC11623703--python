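# Methods

## Problem and scope

`molflows` implements, in a controlled and CPU-sized setting, the machinery
needed to compare discrete flow matching (DFM) formulations for 3D de novo
small-molecule generation. A molecule with N atoms is a fully connected graph
g = (X, A, C, E): positions X in R^(N×3), categorical atom types A, formal
charges C, and a bond order e_ij for every unordered atom pair (with an
explicit `none` class so the edge set is total). A flow model transports a
simple prior to the data distribution along conditional probability paths
p_t(·|z), z = (x0, x1), factorized independently per modality. One network —
the denoiser ĝ1(g_t) — predicts the final molecule from the time-t state and
is trained by a weighted sum of per-modality reconstruction losses

    L = η_X L_X + η_A L_A + η_C L_C + η_E L_E.

Four categorical formulations are interchangeable:

* **Continuous** — ordinary flow matching in R^D from a standard Gaussian
  prior to one-hot vertices, linear interpolant, endpoint-regression loss
  (MSE of the raw denoiser head against the one-hot target). The head's raw
  output is the endpoint estimate used by the vector field
  u = (x̂1 − x_t)/(1 − t).
* **SimplexFlow** — the same linear construction constrained to the
  probability simplex: uniform-simplex (Dirichlet(1)) prior, simplex-valued
  endpoint estimate (softmax head), so that every Euler update with
  dt ≤ 1 − t is a convex combination and closure is exact.
* **Dirichlet** — conditional paths Dir(1 + β(t) e_{x1}) from the uniform
  simplex prior, with the conditional vector field
  u = Σ_i p̂(x1=i) · C(x_i, t) · (e_i − x), where C is obtained from
  conservation of the Beta(1+β, D−1) marginal CDF along trajectories:
  C = −β′(t) ∂_β I_{x_i}(1+β, D−1) / [f_Beta(x_i; 1+β, D−1)(1−x_i)].
  The β-derivative of the regularized incomplete beta function is evaluated
  by central finite differences (h = 1e−4·(1+β)) and C is clamped to
  [0, 500] near simplex vertices, where the beta density underflows.
* **CTMC** — a purely discrete flow: every token starts in a MASK state
  (modelled as an extra, final vocabulary class) and the conditional law at
  time t is the linear mixture (1−t)·δ_mask + t·δ_{x1}. At generation time a
  masked token unmasks with probability dt/(1−t) per step — the hazard
  implied by the linear mixture — drawing its class from the denoiser
  distribution over real classes; unmasked tokens are absorbing, and masks
  surviving to the final step are resolved by a forced draw. Training is
  cross-entropy over real classes, averaged over all positions.

Positions always use the Euclidean linear path from a centered Gaussian
prior. Sampling integrates all modalities jointly on an even grid of 100
Euler steps by default; continuous categorical states are discretized by
argmax at t = 1.

Key parameter defaults: β_max = 100 with schedule
β(t) = min(β_max, β_max·t/(1−t+10⁻³)) (monotone, β(0)=0, β(1)=β_max; the
endpoint Dir(1+100·e) leaves < 5% argmax mass off the target class); loss
weights η_X = 3, η_A = η_C = η_E = 1 (positions moderately up-weighted since
geometry quality depends on them; the categorical weights are symmetric);
training times t ~ Uniform[0,1); prior/endpoint pairs drawn independently
(no optimal-transport coupling).

## Toy denoiser

No GPU-scale message-passing network is attempted. The denoiser is a small
feed-forward model (~10k parameters; `describe()` reports the exact count):
per-atom features (categorical states, incident-bond sums — a one-hop
message pass — local distance summaries, and t), concatenated with a
mean-pooled molecule context, through one tanh layer; separate linear heads
produce atom and charge logits; a pairwise block (bond state, summed node
embeddings, inter-atom distance, t) produces bond logits; positions are
predicted as offsets from centered coordinates, which makes the model
translation-equivariant by construction (it is not rotation-equivariant).
Gradients are hand-written and verified against central finite differences
to < 1e−4 relative error for every variant; optimization is Adam
(lr 5e−3, batch 32). Training is deterministic given the seed, and
checkpoints reload bit-exactly.

## Synthetic toy distribution

The generator emulates the couplings a molecule generator must learn —
element ↔ valency ↔ bonding topology ↔ local geometry — at desk scale. A
draw picks a heavy-atom count uniformly in 3–6, a ring scaffold with
probability 0.35 (chain otherwise), heavy elements i.i.d. from a
scaffold-conditioned categorical over {C, N, O} (chain: .60/.25/.15, ring:
.70/.15/.15), saturates each heavy atom with hydrogens to exact valency
(C:4, N:3, O:2), and embeds at idealized bond lengths (1.5 Å heavy–heavy,
1.09 Å C–H) plus isotropic Gaussian noise σ = 0.05 Å. Every sample is 100%
stable and sanitizable by construction, and the size, atom-type and
bond-order marginals are available in closed form from the configuration, so
trained models can be scored by total variation (TV) against analytic
marginals with no external data. The distribution does **not** emulate
aromaticity, charges, higher bond orders, conformer flexibility or drug-like
ring systems — so passing toy-scale tests demonstrates correct machinery and
qualitative orderings, not drug-scale generation quality.

## Metrics

* *Stability*: valency = Σ bond orders (aromatic = 1.5); an atom is stable
  iff (element, charge, valency) is in the packaged allowed-valency table;
  computed with no cheminformatics toolkit so it is independent of validity.
  Carbon's allowed set includes 4.5 so aromatic-fusion bridgeheads (three
  aromatic bonds) count stable; aromatic five-membered heteroatom cases such as
  pyrrole N (valency 4 under the 1.5 rule) are a known limitation of the
  sum-of-orders convention and would be flagged unstable.
* *Validity*: RDKit default sanitization of the reconstructed molecule.
* *Energy JS*: Jensen–Shannon divergence (natural log, bounded by ln 2)
  between single-point MMFF94 energies on 100 shared equal-width bins over
  the pooled range; energies are single-point (no minimization) and failures
  are dropped and counted.
* *Structural alerts*: distinct flagged SMARTS patterns per sanitizable
  molecule (a matched pattern counts once per molecule). Bundled Dundee and
  Glaxo Wellcome files are curated subsets for desk use; full catalogs can
  be supplied as TSV.
* *OOD ring systems*: rings sharing an atom or bond merge into one system,
  keyed by the canonical SMILES of ring atoms and in-ring bonds; the rate of
  keys absent from a reference frequency table is reported. The bundled
  table is a small synthetic stand-in for a corpus census.
* Batch evaluation splits the sample into repeats and reports mean ± 95% CI
  (normal approximation; single repeats report a zero-width CI).

## Assignment-time diagnostic

For a recorded trajectory, a token's assignment time is the earliest grid
time after which its discrete state (argmax for continuous variants, raw
index for CTMC) never changes; it is measured separately for the state x_t
and for the denoiser prediction, and the mean difference (state − prediction)
quantifies how long a formulation takes to commit a decision the denoiser
has already made.

## Frozen study conditions and what they show

All end-to-end results use: 300 training molecules, 50 epochs, 120 generated
molecules, 100 Euler steps, replicate seeds 0–4. At these sizes the pipeline
(four variants × five replicates plus baselines) runs in about ten minutes
on one CPU.

Findings reproduced at toy scale: trained models beat untrained baselines by
two orders of magnitude in atom-level stability, and the CTMC variant
matches the analytic toy marginals at least as well as the Continuous
variant in 5/5 replicates (TV ≈ 0.02 vs ≈ 0.1), mirroring the qualitative
CTMC-over-Continuous quality ordering.

Finding **not** reproduced at toy scale: the assignment-time ordering (the
expectation that continuous embeddings lag their denoiser more than CTMC
does). Under the linear mask mixture, CTMC unmasking times are exactly
Uniform[0,1], pinning the CTMC state-assignment mean at 0.5, while the toy
task is easy enough that the denoiser commits its predictions early —
hydrogens, roughly half of all atoms, are predicted correctly from t = 0 —
flooring the CTMC gap near 0.3. The simplex-constrained variants' states
track their sharp predictions almost immediately (gaps 0.01–0.1), and the
Continuous gap (~0.28) sits just below CTMC's. The lag phenomenon as
published rests on large-scale continuous models whose predictions stay
blurry and commit late; demonstrating it would require deliberately
degrading the toy models, which this package does not do. The corresponding
acceptance test states the expected ordering and fails honestly at toy
scale; the diagnostics module reports the measured gaps either way.

## Numerical choices and degenerate inputs

Simplex states are renormalized (clip at 0, divide by the row sum) after
Dirichlet Euler updates to absorb float drift; linear-path variants land
exactly on the predicted endpoint at the final step, so no projection is
needed. Argmax ties resolve to the lowest index (numpy convention).
Charges outside the vocabulary on SDF read are clamped to the nearest
vocabulary value with a logged warning; unparseable SDF records are skipped
per record, not fatally. Elements missing from the valency table count as
unstable and are logged once per element. Empty metric batches and all-zero
size histograms are domain errors; an all-mask final state is a domain error
for assignment times.
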