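# Methods

## The model

Given partial measurements X = (X1, …, XN) of a system and a relevance
variable Y, the distributed information bottleneck compresses each
measurement separately: Xi → Ui through its own stochastic channel, after
which the vector U = (U1, …, UN) feeds a predictive model for Y.  Training
minimizes the Lagrangian

    L = β · Σi I(Ui; Xi) − I(U; Y),

so each bit a channel transmits must pay for itself in predictive
information.  Sweeping β from large (all channels silent) to small (all
information through) produces, in one optimization run, a continuum of
compression schemes ordered by the total information they use.  Reading
off per-channel informations along the sweep decomposes the predictive
content of X into per-measurement allocations.

### Variational surrogate

Each channel is a deterministic MLP mapping a raw value to a diagonal
Gaussian p(u|x) = N(μ(x), diag σ(x)²) in a d-dimensional latent space; the
prior r(u) is a standard Gaussian, fixed throughout.  The training loss
replaces each I(Ui;Xi) with its variational upper bound
E_x[KL(p(u|x) ‖ r(u))], available in closed form, and replaces −I(U;Y)
with the decoder cross-entropy (up to the constant H(Y)); a single
reparameterized latent sample per datum per step carries the gradient.
The loss is therefore

    β · Σi E[KL_i] + E[−log q(y | u1, …, uN)]   (nats).

All *reported* information is in bits.

### Precise evaluation of I(Ui;Xi)

The KL cost bounds channel information only loosely (a channel can have
positive KL while transmitting nothing, e.g. shrunken scales with equal
means).  For analysis, frozen channels are measured with a sampled bound
pair on the known Gaussian mixture: the contrastive lower bound
E_j[log p(u_j|x_j) − log (1/K)Σ_k p(u_j|x_k)] and its leave-one-out upper
counterpart, with jackknife standard errors over batches.  For enumerable
features (binary circuit inputs) an unbiased Monte-Carlo evaluation of the
exact mixture integral is used instead; the sampled bounds are verified to
bracket this oracle in the test suite.  For trained binary channels the
upper−lower interval is of order 10⁻³–10⁻² bits, which is what makes the
per-channel decomposition quantitative rather than indicative.

The information-plane vertical axis is the variational lower bound
H(Y) − CE on I(U;Y); it can be slightly negative at initialization (a
uniform decoder on a skewed label marginal) and approaches H(Y) when the
decoder becomes exact.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| latent dim d | 8 per channel | binary/scalar features saturate far below this; larger d only slows the linear algebra |
| encoder MLP | 2×64 tanh, zero-init head | zero head pins every channel exactly at the prior, so sweeps start at 0 bits by construction |
| scale param | softplus(pre + ln(e−1)) + 10⁻⁶ | pre = 0 gives scale 1; the floor guards log terms |
| decoder MLP | 2×128 tanh | enough to memorize a 1024-row truth table; glass runs use one hidden layer of 128 |
| β schedule | geometric 1.0 → 3·10⁻⁵ | at β = 1 every channel closes; at 3·10⁻⁵ a full bit costs ~2·10⁻⁵ nats, effectively free |
| steps | 30 000 | the late, small-β portion does the opening; XOR-coupled inputs have no first-order gradient and need the long tail to break symmetry |
| optimizer | Adam, lr 10⁻³ | standard |
| checkpoints | ~100, log-spaced in step | β is geometric in step, so log spacing is roughly uniform in log β |

Annealing direction is strong→weak bottleneck: the trajectory grows
information over training, and the zero-information start is exact rather
than approximate.  (The reverse direction works but begins from an
arbitrary fully-informative solution.)

Circuit runs train full-batch on the complete truth table with exact row
probabilities — there is no sampling noise in the data distribution, only
in the latent draws.  Tabular (glass) runs use minibatches of 256.

## Boolean-circuit oracle

Circuits are random DAGs of two-operand AND/OR/XOR gates.  The generator
draws each gate's first operand from the pool of not-yet-consumed nodes
(and forces the second from the pool when the remaining gates could not
otherwise absorb it), which guarantees every input feeds the output;
circuits failing the ancestry check are redrawn.  Truth-table enumeration
is guarded at 2²⁰ rows and the subset frontier at 2¹⁴ subsets.  Exact
subset informations I(X_S;Y) come from marginalizing row probabilities in
log base 2; the per-cardinality envelope max_{|S|=k} I(X_S;Y) is the
discrete frontier that an ideal sweep should trace.

## Synthetic glass generator

The generator emulates the statistical shape of a sheared-glass
rearrangement dataset: 2D neighborhoods of radius r_max = 5 (σ_AB = 1)
around a central type-A particle, positions from random sequential
addition of hard disks (minimum separation 0.5, number density 1.0), type
A with probability 0.65, i.e. a Kob–Andersen-like composition.  Each
neighborhood is featurized into 100 radial-band densities — 50 shells per
type, centers uniform on (0.25, 5.0], Gaussian width w = 0.1 — computed as
smeared shell counts Σ exp(−(r − r_k)²/2w²).

Labels are planted: the true occupancy of one near-center type-A shell
(default shell 7, r ≈ 1.0) is thresholded at its median — low occupancy ⇒
rearrangement — and flipped with probability ε (default 0.1).  Classes are
balanced by construction and the Bayes accuracy is 1 − ε.  The planted
band sits near the first trough of g_AA(r), mirroring where structural
signal concentrates in real amorphous systems.

What the generator does *not* emulate: interaction physics beyond the hard
core, shear protocols and genuine rearrangement dynamics, spatial
correlation between positive and negative samples, and multi-shell or
type-B signal.  Passing recovery tests therefore shows that the method
finds a localized, threshold-like radial signal under realistic occupancy
statistics — not that it reproduces measurements on simulated glasses.

g(r) is computed about the central particle (annulus counts normalized by
annulus area and partner density), so no edge correction is needed inside
r_max and an ideal-gas configuration gives g ≡ 1.

The linear baseline is a maximum-margin linear classifier (LinearSVC) on
standardized features with an 80/20 split — the softness construction.

## Per-particle basis

In the per-particle basis the measurements are raw (x, y) positions; one
channel is shared by all particles of a type.  The predictor must be
permutation invariant: the default is an attention set network (one
residual self-attention block over the embedded latents, then attention
pooling with a learned query — two attention stages); a sum-pooling
deep-sets variant is provided and is preferred for larger training runs
since it avoids the S×S attention cost.  Padded elements are masked out of
every softmax and sum; the empty set decodes through a zero pooled vector
to a learned bias.

Three numerical choices matter for this model to train at all.  Raw
positions are divided by a fixed scale (default 2.5, half the neighborhood
radius) so the tanh stack sees O(1) inputs.  The pooled sum is multiplied
by 1/(mean set size), otherwise an O(S) activation saturates the head and
kills every gradient; counts remain linearly decodable through the scale.
And unlike the tabular decoder, the set predictor's head is *not*
zero-initialized: with ~10² prior-noise latents pooled together, a zero
head is a dead symmetric point from which no channel ever receives a
gradient.  The sweep still starts at zero transmitted bits because the
channels themselves start at the prior.

The set sweep anneals β in the *compression* direction (small → large,
default 10⁻⁶ → 3·10⁻³): the permutation-invariant ring/shell feature has
to form before it can be priced, and its formation passes through
high-information states (means large relative to the unit latent noise)
that even a mild penalty forbids — forward annealing verifiably leaves the
model at zero bits.  Sweeping compression upward first learns freely, then
squeezes the learned scheme down to its predictive core.

Because the neighborhood distribution is isotropic, random per-batch
rotation of the training neighborhoods is exact data augmentation; it
drives the shared channels toward properly radial encodings (azimuthal
variation drops several-fold).  It is phased in after 40% of the run:
applied from the start, the extra gradient variance prevents the weak
seed signal from ever taking off.

One piece of geometry shapes what the positional map can show for a
planted band.  A particle at radius r influences band occupancy at radius
r_p whenever |r − r_p| is within the hard-core exclusion radius, so every
particle in the annulus (r_p − σ_hc, r_p) carries real information about
the band — with the band planted at r ≈ 1.0, one exclusion radius from
the inner boundary, the rare innermost particles (high leverage, low
occupancy, weak pruning pressure) compete with the band itself for the
map's maximum.  At strong compression the map resolves into a unimodal
profile peaked on the planted band (the configuration the default recipe
lands on); at weaker compression the exclusion annulus forms a plateau
whose argmax can sit anywhere inside it.  Bands planted outside the
boundary's exclusion shadow (r ≥ 1.2) would avoid the competition
entirely, but their occupancy statistics make the rule unlearnable at the
training scales used here.  The overall picture — per-particle
information concentrated in the low-density region nearest the center —
matches what is observed in real amorphous systems.

A residual limitation at this scale: the compressed, well-localized state
retains angular wobble in its per-particle costs (sector-to-sector
variation around the planted annulus of order half its mean), while the
states with several-fold smoother azimuthal profiles retain 2–3× more
total information and lose the sharp localization.  Driving both down
together requires more data and a longer compression tail than the
default configuration uses.

Per-particle information is reported as the KL cost of that particle's
encoding — the quantity the objective actually penalizes.  Particles share
one channel, so a per-particle marginal I(U;X) does not exist separately;
channel-level sampled bounds are available as a cross-check.  Positional
maps average per-particle KL bits over a 50×50 grid on [−5, 5]² and over
annuli of width 0.1; unoccupied cells are flagged NaN, never zero-filled.
Deterministic (mean-latent) decoding is used for single-neighborhood
prediction so the output is exactly order-invariant.

## Distinguishability and thresholds

The distinguishability of two raw values under a channel is
1 − BC(p(u|x_α), p(u|x_β)), with BC the Bhattacharyya coefficient (closed
form for diagonal Gaussians): 0 = identically encoded, 1 = disjoint
encodings.  The value grid defaults to 64 quantiles of the training
distribution.  Threshold detection scans all m−1 cuts of the grid,
approximates the matrix by three constants (two within-block, one
between-block) and returns the cut minimizing the squared residual; the
cutoff ρ′ is the midpoint of the flanking grid values.  An all-zero matrix
is flagged degenerate rather than assigned an arbitrary cutoff.

Class-conditional feature histograms share one binning; their overlap
Σ min(p̂0, p̂1)·Δ ∈ [0, 1] summarizes separability, and for a learned
threshold-like channel the detected cutoff should fall between the
class-conditional medians.

## Numerical choices and degenerate inputs

* Everything is float64; training is exactly reproducible given a seed
  (one generator drives initialization, minibatching and latent noise).
* Leave-one-out upper bounds can blow up for continuous features when one
  encoding dominates its own mixture term; for enumerable features the
  duplicate-value counts keep the bound finite.  Log-domain arithmetic
  (logsumexp, log1p) is used throughout.
* Non-finite training losses raise a training-failure error carrying the
  step, β and loss components rather than continuing silently.
* Empty subsets, empty neighborhoods, single-class label sets and
  out-of-range indices raise explicit errors (or return exact zeros where
  the quantity is defined, e.g. I(∅;Y) = 0).
* Problem sizes in the test suite and acceptance script are desk-scale by
  design: 10-input circuits (1024 rows, full batch), 2×10⁴ glass samples
  with a 4-dimensional latent and ~8 000 training steps, and a smaller
  planted-radial set run.  These sizes are the package's declared study
  conditions; enlarging them is a config change, not a code change.

## Known limitations

* The sweep is one continuous optimization; hysteresis can make the
  trajectory lag the true frontier right after β drops.  Independent
  per-β retraining (debug mode) is slower but avoids this.
* Near-deterministic channels make the leave-one-out upper bound noisy
  for continuous features; the reported midpoints remain well-behaved
  because lower and upper are averaged.
* Redundant inputs (whose information is fully contained in the others)
  feel almost no opening gradient at small β; reaching the full
  Σ I(Ui;Xi) = N endpoint relies on the long small-β tail of the
  schedule.
* The attention predictor is deliberately small; it is not a faithful
  reproduction of large set-transformer architectures.
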