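# Methods

## Problem and model

`fraglink` addresses fragment linking: given two molecular fragments, each
with one marked exit (attachment) atom, generate a linker of 3–12 heavy
atoms that joins them into a single chemically valid molecule. The model is
a graph variational autoencoder with a sequential, valency-constrained
decoder, plus a controllable-generation layer that rejection-samples the
latent space against attribute classifiers.

The generative factorization is the standard VAE one, p(x, z) =
p(x | z) p(z), with an approximate posterior q(z | x) supplied by a graph
encoder. Three graphs are encoded per example: the two fragments (into a
d_z = 32 latent each; their means are averaged into mu_f) and the whole
molecule (into the narrower d_m-dimensional space its sampled seed z_m
lives in; d_m = 16 by default). The decoder seed is

    z = mu_f + a_f · [z_m, tau(z_m)]

where tau is a linear lift of z_m to the remaining width, [·,·] is
concatenation, and a_f is a learned scalar gate (initialized at 1). During
training z_m is a reparameterized draw from the molecule posterior; at
generation time z_m ~ N(0, I), or — under controllable generation — a
rejection-accepted draw from a fitted latent density.

## Encoders

Two interchangeable backbones:

* **GCN** — three layers of symmetric-normalized propagation with
  self-loops, `act(D^-1/2 (A+I) D^-1/2 H W)`.
* **CensNet-style node/edge co-embedding** — node layers modulate neighbor
  aggregation by a learned scalar per edge routed through the incidence
  matrix; the edge layer propagates edge embeddings over the line graph
  modulated by endpoint node scalars (node → edge → node ordering). With no
  edges both layers reduce to the self-loop term.

Every layer applies ReLU, layer normalization over the feature axis, and
dropout (train mode only; rate 0.05, see "Tuning" below). Graph-level
encodings mean-pool node embeddings and project to (mu, log sigma), the
latter exponentiated so sigma > 0 always holds.

During training the molecule is encoded with its linker atoms flagged in a
feature channel. The linker set is a deterministic function of the
(fragment pair, molecule) conditioning, so this adds no information beyond
the example itself; it lets the posterior spend its capacity on the atoms
the decoder actually has to reproduce.

## Decoder

Generation starts from the intact fragments plus n_linker isolated,
unlabeled nodes carrying the broadcast seed z plus a deterministic
sinusoidal positional tag (unit amplitude — isolated slots are
distinguishable only through these). A FIFO focus queue seeded with the two
attachment atoms drives construction; at every step the current partial
graph is re-encoded from z by the backbone (teacher forcing makes all these
re-encodings independent, which the training loop exploits by batching them
block-diagonally).

For the focus node u, every pair (candidate v, bond order) that respects
the remaining valence budgets and does not duplicate an existing bond is
scored by a two-hidden-layer MLP (width 128) over the feature vector

    Phi(u, v) = [s_u, s_v, d_uv, H0, Ht, D]

where s_x concatenates the re-encoded hidden state of x, its label/budget
features, the raw seed row z + tag_x, and the product (z + tag_x) ⊙ tag_x
(an explicit per-slot selector that markedly improves memorization), d_uv
is the BFS graph distance (sentinel 20 when disconnected), H0 and Ht are
the mean initial and current representations, and D is the optional
2-vector 3D descriptor of the fragment pair (zeros unless supplied). A
pseudo stop action is scored through the same MLP with zeroed s_v. Masked
softmax over the surviving actions; infeasible entries get -inf. Argmax
selection breaks ties toward the lowest (candidate index, bond order), with
stop last.

Unlabeled linker nodes carry a provisional valence budget of 4 (the
vocabulary maximum, carbon) during edge placement. After the edge phase a
node-labeling MLP assigns each linker node an element, masked to elements
whose maximum valence covers the realized bond-order sum — so the final
molecule is valence-valid **by construction**. The largest connected
component is returned (ties: the component containing the first fragment's
attachment atom, then lowest atom index).

## Training

L = L_recon + beta · L_KL. The reconstruction term replays the ground-truth
trajectory (breadth-first from the attachment atoms, lower-index targets
first — the same discipline the decoder uses at generation time) and sums
the cross-entropy of every masked edge/stop decision plus the node-label
cross-entropies. The KL term is the closed-form divergence from N(0, I) of
the molecule posterior plus both fragment posteriors at half weight.

### Tuning

The defaults are the outcome of fitting the architecture to the package's
own trainability requirement (teacher-forced decision accuracy >= 0.9 on
the 500-example toy corpus after 30 epochs):

* beta warm-up 0 → 0.01 over the first 10% of steps. A full-weight KL
  (beta = 1) collapses the molecule posterior (KL → 0) and caps accuracy
  near 0.6; 0.01 keeps the latent informative while still shaping it
  toward the prior enough for N(0, I) sampling to decode sensibly.
* Adam, lr 3e-3 with cosine decay to 10%, gradient-norm clip 5,
  batch size 4 (many small steps help per-example memorization).
* dropout 0.05 (0.1 measurably slows memorization at this scale).
* Encoder width d_hidden = 64; latent dims d_z = 32, d_m = 24; MLP_E width
  128; label head two hidden layers of width 256 with sin/cos per-slot
  selector inputs.
* Node-label cross-entropies are upweighted by 2 in the training objective
  (label decisions are the hardest memorization bucket; the weight
  rebalances gradient mass toward them). Reported reconstruction losses
  include this weight; the per-decision accuracy metric does not involve
  it.

Teacher-forced decision accuracy is evaluated at the posterior mean
z_m = mu_m — the canonical reconstruction seed — with dropout off.

## Controllable generation

A diagonal-covariance Gaussian mixture (k = 10 by default; BIC selection
available) is fitted by EM over the posterior means of the training
molecules. Per attribute (QED > 0.6, SA < 3, surrogate potency > 6 by
default; thresholds overridable) a logistic-regression classifier predicts,
from concat(z_m, mu_f), whether that latent corresponds to a molecule
satisfying the threshold. Classifiers are trained on the known molecules'
posterior latents with their true properties — the same cloud the density
covers, so rejection evaluates them in-distribution. (An alternative table
built from prior-decoded samples is provided for auditing; linear probes on
it carry almost no signal, because properties of the nonlinear decode of an
unstructured prior draw are not linearly readable.) Sampling draws z_m from
the mixture and accepts with probability equal to the product of the
attribute scores (a Bernoulli thinning, valid since each score is at most
1); only accepted latents are decoded. The paired random baseline decodes
z_m ~ N(0, I) for the same fragment pairs.

At toy scale the drug-likeness and potency attributes are anti-correlated
(heteroatom-rich linkers raise the surrogate potency but depress QED), and
their conjunction is empirically empty over the whole corpus; enrichment is
therefore assessed on the controlled potency oracle, with per-attribute and
conjunction rates reported alongside.

## Synthetic data

Real fragment-linker corpora are built by double-cutting drug-like
libraries. The toy generator emulates that structure: random
valence-budgeted trees over {C, N, O, F, S, Cl, Br} (weights
.50/.21/.21/.02/.04/.01/.01), an occasional 5/6-membered ring closure
(probability 0.2), 8–20 heavy atoms; every molecule is double-cut on
acyclic single bonds and one admissible (3–12-atom-linker) example is kept
per parent. The surrogate potency label is deterministic:
pIC50 = 4 + 4 · (N+O count)/(heavy atoms) ∈ [4, 8], chosen so that a
latent classifier can genuinely learn it and both classes exist on any
reasonably sized sample (~27% of toy molecules exceed 6; QED > 0.6 holds
for ~5%, rare because QED penalizes the generator's mostly acyclic,
rotatable-bond-rich topology).

What passing tests on this corpus do show: the architecture can represent
and reconstruct linker chemistry, the valency machinery guarantees
validity, and rejection sampling concentrates generation on
attribute-satisfying latent regions. What they do not show: performance on
real screening libraries (aromatic-ring-rich, synthesizability-filtered
chemistry), docking relevance, or generalization beyond the training
distribution — the trainability check is explicitly a memorization check.

## Numerical choices and degenerate inputs

* All networks run in float64 on a small in-package reverse-mode autodiff
  engine over numpy; gradients are exact (finite-difference checked).
* Masked softmax treats -inf logits exactly (zero probability, zero
  gradient).
* Empty-edge graphs: both backbones reduce to their self-loop terms.
* GMM fitting uses a variance floor of 1e-9, raised to 1e-6 with a warning
  on near-degenerate inputs.
* Rejection sampling caps draws (default 1e5) and returns a flagged
  partial result when exhausted.
* Generation halts within 2·C(n,2) steps; overflow truncates and finalizes
  the partial graph.
* Dataset CSV stores linker indices in the canonical atom order of the
  molecule SMILES, so files round-trip exactly.

## Known limitations

* Stereochemistry, formal charges beyond neutral parsing, protonation
  states and 3D conformers are out of scope; the 3D descriptor D defaults
  to zeros.
* The valence table is fixed (C4 N3 O2 F1 S2 Cl1 Br1); hypervalent sulfur
  chemistry is rejected as invalid.
* The surrogate potency is a composition statistic, far easier to predict
  from the latent than a measured binding affinity; enrichment results on
  the toy corpus are therefore an upper bound on what the same pipeline
  would achieve with experimental labels.
* One CPU, minutes-scale training by design; the package is a faithful
  small-scale implementation, not a large-scale training harness.
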