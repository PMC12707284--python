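# Methods

## The model

`backflow` designs amino-acid sequences for fixed protein backbones.  The
generative model is a discrete flow-matching process over the 21-token state
space (20 amino acids plus a MASK token), conditioned on backbone geometry by
a three-track attention trunk.

### Discrete flow matching

The forward corruption interpolates linearly between the fully masked state
at t = 0 and the native sequence at t = 1: each position independently keeps
its native token with probability t, otherwise it is MASK.  The model is
trained to predict the native token at masked positions with a cross-entropy
loss; the flow time of each training sample is drawn uniformly on [0, 1].

Sampling reverses this continuous-time Markov chain.  A position still masked
at time t unmasks during a step of size dt with probability
min(1, dt / (1 - t)); an unmasking position draws its token from
softmax(logits / tau) with excluded tokens (e.g. cysteine in binder design)
renormalised away.  With the uniform n-step schedule (dt = 1/n) the final
step has dt/(1-t) = 1, so any backbone is fully decoded in exactly n steps —
the default is 10 steps at temperature tau = 0.1, regardless of protein
length.  Tokens never re-mask; under the analytic rate the step index at
which a position unmasks is uniform over the n steps.  Temperatures below
1e-4 switch to a deterministic mode: each step unmasks its expected share of
positions, most-confident first, with restricted argmax token choice; this is
the tau -> 0 limit with the timing randomness removed, and it is
seed-independent by construction.

### The three-track trunk

The trunk carries a single (per-residue) representation, a pair
(residue-pair) representation, and per-residue rigid frames built by
Gram-Schmidt from N, CA, C (x-axis along C-CA, N fixing the xy half-plane,
CA as origin).

One initial triangle block — outgoing and incoming triangle multiplicative
updates, triangle attention around starting and ending nodes, and a pair
transition — runs on the backbone-derived pair features.  Pair features
contain only geometry and chain topology (binned CA-CA distances, clipped
signed sequence offsets within chains, a same-chain flag, and the unit vector
to the partner CA in the query residue's local frame), never the sequence
state or flow time, so this block's output is computed once per backbone and
cached across all sampling steps.  In this architecture the pair track is
never updated from the single track, so the per-block pair updates are
likewise a pure function of the backbone; the sampler memoises them too,
which is an exact (bit-identical) optimisation, verified against per-step
recomputation.

Each main block then

1. updates the single track with gated multi-head attention whose logits
   carry an additive per-pair bias projected from the pair track,
2. applies a single-track transition (two-layer MLP),
3. refines the pair track with outgoing and incoming triangle multiplicative
   updates,
4. updates single + frames with invariant point attention (IPA): query, key
   and value points are predicted in each residue's local frame, mapped to
   global coordinates, and scored by squared distances alongside the scalar
   and pair-bias terms; outputs return to the local frame (plus norms), and a
   small zero-initialised head composes a per-residue rigid update
   (quaternion rotation + translation) onto the frames.

A LayerNorm + linear head emits per-position logits over the 20 amino acids.
All residual branches end in zero-initialised output projections, so a fresh
model is an exact identity on its inputs and emits the uniform distribution —
a property the tests assert exactly.  Because every geometric quantity is a
distance, a frame-local vector or an IPA inner product, the logits are
invariant to global rotations and translations; the suite verifies < 1e-4
maximum deviation under random rigid motions (the binning of distances uses a
1e-6 Å snap so that distances sitting exactly on a bin edge cannot flip bins
under rotational round-off).

The network and its gradients run on a small reverse-mode automatic
differentiation engine over numpy arrays written for this package
(`backflow.autodiff`); every primitive's gradient is checked against central
finite differences in the test suite.  One deliberate scale concession:
triangle attention processes rows in chunks so the (rows, heads, L, L) logit
tensor stays bounded at long lengths; chunked and unchunked paths agree to
machine precision.

### Hyperparameters

The published description of this architecture fixes no sizes, so they are
package choices, config-exposed:

| parameter | default | toy preset | meaning |
|---|---|---|---|
| `n_blocks` | 4 | 2 | main blocks |
| `d_single` | 128 | 64 | single-track width |
| `d_pair` | 64 | 32 | pair-track width |
| `n_heads` | 4 | 4 | attention heads everywhere |
| `n_ipa_points` | 4 | 4 | IPA points per head |
| distance bins | 40 over 2–22 Å + overflow | same | pair distance channel |
| offset clip | ±32 | same | relative-position channel |
| time embedding | 8-dim Fourier | same | flow-time channel |

Triangle-multiplication hidden channels default to `d_pair / 2`.  LayerNorm
placement is pre-norm throughout.  The single-track transition after
attention is included by default (the source description is silent on it).

## Training

AdamW (betas 0.9/0.999, weight decay 0.01) with a linear learning-rate warmup
from 0 to 1e-3 — 1000 steps at the published scale, 100 at toy scale — and
constant rate afterwards; global-norm gradient clipping at 1.0; batch size 8.
Per sample: crop to the crop size (256 published, 64 toy) using spatial
interface-centred crops for half the samples and per-chain contiguous windows
for the rest; perturb coordinates with Gaussian noise under one of two
schemes (half clean / half 0.2 Å, or half 0.02 Å / half 0.2 Å), always
setting the categorical noise token that matches the sigma actually applied;
draw t uniformly, corrupt the sequence, and take the cross-entropy on masked
positions only (config-exposed; the all-positions variant changes a fixed
batch's loss reproducibly).  Training is seed-deterministic on one device.
Fine-tuning from a prior checkpoint is supported by loading its state dict.

## The toy world

The synthetic generator stands in for structure databases.  Backbones are
ideal helices (rise 1.5 Å/residue, 100°/residue, radius 2.3 Å), zigzag
strands (rise 3.3 Å/residue), and hairpins (two antiparallel strands joined
by a four-residue semicircular turn), with N/C/O atoms placed off the CA
trace so frames are well-defined and chirality alternates along strands.
Each structure's "native" sequence is a fixed table lookup on binned
d(CA_i, CA_{i-2}) and d(CA_i, CA_{i+2}) descriptors (clamped at chain ends).
Because the rule is a deterministic function of the clean geometry, the
Bayes-optimal recovery is 1.0, giving toy training a known ceiling; chance is
0.05.  The rule writes its signal into exactly the local distance pattern the
trunk's pair features expose, which is what makes desk-scale learnability a
meaningful end-to-end check: the toy acceptance run (300 structures of
24–48 residues, 300 steps, toy preset) reaches held-out recovery ≈ 1.0 at
temperature 0.1.

What the toy world does **not** emulate: real side-chain packing, solvent
exposure, long-range energetic coupling between sequence positions, or any
physical energetics — the structure→sequence map is local and noiseless.
Passing toy tests therefore demonstrates that the machinery (features, trunk,
flow, training) works and that geometric information flows end to end; it
does not certify recovery rates on real proteins.

Two-chain toy complexes place strands at a controlled gap and return a
ground-truth interface mask computed by exhaustive distance scan over the
generator's own coordinates.  Synthetic profile pairs plant functional sites
(conserved 0.95-dominant in the natural profile, uniform in the designed one)
and structural sites (0.95-dominant in both), over a moderate-conservation
background (0.5-dominant plus three minor letters) identical in the two
profiles.  Synthetic all-against-all ipAE tables plant an on/off-target gap
with configurable noise and a pTM column with a configurable failure
fraction.

## Evaluation machinery

- **Sequence recovery**: exact-match fraction between designed and native.
- **Couplings**: mutual information between alignment columns with a uniform
  pseudocount and average-product correction (APC).  This replaces a
  pseudolikelihood DCA fit: at desk scale, MI+APC has the same ranking
  semantics for the planted-signal and contact-precision analyses, and an
  externally computed coupling matrix can be passed to `contact_agreement`
  directly.  Contact precision ranks pairs within sequence-separation strata
  (short 6–11, medium 12–23, long ≥ 24) and reports the contacted fraction of
  the top L, L/2, L/5 pairs per stratum ("top L" is interpreted per stratum;
  ties break lexicographically; empty strata report NaN, not 0).  Contacts
  default to CA–CA < 8 Å, with a pseudo-CB construction available; the source
  analyses do not state their cutoff.
- **Refold filters**: strict inequalities exactly as printed — AF2 screen:
  binder RMSD < 1.5, interface pAE < 7, binder pLDDT > 90; AF3 screen:
  ipAE_i < 1.5, binder pTM > 0.8, complex RMSD < 2.5.  The structure success
  rate is the percentage of designed backbones with ≥ 1 passing sequence; the
  sequence success rate is the percentage of passing sequences.
- **Specificity**: S_spec = min over off-target ipAE_i minus on-target
  ipAE_i ("best off-target" = the minimum, i.e. the most confident and
  therefore worst-case off-target).  Selection requires pTM > 0.8 strictly;
  ties break toward lower on-target ipAE, then binder id.  The scaling
  analysis samples N sequences per backbone *without replacement* (matching
  "designed N sequences"), applies the pTM filter inside the resampling as
  well as in final selection (both choices config-exposed), and averages the
  maximum over 100 repetitions.
- **Profile contrast**: conservation is the normalized-entropy index
  C = 1 − H(f)/ln 20 over gap-excluded column frequencies (an external
  conservation program's per-column indices can be substituted).  Profile
  divergence is the per-position 1-Wasserstein distance between the two
  20-dim column distributions under the discrete 0/1 ground metric — which
  equals total variation — averaged over positions with data in both
  profiles; columns with > 50% gaps in the natural profile are excluded.  An
  alternative reading (1-D Wasserstein between pooled conservation values) is
  deliberately not the default, since the per-position form is what the
  domain-level averaging requires.  Annotation-level differences use a
  two-sided Mann–Whitney U of per-domain divergence for annotated vs
  non-annotated domains, with Benjamini–Hochberg q-values over all terms
  tested in one run as a single family.  Functional-site scores subtract
  designed from natural conservation; precision–recall evaluation subsamples
  negatives to 10× the positives (seeded) and reports average precision.

## Numerical choices and degenerate inputs

- Frames: collinear N/CA/C raises a per-residue error naming the residue.
  Missing O is tolerated (frames need N/CA/C only); missing N/CA/C drops the
  residue at parse time with a count.
- Altlocs resolve to highest occupancy (first-in-file on ties); insertion
  codes are flattened in file order; residues are indexed 0-based and
  contiguous internally with author numbering kept for reporting.
- Interfaces use backbone atoms (the model is backbone-conditioned; inputs
  here carry no side chains).  The published 5 Å / 8 Å rules were applied to
  full-atom structures, so absolute residue counts can differ slightly; the
  atom set is an explicit argument of the implementation's data flow rather
  than a hidden constant.
- The interface qualification rule (≥ 5 residues per chain within 5 Å)
  returns null rather than an empty annotation; `min_residues=0` disables it.
- Spatial crop centres are uniform over interface residues (over all residues
  when no interface exists); contiguous crops allocate the crop across chains
  proportionally with largest-remainder rounding.
- Sampler edge cases: t + dt may not exceed 1; excluding all 20 tokens is an
  error; positions fixed by the caller are placed before step one and never
  revisited; an empty loss selection is defined as 0 with a warning.
- The empirical per-component noise sd over 10,000 atoms must sit within 5%
  of sigma; this is a Monte-Carlo check, not a distributional proof.

## Problem sizes

Test-suite and acceptance runs use the toy preset: 300 training structures of
24–48 residues, 300 optimisation steps at batch 8 and crop 64, 20 held-out
structures for recovery, decodes at lengths 50 and 500, 10,000-position
sampler checks, 1,000-row filter tables, 240-binder specificity campaigns,
120-column profile pairs at depth 400, and 500–1,000 simulated terms for test
calibration.  These sizes were chosen so the whole pipeline — including
training — re-runs from scratch in minutes on one CPU core while keeping
every statistical check at ≥ 3 standard errors of resolution.

## Known limitations

- The trunk is desk-scale and trained only on the toy world here; no
  pretrained weights for real proteins ship with the package.
- No side chains, no solvent model, no structure-prediction or confidence
  head: refold metrics (ipAE, pTM, pLDDT, RMSD) are consumed as inputs.
- MI+APC underestimates couplings relative to pseudolikelihood DCA on deep
  real alignments; it is the in-repo estimator, not a DCA replacement.
- The conservation index is entropy-based, not the weighted sum-of-pairs
  variants some conservation programs use; rankings agree on concentrated
  columns but absolute values differ.
- Training is single-device; there is no distributed data pipeline.
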