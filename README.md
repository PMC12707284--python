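# backflow

Structure-conditioned protein sequence design at desk scale: a three-track
attention trunk conditioned on backbone geometry, trained and sampled with
discrete flow matching, together with the evaluation and analysis machinery
that surrounds sequence design in practice — sequence recovery,
coupling–contact agreement, refold-confidence filters and binder success
rates, binder specificity scoring, and natural-vs-designed profile contrast
for functional-site prediction.

## Who this is for

People building or studying fixed-backbone ("inverse folding") design
pipelines who want a complete, transparent, CPU-sized implementation of the
whole loop: read a backbone, featurize it, run a global-attention trunk,
sample sequences in a handful of parallel steps, and push the designs through
the standard downstream analyses.  Everything — including the network
gradients — runs on numpy, so every step is inspectable and deterministic.

## The model

Sequences live in a 21-token space (20 amino acids + MASK).  The forward
corruption of discrete flow matching interpolates between the all-MASK state
at t = 0 and the native sequence at t = 1: each position keeps its native
token with probability t.  Training minimises the cross-entropy

    L = E_{t ~ U(0,1)}  CE( f_theta(x_t, backbone, t),  x_native )

on masked positions.  Sampling reverses the chain: a masked position unmasks
during a step of size dt with probability dt/(1 − t) and draws its amino acid
from softmax(logits/τ), excluded tokens (e.g. cysteine) renormalised away.
With a uniform 10-step schedule the last step unmasks everything, so a full
sequence is decoded in 10 forward passes regardless of length.

The conditioning network is a three-track trunk.  Per-residue rigid frames
(R_i, t_i) come from N/CA/C by Gram–Schmidt.  An initial triangle block
(triangle multiplicative updates + triangle attention) runs once per backbone
on sequence-independent pair features and is cached across all sampling
steps.  Main blocks update the single track by gated attention with a pair
bias, the pair track by outgoing/incoming triangle multiplicative updates

    z_ij ← z_ij + g_ij ⊙ Linear( Σ_k a_ik ⊙ b_jk )        (outgoing)

and the geometry by invariant point attention, whose logits combine scalar
attention, a pair bias and squared distances between frame-mapped points, so
the final logits are invariant to global rigid motions (verified to < 1e-4).

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

`examples/01_design_sequences.py` trains the desk-scale trunk on the toy
world — ideal helices, strands and hairpins whose "native" sequence is a
fixed function of local backbone geometry — and designs sequences for a
held-out 40-residue hairpin:

```
training loss: 2.621 -> 0.593 (uniform baseline ln 20 = 3.00)
native: YPRRRRRRRRRRRRRRTDWQQNPRRRRRRRRRRRRRRRDP
design: YPRRRRRRRRRRRRRRYPPQQQPRRRRRRRRRRRRRRRDP  recovery=0.90  mean_logp=-0.03
design: YPRRRRRRRRRRRRRRYPQQQQPRRRRRRRRRRRRRRRYP  recovery=0.88  mean_logp=-0.07
design: YPRRRRRRRRRRRRRRYDQQQQPRRRRRRRRRRRRRRRYP  recovery=0.90  mean_logp=-0.06
```

The loss falls from the uniform baseline ln 20 ≈ 3.00 toward zero; each
design is produced in 10 parallel unmasking steps; recovery is the fraction
of positions matching the native sequence (chance level 0.05 — here the model
has learned the strand/turn vocabulary after 150 steps, and reaches ≈ 1.0
recovery with the 300-step schedule the acceptance run uses).  The remaining
examples cover interface detection and crops, refold filters and success
rates, binder specificity scaling, and profile contrast:

```bash
python examples/04_binder_specificity.py
```

```
best T0 binder: T0_binder2  S_spec=4.79  pTM=0.92
designs/backbone -> mean best S_spec across targets:
  n= 1: 3.63
  n= 2: 4.09
  n= 5: 4.57
  n=10: 4.80
  n=30: 4.90
```

S_spec is the gap between the most confident off-target ipAE and the
on-target ipAE (planted true gap: 4.0); the curve shows the expected best
specificity as more sequences are designed per backbone — rising steeply at
first, then saturating.

A thin CLI mirrors the library (`backflow prep | synth | train-toy | design |
evaluate | specificity | profile-contrast`); every run writes a manifest with
its arguments, seed and input checksums next to its outputs.

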