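# Methods

## Problem

In plasma of patients with low tumor burden, circulating tumor DNA (ctDNA)
is often below 0.1% of the circulating free DNA, the same order of magnitude
as the residual error rate of UMI-consensus sequencing. Calling mutations or
detecting cancer at these levels requires a background error model that says,
for each individual read position, how likely an erroneous non-reference base
is — and a statistical layer that aggregates weak evidence across reads and
across a patient-specific catalog of candidate mutations.

`plasmavar` has two parts: a read-level error model (a small feed-forward
softmax network over read and sequence-context features) and a likelihood /
EM / likelihood-ratio machinery for single-site variant calling and
catalog-level tumor-fraction estimation.

## The error model

Each observation is one read × one genomic position. The observed allele
X ∈ {A, C, G, T} is treated as a draw from a four-way multinomial whose
probabilities are predicted from the feature set D of that read position:

    P(X = a | D) = softmax(f(D))_a

with f a multilayer perceptron: the encoded features pass through hidden
layers of 128, 64 and 32 ReLU units into a 4-node softmax head. The loss is
the mean negative log-likelihood of the observed allele. Features come in
three kinds:

* **numeric** (read position, fragment size, sequence length, UMI group
  size, number of other errors in the read, and optionally UMI disagreement
  counts, indel counts, window GC and 1-/2-mer Shannon entropies) —
  standardized with per-feature mean/sd frozen from the training table.
  This is the inference behaviour of batch normalisation; freezing the
  statistics makes prediction deterministic.
* **categorical** (strand, first-in-pair) — one-hot with level lists frozen
  from the training data.
* **embedded** — the trinucleotide context, a 64-symbol vocabulary mapped
  through a learned 3-dimensional embedding, so contexts with similar error
  behaviour can cluster.

The default feature set is the eight retained by cross-validated selection:
seven read-level features plus the trinucleotide context; the full
fourteen-feature set is available through `FeatureSchema`.

Training uses Adam (lr 1e-3, batch 1024 by default), at most 100 epochs,
early stopping on validation NLL with patience 5–8. The validation split is
by sample identifier when at least three samples are present, so a model is
never validated on reads from a training sample; otherwise a seeded random
row split is used. All randomness flows from explicit seeds: two runs with
the same seed produce identical weights.

### Training data and the 1/β rescaling

Training rows are all read-alignment mismatches (harvested from MD tags,
excluding germline-variant and catalog positions) plus a uniformly
downsampled fraction β of the reference-matching positions. β is recorded in
the model artifact. Raw predictions therefore live in the reweighted
distribution; before deriving error rates, the probability of the context's
central base — the class that was downsampled — is multiplied by 1/β and the
four-vector renormalised. This is the standard prior-shift correction for
class subsampling; its adequacy is checked empirically (held-out rate
recovery within 10% and a binned predicted-vs-empirical slope of 1 ± 0.15
in the acceptance suite) rather than assumed.

The default β, when not given, targets roughly ten matches per mismatch:
enough reference signal for the four-way head while keeping the table small.

### Conditional error rates

The calling layer restricts each site to reads observing the reference R or
the candidate alternative M. The rates it needs are conditional:

    e(R→M) = P(X=M | Y=R) / (P(X=R | Y=R) + P(X=M | Y=R))

evaluated from the forward pass with the observed (reference-centred)
context, and e(M→R) from a second, counterfactual pass in which the central
base of the trinucleotide is replaced by M — the context is the only model
input that encodes the true base. In that pass the downsampled class is the
substituted central base, so the 1/β correction follows the context.

### Feature importance and selection

`loco_importance` trains, per cross-validation fold, a full model and one
model per left-out feature; a feature's importance is the mean increase in
validation NLL when it is missing. Leaving out the trinucleotide supplies
the central reference base as a plain categorical feature, so only the
neighbouring-base information is withheld. `stepwise_selection` removes
features cumulatively from least to most important; a feature survives only
if its removal worsens validation loss in every fold relative to the
full-model baseline, and the procedure stops at the first such feature.

## The statistical model

For candidate site i with N_i retained reads, let Z_i ~ Bernoulli(r)
indicate whether mutation i is present in the sample at all, and given
Z_i = 1 let each fragment carry the mutant allele with probability f/2
(tumor fraction f; clonal heterozygous mutation). Marginalising the
latent true alleles gives the observed-data likelihood

    L(f, r) = ∏_i [ (1−r) ∏_{x=R}(1−e^{R→M}) ∏_{x=M} e^{R→M}
            + r ∏_{x=R}((1−e^{R→M})(1−f/2) + e^{M→R} f/2)
                ∏_{x=M}(e^{R→M}(1−f/2) + (1−e^{M→R}) f/2) ]

computed in log space with a stable two-branch log-sum-exp.

**EM.** With latent (Z_i, Y_ij), the E-step computes z_i = P(Z_i=1 | data)
and, within the mutated branch, P(Y_ij = M | x_ij); the M-step sets r to the
mean z_i and f/2 to the z-weighted expected mutant-fragment fraction.
Iteration stops when the observed-data log-likelihood gains less than 1e-8
(monotonicity is asserted in tests); at most 1000 iterations. Because the
surface can be bimodal between (low f, high r) and (high f, low r), four
deterministic starts are tried — pooled-signal, hottest-site, and two fixed
corners — and the best likelihood kept. Reads with identical (site, allele,
error-rate) values are collapsed into weighted rows first; this is an exact
rewrite of the likelihood that makes constant-rate simulations hundreds of
times faster.

**Tests.** Cancer calling across a catalog uses Q = −2 log L(0,0)/L(f̂, r̂)
against χ²(2); single-site variant calling fixes r = 1 (the site's presence
is governed by f alone) and uses χ²(1). Q is clamped at zero. The null
f = r = 0 sits on the parameter boundary, so the χ² reference is
conservative; the acceptance suite verifies rejection ≤ α + 3 MC-SE rather
than exact calibration. r is maximised over [0, 1] without enforcing
r ≥ 1/K; with the unconstrained MLE the LRT can only be more conservative
under the null.

**Numerical guards.** Error rates are floored at 1e-8 (zero rates break the
log-likelihood) and capped at 0.3 (rates approaching 1/2 make f
unidentifiable and are extrapolation artifacts of the model, not data).
Zero-coverage sites return f̂ = 0, p = 1. A utility removes catalog
positions shared between patients before cross-patient calls.

## The synthetic-data generator

Three levels, all seeded and returning ground truth:

* **Site-level** (`simulate_site_data`): draws Z_i, the mutant fragments at
  rate f/2 and the observed alleles at the supplied error rates — the
  generative model itself, for testing the statistical layer.
* **Table-level** (`simulate_training_table`): feature rows with a known
  (optionally feature-dependent) error-rate law and β-thinning of matches,
  for testing model calibration and feature selection. `central_base`
  restricts the table to one reference base, a single-stratum design whose
  allele distribution is learnable without any context feature.
* **Alignment-level** (`simulate_alignments`): a random reference plus
  paired consensus-style SAM reads with correct flags, match CIGARs, MD
  consistent with seq-vs-reference, cD/cE tags, insert sizes from a
  two-component nucleosomal mixture (means 162/340 bp, sds 15/30, weights
  0.75/0.25 — the mono-/di-nucleosomal peaks of plasma DNA), per-cycle
  errors from a log-linear read-end/strand profile, and tumor alleles
  injected per fragment at rate f/2 at catalog sites. The second mate is
  overlap-trimmed. A truth table lists every emitted substitution.

What the generator does **not** emulate: context-specific error spectra
(the 12 substitution classes get uniform alternative alleles), mapping
artifacts, indel errors, soft-clipping, GC-coverage bias, batch effects, or
real panel design. Passing tests therefore demonstrate the correctness of
the estimation machinery under the stated generative assumptions, not
clinical performance.

## Problem sizes

The test and acceptance runs use: enumeration oracles on instances with
K·max(N_i) ≤ 12; 100 random instances against the numerical MLE; 2000 null
catalogs (K=10, N_i=1000, e=1e-3); 200 recovery replicates (K=20, N_i=2000,
f=0.05, r=0.8); error-model training tables of 2–4 million positions before
thinning; LOCO/stepwise on ~22k-row tables with a (32,16) network; and
end-to-end alignment replicates at ~5000× site coverage. These sizes were
chosen so each property is measured with comfortable Monte-Carlo margins on
a single CPU.

One measurement detail matters for the calibration slope: the lowest-rate
bins (~1e-4) of a held-out table must contain enough empirical mismatches
that the log-scale comparison reflects the model rather than Poisson noise.
The slope is therefore computed on a 2-million-row held-out set with each
bin weighted by its observed mismatch count in the log-log fit.

## Known limitations

* The 4-way multinomial head couples the error model to the reference-base
  composition of the training data; very small tables underfit, which the
  early-stopping metadata (`training_meta`) makes visible.
* e(M→R) rests on the central-base substitution heuristic; nothing in
  training ever shows the network a mutant-centred context with mutant
  reads, so these rates are extrapolations. At low f they enter the
  likelihood only through second-order terms.
* The f/2 heterozygous-clonal assumption is fixed; subclonal catalogs bias
  f̂ downward.
* Indels are counted as read-level features but never called.
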