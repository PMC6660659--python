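# cloudsig

Probabilistic assignment of mutational signatures to **individual somatic
mutations**, exploiting the sequential dependency of mutational processes in
clustered (kataegis-like) regions of cancer genomes.

Classical signature refitting treats every single-base substitution in a
sample as an independent draw from a mixture of signatures. But mutations that
lie close together on the genome — dense *clouds*, as opposed to the isolated
*sky* mutations hundreds of kilobases apart — are often produced by the same
process in a single event, so the signature of one mutation is informative
about its neighbours. `cloudsig` implements a composite model that keeps the
independence assumption for sky while modelling clouds as a hidden Markov
chain of signatures that may be interspersed with independent draws, and uses
it to decode a signature (and a chain/mixture generator label) for every
mutation.

## The model

Mutations are mapped to the standard *L* = 96 substitution-in-context
categories (pyrimidine-normalized base change × 5' flank × 3' flank) and a
fixed emission matrix *E* (*K* signatures × 96, e.g. a COSMIC v2 subset) is
supplied; only the *K*² + 2 chain parameters are learned, per sample:

* **sky** mutations (nearest flanking mutation farther than a distance
  threshold, default 2000 bp) follow a multinomial mixture: signature
  *Q*ₜ ~ π, category *O*ₜ ~ *E*[*Q*ₜ].
* **cloud** mutations (maximal runs of ≥ 2 mutations with consecutive gaps ≤
  threshold) are modelled by a dynamic Bayesian network: a binary indicator
  *I*ₜ chooses chain generation (*I*ₜ = 0) or an independent mixture draw
  (*I*ₜ = 1), with Pr(*I*ₜ | *I*ₜ₋₁) = *B* and starting law ρ. The signature
  transition uses the *K*×*K* matrix *A* only along uninterrupted chain steps:

  Pr(*Q*ₜ = j | *Q*ₜ₋₁ = i, *I*ₜ₋₁ = f, *I*ₜ = g) = *A*ᵢⱼ if f = g = 0, else πⱼ.

  At sky positions the indicator is clamped to the mixture state, so the model
  reduces exactly to the mixture there.

Training is per-sample Baum-Welch EM over the clamped 2*K*-state lattice
(chromosomes are independent sequences sharing one sample's parameters), with
multiple random restarts; decoding is by the Viterbi algorithm, yielding for
every mutation a signature and a *sequence-dependent* flag (chain-generated
under the most likely path). Downstream tools compute signature exposures per
sky/cloud compartment, signature→signature transition counts inside
chain-generated runs, their enrichment as Pearson residuals (optionally
correcting for self-transitions), and context-preserving permutation nulls.
A simulator generates cohorts from the model's own generative semantics with
full ground truth. See `docs/methods.md` for assumptions, defaults and known
identifiability limits.

## Worked example

```python
import numpy as np
import cloudsig as cs

# synthetic, well-separated signatures and a persistent chain regime
sig = cs.synthetic_signatures(4, separation=0.95, seed=5)
pi = np.array([0.4, 0.3, 0.2, 0.1])
A = np.full((4, 4), 0.05 / 3); np.fill_diagonal(A, 0.95)
params = cs.CloudSignatureParams(pi, A, rho=np.array([0.5, 0.5]),
                        B=np.array([[0.90, 0.10], [0.60, 0.40]]),
                        signatures=sig, threshold=2000)
spec = cs.LayoutSpec(n_chromosomes=4, sky_per_chromosome=150,
                     clouds_per_chromosome=100, cloud_size_mean=4.0)
table, truth = cs.sample_cohort(spec, params, n_samples=1, seed=11)

model = cs.CloudSignatureModel(signatures=sig, threshold=2000,
                               n_restarts=5, random_state=0).fit(table)
assignments = model.predict(table)
```

The run above prints (via the surrounding report code in this example):

```
mutations: 2116
clouds: 400, cloud mutations: 1516 (71.6%), mean cloud size: 3.79
train log-likelihood: -9162.7 (16 EM iterations)
pi fitted : [0.412 0.288 0.197 0.103]     # planted [0.4 0.3 0.2 0.1]
agreement with planted signatures: 95.5%
sequence-dependent cloud mutations: 36.4%
chain transitions: 398  self-transition residuals: [13.7, 14.1, 16.0, 15.1]
```

The mixture marginal π is recovered to the second decimal and 95.5% of
mutations get their true signature back. The Viterbi sequence-dependent
fraction is conservative — a chain step can often be re-explained as a
mixture interruption, so the most likely path under-uses the chain (see
`docs/methods.md`) — while the strongly positive self-transition residuals
recover the planted persistence of processes within clouds.

The same pipeline is available from a shell:

```sh
cloudsig simulate --preset small --seed 0 --outdir sim/
cloudsig train --input sim/cohort.tsv --signatures sim/signatures.tsv \
               --restarts 10 --seed 1 --outdir run/
cloudsig exposures --assignments run/assignments.tsv --outdir run/
cloudsig enrich --assignments run/assignments.tsv --exclude-diagonal --outdir run/
cloudsig cv --input sim/cohort.tsv --signatures sim/signatures.tsv \
            --thresholds 500,1000,2000,4000 --outdir cv/
```

Real data enter as a tab-separated mutation table (`sample`, `chrom`, `pos`,
then either a `category` label like `A[C>T]G` or `ref`/`alt` with flanking
bases) plus a signature file in the COSMIC v2 text layout, optionally
subset (e.g. `--subset "Signature 1,Signature 2,Signature 3,Signature 5,..."`
for the 12-signature breast-cancer set, for which the model has 146 free
parameters).

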