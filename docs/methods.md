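# Methods

## Model and assumptions

The package treats PPI denoising as label propagation over *pair evidence
space*: two protein pairs with near-identical evidence profiles should be
equally likely to be a real interaction. Pairs are therefore embedded as
17-component vectors, collapsed into fingerprints (identical-vector
classes), and connected in a k-nearest-neighbor similarity graph. A random
walk with restart from high-confidence fingerprints then scores every
fingerprint — and hence every pair — by proximity, in evidence space, to
known-reliable interactions. The underlying assumptions: (i) evidence
sources are informative for interaction status even when individually
noisy; (ii) reliability transfers between pairs with similar evidence;
(iii) complexes appear as dense, small-diameter subgraphs of the
reconstructed weighted network.

## Pair features

* **D** — sum of domain–domain interaction confidences over all cross
  domain pairs (unordered lookup). Raw sum, no normalization.
* **MF/BP/CC** — per-aspect GO semantic similarity: information content
  IC(t) = −log(fraction of the aspect's annotated corpus covered by t or
  its descendants), term-pair similarity 2·IC(MICA)/(IC(t₁)+IC(t₂)) with
  0/0 := 0, averaged over all cross term pairs; 0 if either protein is
  unannotated. Bounded in [0, 1].
* **mf/bp/cc** — 1 iff the proteins share a GO-slim term after removing
  the trivial aspect roots. The source text is ambiguous about which GO
  feature family is boolean; the definitions force semantic similarity to
  be numeric and slim sharing to be boolean, so that is what is
  implemented.
* **CE** — Pearson correlation of (optionally log2(x+1)-transformed)
  expression profiles; missing or zero-variance profiles give 0.
* **S, TAP1–5** — pass-through association/reliability scores with default
  0; the package does not recompute them from raw data.
* **EPPI1/2** — 0/1 membership in two curated interaction databases.
* **CD** — stored as 1 − Czekanowski-Dice distance of interaction
  neighborhoods (N(x) includes x), so that, like every other feature,
  larger means stronger evidence; a flag restores the raw distance.

Missing evidence is encoded as 0, never NA, so every pair is
fingerprintable.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `T` | 10 | nearest fingerprints linked per fingerprint |
| `alpha` | 0.8 | restart probability of the walk |
| `tol` | 1e-6 | L1 stopping threshold |
| `T_in` | 0.6 | cluster admission threshold on E_vk |
| `d` | 2 | cluster diameter bound (unweighted hops) |
| `omega` | 0.25 | NA match threshold (0.20 is the common alternative) |
| `min_complex_size` | 3 | heteromeric filter for emitted/benchmark complexes |
| `quantize_precision` | 4 | decimals defining vector identity |

`d` has no published value; 2 is the standard small-diameter constraint
for complexes and is configurable. Quantization (round-half-even to 4
decimals) makes "same vector" well defined for continuous features; it is
the knob that controls how aggressively pairs collapse into fingerprints.

## Numerical choices

* **Similarity rescale.** The min/max in
  M_ij = 1 − (dist − d_min)/(d_max − d_min) are taken globally over all
  pairwise distances realized during kNN construction (the printed formula
  is index-degenerate); the top-T choice itself is monotone in raw
  distance and unaffected. If d_max = d_min every edge gets weight 1.
* **kNN.** Exact blocked brute force; ties at the T-th distance break
  toward the smaller fingerprint ID; the directed relation is symmetrized
  by union; the walk uses the row-normalized weighted adjacency. Rows with
  zero incident weight (possible only in pathological tiny graphs) stay
  zero and are logged.
* **Seed prior.** The "+1 per seed" prior is normalized to 1/|seeds|; the
  walk is linear in F₀, so rankings are identical (property-tested).
* **Walk.** F_r = (1−α) M F_{r−1} + α F₀ exactly as written, multiplying
  the row-stochastic matrix on the left; mass is not renormalized between
  iterations. Convergence is geometric with ratio (1−α) in the max norm;
  the per-step *L1* contraction by (1−α) additionally requires column sums
  of M ≤ 1 (e.g. regular graphs, where M is doubly stochastic), which is
  how the property is exercised in the tests. The fixed-point residual of
  the returned vector is checked against 10·tol.
* **Expansion.** E_vk is recomputed after every admission; candidate ties
  break by higher vertex weight, then smaller ID. A singleton seed has
  w_k = 0, so its best-connected neighbor is admitted via an +inf sentinel
  (a skip mode is available). Note that in a uniform clique the m-th
  member arrives at E = 2/(m−1): with T_in = 0.6 uniform cliques stop
  growing at five members, which matters for oracle tests but not for
  NA-based matching (a size-5 core of a size-8 complex still matches at
  ω = 0.25).
* **Queue semantics.** Cluster members are removed from the seed queue
  only; with overlap allowed (default) they may join later clusters.
  Clusters with identical membership are emitted once.
* **Hypergeometric tail.** P(X ≥ k) is computed through scipy's stable
  survival function (vectorized batch form available); tests verify it
  against exact integer enumeration for every parameterization with
  V ≤ 60. No multiple-testing correction by default; a Bonferroni flag
  exists.
* **Seed rule.** "Backed by at least two accurate databases" is resolved
  as: ≥ 2 non-zero components among {EPPI1, EPPI2, TAP1, TAP5}, and
  strictly more than half of all 17 components non-zero. Both the
  indicator set and the threshold are configurable, since the narrative
  descriptions of the rule are inconsistent about which sources count.

## Synthetic fixtures

The generator plants `n_complexes` disjoint complexes (sizes uniform in
[min_size, max_size]) among `n_proteins`, draws within-complex edges with
probability `p_in` and background edges with `p_bg`, and emulates each
evidence source around that truth: one latent factor per complex gives
co-complex expression correlation ≈ ρ; a three-aspect root→branch→leaf
ontology gives each complex a leaf term carried by members with
probability `annotation_prob` (branches double as slim terms); each
complex owns a high-confidence interacting domain pair; the observed
networks (two EPPI sets, five TAP tables, a STRING-like table) are
independently corrupted copies of the true edge set — each true edge
dropped with probability `fn`, round(fp·|E|) spurious pairs added,
retained edges scoring Beta(5, 2) and spurious ones Beta(2, 5). The first
EPPI set doubles as the CD topology network.

Defaults (n = 300, 20 complexes of 5–8 proteins, p_in = 0.9,
p_bg = 0.005, fp = fn = 0.1, m = 50 samples, ρ = 0.7,
annotation_prob = 0.8) define the "easy" regime used by the end-to-end
tests and the acceptance script; a noisier "hard" preset exists. These
sizes keep a full pipeline run under a minute on one CPU while still
producing ~45,000 pairs and ~30,000 fingerprints.

What the fixture does *not* emulate: realistic degree distributions,
GO DAG depth and annotation sparsity, overlapping complexes, batch
structure in expression, or correlated errors between sources (each
observed network is corrupted independently). Passing end-to-end tests
therefore demonstrates that the machinery recovers planted structure
under controlled noise — not a performance claim about any real
interactome.

## Known limitations

* Brute-force kNN is quadratic in the number of fingerprints; it is exact
  and fine at fixture scale, but proteome-scale fingerprint sets would
  need an approximate-neighbor backend behind the same contract.
* Benchmark matching uses the ∃-match counts for N_cp/N_cb as defined;
  best-match bookkeeping beyond that is not implemented.
* Evaluation against a real benchmark (e.g. a curated complex catalogue)
  requires the user to supply the files; the package ships no downloads.
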