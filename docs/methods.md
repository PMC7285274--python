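# Methods

`transitnet` compares the co-occurrence structure of a microbial
community between two conditions (here labelled active, ACT, and
sedentary, SED) and asks which taxa drive the reorganization of one
condition's network into the other's. This note records the model, the
defaults, the numerical choices, and what the synthetic data do and do
not establish.

## Network construction

Taxa (rows of the abundance table) are nodes. For each condition's
samples, the association of every taxon pair is the Spearman rank
correlation rho (midranks for ties); its two-sided p-value uses the
t approximation on n − 2 degrees of freedom. An undirected edge (i, j)
exists iff p_ij < 1e-5 — a single, fixed, stringent per-pair cut rather
than an FDR-style family correction, chosen because one hard threshold
keeps the edge rule auditable and the resulting graphs comparable across
conditions. Negative correlations form edges exactly like positive
ones; the signed rho is kept as an edge attribute. Constant rows are
assigned rho = 0, p = 1 by contract.

An exact-permutation p-value mode exists for very small cohorts; it
enumerates the full permutation null and is therefore limited to n ≤ 8
samples, where enumeration (≤ 40 320 permutations per pair) is
affordable.

Pre-filtering is explicit and separate from reading: by default taxa
present in < 20% of samples are dropped before correlation
(`min_prevalence = 0.2`, `min_mean_count = 0`). Counts are used raw by
default; an optional per-sample relative-abundance transform is
available but changes Spearman results only through the per-sample
rescaling (rank correlations are invariant to per-taxon monotone
transforms, not to per-sample ones).

## Topology

On the binary undirected network:

- **Clustering** C_v = 2·T_v / (k_v(k_v − 1)), the fraction of a node's
  neighbor pairs that are directly linked (0 when k_v < 2).
- **Flow coefficient.** `flow_raw_v` counts the node's neighbor pairs
  with *no* direct edge — each such pair communicates through the
  length-2 path mediated by v, so the count is a local betweenness-like
  measure in units of node pairs. `flow_norm_v` divides by k_v(k_v−1)/2.
  On a binary graph open and closed neighbor pairs partition the
  neighborhood, so `flow_norm + C = 1` for every node of degree ≥ 2;
  this identity is used as a cross-metric test. Because of it, group
  comparisons on `flow_norm` would be algebraically redundant with
  clustering, so comparisons and keystone ranking default to
  `flow_raw`, which also carries the degree scale.
- **Global efficiency** E = mean over unordered pairs of 1/d(i, j),
  with 1/∞ := 0 for disconnected pairs. The characteristic path length
  (mean d over connected pairs) is reported alongside; E is the primary
  global metric because it remains defined and comparable on the
  disconnected graphs that stringent thresholding produces.
- **Assortativity** is Newman's degree correlation over edge ends. It
  is undefined (NaN sentinel) when endpoint-degree variance is zero
  (regular graphs) and an error on edgeless graphs.

## Surrogate normalization

Observed metrics can be normalized against an ensemble (default 1000)
of degree-preserving randomizations: Maslov–Sneppen double-edge swaps,
10 attempted swaps per edge, rejecting swaps that create self-loops or
multi-edges. The normalized value is observed / surrogate mean;
z-scores are emitted as well, since "the parameters obtained" from a
surrogate ensemble admit either convention. Both global scalars and
per-node vectors are normalized, with explicit column labels. A
density-only Erdős–Rényi null is available behind a flag for
sensitivity analysis. Ensembles are seed-reproducible: per-surrogate
streams are spawned from one root `SeedSequence`.

## Statistical comparison

Per-node metric distributions of the two networks are compared with a
tie-corrected Kruskal–Wallis test (chi-squared reference). The family
of metric tests is gated either by Bonferroni division of a family
alpha or by a single fixed critical value, default p < 1e-4 (the
Methods-stated gate is preferred over the looser figure-caption value
where the two disagree). Normality is checked with a Lilliefors-style
KS statistic whose p-value comes from a seeded parametric bootstrap,
because the textbook KS null is anti-conservative once the normal's
parameters are estimated from the sample.

**Limitation, printed with every report:** nodes of a network are not
independent samples. The p-values quantify rank separation of the two
per-node value sets; they are not population-level inference. The
comparison is performed as published, with the caveat attached rather
than silently "corrected".

## Transition networks and keystones

Let A and B be the two condition networks on a shared taxon ordering
(intersection by default; union with zero-padding optional), each
represented by its thresholded signed-correlation matrix (rho where an
edge exists, 0 elsewhere, unit diagonal for conditioning; a flag
switches to the raw 0/1 adjacency). The transition matrix T from A to
B is defined by the product relation **A·T = B** and computed as

    T = pinv(A) · B

with a rank-truncated Moore–Penrose pseudoinverse (singular values
below dim·eps·σ_max are dropped — the standard rank-revealing cutoff,
reported in the output together with the residual ‖A·T − B‖_F). The
pseudoinverse never fails on singular inputs; on full-rank inputs the
residual is numerically zero and A = B gives T = I.

Two readings of the inverse-product construction circulate: the
`consistent` mode above, which satisfies the defining relation, and a
`literal` mode T = pinv(B)·A (inverse of the *target* times the
source), which instead satisfies B·T = A. Both are implemented;
`consistent` is the default and `literal` is kept so either convention
can be reproduced. The direction labels of published analyses are
ambiguous between these readings, so the package documents both rather
than guessing.

T is dense and signed, but the flow coefficient is a binary-graph
measure, so a binarized view is taken: symmetrize as max(|T|, |Tᵀ|),
zero the diagonal, and keep the strongest entries down to a target edge
density — by default the mean density of the two condition networks, so
that flow coefficients are comparable between X, Y and the condition
networks. Ties at the cut break lexicographically by taxon label,
making the view deterministic.

Keystones of a direction are the ceil(0.10·n) taxa with the highest
`flow_raw` on the binarized transition network (fraction configurable);
taxa tied with the boundary value are all included.

## Synthetic data generator

The generator emulates the *shape* of a two-lifestyle 16S cohort:
64 active-like and 45 sedentary-like samples over 150 taxa by default,
zero-inflated overdispersed counts, and a planted co-occurrence graph
per condition with designated bottleneck hubs.

**Counts.** A Gaussian copula: draw a latent multivariate normal with
the planted correlation structure, push each margin through the normal
CDF, then through a zero-inflated negative-binomial quantile function.
Per-taxon NB means are lognormal (median 20, log-sd 1.0); the NB size
(dispersion) is 0.5, giving variance ≫ mean as in real 16S data; the
zero-inflation mass is 0.2. The zero mass sits at the *bottom* of the
latent ranks — a structural-zero reading in which taxa drop below
detection when their latent abundance is low. This choice is
deliberate: an independent post-hoc zero mask would attenuate rank
correlations by roughly (1 − π)² and make strongly planted edges
undetectable at the smaller group size, defeating the generator's
purpose of carrying a known, recoverable ground truth. Realized zero
fraction of the default table is ≈ 0.33.

**Planted graphs.** Taxa are partitioned into modules realized as
correlation *cliques* (every within-module pair correlated equally).
This is a mathematical necessity, not a convenience: a valid
(positive-semidefinite) correlation matrix cannot host a strongly
coupled neighborhood with missing internal pairs — eigenvalue-clipping
repair of such targets moves entries by 0.2–0.45, far beyond the 0.05
repair budget the generator enforces. Open neighbor pairs (flow) must
therefore come from degree structure and coupling strength, not from
holes punched into modules. Concretely:

- the **sedentary-like** graph is module-confined and tightly coupled
  (magnitude 0.8) at density 0.05 — few, cohesive modules: high
  clustering, low efficiency;
- the **active-like** graph is denser (0.08), with weaker, more
  distributed couplings (0.65) and cross-module shortcut edges routed
  through hub taxa, each hub bridging a disjoint pair of modules at
  magnitude 0.55 — 0.55 is near the largest value that keeps a hub
  attached to two modules inside the positive-definite cone, and
  disjointness of the bridged pairs is likewise a PD requirement.

Requested densities are realized exactly (within one edge) by a
budgeted clique partition; incompatible requests raise with the counts.
The magnitudes are chosen so planted edges clear p < 1e-5 with high
probability at the respective group sizes (0.8 at n = 45; 0.65 at
n = 64), which is what makes the ground truth recoverable and the
recovery tests meaningful. Any residual non-positive-definiteness is
repaired by iterated eigenvalue clipping; the repair delta is recorded
in the ground truth and capped at 0.05.

**What the generator does not emulate.** Compositionality (library-size
coupling), phylogenetic correlation of abundances, realistic taxon
name structure, batch effects, and non-clique association motifs.
Passing tests therefore establish that the *pipeline* recovers planted
structure under realistic marginals and sparsity — not that real gut
networks have clique-modular structure, and not that Spearman
thresholding is robust to compositional artifacts (it is not claimed to
be; compositionality-aware estimators are out of scope by design).

## Determinism and seeds

Every stochastic component takes an explicit seed and derives
independent child streams via `numpy.random.SeedSequence`; the pipeline
spawns stage seeds from one root seed and records them in its run
manifest. Same table + same config ⇒ byte-identical outputs.

## Problem sizes used in the shipped checks

The test-suite and the reproduction script run at deliberately modest
sizes chosen to exercise every code path at full fidelity: oracle
equivalence on 200 random graphs of ≤ 15 nodes, surrogate contracts on
a 100-node graph × 1000 rewirings, recovery studies on 25–50 replicate
cohorts of 30 taxa, and the full default cohort (150 taxa, 109
samples) for the directional contrast and transition analysis. All
numbers printed by the examples and the reproduction script are
computed at run time.

## Known limitations

- Per-node significance tests treat nodes as exchangeable observations
  (see caveat above).
- The p < 1e-5 edge rule is a per-pair cut; the package does not claim
  family-wise error control over the ~n²/2 pair tests.
- The transition matrix is a static algebraic object; no temporal or
  dynamical interpretation (no trajectory simulation) is offered.
- Binarization of T discards magnitude information beyond the density
  cut; the dense signed T is always available for other analyses.
- Assortativity of sparse modular graphs is dominated by within-module
  degree homogeneity; differences between conditions should be read
  qualitatively.
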