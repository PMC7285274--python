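# transitnet

Two-condition microbial co-occurrence networks, the transition
matrices between them, and the keystone taxa that drive the
reorganization.

## The problem

Lifestyle (e.g. physically active vs sedentary) reshapes the gut
microbiota not only through which taxa are abundant but through how
taxa co-occur. Given a taxa × samples count table with each sample
assigned to one of two conditions, `transitnet`:

1. builds one co-occurrence network per condition — nodes are taxa,
   and an edge joins pair (i, j) when its Spearman rank correlation is
   significant at *p* < 10⁻⁵;
2. characterizes each network by clustering *C*, global efficiency
   *E* = ⟨1/d(i,j)⟩, degree assortativity, and the **flow
   coefficient** FC — for node *v*, the number of neighbor pairs with
   no direct edge, i.e. the length-2 paths that must route *through*
   *v* (a local betweenness-like measure of transmissibility);
3. normalizes metrics against degree-preserving surrogate ensembles
   (Maslov–Sneppen rewiring, default 1000 surrogates) and compares
   per-node distributions between conditions with a tie-corrected
   Kruskal–Wallis test gated at *p* < 10⁻⁴;
4. solves the **transition networks** between the condition matrices
   A and B: T = pinv(A)·B, so that A·T = B in the least-squares sense
   (rank-truncated pseudoinverse; the printed inverse-product variant
   pinv(B)·A is available as `mode="literal"`), binarizes T at matched
   density, and reports the taxa in the top 10% of FC on the
   transition network as the **driving keystones** of the A→B
   reorganization.

A synthetic-data module generates two-condition cohorts (64/45 samples,
150 taxa, zero-inflated negative-binomial counts via a Gaussian copula)
with planted module structure and bottleneck hubs, so every stage is
testable against known ground truth. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Scripts under `examples/` each demonstrate one capability. Running
`python examples/03_compare_conditions.py` on the default synthetic
cohort prints:

```
metric              H          p  sig  mean(ACT)  mean(SED)
degree          16.45   4.99e-05  *     10.213      6.973
clustering       0.73   3.93e-01  -      0.720      0.545
flow_raw        54.79   1.34e-13  *      8.567      1.867
```

The active-like network carries significantly more open length-2
paths per node (mean flow 8.6 vs 1.9 node pairs, *p* ≈ 10⁻¹³ across
the 1e-4 gate) while clustering does not separate — the
flow coefficient sees a difference in transmissibility that clustering
is blind to. And `python examples/04_transition_keystones.py`:

```
consistency residuals ||A.T - B||_F: 9.11e-13 / 9.84e-13
planted bottleneck hubs: taxon_077, taxon_045, taxon_079
...
SED->ACT: top 15 keystones (fraction 10%)
  1. taxon_077  FC(raw)=188 <- planted hub
  2. taxon_079  FC(raw)=143 <- planted hub
  3. taxon_045  FC(raw)=132 <- planted hub
```

The three planted bottleneck taxa — which bridge modules only in the
active-like condition — top the keystone list of the direction that
must create their shortcuts.

## Command line

The same pipeline is available as a thin CLI:

```bash
transitnet simulate --n-taxa 150 --n-act 64 --n-sed 45 --seed 1 --out fixtures/
transitnet build --table fixtures/table.tsv --metadata fixtures/metadata.tsv \
    --group ACT --p-threshold 1e-5 --out act.graphml
transitnet topology --net act.graphml --out act_topology.tsv --normalize --seed 42
transitnet compare --profile-a act_topology.tsv --profile-b sed_topology.tsv \
    --alpha 0.0001 --out comparison.tsv
transitnet transition --net-a act.graphml --net-b sed.graphml --out keystones.tsv
transitnet run --table fixtures/table.tsv --metadata fixtures/metadata.tsv \
    --seed 1 --out run/      # full pipeline + manifest.json
```

Exit codes: 0 success, 1 usage error, 2 data error. `run` writes a
machine-readable manifest (parameters, stage seeds, versions) that
makes the run exactly reproducible.

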