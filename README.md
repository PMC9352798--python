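# lri-net

Game-theoretic scoring of gene co-expression networks with the **Link
Relevance Index (LRI)**, applied to case/control transcriptomics — the
setting where conventional analysis ranks genes by differential
expression, while this method instead asks how *relevant* each gene is to
the co-expression structure of the diseased state.

## The model

Let (N, g^E) be a co-expression network on a gene panel N derived from a
microarray experiment situation E = ⟨N; S_D; S_R; A^{S_D}; A^{S_R}⟩
(diseased and reference expression matrices). Write N(g^E) for the genes
carrying at least one link, n(g^E) = |N(g^E)|, and g_i^E for the *star*
of gene i (its incident links). The **microarray network game** is the
cooperative game on link subsets with characteristic function

    v(g) = (1/n(g^E)) · Σ_{i ∈ N(g^E)} u_{g_i^E}(g),

an average of unanimity games u_T (worth 1 iff T ⊆ g). The **LRI** of
gene i is the position value of this game — half the Shapley value of
each incident link — which collapses to the closed form

    F_i = (1 / (2 n(g^E))) · ( 1 + Σ_{j ~ i} 1/deg(j) ),

for active genes and 0 for isolated ones. The allocation is efficient
(Σ F_i = v(g^E) = 1), anonymous, additive, and invariant to superfluous
links. Genes with F_i > 0 are the **salient genes**; the pipeline then
compares them against marker lists and conventional DEGs and runs
right-sided hypergeometric enrichment over user-supplied GMT gene sets.

All scores are computed in exact rational arithmetic; floats are a
display view.

## Worked example

The 4-gene network with links {12, 13, 14, 23}:

```sh
$ printf 'gene_a\tgene_b\n1\t2\n1\t3\n1\t4\n2\t3\n' > edges.tsv
$ lri-net score --network edges.tsv --mode closed --out scores.tsv
4 genes scored (mode=closed) -> scores.tsv
$ cat scores.tsv
gene    lri_exact       lri_float       degree  rank
1       3/8     0.375   3       1
2       11/48   0.229167        2       2
3       11/48   0.229167        2       2
4       1/6     0.166667        1       4
```

Gene 1 is the hub (degree 3) and receives 18/48 of the total unit worth;
the two degree-2 genes receive 11/48 each and the leaf 8/48; the scores
sum to 1 (efficiency). `--mode sum` and `--mode oracle` compute the same
allocation through the star-sum formula and a brute-force link-Shapley
enumeration and agree exactly.

The same result from expression data end to end, on synthetic data with
one planted 10-gene co-expressed module:

```sh
$ lri-net simulate --seed 42 --out-dir sim/
1000 genes x 100+100 samples -> sim
$ lri-net build --expr sim/expr.tsv --meta sim/meta.tsv --threshold 0.9 --out sim_edges.tsv
10 active genes, 45 edges -> sim_edges.tsv
$ lri-net score --network sim_edges.tsv --out sim_scores.tsv
10 genes scored (mode=closed) -> sim_scores.tsv
```

The module members are the only genes correlated above τ = 0.9, form a
10-clique, and each scores exactly 1/10 — the planted structure is
recovered perfectly (`sim/truth.json` holds the ground truth). Other
subcommands: `deg` (Welch test + BH + |LFC| filter), `salient`,
`compare`, `enrich`, and `run` for the full configured pipeline.

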