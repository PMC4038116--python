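# bicliques

Exact enumeration of **all maximal bicliques** in a bipartite graph, with
the supporting machinery needed to use it on biological association data:
twin-vertex data reduction, clique inflation, two random bipartite graph
generators, score-matrix thresholding, and construction of the
hierarchical biclique DAG used to organize gene sets by their shared
genes.

## The problem

Let *G* = (*U* ∪ *V*, *E*) be a bipartite graph with |*U*| = *m* ≥ |*V*| =
*n*. A *biclique* (*L*, *R*) with *L* ⊆ *U*, *R* ⊆ *V* is a complete
bipartite subgraph; it is *maximal* when no vertex can be added to either
side. In gene-set analysis, *U* holds genes and *V* holds gene sets or
phenotypes, so a maximal biclique is a group of functions together with
exactly the genes they share — the natural unit for building an ontology
of functions from heterogeneous gene sets. The number of maximal bicliques
can be exponential in *n*, so the enumerator must prune aggressively.

## The algorithms

**MBEA** explores subsets of *V* depth-first. Each search node carries
⟨*L*, *R*, *P*, *Q*⟩: the current seed *R*, its common neighborhood *L*,
the candidates *P*, and the former candidates *Q*. Expanding a candidate
*x* forms *L*′ = *L* ∩ *N*(*x*); candidates adjacent to *all* of *L*′ (the
set *S*) are absorbed at once, making (*L*′, *R* ∪ {*x*} ∪ *S*) maximal,
and the branch is pruned whenever some former candidate is adjacent to all
of *L*′ (it would belong to every biclique below, proving them all
non-maximal). **iMBEA** additionally processes candidates in
non-decreasing order of common-neighborhood size |*N<sub>L</sub>*(*v*)|
and retires absorbed candidates whose neighborhood equals that of *x*,
which prunes dominated branches and markedly shrinks the search tree on
graphs with variable degree structure.

Before enumeration, vertices with identical neighborhoods (*twins*) are
merged into one representative and re-expanded afterwards — an exact
reduction, since twins always travel together in maximal bicliques.

## Worked example

The seven-by-five graph with edges {u1,u2}×{v1,v2,v3} ∪ {u3..u7}×{v5}:

```python
import bicliques as bc

edges = [(u, v) for u in ("u1", "u2") for v in ("v1", "v2", "v3")]
edges += [(u, "v5") for u in ("u3", "u4", "u5", "u6", "u7")]
g = bc.BipartiteGraph.from_edges(edges)

result = bc.enumerate_maximal_bicliques(g, "imbea")
print(result.count)                 # 2
print(bc.edge_maximum(result))      # Biclique(left=('u1', 'u2'), right=('v1', 'v2', 'v3'))
print(bc.vertex_maximum(result))    # Biclique(left=('u3', 'u4', 'u5', 'u6', 'u7'), right=('v5',))
```

The graph contains exactly two maximal bicliques. The *edge-maximum* one
(largest |*L*|·|*R*|) is the 2×3 block with 6 edges on 5 vertices; the
*vertex-maximum* one (largest |*L*|+|*R*|) is the star with 6 vertices and
5 edges — the two objectives genuinely disagree.

The same from the shell, given the graph as a DIMACS-style edge list
(`e <left> <right>` lines):

```
$ bicliques --quiet enumerate fig1.el --stats
u1 u2	v1 v2 v3
u3 u4 u5 u6 u7	v5
nodes=3
leaves_pruned=0
max_depth=1
bicliques=2
```

Other subcommands: `generate` (Erdős–Rényi or degree-controlled random
bipartite graphs), `threshold` (score matrix → association edge list),
`dag` (biclique TSV → DOT hierarchy), `inflate`, `transactions`. All
outputs are byte-deterministic; `enumerate` output pipes directly into
`dag`.

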