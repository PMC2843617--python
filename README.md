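# setnet

Integrated analysis of gene/protein lists for systems biologists: set
algebra on lists, Fisher-exact enrichment against GMT gene-set libraries,
expansion of seed lists into connecting subnetworks over background
networks, and construction of a "network of lists" linking lists with
statistically significant overlap.

High-content experiments — expression microarrays, ChIP screens, RNAi,
proteomics, phosphoproteomics — each produce lists of genes or proteins.
Comparing such lists with each other and with prior-knowledge libraries
(pathways, Gene Ontology terms, kinase substrates, microRNA targets, ...)
is the workhorse of downstream interpretation. `setnet` provides that
workflow as a plain Python library and CLI, with no server or external
database required.

## What it computes

**Enrichment.** The overlap of a user list (size *a* within the background
universe of *N* genes) with a library set (size *b*) is scored by the
one-sided Fisher exact test: with *k* genes shared, the p-value is the
hypergeometric upper tail

```
p = Σ_{i=k}^{min(a,b)}  C(b,i) · C(N−b, a−i) / C(N,a)
```

i.e. the chance of an overlap at least as large under random sampling.
Per user list, p-values over a library are adjusted by Bonferroni
(`min(1, n·p)`) and Benjamini–Hochberg (step-up FDR) corrections, and terms
are ranked by ascending raw p.

**Expansion.** Seed genes are mapped onto a background network
(protein–protein interactions from SIF files, thresholded co-expression
tables, or co-annotation graphs derived from a GMT library via the Jaccard
co-membership index). All shortest paths of length ≤ `max_steps` between
seed pairs are enumerated; interior nodes are admitted as *intermediates*
when their **specificity** — the fraction of their background links that go
to seeds — meets a cutoff. Intermediates are ranked by subnetwork links /
background degree, and the subnetwork can be exported as Cytoscape-ready
SIF or converted back into an expanded gene list.

**Network of lists.** User lists and library sets become nodes; an edge
connects two lists whose overlap is significant after Bonferroni correction
(corrected p < 0.05 by default). Library-set nodes are classed
`single_overlap` or `multi_overlap` by how many input lists they hit.

## Worked example

```python
import networkx as nx
from setnet import (BackgroundNetwork, ExpansionParams, GeneList,
                    GeneSetLibrary, expand, overlap_matrix, rank_terms,
                    subnetwork_to_list)

# --- enrichment ---------------------------------------------------------
lib = GeneSetLibrary("demo", [
    GeneList("CELL_CYCLE", genes=("CDK1", "CDK2", "CCNB1", "CCNA2", "TP53")),
    GeneList("APOPTOSIS",  genes=("TP53", "BAX", "CASP3", "CASP9")),
    GeneList("RIBOSOME",   genes=("RPL3", "RPL4", "RPS6")),
])
user = GeneList("hits", genes=("CDK1", "CDK2", "CCNB1", "TP53"))
table = rank_terms(overlap_matrix([user], lib), "hits")
print(table[["term", "k", "p_raw", "p_bonferroni"]].to_string(index=False))
```

prints

```
      term  k    p_raw  p_bonferroni
CELL_CYCLE  4 0.015152      0.045455
 APOPTOSIS  1 0.893939      1.000000
  RIBOSOME  0 1.000000      1.000000
```

The library's 11 unique genes form the universe (N = 11); drawing the 4
user genes at random would land all four inside CELL_CYCLE only ~1.5% of
the time (5/C(11,4)), and the term stays significant after Bonferroni over
the three sets.

```python
# --- expansion ----------------------------------------------------------
net = BackgroundNetwork(nx.Graph(
    [("A", "X"), ("X", "B"), ("A", "Y"), ("Y", "C"), ("X", "Z")]))
sub = expand(GeneList("seeds", genes=("A", "B", "C")), net,
             ExpansionParams(max_steps=2, specificity_cutoff=0.0))
print({v: round(im.specificity, 3) for v, im in sub.intermediates.items()})
print(subnetwork_to_list(sub).genes)
```

prints

```
{'Y': 1.0, 'X': 0.667}
('A', 'B', 'C', 'Y', 'X')
```

X connects seeds A and B but spends one of its three background links on
the non-seed Z (specificity 2/3); Y's links all go to seeds (specificity
1.0), so Y outranks X. At `specificity_cutoff=0.7` only Y survives.

The same operations are available from the shell:

```sh
setnet enrich --lists hits.txt --gmt library.gmt --out-dir results/
setnet expand --list seeds.txt --network ppi.sif --max-steps 2 \
              --specificity 0.5 --out-sif sub.sif --out-list expanded.txt
setnet netoflists --lists a.txt --lists b.txt --gmt library.gmt \
                  --alpha 0.05 --format graphml --out lists.graphml
```

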