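# ctdnet

Tools for connecting a single anchored protein — the RNA polymerase II
largest subunit (RPB1/RPO21), whose C-terminal domain (CTD) serves as a
protein-binding scaffold — to complex downstream phenotypes in budding
yeast, by combining fold-change differential expression, GO-category
enrichment, anchored interaction-network pruning, and flow-cytometry
DNA-content gating.

The intended user is a yeast geneticist or systems biologist who has (a) a
mutant-versus-control expression ratio table, (b) a protein-interaction
edge list (e.g. a BioGRID download), (c) a flat gene→GO annotation, and
(d) a curated list of the anchor's interactors with direct CTD-binding
evidence — and who wants candidate genetic pathways linking the anchor to
observed phenotypes such as chromosome mis-segregation, cell-wall defects
or DNA-content drift.

## The method

1. **Regulation calling.** A gene with mutant/control ratio *r* is *up* if
   *r* ≥ 2, *down* if *r* ≤ 0.5, otherwise *unchanged* (cutoffs and boundary
   strictness configurable). Differentially expressed (DE) genes lacking any
   functional annotation are excluded from network construction.

2. **Enrichment.** Each GO category of size *K* in a universe of *N* genes
   is tested for overrepresentation among the *n* DE genes via the
   hypergeometric upper tail P(X ≥ k), with Benjamini–Hochberg step-up FDR
   correction across all tested categories at α = 0.05.

3. **Anchored subnetworks.** For each phenotype-related category, the DE
   genes annotated to it seed a direct-interaction network (edges incident
   to a seed). After merging with the anchor's first-interaction star, the
   network is pruned to its *contiguous* core: exactly the nodes lying on at
   least one simple path from the anchor to a DE gene in which every node is
   admissible — the anchor, a DE gene, or a bridge interactor (the curated
   CTD-evidence set in strict mode; any first interactor in relaxed mode).
   Pruning is computed via the block-cut tree and is verified in the tests
   against exhaustive simple-path enumeration.

4. **DNA-content gating.** Fluorescence events are gated with brackets
   anchored on the strongest G1 signal peak (SSP) and marker range
   MR = SSP/4: G1 = SSP ± MR, G2 = 2·SSP ± MR, S = the open interval between
   them, plus sub-G1 and >2C remainders. Per-bracket percentages quantify
   ploidy drift across growth cycles.

A synthetic-study generator produces all inputs with planted ground truth
(planted up/down sets, an unannotated DE fraction, and a mediator-like
connector that is the unique evidence bridge from the anchor to the planted
DE genes of every phenotype category), so the full pipeline is testable
end to end without any downloads.

## Worked example

```sh
ctdnet synth study --seed 5 --out-dir fixtures/
ctdnet de --expr fixtures/expression.tsv --out calls.tsv
# -> 818 of 6221 genes differentially expressed (325 up, 493 down)

ctdnet enrich --calls calls.tsv --annotation fixtures/annotation.tsv --out enrich.tsv
# -> 0 of 24 overlapping categories significant at 0.05

ctdnet build --interactions fixtures/interactions.tsv --calls calls.tsv \
    --annotation fixtures/annotation.tsv --anchor RPB1 \
    --evidence fixtures/evidence_interactors.txt \
    --categories fixtures/categories.yaml --out-prefix net
# -> cell_cycle_repair: 15 nodes, 14 edges after pruning
# -> cell_wall_membrane: 14 nodes, 13 edges after pruning
# -> chromosome_segregation: 15 nodes, 14 edges after pruning
# -> merged inset: 354 nodes, 278 edges
```

The `de` line reports the DE composition of the generated ratio table: 325
up-regulated and 493 down-regulated genes out of a 6,221-gene universe.
(The planted phenotype categories are deliberately not enriched beyond
background here; the enrichment step simply validates category choices, and
its calibration is exercised separately by the acceptance script.) Each
pruned network retains the anchor, the planted connector (the one evidence
interactor on an anchor→DE path), and the planted DE genes of that
category; every other gene fails the contiguity requirement and is
deleted. The per-network `.nodes.tsv` / `.attrs.tsv` files carry the
role and regulation of each node (anchor = pink, evidence interactor with
no expression change = light blue, DE genes green/red for up/down).

For DNA-content gating:

```sh
ctdnet synth facs --seed 5 --cycles 0..11 --out-dir facs/
ctdnet facs --events facs/cycle00.csv --events facs/cycle11.csv \
    --fixed-ssp 200 --out gates.tsv
# -> cycle00: G1 61.1%, S 17.7%, G2 21.2%, >2C 0.1%
# -> cycle11: G1 24.3%, S 26.5%, G2 21.6%, >2C 27.6%
```

The G1 fraction falls and the >2C fraction rises across growth cycles as
the simulated aneuploid subpopulation accumulates, then plateaus after the
equilibrium cycle.

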