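# coregnet

Topology-consistency analysis of disease-specific TF–miRNA co-regulatory
networks built from differentially expressed (DE) gene sets — on fully
synthetic, seeded data.

The pipeline has five stages:

1. **simdata** — simulate a negative-binomial count matrix with planted DE
   genes (variance `mu + alpha*mu^2`, trend `alpha(mu) = a1 + a0/mu`), a
   typed regulatory interaction database (TF→gene, TF→miRNA, miRNA→gene,
   miRNA→miRNA) with heavy-tailed out-degrees, and a disease-annotation node
   set enriched around the planted regulators. Ground truth is emitted for
   recovery tests.
2. **de_methods** — four simplified DE procedures sharing normalization,
   dispersion, exact-test and BH machinery:
   `deseq_like` (median-of-ratios size factors + conditional NB exact test on
   group count sums with trend dispersion), `edger_like` (total-count scaling
   + empirical-Bayes shrunken gene-wise dispersions + the same exact test),
   `vst_like` (variance-stabilizing transform + moderated t) and `voom_like`
   (log-cpm + precision weights + weighted moderated t).
3. **netbuild** — hypergeometric recovery of miRNAs whose targets *and*
   regulator TFs are enriched in the DE set (BH per family, cutoff 0.001),
   database subgraph on DE genes + recovered miRNAs, optional
   disease-annotation filter (both endpoints annotated).
4. **keyplayers** — hubs (top 10% by total degree, ceiling rule), an exact
   minimum dominating set (directed domination, branch-and-bound with greedy
   fallback) and a greedy minimum connected dominating set of the largest
   weakly connected component.
5. **consistency** — pairwise overlap coefficients
   (`|X∩Y| / min(|X|,|Y|)`), all-method intersections, node/edge Venn
   counts, and a robustness test against networks built from random
   pseudo-DE gene sets with add-one empirical p-values `(r+1)/(N+1)`.

## CLI

Every stage is a subcommand of `coregnet`; all I/O is headered TSV.

```bash
coregnet simulate --seed 1 --out-dir run/inputs
coregnet de --counts run/inputs/counts.tsv --groups run/inputs/groups.tsv \
    --method deseq_like --out run/deseq.tsv
coregnet network --db-edges run/inputs/db_edges.tsv --db-nodes run/inputs/db_nodes.tsv \
    --de-genes run/deseq.tsv.genes.tsv --disease run/inputs/disease.tsv \
    --out-edges run/net_e.tsv --out-nodes run/net_n.tsv
coregnet topology --network-edges run/net_e.tsv --network-nodes run/net_n.tsv \
    --out run/keyplayers.tsv
coregnet compare run/kp_a.tsv run/kp_b.tsv --out run/overlaps.tsv
coregnet robustness --db-edges ... --universe ... --reference run/keyplayers.tsv \
    --m 1000 --n-random 100 --seed 1 --out run/robustness.tsv
```

Or run the whole study (simulation → 4 DE methods → networks → key players →
overlap/Venn tables → robustness) in one go:

```bash
coregnet run-all --out-dir run --seed 1
```

`run/manifest.json` records the configuration, seed and cardinalities of
every stage; a fixed seed reproduces the run byte-for-byte.

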