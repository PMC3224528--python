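# regraft

**Clade-placement inference for single-gene phylogenies.**

When a gene tree puts a clade somewhere surprising — say, the
euglenophyte or chlorarachniophyte copies of a Calvin-cycle enzyme
clustering with "non-green" algae instead of their green plastid
donors — the interesting question is not just *where* the maximum
likelihood puts the clade but *which alternative positions the data can
exclude*.  `regraft` implements that analysis end to end:

* site-wise log-likelihoods under **WAG(+F)+I+Γ₄** (Felsenstein pruning,
  discrete-gamma rates, invariant sites, empirical frequencies);
* **exhaustive re-grafting**: prune the query clade, keep the backbone
  topology fixed, and build one candidate tree per backbone edge
  (2m − 3 candidates for m backbone leaves);
* **topology tests** from the site-likelihood matrix via RELL bootstrap:
  BP, Kishino–Hasegawa, Shimodaira–Hasegawa, and the approximately
  unbiased (**AU**) test from a multiscale bootstrap — `BP(r)` curves
  fitted by weighted least squares to `z(r) = d√r + c/√r`, p = 1 − Φ(d − c);
* **ML tree search and bootstrap support** (ML distances → neighbor
  joining → NNI hill climbing; column-resampled replicates);
* **indel synapomorphy scanning**: gap blocks shared by whole named taxon
  groups and absent from others, reported in reference-sequence
  coordinates;
* a **simulator** that generates 56-taxon × 327-column fixtures with a
  known tree, a query clade planted inside a donor group (a horizontal
  gene transfer signal), and planted group-specific deletions — so every
  stage is testable without downloads.

For whom: molecular evolutionists testing endosymbiotic/horizontal gene
transfer hypotheses on single-protein datasets, and anyone needing a
transparent, fully scriptable AU-test stack in Python.

## Worked example

`examples/02_place_query_clade.py` simulates the default fixture (a
3-taxon "euglenophyte" query clade attached inside the stramenopile
group of a 56-taxon tree, 327 columns, α = 0.8, p_inv = 0.1), prunes the
clade, scores every re-graft, and tests all placements:

```
103 candidate topologies (2m-3 for m=53)
true attachment: stramenopile_01
best by lnL:     stramenopile_01
true edge: delta_lnL=0.00  AU=0.989  KH=0.982  SH=1.000
102/103 placements rejected at the 5% level by the AU test
```

The planted attachment edge is ranked first, its AU p-value is far above
the 5% rejection level, and essentially every alternative placement is
rejected — the pattern a strongly localised clade produces.  The indel
companion (`examples/01_simulate_and_scan_indels.py`) recovers the
planted gap blocks exactly:

```
columns [81, 85): present=euglenophyte,stramenopile absent in 7 groups (deletion-like)
columns [196, 200): present=cyanobacteria absent in 8 groups (deletion-like)
```

A deletion shared exclusively by the query clade and its donor group is
exactly the kind of character evidence used to corroborate a transfer
hypothesis.  The other examples show ML tree fitting with bootstrap
support and the AU machinery on a hand-made likelihood matrix.

There is also a thin CLI (`regraft simulate|fit|bootstrap|place|autest|
scan-indels|run`); `regraft run config.yaml` executes the whole chain
(read → mask → fit/accept tree → enumerate → evaluate → test → scan) and
writes every intermediate plus a JSON manifest into a run directory.

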