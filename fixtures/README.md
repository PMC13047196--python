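# Bundled synthetic fixture set

A small synthetic casing-soil data set (2 peat groups x 3 growth stages x
2 replicates, 60 taxa, 2,000 reads per sample) generated by the package's
own community simulator:

```python
from casingsoil import SimDesign, simulate_dataset
from casingsoil.io import write_count_table, write_metadata, write_tree

design = SimDesign(n_taxa_pool=60, groups=(0, 100), stages=3, replicates=2,
                   depth=2000, selection_strength=30.0, trait_signal=0.1,
                   dispersal_regime="neutral", stage_amplitude=1.0, seed=1)
table, tree, meta, _ = simulate_dataset(design)
write_count_table(table, "fixtures/counts.tsv")
write_metadata(meta, "fixtures/metadata.tsv")
write_tree(tree, "fixtures/tree.nwk")
```

Files: `counts.tsv` (samples x taxa), `metadata.tsv` (design factors +
physicochemical variables + latent peat axis), `tree.nwk` (rooted binary
phylogeny over the 60 taxa). Entirely synthetic; no sequencing data.
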