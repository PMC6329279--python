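# exprembed

Gene and sample embeddings from bulk expression matrices, with the
downstream analyses that make them useful: neighbor queries, embedding-
dimension interpretation via over-representation analysis, UPGMA
molecular subtyping, and responder/non-responder biomarker discovery.

## Who this is for

Computational biologists with a large expression matrix (e.g. TCGA-style
RSEM tables, genes × samples) who want an unsupervised, knowledge-base-
free representation of genes and samples: genes that behave alike across
samples end up close together, sample groups (cancer types, response
groups) separate, and individual embedding dimensions can be read out
and tested for biological meaning.

## The model

Every gene *a* and sample *i* gets an m-dimensional vector (default
m = 50) and a scalar bias. Predicted log2 expression is

    Ĝ_ai = G_a · S_i + b_a + b_i

— biased matrix factorization, trained collaborative-filtering style on
individual matrix cells: uniform init on [-0.05, 0.05], mini-batch Adam
(batch 64), mean squared loss, 3 epochs by default, with a learning-rate
range test for picking the rate. Raw counts are floored at 1 and
log2-transformed first; samples whose type code starts with "1"
(normals) can be filtered out.

Downstream, relatedness is Euclidean distance in embedding space.
"Close neighbors" of an anchor gene are genes strictly within a
threshold (0.1 by default). A sample group's centroid times the gene
entity matrix gives the group's predicted expression profile; genes
close to an anchor exclusively in a responder profile, intersected with
the anchor's entity-space neighbors, are candidate biomarkers.

See `docs/methods.md` for the full account, including what the
synthetic-data generator does and does not emulate.

## Worked example

Simulate a responder scenario (three sample groups; an anchor gene whose
10-gene module shifts expression only in the responder group), train an
embedding, and query it:

```
exprembed simulate --preset responder --seed 7 --out data
exprembed train --input data/expr.tsv --dim 10 --epochs 30 --lr 0.01 \
    --seed 7 --out model
```

Training logs `final train MSE 0.0185747, val MSE 0.020484` — the
held-out-cell error sits just above the generator's noise variance
(0.01), i.e. the factorization has recovered essentially all the planted
structure. Gene-space neighbors of one module member now recover its
co-module:

```python
>>> from exprembed import load_model, close_neighbors
>>> model = load_model("model")
>>> for h in close_neighbors(model, "GENE0001", threshold=0.35)[:3]:
...     print(h.entity_id, round(h.distance, 4))
GENE0006 0.1578
GENE0005 0.1806
GENE0003 0.206
```

All 9 hits at this threshold are the other members of GENE0001's planted
module. (A learned embedding is only identified up to a linear map, so
the neighbor threshold is always relative to one model's own distance
scale — use `lr-find`-style inspection or a known gene pair to calibrate
it.)

The discovery workflow, run on the scenario's ground-truth vectors:

```python
>>> from exprembed import SynthConfig, discover
>>> from exprembed.simulate import make_responder_scenario, model_from_truth
>>> cfg = SynthConfig(n_groups=3, group_separation=3.0,
...                   modules=((10, 0.05), (20, 0.05)), seed=7)
>>> expr, truth, spec = make_responder_scenario(cfg)
>>> res = discover(model_from_truth(truth), expr, spec).anchors[truth.anchor_id]
>>> len(res.responder_exclusive_neighbors), len(res.entity_neighbors)
(12, 9)
>>> res.candidates
('GENE0001', 'GENE0002', 'GENE0003', 'GENE0004', 'GENE0005',
 'GENE0006', 'GENE0007', 'GENE0008', 'GENE0009')
```

The 9 candidates — responder-exclusive profile neighbors intersected
with entity-space neighbors of the anchor — are exactly the planted
module members, and their Pearson correlation with the anchor across
responder samples is 0.966–0.975.

Other subcommands: `preprocess` (floor + log2 + normal-sample filter),
`lr-find`, `neighbors`, `enrich` (Fisher + BH over a GMT collection),
`subtype` (signature-dimension UPGMA clustering), `export-projector`
(TensorBoard-projector TSVs). `exprembed --help` lists everything;
`--config file` supplies flag defaults from a flat `key = value` file.

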