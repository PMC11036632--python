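# picostruct

Structured PICO extraction from randomized-controlled-trial abstracts.

Systematic reviews in evidence-based medicine need the design and key
results of each trial — its arms, interventions, medications, endpoints and
outcomes — as structured records, not as highlighted sentences. `picostruct`
treats PICO elements as **nested templates**: a schema declares template
types (10 in the shipped clinical-trial schema, rooted at `Publication`)
whose slots hold either verbatim text spans of the abstract or child
template instances. Extracting a document means producing a typed, acyclic,
connected forest of filled template instances, including *how many*
instances of each type the document describes (the template cardinality is
inferred, not given).

Two engines solve the task:

**Extractive.** Token boundary tagging + learned compatibility + clustering.
A document encoder yields contextual token vectors h₁…hₙ; two affine
softmax heads tag each token as the start/end of a slot filler
(`start:Frequency` … `end:Frequency`; everything in between is untagged,
unlike IOB). Matched start/end pairs give fillers with representations
e = relu(W_r(h_s + h_e) + b_r). A learned symmetric compatibility
q(eᵢ,eⱼ) = σ(wᵀ relu(W(eᵢ+eⱼ) + b) + b′) ∈ (0,1) scores whether two fillers
belong to the same template instance. Per template type, fillers are
partitioned either by exhaustively maximizing the clustering score
h(ℂ) = mean over clusters C of g(C) (g = mean pairwise q within C) for a
given cluster count, or by average-linkage agglomerative clustering with a
threshold τ fitted from training data (midpoint of the mean same-instance
and mean different-instance compatibilities) — which infers the cardinality.

**Generative.** Linearization + grammar-constrained seq2seq decoding. A
forest is serialized depth-first into a token sequence with special
brackets, e.g.

```
[start:Medication] [start:Drug] insulin [end:Drug] [end:Medication]
```

Exactly the valid serializations are described by a right-linear CFG derived
from the schema (per template: a head rule, a terminator rule, one rule per
textual slot, one per template-valued slot). At decoding time a stack tracks
the open brackets; at every step the grammar-allowed token set (inside a
textual slot: the document's tokens plus the slot's end bracket) masks the
model vocabulary and the highest-scoring allowed token is emitted greedily.
The output is therefore always parseable back into a schema-valid forest.

Evaluation reports micro slot F1 (greedy one-to-one matching of predicted
vs. gold fillers on slot label + normalized string; an optional strict mode
aligns instances first), per-template mean F1, and the per-template mean
absolute deviation between predicted and gold cardinalities.

A seeded synthetic-corpus generator produces RCT-like abstracts with gold
forests so that the full pipeline — including training of the bundled tiny
numpy backends — runs end to end on one CPU with no external data or
pretrained weights.

## Worked example

Four fillers have been extracted from an abstract — two `PercentageAffected`
values ("16", "8") and two `TimePoint` values ("week 24", "week 12") — and a
trained compatibility model scored every pair (q(16, week 24) = 0.7,
q(8, week 12) = 0.8, all cross-instance pairs ≤ 0.4). Threshold clustering
groups them into two `Outcome` instances:

```python
import numpy as np
from picostruct.extractive import FillerRepr, hac_cluster
from picostruct.schema import TextSpan

sim = {frozenset({"16", "8"}): 0.1, frozenset({"16", "week 24"}): 0.7,
       frozenset({"16", "week 12"}): 0.4, frozenset({"8", "week 24"}): 0.3,
       frozenset({"8", "week 12"}): 0.8, frozenset({"week 24", "week 12"}): 0.2}

def q(a, b):
    return 1.0 if a.span.text == b.span.text else sim[frozenset({a.span.text, b.span.text})]

fillers = [
    FillerRepr(e=np.zeros(1), slot=slot,
               span=TextSpan("doc", 10*i, 10*i + len(t), i, i, t))
    for i, (t, slot) in enumerate([
        ("16", "PercentageAffected"), ("8", "PercentageAffected"),
        ("week 24", "TimePoint"), ("week 12", "TimePoint")])
]
clustering = hac_cluster(fillers, q, tau=0.5)
for k, cluster in enumerate(clustering.clusters, 1):
    print(f"Outcome {k}: " + ", ".join(f"{f.slot}={f.span.text}" for f in cluster))
print(f"clustering score h = {clustering.score:.2f}")
```

prints

```
Outcome 1: PercentageAffected=16, TimePoint=week 24
Outcome 2: PercentageAffected=8, TimePoint=week 12
clustering score h = 0.75
```

i.e. the document is inferred to describe two outcomes (cardinality 2), each
pairing a percentage with its time point; h = 0.75 is the mean within-cluster
compatibility of the chosen partition.

## Command line

```bash
picostruct fixtures --n 200 --seed 42 --out train.jsonl
picostruct fixtures --n 50 --seed 43 --out test.jsonl
picostruct train-extractive --corpus train.jsonl --out ext.npz --seed 1
picostruct extract --model-dir ext.npz --corpus test.jsonl --out pred.jsonl
picostruct evaluate --gold test.jsonl --pred pred.jsonl --report report.json
picostruct train-generative --corpus train.jsonl --out gen.npz --seed 1
picostruct generate --model-dir gen.npz --corpus test.jsonl --out pred_gen.jsonl
```

Corpora are JSONL files (one document per line: text plus, for gold data,
the instance forest with character-offset spans); schemas are YAML/JSON and
default to the shipped 10-template clinical-trial schema.

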