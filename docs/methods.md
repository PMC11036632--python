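# Methods

## Data model

A schema is a set of template types, each with an ordered list of named
slots; a slot is *textual* (filled by verbatim character spans of the
abstract) or *template-valued* (filled by child instances of a declared
type). Slot names are globally unique, the template-reference graph is
acyclic, and every type is reachable from a single root. An extraction
result is an instance forest: typed instances whose slots hold ordered
filler lists. The linearizer requires the containment graph to be acyclic
(termination) and connected (no unserializable isolated instances);
`validate_forest` checks exactly these conditions plus slot typing.

Character offsets are 0-based half-open; token indices are inclusive — this
matches start/end token tagging, where a one-token filler carries both its
start and its end label, and makes character/token round-tripping
unambiguous. Slot multiplicity is unbounded lists; schemas may declare a
`max_multiplicity` used for validation only.

The shipped default schema has the ten clinical-trial template types
(`Publication` root; `Publication`, `ClinicalTrial`, `Population` fixed at
cardinality one per document) and a 27-textual / 9-template-valued slot
inventory covering the slot names established for this data model
(Journal, PMID, PublicationYear, Frequency, Drug, DoseValue, DoseUnit,
PercentageAffected, TimePoint, NumberAffected, ObservedResult, Country,
Ethnicity, Precondition, FinalNumPatientsArm, NumberPatientsCT, …). The
full published inventory for this family of corpora is larger (85 slots);
the schema file format accepts any inventory, so corpora annotated against
the complete ontology can supply their own schema. Slot declaration order
follows the typical surface order of the corresponding facts in abstracts;
this matters because declaration order doubles as the slot ordering
operator (below).

## Extractive engine

*Boundary tagging.* Two affine heads over the encoder states give per-token
softmax distributions across the slot inventory plus a no-slot label; the
argmax tags each token as a filler start and/or end (a token may start one
slot and end another — the heads are independent). Ties break to the lowest
label index, which is the no-slot label. Predicted boundaries are joined
sentence-wise: starts are processed left to right, each consuming the
nearest unconsumed same-label end at or after its own position; unmatched
boundary tokens are discarded. The greedy order realizes the per-start
minimal-distance rule deterministically; it always produces a maximum
matching (exchange argument over the interval structure), though with two
starts competing for one end the earlier start wins by design.

*Compatibility and clustering.* Filler representations and the two-layer
symmetric compatibility q are exactly the formulas in the README; symmetry
is exact (bit-for-bit) because the inputs enter only through their sum. The
cluster score g is the mean pairwise q within a cluster. The mean literally
taken over the Cartesian product C × C would include self-pairs q(e, e),
which the model never needs to evaluate elsewhere and which the published
worked example leaves undefined; the default therefore averages over
unordered off-diagonal pairs and scores singletons 1.0, which reproduces
that worked example. `include_self_pairs=True` restores the literal
reading. The clustering score h is the unweighted mean of g over clusters.

Two search procedures are provided: exhaustive maximization of h over all
partitions with a prescribed number of blocks (restricted-growth-string
enumeration, bounded at 10 fillers by default; ties break to the first
partition in canonical order), and threshold HAC. HAC is UPGMA on the
dissimilarity 1 − q, cut at cophenetic distance 1 − τ (scipy `linkage` +
`fcluster`): clusters merge while the best inter-cluster mean compatibility
is ≥ τ, so the boundary case "equal to τ" merges. Average linkage is chosen
for consistency with g's mean-pairwise objective. τ is fitted as the
midpoint of two training-set statistics: the mean q over same-instance
pairs and the mean q over different-instance pairs (the combining function
is configurable; the midpoint is the natural symmetric choice).

*Instance assembly.* Each cluster becomes one instance, slots filled from
the extraction labels; fixed-cardinality templates skip clustering and pool
all their fillers into a single instance. The extractive architecture does
not predict template-valued links, so instances are attached under the root
through the schema's containment chain where that chain is unique (in the
default schema it always is); templates with ambiguous containment would be
left unattached and reported. Extractive predictions are accordingly scored
on textual slots; the attachment is a structural convenience, not a claim.

*Training.* How the tagging and compatibility losses should combine is an
open design point; here they are jointly optimized as an unweighted sum of start cross-entropy, end cross-entropy and pairwise
binary cross-entropy (positives = same gold instance, negatives subsampled
to 3× the positives with a seeded generator). Unweighted joint training is
the simplest defensible choice and converges without balancing on the
synthetic corpus; a staged or weighted scheme is a one-line change in
`_extractive_step`.

## Generative engine

*Linearization.* Depth-first: `[start:T]`, then each filled slot in
declaration order (the slot ordering operator Ω), each filler list ordered
by document position (ω; template-valued fillers by the position of their
earliest textual descendant, ties by insertion order), each filler wrapped
in its slot's start/end specials; textual fillers emit their document
tokens verbatim. Both orders are arbitrary-but-fixed choices needed only to
make training targets deterministic; decoding accepts any slot order the
grammar allows. Parsed free text that does not occur verbatim in the
document is kept and flagged as hallucinated rather than rejected;
evaluation counts it as an ordinary (wrong) filler.

*Grammar and decoding.* The four rule schemas instantiate one head rule and
one terminator per template, plus one rule per slot; a template with s
slots contributes 2 + s rules. Derivability is decided by an equivalent
stack machine that yields the exact allowed-next-token set at every prefix
(verified against brute-force rule expansion in the tests). Decoding is
greedy: disallowed vocabulary entries are masked to −∞ and the argmax
allowed token emitted; `[start:X]` pushes, the matching `[end:X]` pops;
generation ends when the root frame is popped. Beam search is deliberately
out of scope. The default length budget is 4× the input length; hitting it
auto-closes the open frames in stack order (a template slot still awaiting
its child first receives an empty child) so the output always parses, and
the result is flagged truncated. The textual-slot mask uses the set of
token types occurring in the input document; the backbone's native
end-of-sequence token is never in any allowed set.

## Desk-scale backends

No large pretrained encoders are bundled; the backends are small numpy
models (hand-written backprop, Adam, lr(epoch) = lr₀·λᵉ with batch size
one) that make every algorithm trainable and testable on one CPU. They are
honest implementations of the two contracts, not stand-ins for the
large-model results on real abstracts.

*Encoder (extractive), d = 32.* Per token: trainable 8-d embeddings of the
token and its two neighbours plus fixed sinusoidal sentence-position
features, through one ReLU layer. The sentence-position channel is what
lets the compatibility model learn "same sentence ⇒ same instance", which
is the generator's proximity structure; lexical identity drives the
boundary taggers.

*Seq2seq (generative), d = 32.* The encoder is the same token+context
feature map. The decoder is single-step feedforward: its state is a
function of (i) the previous output token, (ii) the current grammar-stack
frame (the start special of the innermost open template/slot — computable
from the prefix, so teacher forcing parallelizes over time), (iii) an
attention context over encoder states with query-gated deterministic
copy-pointer biases, and (iv) a direct lookahead window of the encoder
states at the six positions after the copy pointer. The copy pointer tracks
the document position of the last emitted document token (advancing on
contiguous copies, else jumping to the next occurrence at or after the
pointer — generation order is monotone in document position under ω/Ω).
Output scores are a full-vocabulary affine softmax; there is no pointer
head. The lookahead window is what makes the two genuinely contextual
decisions learnable at this scale: "does another instance follow?" (emit a
slot start vs. the template's end special) and "which of this document's
candidate fillers comes next". Without it, softmax attention at d = 32
reliably sticks in content-matched but position-wrong local minima.

Training is teacher forcing with token-level cross-entropy on the
linearized gold forests; the output layer starts at zero, so the initial
loss is exactly log |V|. All special tokens are atomic vocabulary entries;
they can never be split because the model vocabulary *is* the tokenization.
A deterministic mock encoder (seeded hash embeddings) supports tests that
need an encoder but no training.

## Synthetic corpus

The generator emulates the structural properties the algorithms depend on:
multi-sentence abstracts with every gold filler verbatim at its recorded
span; one Publication/ClinicalTrial/Population per document; two arms, each
with one intervention and medication; one to two outcomes per arm (so 2–4
Outcome instances per document), endpoints on roughly 70 % of outcomes (at
least one per document), one to two between-group difference records, one
evidence-quality record. Optional slots (NumberAffected, ObservedResult,
AggregationMethod, MeasurementDevice, second Country/Precondition) appear
with probability 0.8/0.3–0.4. Fillers come from per-slot pools that are
token-disjoint across slots and sampled without replacement per document,
and scaffold words never collide with pool tokens — so every filler string
occurs exactly once per document, string-match evaluation is unambiguous
and leftmost span re-matching after parsing is exact. Each instance's
fillers share one sentence; different instances occupy different sentences.

What this does *not* emulate: the linguistic variability of PubMed
abstracts (paraphrase, coreference, discontinuous mentions), subword
tokenization, annotation noise, shared or ambiguous filler strings, and
document lengths beyond a few hundred tokens. Passing the desk-scale
recovery experiments therefore demonstrates that the pipelines, losses and
decoding are correct and learnable — not that these tiny backends would
reach any particular accuracy on real trial reports.

Two oracles support the tests: a gold-indicator compatibility (q = 1 iff
two fillers share a gold instance) under which threshold clustering at
τ = 0.5 must recover gold cardinalities exactly, and a teacher logit
provider that scores the gold continuation highest at every gold prefix,
under which constrained decoding must reproduce the gold linearization
token for token.

## Study sizes and numerical choices

The recovery experiments train on 200 synthetic documents and score 50
held-out ones, with d = 32 backends, 20 epochs (extractive) / 30 epochs
(generative), lr₀ = 10⁻², λ = 0.97, and a single run seed feeding every
random choice; these sizes keep the whole suite and the acceptance script
in the minutes range on one CPU while leaving wide margins on the recovery
thresholds. Softmax computations subtract the row maximum; cross-entropy
adds 1e-12 inside the log; compatibility symmetry is exact by construction,
so tests assert equality, not closeness. Degenerate inputs fail loudly:
empty documents, empty clusters and empty corpora raise, and an empty
allowed-token set during decoding is an assertion (the grammar guarantees
it cannot occur).

## Known limitations

- The extractive engine cannot represent overlapping fillers that share a
  start or end token of the same slot, and the tagging round-trip is
  guaranteed only for non-crossing spans within a sentence.
- Strict (instance-aligned) evaluation uses greedy alignment by filler
  overlap, which is not globally optimal for pathological overlap patterns.
- Large pretrained backbones (Longformer/Flan-T5-class) are out of scope
  here; the contracts (`EncoderBackend`, `LogitProvider`) are the
  integration points for them.
- Absolute F1 values depend on the matching criterion; reports carry the
  criterion id, and scores under different criteria are not comparable.
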