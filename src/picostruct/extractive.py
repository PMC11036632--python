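"""Extractive pipeline: boundary heads, learned compatibility, clustering.

Slot fillers are extracted by per-token start/end classification over the
slot inventory (plus a no-slot label), joined into spans, and embedded as

    e = relu(W_r (h_s + h_e) + b_r)

from the encoder states of their start and end tokens.  A learned symmetric
compatibility q(e_i, e_j) in (0, 1) — two linear layers with a ReLU between
them and a sigmoid on top, applied to e_i + e_j — scores whether two fillers
belong to the same template instance.  Fillers routed to one template type
are then partitioned either by exhaustive maximization of the clustering
score h (mean over clusters of the mean pairwise compatibility g) for a given
cluster count, or by threshold HAC (average linkage over q), which also
infers the cluster count and hence the template cardinality.

The cluster-score pair set: the mean-pairwise definition literally ranges
over the full Cartesian product C x C, but the published worked example
leaves the diagonal undefined, so the default here averages over unordered
off-diagonal pairs and scores singleton clusters 1.0; ``include_self_pairs``
restores the literal reading (requiring q(e, e) to be evaluated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .corpus import TokenizedDocument
from .schema import (
    InstanceForest,
    SchemaConfig,
    TemplateInstance,
    TextSpan,
)
from .tagging import NO_SLOT, BoundaryTags, tags_to_spans

__all__ = [
    "BoundaryHeads",
    "FillerRepr",
    "CompatibilityModel",
    "Clustering",
    "ClusterThreshold",
    "predict_boundaries",
    "filler_representation",
    "compatibility",
    "cluster_score",
    "clustering_score",
    "partitions_with_k_blocks",
    "best_clustering_exhaustive",
    "fit_threshold",
    "hac_cluster",
    "route_fillers",
    "assemble_instances",
    "extract",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Parametric pieces
# ---------------------------------------------------------------------------

@dataclass
class BoundaryHeads:
    """Affine start/end classifiers over the slot inventory.

    ``labels`` lists the |S| output classes; index 0 is the no-slot label,
    which also serves as the deterministic argmax tie-break (lowest index
    wins under ``np.argmax``).
    """

    W_s: np.ndarray  # (|S|, d)
    b_s: np.ndarray  # (|S|,)
    W_e: np.ndarray
    b_e: np.ndarray
    labels: list[Optional[str]]  # labels[0] is NO_SLOT (None)

    @classmethod
    def init(cls, schema: SchemaConfig, d: int, rng: np.random.Generator,
             scale: float = 0.1) -> "BoundaryHeads":
        labels: list[Optional[str]] = [NO_SLOT] + schema.textual_slot_names
        k = len(labels)
        return cls(
            W_s=scale * rng.standard_normal((k, d)),
            b_s=np.zeros(k),
            W_e=scale * rng.standard_normal((k, d)),
            b_e=np.zeros(k),
            labels=labels,
        )


@dataclass(frozen=True)
class FillerRepr:
    e: np.ndarray  # (d,), entrywise >= 0
    slot: str
    span: TextSpan


@dataclass
class CompatibilityModel:
    W_h: np.ndarray  # (d, d)
    b_h: np.ndarray  # (d,)
    w_s: np.ndarray  # (d,)
    b_scalar: float

    @classmethod
    def init(cls, d: int, rng: np.random.Generator, scale: float = 0.1):
        return cls(
            W_h=scale * rng.standard_normal((d, d)),
            b_h=np.zeros(d),
            w_s=scale * rng.standard_normal(d),
            b_scalar=0.0,
        )


@dataclass
class Clustering:
    template: str
    clusters: list[list[FillerRepr]]
    cluster_scores: list[float] = field(default_factory=list)
    score: float = 0.0  # h


@dataclass(frozen=True)
class ClusterThreshold:
    tau: float
    same_mean: float
    diff_mean: float


# ---------------------------------------------------------------------------
# Forward operations
# ---------------------------------------------------------------------------

def predict_boundaries(H: np.ndarray, heads: BoundaryHeads) -> BoundaryTags:
    """Per-token argmax of the start and end softmax distributions.

    ``H`` is the (n, d) encoder output.
    """
    if H.shape[1] != heads.W_s.shape[1]:
        raise ValueError(
            f"encoder dim {H.shape[1]} != head dim {heads.W_s.shape[1]}"
        )
    p_start = softmax(H @ heads.W_s.T + heads.b_s)
    p_end = softmax(H @ heads.W_e.T + heads.b_e)
    start = [heads.labels[i] for i in p_start.argmax(axis=1)]
    end = [heads.labels[i] for i in p_end.argmax(axis=1)]
    return BoundaryTags(start, end)


def filler_representation(
    h_s: np.ndarray, h_e: np.ndarray, W_r: np.ndarray, b_r: np.ndarray,
    slot: str = "", span: Optional[TextSpan] = None,
) -> FillerRepr:
    """e = relu(W_r (h_s + h_e) + b_r); symmetric in its two token vectors."""
    if h_s.shape != h_e.shape or W_r.shape[1] != h_s.shape[0]:
        raise ValueError("dimension mismatch in filler representation")
    e = relu(W_r @ (h_s + h_e) + b_r)
    return FillerRepr(e=e, slot=slot, span=span)


def compatibility(e_i: np.ndarray, e_j: np.ndarray, model: CompatibilityModel) -> float:
    """q(e_i, e_j) = sigmoid(w_s . relu(W_h (e_i + e_j) + b_h) + b).

    Exactly symmetric: the two inputs enter only through their sum.
    """
    if e_i.shape != e_j.shape or model.W_h.shape[1] != e_i.shape[0]:
        raise ValueError("dimension mismatch in compatibility")
    hidden = relu(model.W_h @ (e_i + e_j) + model.b_h)
    return float(sigmoid(model.w_s @ hidden + model.b_scalar))


QFunc = Callable[[FillerRepr, FillerRepr], float]


def model_q(model: CompatibilityModel) -> QFunc:
    return lambda a, b: compatibility(a.e, b.e, model)


def cluster_score(
    cluster: Sequence[FillerRepr], q: QFunc, include_self_pairs: bool = False
) -> float:
    """Mean pairwise compatibility g(C) of a cluster.

    Default pair set: unordered off-diagonal pairs; singletons score 1.0.
    With ``include_self_pairs`` the literal Cartesian product C x C is used.
    """
    if not cluster:
        raise ValueError("empty cluster")
    n = len(cluster)
    if include_self_pairs:
        total = sum(q(a, b) for a in cluster for b in cluster)
        return total / (n * n)
    if n == 1:
        return 1.0
    total = sum(
        q(cluster[i], cluster[j]) for i in range(n) for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2)


def clustering_score(
    clusters: Sequence[Sequence[FillerRepr]], q: QFunc,
    include_self_pairs: bool = False,
) -> float:
    """h: arithmetic mean of the cluster scores."""
    if not clusters:
        raise ValueError("empty clustering")
    return sum(
        cluster_score(c, q, include_self_pairs) for c in clusters
    ) / len(clusters)


# ---------------------------------------------------------------------------
# Partition search
# ---------------------------------------------------------------------------

def partitions_with_k_blocks(n: int, k: int) -> Iterator[list[list[int]]]:
    """All set partitions of range(n) into exactly k blocks, in restricted-
    growth-string order (canonical: blocks sorted by their smallest member)."""
    if not (1 <= k <= n):
        return
    rgs = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            if max_label + 1 == k:
                blocks: list[list[int]] = [[] for _ in range(k)]
                for idx, lab in enumerate(rgs):
                    blocks[lab].append(idx)
                yield [list(b) for b in blocks]
            return
        # pruning: remaining positions must be able to reach k labels
        for lab in range(min(max_label + 1, k - 1) + 1):
            if (max(max_label, lab) + 1) + (n - i - 1) < k:
                continue
            rgs[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n else iter(())


def best_clustering_exhaustive(
    fillers: Sequence[FillerRepr],
    m: int,
    q: QFunc,
    include_self_pairs: bool = False,
    max_n: int = 10,
) -> Clustering:
    """h-maximal partition of the fillers into exactly m blocks, found by
    enumerating all set partitions with m blocks.

    Ties break toward the partition that enumerates first in canonical
    restricted-growth order (lexicographically smallest by sorted member
    indices).  ``max_n`` bounds the enumeration (Bell-number growth).
    """
    n = len(fillers)
    if n > max_n:
        raise ValueError(f"{n} fillers exceed enumeration bound {max_n}")
    if not (1 <= m <= n):
        raise ValueError(f"cluster count {m} out of range [1, {n}]")
    best_blocks = None
    best_h = -np.inf
    for blocks in partitions_with_k_blocks(n, m):
        h = clustering_score(
            [[fillers[i] for i in b] for b in blocks], q, include_self_pairs
        )
        if h > best_h:
            best_h, best_blocks = h, blocks
    clusters = [[fillers[i] for i in b] for b in best_blocks]
    return Clustering(
        template="",
        clusters=clusters,
        cluster_scores=[cluster_score(c, q, include_self_pairs) for c in clusters],
        score=float(best_h),
    )


def fit_threshold(
    pairs: Sequence[tuple[FillerRepr, FillerRepr, bool]], q: QFunc
) -> ClusterThreshold:
    """Clustering threshold from labelled training pairs.

    ``pairs`` holds (filler, filler, same_instance) triples.  tau is the
    midpoint of the mean compatibility of same-instance pairs and the mean
    of different-instance pairs.
    """
    same = [q(a, b) for a, b, lab in pairs if lab]
    diff = [q(a, b) for a, b, lab in pairs if not lab]
    if not same or not diff:
        raise ValueError("need at least one pair of each class")
    same_mean = float(np.mean(same))
    diff_mean = float(np.mean(diff))
    return ClusterThreshold(
        tau=(same_mean + diff_mean) / 2.0, same_mean=same_mean, diff_mean=diff_mean
    )


def hac_cluster(
    fillers: Sequence[FillerRepr], q: QFunc, tau: float, template: str = ""
) -> Clustering:
    """Average-linkage agglomerative clustering on compatibility.

    Clusters merge while the best inter-cluster mean compatibility is >= tau
    (equivalently: UPGMA on the dissimilarity 1 - q, cut at cophenetic
    distance 1 - tau).  The cluster count — the inferred template
    cardinality — falls out of the threshold.
    """
    if not fillers:
        raise ValueError("no fillers to cluster")
    n = len(fillers)
    if n == 1:
        labels = np.array([1])
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = 1.0 - q(fillers[i], fillers[j])
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=1.0 - tau, criterion="distance")
    clusters: dict[int, list[FillerRepr]] = {}
    order: dict[int, int] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(fillers[idx])
        order.setdefault(lab, idx)
    ordered = [clusters[lab] for lab in sorted(clusters, key=order.get)]
    return Clustering(
        template=template,
        clusters=ordered,
        cluster_scores=[cluster_score(c, q) for c in ordered],
        score=clustering_score(ordered, q) if ordered else 0.0,
    )


# ---------------------------------------------------------------------------
# Instance assembly
# ---------------------------------------------------------------------------

def route_fillers(
    fillers: Sequence[FillerRepr], schema: SchemaConfig
) -> dict[str, list[FillerRepr]]:
    """Group fillers by the template type owning their predicted slot label."""
    routed: dict[str, list[FillerRepr]] = {}
    for f in fillers:
        try:
            owner = schema.slot(f.slot).owner
        except KeyError:
            raise ValueError(f"slot label {f.slot!r} not in schema") from None
        routed.setdefault(owner, []).append(f)
    return routed


def _containment_chain(schema: SchemaConfig, template: str) -> Optional[list[tuple[str, str]]]:
    """Unique chain of (parent template, slot) links from root to ``template``,
    or None when the containment path is ambiguous."""
    if template == schema.root:
        return []
    parents = schema.parents_of(template)
    if len(parents) != 1:
        return None
    slot = parents[0]
    above = _containment_chain(schema, slot.owner)
    if above is None:
        return None
    return above + [(slot.owner, slot.name)]


def assemble_instances(
    doc: TokenizedDocument,
    clusterings: dict[str, Clustering],
    schema: SchemaConfig,
) -> InstanceForest:
    """Build a validated forest out of per-template filler clusterings.

    One instance per cluster; fixed-cardinality templates contribute a single
    pooled instance.  Instances are then attached under the root through the
    schema's unique containment chain (synthesizing intermediate instances as
    needed); templates with an ambiguous containment path stay unattached and
    are reported via the returned forest's ``unattached`` attribute.
    """
    counter = [0]

    def make(template: str) -> TemplateInstance:
        counter[0] += 1
        return TemplateInstance(
            instance_id=f"{doc.doc_id}#{template}{counter[0]}", type=template
        )

    instances: list[TemplateInstance] = []
    by_template: dict[str, list[TemplateInstance]] = {}
    for template, clustering in clusterings.items():
        tspec = schema.template(template)
        groups = clustering.clusters
        if tspec.fixed_cardinality is not None:
            pooled = [f for c in groups for f in c]
            groups = [pooled] if pooled else []
        for cluster in groups:
            inst = make(template)
            for f in sorted(cluster, key=lambda f: (f.span.token_start, f.span.token_end)):
                inst.add(f.slot, f.span)
            instances.append(inst)
            by_template.setdefault(template, []).append(inst)

    # root chain: synthesize missing ancestors so the forest validates
    def ensure(template: str) -> TemplateInstance:
        if by_template.get(template):
            return by_template[template][0]
        inst = make(template)
        instances.insert(0, inst)
        by_template.setdefault(template, []).insert(0, inst)
        return inst

    root = ensure(schema.root)
    unattached: list[TemplateInstance] = []
    for template in list(by_template):
        if template == schema.root:
            continue
        chain = _containment_chain(schema, template)
        if chain is None:
            unattached.extend(by_template[template])
            continue
        parent_template, slot_name = chain[-1]
        for inst in by_template[template]:
            parent = ensure(parent_template)
            if inst not in parent.fillers(slot_name):
                parent.add(slot_name, inst)
    # fixpoint: synthesized ancestors must themselves end up attached
    changed = True
    while changed:
        changed = False
        attached_ids = set()
        stack = [root]
        while stack:
            node = stack.pop()
            if id(node) in attached_ids:
                continue
            attached_ids.add(id(node))
            stack.extend(node.children())
        for template, insts in by_template.items():
            if template == schema.root:
                continue
            chain = _containment_chain(schema, template)
            if chain is None:
                continue
            parent_template, slot_name = chain[-1]
            for inst in insts:
                if id(inst) not in attached_ids:
                    parent = ensure(parent_template)
                    if inst not in parent.fillers(slot_name):
                        parent.add(slot_name, inst)
                        changed = True

    forest = InstanceForest(
        doc_id=doc.doc_id,
        instances=[i for i in instances if i not in unattached],
        root=root.instance_id,
    )
    forest.unattached = unattached  # type: ignore[attr-defined]
    return forest


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def extract(
    doc: TokenizedDocument,
    encoder,
    heads: BoundaryHeads,
    W_r: np.ndarray,
    b_r: np.ndarray,
    compat: CompatibilityModel,
    tau: float,
    schema: SchemaConfig,
) -> InstanceForest:
    """Boundary prediction -> span joining -> filler embedding -> routing ->
    threshold HAC -> instance assembly."""
    H = encoder.encode(doc)
    tags = predict_boundaries(H, heads)
    spans = tags_to_spans(doc, tags)
    fillers = [
        filler_representation(
            H[s.token_start], H[s.token_end], W_r, b_r, slot=slot, span=s
        )
        for slot, s in spans
    ]
    routed = route_fillers(fillers, schema)
    q = model_q(compat)
    clusterings = {
        template: hac_cluster(fl, q, tau, template=template)
        for template, fl in routed.items()
        if fl
    }
    return assemble_instances(doc, clusterings, schema)
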