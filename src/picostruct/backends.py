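"""Desk-scale model backends and training loops for both engines.

Two contracts are implemented here:

* **Encoder backends** map a tokenized document to one d-dimensional vector
  per token (``encode``).  :class:`MockEncoder` is a deterministic test
  double (seeded hash embeddings); :class:`TinyEncoder` is a trainable
  token+context feature encoder (embedding of the token and its two
  neighbours plus fixed sentence-position sinusoids, one ReLU layer,
  d = 32 by default).
* **Seq2seq logit providers** score the next output token given the input
  document and the generated prefix.  :class:`TinySeq2Seq` is a trainable
  single-layer attention decoder conditioned on the previous token, the
  current grammar-stack frame and a deterministic copy pointer; its output
  layer is a full-vocabulary softmax.

Both models train with Adam under the exponential learning-rate schedule
lr(epoch) = lr0 * lambda^epoch, batch size one document, all randomness
derived from a single run seed.  These backends exist to make every
algorithm in the package exercisable and testable on a single CPU; they are
not a substitute for large pretrained encoders on real abstracts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._nn import Adam, cross_entropy_rows, sinusoid_table, softmax_rows
from .corpus import TokenizedDocument
from .extractive import (
    BoundaryHeads,
    CompatibilityModel,
    FillerRepr,
    fit_threshold,
    model_q,
)
from .grammar import (
    Grammar,
    GrammarCursor,
    build_grammar,
    linearize,
    start_token,
)
from .schema import InstanceForest, SchemaConfig, TextSpan
from .tagging import NO_SLOT, spans_to_tags

__all__ = [
    "TrainingConfig",
    "MockEncoder",
    "TinyEncoder",
    "ExtractiveCheckpoint",
    "train_extractive",
    "TinySeq2Seq",
    "train_generative",
    "build_vocabulary",
]

UNK = "<unk>"
BOS = "<s>"


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings.  ``lam`` is the per-epoch exponential decay of the
    learning rate: lr(epoch) = learning_rate * lam**epoch."""

    learning_rate: float = 1e-2
    lam: float = 0.97
    epochs: int = 30
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("lam must be in (0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    def lr_at(self, epoch: int) -> float:
        return self.learning_rate * self.lam ** epoch


def build_vocabulary(
    docs: Sequence[TokenizedDocument], extra: Sequence[str] = ()
) -> dict[str, int]:
    """Word-type vocabulary: <unk>=0, <s>=1, then sorted corpus types and
    extra (special) tokens.  Special tokens are atomic entries; they can
    never be split because the vocabulary is the tokenization."""
    types = sorted({t for d in docs for t in d.surfaces()} | set(extra))
    vocab = {UNK: 0, BOS: 1}
    for t in types:
        if t not in vocab:
            vocab[t] = len(vocab)
    return vocab


def _ids(vocab: dict[str, int], tokens: Sequence[str]) -> np.ndarray:
    return np.array([vocab.get(t, 0) for t in tokens], dtype=np.int64)


# ---------------------------------------------------------------------------
# Mock encoder
# ---------------------------------------------------------------------------

class MockEncoder:
    """Deterministic pseudo-embeddings from a seeded hash of the token
    surface (and optionally its position)."""

    def __init__(self, dim: int = 32, seed: int = 0, use_position: bool = False):
        self.output_dim = dim
        self.seed = seed
        self.use_position = use_position

    def _vector(self, key: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.seed}\x1f{key}".encode(), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        return rng.standard_normal(self.output_dim)

    def encode(self, doc: TokenizedDocument) -> np.ndarray:
        rows = []
        for i, tok in enumerate(doc.tokens):
            key = f"{tok.surface}\x1f{i}" if self.use_position else tok.surface
            rows.append(self._vector(key))
        return np.stack(rows)


# ---------------------------------------------------------------------------
# Trainable encoder + extractive training
# ---------------------------------------------------------------------------

_SENT_DIM = 8


class TinyEncoder:
    """Trainable context encoder: h_i = relu(W1 [E(w_{i-1}); E(w_i);
    E(w_{i+1}); sent_pos(i)] + b1).

    The sentence-position sinusoids give the downstream compatibility model a
    within-document proximity signal; token embeddings carry lexical
    identity.  Out-of-vocabulary and out-of-range neighbours map to <unk>.
    """

    def __init__(self, vocab: dict[str, int], dim: int = 32, emb_dim: int = 8,
                 seed: int = 0):
        self.vocab = vocab
        self.output_dim = dim
        self.emb_dim = emb_dim
        rng = np.random.default_rng(seed)
        feat = 3 * emb_dim + _SENT_DIM
        self.params = {
            "E": 0.5 * rng.standard_normal((len(vocab), emb_dim)),
            "W1": (1.0 / np.sqrt(feat)) * rng.standard_normal((feat, dim)),
            "b1": np.zeros(dim),
        }
        self._sent = sinusoid_table(256, _SENT_DIM)

    def _features(self, doc: TokenizedDocument):
        ids = _ids(self.vocab, doc.surfaces())
        prev = np.concatenate([[1], ids[:-1]])  # BOS at left edge
        nxt = np.concatenate([ids[1:], [1]])
        sent = np.array([doc.sentence_of(i) for i in range(doc.n_tokens)])
        sent = np.clip(sent, 0, len(self._sent) - 1)
        E = self.params["E"]
        F = np.concatenate([E[prev], E[ids], E[nxt], self._sent[sent]], axis=1)
        return F, (ids, prev, nxt)

    def forward(self, doc: TokenizedDocument):
        F, idx = self._features(doc)
        Hpre = F @ self.params["W1"] + self.params["b1"]
        return np.maximum(Hpre, 0.0), (F, Hpre, idx)

    def encode(self, doc: TokenizedDocument) -> np.ndarray:
        H, _ = self.forward(doc)
        return H

    def backward(self, cache, dH, grads) -> None:
        F, Hpre, (ids, prev, nxt) = cache
        dHpre = dH * (Hpre > 0)
        grads["W1"] += F.T @ dHpre
        grads["b1"] += dHpre.sum(axis=0)
        dF = dHpre @ self.params["W1"].T
        e = self.emb_dim
        np.add.at(grads["E"], prev, dF[:, :e])
        np.add.at(grads["E"], ids, dF[:, e: 2 * e])
        np.add.at(grads["E"], nxt, dF[:, 2 * e: 3 * e])


@dataclass
class ExtractiveCheckpoint:
    """Everything the extractive pipeline needs at inference time."""

    encoder: TinyEncoder
    heads: BoundaryHeads
    W_r: np.ndarray
    b_r: np.ndarray
    compat: CompatibilityModel
    tau: float
    schema: SchemaConfig
    history: list[float] = field(default_factory=list)  # per-epoch mean loss

    def extract(self, doc: TokenizedDocument) -> InstanceForest:
        from .extractive import extract

        return extract(
            doc, self.encoder, self.heads, self.W_r, self.b_r, self.compat,
            self.tau, self.schema,
        )

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            **{f"enc_{k}": v for k, v in self.encoder.params.items()},
            "W_s": self.heads.W_s, "b_s": self.heads.b_s,
            "W_e": self.heads.W_e, "b_e": self.heads.b_e,
            "W_r": self.W_r, "b_r": self.b_r,
            "C_Wh": self.compat.W_h, "C_bh": self.compat.b_h,
            "C_ws": self.compat.w_s,
            "C_b": np.array([self.compat.b_scalar]),
            "tau": np.array([self.tau]),
        }


def _gold_fillers(forest: InstanceForest) -> list[tuple[str, TextSpan, str]]:
    """(slot, span, owning instance id) for every gold textual filler."""
    out = []
    for inst in forest.instances:
        for slot, f in inst.textual_fillers():
            if isinstance(f, TextSpan):
                out.append((slot, f, inst.instance_id))
    out.sort(key=lambda x: (x[1].token_start, x[1].token_end, x[0]))
    return out


def _pair_sample(
    fillers: list[tuple[str, TextSpan, str]],
    schema: SchemaConfig,
    rng: np.random.Generator,
    neg_ratio: float = 3.0,
) -> list[tuple[int, int, float]]:
    """Same-template filler index pairs, positives = same gold instance;
    negatives subsampled to ``neg_ratio`` x positives for class balance."""
    by_template: dict[str, list[int]] = {}
    for k, (slot, _, _) in enumerate(fillers):
        by_template.setdefault(schema.slot(slot).owner, []).append(k)
    pos, neg = [], []
    for idxs in by_template.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                i, j = idxs[a], idxs[b]
                same = fillers[i][2] == fillers[j][2]
                (pos if same else neg).append((i, j, 1.0 if same else 0.0))
    if len(neg) > neg_ratio * max(len(pos), 1):
        keep = rng.choice(
            len(neg), size=int(neg_ratio * max(len(pos), 1)), replace=False
        )
        neg = [neg[k] for k in sorted(keep)]
    return pos + neg


def train_extractive(
    corpus: Sequence[tuple[TokenizedDocument, InstanceForest]],
    schema: SchemaConfig,
    config: TrainingConfig = TrainingConfig(),
    dim: int = 32,
) -> ExtractiveCheckpoint:
    """Joint training of boundary heads, filler representation and
    compatibility on gold forests (cross entropy for the two taggers, binary
    cross entropy on same-instance pairs, unweighted sum).

    Returns a checkpoint with the clustering threshold fitted on the
    training pairs.  Deterministic given the config seed.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(config.seed)
    vocab = build_vocabulary([doc for doc, _ in corpus])
    encoder = TinyEncoder(vocab, dim=dim, seed=config.seed)
    heads = BoundaryHeads.init(schema, dim, rng)
    K = len(heads.labels)
    label_index = {lab: k for k, lab in enumerate(heads.labels)}
    Wr = (1.0 / np.sqrt(dim)) * rng.standard_normal((dim, dim))
    br = np.zeros(dim)
    compat = CompatibilityModel.init(dim, rng)

    params = {
        **encoder.params,
        "W_s": heads.W_s, "b_s": heads.b_s, "W_e": heads.W_e, "b_e": heads.b_e,
        "W_r": Wr, "b_r": br,
        "C_Wh": compat.W_h, "C_bh": compat.b_h, "C_ws": compat.w_s,
        "C_b": np.array([compat.b_scalar]),
    }
    opt = Adam(params, lr=config.learning_rate)

    # precompute supervision
    prepared = []
    for doc, forest in corpus:
        gold = _gold_fillers(forest)
        tags = spans_to_tags(doc, [(s, sp) for s, sp, _ in gold])
        st = np.array([label_index[l] for l in tags.start_labels])
        en = np.array([label_index[l] for l in tags.end_labels])
        pairs = _pair_sample(gold, schema, rng)
        prepared.append((doc, gold, st, en, pairs))

    history: list[float] = []
    order = np.arange(len(prepared))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        lr = config.lr_at(epoch)
        total = 0.0
        for di in order:
            doc, gold, st, en, pairs = prepared[di]
            loss = _extractive_step(
                encoder, params, K, doc, gold, st, en, pairs, opt, lr
            )
            total += loss
        history.append(total / len(prepared))

    compat2 = CompatibilityModel(
        W_h=params["C_Wh"], b_h=params["C_bh"], w_s=params["C_ws"],
        b_scalar=float(params["C_b"][0]),
    )
    heads2 = BoundaryHeads(
        W_s=params["W_s"], b_s=params["b_s"], W_e=params["W_e"],
        b_e=params["b_e"], labels=heads.labels,
    )
    checkpoint = ExtractiveCheckpoint(
        encoder=encoder, heads=heads2, W_r=params["W_r"], b_r=params["b_r"],
        compat=compat2, tau=0.5, schema=schema, history=history,
    )
    checkpoint.tau = _fit_tau(checkpoint, corpus)
    return checkpoint


def _extractive_step(encoder, params, K, doc, gold, st, en, pairs, opt, lr):
    H, cache = encoder.forward(doc)
    n = doc.n_tokens
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    Ls = H @ params["W_s"].T + params["b_s"]
    Le = H @ params["W_e"].T + params["b_e"]
    loss_s, dLs = cross_entropy_rows(Ls, st)
    loss_e, dLe = cross_entropy_rows(Le, en)
    grads["W_s"] += dLs.T @ H
    grads["b_s"] += dLs.sum(axis=0)
    grads["W_e"] += dLe.T @ H
    grads["b_e"] += dLe.sum(axis=0)
    dH = dLs @ params["W_s"] + dLe @ params["W_e"]

    loss_p = 0.0
    if gold and pairs:
        s_idx = np.array([sp.token_start for _, sp, _ in gold])
        e_idx = np.array([sp.token_end for _, sp, _ in gold])
        hsum = H[s_idx] + H[e_idx]
        epre = hsum @ params["W_r"].T + params["b_r"]
        reps = np.maximum(epre, 0.0)

        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        yy = np.array([p[2] for p in pairs])
        x = reps[ii] + reps[jj]
        hpre2 = x @ params["C_Wh"].T + params["C_bh"]
        hh = np.maximum(hpre2, 0.0)
        logit = hh @ params["C_ws"] + params["C_b"][0]
        qv = 1.0 / (1.0 + np.exp(-logit))
        eps = 1e-12
        loss_p = float(
            -(yy * np.log(qv + eps) + (1 - yy) * np.log(1 - qv + eps)).mean()
        )
        dlogit = (qv - yy) / len(pairs)
        grads["C_ws"] += hh.T @ dlogit
        grads["C_b"] += np.array([dlogit.sum()])
        dhh = np.outer(dlogit, params["C_ws"])
        dhpre2 = dhh * (hpre2 > 0)
        grads["C_Wh"] += dhpre2.T @ x
        grads["C_bh"] += dhpre2.sum(axis=0)
        dx = dhpre2 @ params["C_Wh"]
        dreps = np.zeros_like(reps)
        np.add.at(dreps, ii, dx)
        np.add.at(dreps, jj, dx)
        depre = dreps * (epre > 0)
        grads["W_r"] += depre.T @ hsum
        grads["b_r"] += depre.sum(axis=0)
        dhsum = depre @ params["W_r"]
        np.add.at(dH, s_idx, dhsum)
        np.add.at(dH, e_idx, dhsum)

    encoder.backward(cache, dH, grads)
    opt.step(grads, lr=lr)
    return loss_s + loss_e + loss_p


def _fit_tau(ckpt: ExtractiveCheckpoint, corpus) -> float:
    """Threshold from the training-set mean compatibility of same- and
    different-instance gold pairs (midpoint rule)."""
    q = model_q(ckpt.compat)
    pairs = []
    for doc, forest in corpus:
        H = ckpt.encoder.encode(doc)
        gold = _gold_fillers(forest)
        reps = []
        for slot, sp, inst_id in gold:
            e = np.maximum(
                ckpt.W_r @ (H[sp.token_start] + H[sp.token_end]) + ckpt.b_r, 0.0
            )
            reps.append((FillerRepr(e=e, slot=slot, span=sp), inst_id,
                         ckpt.schema.slot(slot).owner))
        for a in range(len(reps)):
            for b in range(a + 1, len(reps)):
                if reps[a][2] != reps[b][2]:
                    continue
                pairs.append(
                    (reps[a][0], reps[b][0], reps[a][1] == reps[b][1])
                )
    try:
        return fit_threshold(pairs, q).tau
    except ValueError:
        return 0.5


# ---------------------------------------------------------------------------
# Tiny seq2seq + generative training
# ---------------------------------------------------------------------------

_N_OFFSET = 8  # exact relative offsets j - ptr - 1 in [0, 8)
_N_DIST = _N_OFFSET + 2  # + wide forward bump + behind-pointer indicator
_N_WINDOW = 6  # lookahead window: encoder states at ptr+1 .. ptr+6


class TinySeq2Seq:
    """Single-layer attention decoder over a feedforward context encoder.

    The decoder state at step t is a function of the previous output token,
    the current grammar-stack frame (the start special of the innermost open
    template/slot) and an attention context over the encoder states; the
    attention logits carry a deterministic copy-pointer bias (features of
    j - ptr, where ptr is the document position of the last copied token).
    Output scores are a full-vocabulary affine softmax.  Stack and pointer
    are deterministic functions of the prefix, so teacher forcing
    parallelizes over time steps.
    """

    def __init__(self, vocab: dict[str, int], grammar: Grammar, dim: int = 32,
                 emb_dim: int = 16, seed: int = 0):
        self.vocab = vocab
        self.inv_vocab = {i: t for t, i in vocab.items()}
        self.grammar = grammar
        self.dim = dim
        self.emb_dim = emb_dim
        rng = np.random.default_rng(seed)
        V = len(vocab)
        e, d = emb_dim, dim
        self.params = {
            "E": 0.5 * rng.standard_normal((V, e)),
            "W1e": (1.0 / np.sqrt(3 * e)) * rng.standard_normal((3 * e, d)),
            "b1e": np.zeros(d),
            "Wq": (1.0 / np.sqrt(2 * e)) * rng.standard_normal((2 * e, d)),
            "bq": np.zeros(d),
            "Wg": np.zeros((2 * e, _N_DIST)),
            # forward-local prior: favour positions just after the copy
            # pointer, penalize already-consumed ones (generation order is
            # monotone in document position for the canonical orderings)
            "bg": np.concatenate([np.zeros(_N_OFFSET), [1.0, -2.0]]),
            "Wk": (1.0 / np.sqrt(d)) * rng.standard_normal((d, d)),
            "Wv": (1.0 / np.sqrt(d)) * rng.standard_normal((d, d)),
            "W2": (1.0 / np.sqrt(2 * e + (1 + _N_WINDOW) * d))
            * rng.standard_normal((2 * e + (1 + _N_WINDOW) * d, d)),
            "b2": np.zeros(d),
            "Wout": np.zeros((V, d)),
            "bout": np.zeros(V),
        }

    @property
    def vocabulary(self) -> list[str]:
        return [self.inv_vocab[i] for i in range(len(self.vocab))]

    # -- deterministic prefix state --------------------------------------
    def _replay(self, doc_tokens: list[str], out_tokens: Sequence[str]):
        """Stack-context token and pointer before each of the T+1 steps
        (teacher forcing uses the first T)."""
        cursor = GrammarCursor(self.grammar)
        positions: dict[str, list[int]] = {}
        for k, t in enumerate(doc_tokens):
            positions.setdefault(t, []).append(k)

        def reset_to(tok: str, after: int) -> int:
            # first occurrence after the pointer (generation is monotone in
            # document position under the canonical orderings), else leftmost
            occ = positions.get(tok)
            if not occ:
                return -1
            for k in occ:
                if k > after:
                    return k
            return occ[0]

        stack_tok, ptrs = [], []
        ptr = -1
        for tok in list(out_tokens) + [None]:
            top = cursor.stack[-1].name if cursor.stack else None
            stack_tok.append(start_token(top) if top else BOS)
            ptrs.append(ptr)
            if tok is None:
                break
            if tok.startswith("[start:") or tok.startswith("[end:"):
                cursor.advance(tok)
            else:
                cursor.advance(tok, is_doc_token=True)
                if ptr >= 0 and ptr + 1 < len(doc_tokens) \
                        and doc_tokens[ptr + 1] == tok:
                    ptr += 1
                else:
                    ptr = reset_to(tok, ptr)
        return stack_tok, ptrs

    def _dist_features(self, ptrs: np.ndarray, n: int) -> np.ndarray:
        """(T, n, 10) deterministic copy-pointer features: one-hot exact
        relative offsets j - ptr - 1 in [0, 8) (learned relative-position
        attention biases, gated per step by the query input), a wide forward
        bump and a behind-pointer indicator.  ptr = -1 (nothing copied yet)
        anchors the offsets at the document start."""
        j = np.arange(n)[None, :]
        p = np.asarray(ptrs)[:, None]
        rel = j - p - 1
        offsets = np.stack(
            [(rel == k).astype(float) for k in range(_N_OFFSET)], axis=2
        )
        wide = np.exp(-np.abs(rel) / 8.0)[:, :, None]
        behind = (rel < 0).astype(float)[:, :, None]
        return np.concatenate([offsets, wide, behind], axis=2)

    # -- forward ----------------------------------------------------------
    def _encode(self, doc_ids: np.ndarray):
        E = self.params["E"]
        prev = np.concatenate([[1], doc_ids[:-1]])
        nxt = np.concatenate([doc_ids[1:], [1]])
        feat = np.concatenate([E[prev], E[doc_ids], E[nxt]], axis=1)
        hpre = feat @ self.params["W1e"] + self.params["b1e"]
        return np.maximum(hpre, 0.0), (feat, hpre, doc_ids, prev, nxt)

    def _forward(self, doc_ids, p_ids, s_ids, D):
        P = self.params
        h, enc_cache = self._encode(doc_ids)
        qin = np.concatenate([P["E"][p_ids], P["E"][s_ids]], axis=1)
        qpre = qin @ P["Wq"] + P["bq"]
        q = np.maximum(qpre, 0.0)
        G = qin @ P["Wg"] + P["bg"]  # (T, n_dist) per-step gate weights
        K = h @ P["Wk"]
        A = q @ K.T / np.sqrt(self.dim) + np.einsum("tk,tnk->tn", G, D)
        alpha = softmax_rows(A)
        U = h @ P["Wv"]
        c = alpha @ U
        # lookahead window: encoder states at fixed offsets after the copy
        # pointer, read directly (the offset one-hots double as selectors)
        window = [D[:, :, k] @ h for k in range(_N_WINDOW)]
        zin = np.concatenate([P["E"][p_ids], P["E"][s_ids], c, *window], axis=1)
        zpre = zin @ P["W2"] + P["b2"]
        z = np.maximum(zpre, 0.0)
        logits = z @ P["Wout"].T + P["bout"]
        cache = (h, enc_cache, qin, qpre, q, K, alpha, U, zin, zpre, z,
                 p_ids, s_ids, D)
        return logits, cache

    def loss_and_grads(self, doc_ids, y_ids, p_ids, s_ids, D):
        P = self.params
        logits, cache = self._forward(doc_ids, p_ids, s_ids, D)
        loss, dlogits = cross_entropy_rows(logits, y_ids)
        (h, enc_cache, qin, qpre, q, K, alpha, U, zin, zpre, z,
         p_ids2, s_ids2, Df) = cache
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        e = self.emb_dim
        d = self.dim

        grads["Wout"] += dlogits.T @ z
        grads["bout"] += dlogits.sum(axis=0)
        dz = dlogits @ P["Wout"]
        dzpre = dz * (zpre > 0)
        grads["W2"] += zin.T @ dzpre
        grads["b2"] += dzpre.sum(axis=0)
        dzin = dzpre @ P["W2"].T
        dEp = dzin[:, :e].copy()
        dEs = dzin[:, e: 2 * e].copy()
        dc = dzin[:, 2 * e: 2 * e + d]

        dalpha = dc @ U.T
        dU = alpha.T @ dc
        grads["Wv"] += h.T @ dU
        dh = dU @ P["Wv"].T
        for k in range(_N_WINDOW):
            lo = 2 * e + (1 + k) * d
            dh += Df[:, :, k].T @ dzin[:, lo: lo + d]
        dA = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
        dq = dA @ K / np.sqrt(self.dim)
        dK = dA.T @ q / np.sqrt(self.dim)
        grads["Wk"] += h.T @ dK
        dh += dK @ P["Wk"].T
        dG = np.einsum("tn,tnk->tk", dA, Df)
        grads["Wg"] += qin.T @ dG
        grads["bg"] += dG.sum(axis=0)
        dqpre = dq * (qpre > 0)
        grads["Wq"] += qin.T @ dqpre
        grads["bq"] += dqpre.sum(axis=0)
        dqin = dqpre @ P["Wq"].T + dG @ P["Wg"].T
        dEp += dqin[:, :e]
        dEs += dqin[:, e:]

        feat, hpre, doc_ids2, prev, nxt = enc_cache
        dhpre = dh * (hpre > 0)
        grads["W1e"] += feat.T @ dhpre
        grads["b1e"] += dhpre.sum(axis=0)
        dfeat = dhpre @ P["W1e"].T
        np.add.at(grads["E"], prev, dfeat[:, :e])
        np.add.at(grads["E"], doc_ids2, dfeat[:, e: 2 * e])
        np.add.at(grads["E"], nxt, dfeat[:, 2 * e:])
        np.add.at(grads["E"], p_ids2, dEp)
        np.add.at(grads["E"], s_ids2, dEs)
        return loss, grads

    # -- LogitProvider contract ------------------------------------------
    def next_scores(
        self, doc: TokenizedDocument, prefix: Sequence[str]
    ) -> np.ndarray:
        doc_tokens = doc.surfaces()
        doc_ids = _ids(self.vocab, doc_tokens)
        stack_tok, ptrs = self._replay(doc_tokens, prefix)
        t = len(prefix)
        prev_tok = prefix[-1] if prefix else BOS
        p_ids = _ids(self.vocab, [prev_tok])
        s_ids = _ids(self.vocab, [stack_tok[t]])
        D = self._dist_features(np.array([ptrs[t]]), len(doc_tokens))
        logits, _ = self._forward(doc_ids, p_ids, s_ids, D)
        return logits[0]


def _teacher_inputs(model: TinySeq2Seq, doc: TokenizedDocument,
                    gold_tokens: list[str]):
    doc_tokens = doc.surfaces()
    doc_ids = _ids(model.vocab, doc_tokens)
    y_ids = _ids(model.vocab, gold_tokens)
    p_ids = _ids(model.vocab, [BOS] + gold_tokens[:-1])
    stack_tok, ptrs = model._replay(doc_tokens, gold_tokens)
    s_ids = _ids(model.vocab, stack_tok[:-1])
    D = model._dist_features(np.array(ptrs[:-1]), len(doc_tokens))
    return doc_ids, y_ids, p_ids, s_ids, D


def train_generative(
    corpus: Sequence[tuple[TokenizedDocument, InstanceForest]],
    schema: SchemaConfig,
    config: TrainingConfig = TrainingConfig(),
    dim: int = 32,
    grammar: Optional[Grammar] = None,
) -> TinySeq2Seq:
    """Teacher-forced training of the tiny seq2seq on gold linearizations
    (token-level cross entropy).  Returns the trained logit provider."""
    if not corpus:
        raise ValueError("empty training corpus")
    if grammar is None:
        grammar = build_grammar(schema)
    specials = set(grammar.special_tokens)
    vocab = build_vocabulary([doc for doc, _ in corpus], extra=sorted(specials))
    model = TinySeq2Seq(vocab, grammar, dim=dim, seed=config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    prepared = []
    for doc, forest in corpus:
        gold_tokens = linearize(forest, schema)
        missing = [t for t in gold_tokens if t in specials and t not in vocab]
        if missing:
            raise ValueError(f"special tokens unregistered: {missing}")
        prepared.append(_teacher_inputs(model, doc, gold_tokens))

    model.history = []  # type: ignore[attr-defined]
    order = np.arange(len(prepared))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        lr = config.lr_at(epoch)
        total = 0.0
        for di in order:
            doc_ids, y_ids, p_ids, s_ids, D = prepared[di]
            loss, grads = model.loss_and_grads(doc_ids, y_ids, p_ids, s_ids, D)
            opt.step(grads, lr=lr)
            total += loss
        model.history.append(total / len(prepared))
    return model
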