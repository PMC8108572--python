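"""Per-phase topic modeling with latent Dirichlet allocation.

Within each detected phase the tweet texts form one corpus.  A vocabulary is
built from tokens occurring at least ``min_count`` times (default 20), an
LDA model is fitted for each candidate topic count K on a grid (default 2
to 50) with a fixed number of training passes (default 100), and the K
minimizing corpus perplexity is selected.  Perplexity here is the exponential
of the negative mean per-token log-likelihood under the fitted point
estimates,

    PP = exp( - (1/N) * sum_{d,w} n_dw * log( theta_d . beta_{.,w} ) ),

where ``theta_d`` is document d's topic mixture and ``beta`` the topic-word
matrix; a uniform model over V words therefore has perplexity exactly V.

Fitting is batch variational inference (scikit-learn backend) with a
symmetric document-topic prior alpha = 1/K and topic-word prior 0.01 unless
overridden; everything is reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

__all__ = [
    "PhaseCorpus",
    "Vocabulary",
    "LdaTopicModel",
    "build_vocabulary",
    "fit_lda",
    "compute_perplexity",
    "select_topic_count",
    "select_from_curve",
    "assign_topics",
]


@dataclass(frozen=True)
class PhaseCorpus:
    """Tokenized documents of one phase, with back-references to record ids."""

    phase_id: int
    docs: tuple[tuple[str, ...], ...]
    record_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        docs = tuple(tuple(d) for d in self.docs)
        ids = tuple(self.record_ids)
        if len(docs) != len(ids):
            raise ValueError("docs and record_ids must have equal length")
        object.__setattr__(self, "docs", docs)
        object.__setattr__(self, "record_ids", ids)

    def __len__(self) -> int:
        return len(self.docs)


@dataclass(frozen=True)
class Vocabulary:
    """Dense token -> id map over tokens meeting the frequency floor."""

    token_to_id: dict[str, int]
    counts: dict[str, int]
    min_count: int = 20

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def id_to_token(self) -> list[str]:
        out = [""] * len(self.token_to_id)
        for tok, i in self.token_to_id.items():
            out[i] = tok
        return out


@dataclass(frozen=True)
class LdaTopicModel:
    """Fitted LDA point estimates for one phase.

    ``topic_word`` is K x V with rows summing to 1; ``doc_topic`` is D' x K
    (one row per fitted document, rows summing to 1).  ``doc_ids`` names the
    fitted documents; documents emptied by vocabulary filtering are absent
    here and carry a null topic downstream.
    """

    K: int
    topic_word: np.ndarray
    doc_topic: np.ndarray
    doc_ids: tuple[str, ...]
    epochs: int = 100
    seed: int = 0
    alpha: float = field(default=0.0)
    beta: float = 0.01

    def __post_init__(self) -> None:
        tw = np.asarray(self.topic_word, dtype=float)
        dt = np.asarray(self.doc_topic, dtype=float)
        if tw.shape[0] != self.K or dt.shape[1] != self.K:
            raise ValueError("matrix shapes inconsistent with K")
        if not np.allclose(tw.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("topic_word rows must sum to 1")
        if len(dt) and not np.allclose(dt.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("doc_topic rows must sum to 1")
        object.__setattr__(self, "topic_word", tw)
        object.__setattr__(self, "doc_topic", dt)
        object.__setattr__(self, "doc_ids", tuple(self.doc_ids))


def build_vocabulary(corpus: PhaseCorpus, min_count: int = 20) -> Vocabulary:
    """Vocabulary over tokens occurring at least ``min_count`` times.

    The bound is inclusive (a token at exactly ``min_count`` is kept) and
    ids are dense, assigned in first-occurrence order.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    order: list[str] = []
    for doc in corpus.docs:
        for tok in doc:
            if tok not in counts:
                counts[tok] = 0
                order.append(tok)
            counts[tok] += 1
    kept = [tok for tok in order if counts[tok] >= min_count]
    if not kept:
        raise ValueError(
            f"no token reaches min_count={min_count}; "
            "lower min_count or supply more documents"
        )
    return Vocabulary(
        token_to_id={tok: i for i, tok in enumerate(kept)},
        counts={tok: counts[tok] for tok in kept},
        min_count=min_count,
    )


def doc_term_matrix(
    corpus: PhaseCorpus, vocab: Vocabulary
) -> tuple[sparse.csr_matrix, list[int]]:
    """Sparse counts for documents that are non-empty under ``vocab``.

    Returns the matrix and the indices (into the corpus) of the retained
    documents.
    """
    rows, cols, data = [], [], []
    kept: list[int] = []
    for d, doc in enumerate(corpus.docs):
        ids = [vocab.token_to_id[t] for t in doc if t in vocab.token_to_id]
        if not ids:
            continue
        r = len(kept)
        kept.append(d)
        seen: dict[int, int] = {}
        for i in ids:
            seen[i] = seen.get(i, 0) + 1
        for i, c in seen.items():
            rows.append(r)
            cols.append(i)
            data.append(c)
    X = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(kept), len(vocab)), dtype=np.float64
    )
    return X, kept


def fit_lda(
    corpus: PhaseCorpus,
    vocab: Vocabulary,
    K: int,
    epochs: int = 100,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
    restarts: int = 3,
) -> LdaTopicModel:
    """Fit one LDA model by batch variational inference.

    ``epochs`` is the number of full passes over the corpus.  ``alpha``
    defaults to the symmetric 1/K document-topic prior.  Variational
    inference is sensitive to initialization, so the fit is restarted
    ``restarts`` times from seeds derived deterministically from ``seed``
    and the run with the lowest training perplexity is kept; identical
    inputs and seed reproduce identical distributions.
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    X, kept = doc_term_matrix(corpus, vocab)
    if not 2 <= K <= max(X.shape[0], 2):
        raise ValueError(
            f"K={K} outside valid range [2, {X.shape[0]}] for this corpus"
        )
    if alpha is None:
        alpha = 1.0 / K
    restart_seeds = [seed] + list(
        np.random.default_rng(seed).integers(2**31 - 1, size=restarts - 1)
    )
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for rs in restart_seeds:
        lda = LatentDirichletAllocation(
            n_components=K,
            doc_topic_prior=alpha,
            topic_word_prior=beta,
            learning_method="batch",
            max_iter=epochs,
            random_state=int(rs),
        )
        dt = lda.fit_transform(X)
        tw = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
        dt = dt / dt.sum(axis=1, keepdims=True)
        pp = _matrix_perplexity(X, dt, tw)
        if best is None or pp < best[0]:
            best = (pp, tw, dt)
    _, topic_word, doc_topic = best
    return LdaTopicModel(
        K=K,
        topic_word=topic_word,
        doc_topic=doc_topic,
        doc_ids=tuple(corpus.record_ids[d] for d in kept),
        epochs=epochs,
        seed=seed,
        alpha=alpha,
        beta=beta,
    )


def _matrix_perplexity(
    X: sparse.csr_matrix, doc_topic: np.ndarray, topic_word: np.ndarray
) -> float:
    """Perplexity of count matrix X under point-estimate mixtures."""
    coo = X.tocoo()
    p = np.einsum(
        "ik,ik->i", doc_topic[coo.row], topic_word[:, coo.col].T
    )
    ll = float(coo.data @ np.log(np.maximum(p, 1e-300)))
    n = float(coo.data.sum())
    if n == 0:
        raise ValueError("empty count matrix")
    return float(np.exp(-ll / n))


def compute_perplexity(
    model: LdaTopicModel, corpus: PhaseCorpus, vocab: Vocabulary
) -> float:
    """Corpus perplexity under the model's point estimates.

    exp of the negative total token log-likelihood divided by the token
    count, where each token's likelihood is the document's topic mixture
    dotted with the topic-word column.  Out-of-vocabulary tokens are ignored
    (they were never modeled).
    """
    id_of = {rid: r for r, rid in enumerate(model.doc_ids)}
    X, kept = doc_term_matrix(corpus, vocab)
    rows = [
        r for r, d in enumerate(kept) if corpus.record_ids[d] in id_of
    ]
    if not rows:
        raise ValueError("corpus has no in-vocabulary tokens")
    theta = np.vstack(
        [model.doc_topic[id_of[corpus.record_ids[kept[r]]]] for r in rows]
    )
    return _matrix_perplexity(X[rows], theta, model.topic_word)


def select_topic_count(
    corpus: PhaseCorpus,
    vocab: Vocabulary,
    k_min: int = 2,
    k_max: int = 50,
    k_step: int = 1,
    epochs: int = 100,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
    restarts: int = 3,
) -> tuple[int, dict[int, float], dict[int, LdaTopicModel]]:
    """Sweep the topic-count grid and pick the perplexity minimum.

    Returns the selected K (ties broken toward smaller K), the full
    perplexity curve for audit, and the fitted model per K.
    """
    if k_min < 2:
        raise ValueError("k_min must be at least 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    X, kept = doc_term_matrix(corpus, vocab)
    if X.shape[0] < k_min:
        raise ValueError(
            f"only {X.shape[0]} non-empty documents; need at least k_min={k_min}"
        )
    curve: dict[int, float] = {}
    models: dict[int, LdaTopicModel] = {}
    for K in range(k_min, min(k_max, X.shape[0]) + 1, k_step):
        model = fit_lda(corpus, vocab, K, epochs=epochs, seed=seed,
                        alpha=alpha, beta=beta, restarts=restarts)
        curve[K] = compute_perplexity(model, corpus, vocab)
        models[K] = model
    return select_from_curve(curve), curve, models


def select_from_curve(curve: Mapping[int, float]) -> int:
    """Perplexity-minimizing K; ties break toward the smaller K."""
    if not curve:
        raise ValueError("empty perplexity curve")
    return min(curve, key=lambda k: (curve[k], k))


def assign_topics(
    model: LdaTopicModel, corpus: PhaseCorpus
) -> dict[str, int | None]:
    """Dominant topic per record id (argmax of the topic mixture).

    Ties break toward the lowest topic id; documents emptied by vocabulary
    filtering get ``None``.
    """
    assigned: dict[str, int | None] = {rid: None for rid in corpus.record_ids}
    for rid, theta in zip(model.doc_ids, model.doc_topic):
        assigned[rid] = int(np.argmax(theta))  # argmax takes first max: low id
    return assigned


def align_topics(
    estimated: np.ndarray, truth: np.ndarray
) -> tuple[list[int], np.ndarray]:
    """Greedy cosine matching of estimated topic-word rows to true rows.

    Returns, for each true topic, the index of the matched estimated topic,
    and the cosine similarity of each matched pair.  Used to score parameter
    recovery on synthetic corpora, where topic labels are arbitrary.
    """
    est = estimated / np.linalg.norm(estimated, axis=1, keepdims=True)
    tru = truth / np.linalg.norm(truth, axis=1, keepdims=True)
    sim = tru @ est.T
    mapping = [-1] * len(tru)
    cosines = np.zeros(len(tru))
    used: set[int] = set()
    # repeatedly take the globally best remaining (true, est) pair
    pairs = sorted(
        ((sim[i, j], i, j) for i in range(sim.shape[0]) for j in range(sim.shape[1])),
        reverse=True,
    )
    matched: set[int] = set()
    for s, i, j in pairs:
        if i in matched or j in used:
            continue
        mapping[i] = j
        cosines[i] = s
        matched.add(i)
        used.add(j)
        if len(matched) == len(tru):
            break
    return mapping, cosines
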