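"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Implements the full loop: tokenization with stopword filtering and
collocation (bigram) merging, the collapsed Gibbs sampler with exact count
bookkeeping, held-out perplexity via fold-in, UMass coherence, and
topic-count selection combining both.

The sampling conditional for token i in document d is

    p(z_i = k | rest)  ∝  (n_dk + α) · (n_kw + β) / (n_k + V·β)

with the current token excluded from all counts. The inner sweep is JIT
compiled with numba when available; the uniform variates driving each sweep
are drawn outside the kernel, so results are bit-identical either way.
"""

from __future__ import annotations

import json
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_TOKEN_RE = re.compile(r"[a-z][a-z0-9_']*")

DEFAULT_STOPWORDS = frozenset(
    """a about above after again all am an and any are as at be because been
    before being below between both but by can could did do does doing down
    during each few for from further had has have having he her here hers him
    his how i if in into is it its just me more most my no nor not now of off
    on once only or other our out over own same she so some such than that the
    their them then there these they this those through to too under until up
    very was we were what when where which while who whom why will with would
    you your yours""".split()
)


class CorpusError(ValueError):
    pass


@dataclass
class TokenizedCorpus:
    documents: list  # list of np.ndarray of token ids
    vocabulary: list  # id -> token
    merged_bigrams: dict = field(default_factory=dict)  # "a_b" -> ("a", "b")
    doc_ids: Optional[list] = None  # original indices of kept documents

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.documents))


def from_token_lists(token_docs: Sequence[Sequence]) -> TokenizedCorpus:
    """Build a corpus from pre-tokenized documents (e.g. generator output)."""
    vocab: dict = {}
    documents = []
    doc_ids = []
    for i, doc in enumerate(token_docs):
        ids = [vocab.setdefault(str(t), len(vocab)) for t in doc]
        if ids:
            documents.append(np.asarray(ids, dtype=np.int64))
            doc_ids.append(i)
    if not documents:
        raise CorpusError("all documents empty")
    vocabulary = [None] * len(vocab)
    for token, idx in vocab.items():
        vocabulary[idx] = token
    return TokenizedCorpus(documents=documents, vocabulary=vocabulary, doc_ids=doc_ids)


def preprocess_for_lda(
    texts: Sequence[str],
    stopwords=DEFAULT_STOPWORDS,
    min_token_len: int = 3,
    bigram_min_count: int = 20,
    bigram_threshold: float = 0.3,
) -> TokenizedCorpus:
    """Lowercase, tokenize, filter, and merge frequent collocations.

    Adjacent pairs with count >= ``bigram_min_count`` and normalized
    pointwise mutual information >= ``bigram_threshold`` are merged into a
    single ``a_b`` token (greedy left-to-right, one pass). Documents left
    empty after filtering are dropped with a warning.
    """
    token_docs = []
    for text in texts:
        tokens = [
            t
            for t in _TOKEN_RE.findall(text.lower())
            if len(t) >= min_token_len and t not in stopwords
        ]
        token_docs.append(tokens)

    unigram: Counter = Counter()
    pair: Counter = Counter()
    for tokens in token_docs:
        unigram.update(tokens)
        pair.update(zip(tokens, tokens[1:]))
    total = sum(unigram.values())
    merges: dict = {}
    if total:
        for (a, b), c in pair.items():
            if c < bigram_min_count:
                continue
            p_ab = c / total
            p_a = unigram[a] / total
            p_b = unigram[b] / total
            npmi = math.log(p_ab / (p_a * p_b)) / (-math.log(p_ab))
            if npmi >= bigram_threshold:
                merges[(a, b)] = f"{a}_{b}"

    merged_docs = []
    for tokens in token_docs:
        out = []
        i = 0
        while i < len(tokens):
            if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) in merges:
                out.append(merges[(tokens[i], tokens[i + 1])])
                i += 2
            else:
                out.append(tokens[i])
                i += 1
        merged_docs.append(out)

    n_dropped = sum(1 for d in merged_docs if not d)
    if n_dropped:
        logger.warning("%d documents empty after preprocessing; dropped", n_dropped)
    corpus = from_token_lists(merged_docs)
    corpus.merged_bigrams = {v: k for k, v in merges.items()}
    return corpus


@dataclass
class TopicModelState:
    K: int
    alpha: float
    beta: float
    n_dk: np.ndarray  # D x K
    n_kw: np.ndarray  # K x V
    n_k: np.ndarray  # K
    z: np.ndarray  # flat per-token assignments
    tokens: np.ndarray  # flat token ids
    doc_of: np.ndarray  # flat doc index per token
    doc_lengths: np.ndarray
    seed: int
    iterations_run: int = 0
    log_likelihood: list = field(default_factory=list)

    @property
    def n_words(self) -> int:
        return self.n_kw.shape[1]

    def check_invariants(self) -> None:
        if (self.n_dk < 0).any() or (self.n_kw < 0).any() or (self.n_k < 0).any():
            raise AssertionError("negative count")
        if not np.array_equal(self.n_dk.sum(axis=1), self.doc_lengths):
            raise AssertionError("doc-topic counts do not sum to doc lengths")
        if not np.array_equal(self.n_kw.sum(axis=1), self.n_k):
            raise AssertionError("topic-word counts do not sum to topic totals")
        if not np.array_equal(self.n_dk.sum(axis=0), self.n_k):
            raise AssertionError("doc-topic totals disagree with topic totals")

    def phi_hat(self) -> np.ndarray:
        V = self.n_words
        return (self.n_kw + self.beta) / (self.n_k[:, None] + V * self.beta)

    def theta_hat(self) -> np.ndarray:
        return (self.n_dk + self.alpha) / (
            self.doc_lengths[:, None] + self.K * self.alpha
        )

    def save(self, path) -> None:
        payload = {
            "K": self.K,
            "alpha": self.alpha,
            "beta": self.beta,
            "seed": self.seed,
            "iterations_run": self.iterations_run,
            "log_likelihood": self.log_likelihood,
            "n_kw": self.n_kw.tolist(),
            "n_dk": self.n_dk.tolist(),
            "z": self.z.tolist(),
            "tokens": self.tokens.tolist(),
            "doc_of": self.doc_of.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TopicModelState":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        n_dk = np.asarray(payload["n_dk"], dtype=np.int64)
        n_kw = np.asarray(payload["n_kw"], dtype=np.int64)
        return cls(
            K=payload["K"],
            alpha=payload["alpha"],
            beta=payload["beta"],
            n_dk=n_dk,
            n_kw=n_kw,
            n_k=n_kw.sum(axis=1),
            z=np.asarray(payload["z"], dtype=np.int64),
            tokens=np.asarray(payload["tokens"], dtype=np.int64),
            doc_of=np.asarray(payload["doc_of"], dtype=np.int64),
            doc_lengths=n_dk.sum(axis=1),
            seed=payload["seed"],
            iterations_run=payload["iterations_run"],
            log_likelihood=payload["log_likelihood"],
        )


@njit(cache=False)
def _gibbs_sweep(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta, u):
    K = n_kw.shape[0]
    V = n_kw.shape[1]
    vbeta = V * beta
    p = np.empty(K)
    for i in range(tokens.shape[0]):
        w = tokens[i]
        d = doc_of[i]
        k_old = z[i]
        n_dk[d, k_old] -= 1
        n_kw[k_old, w] -= 1
        n_k[k_old] -= 1
        total = 0.0
        for k in range(K):
            total += (n_dk[d, k] + alpha) * (n_kw[k, w] + beta) / (n_k[k] + vbeta)
            p[k] = total
        target = u[i] * total
        k_new = 0
        while k_new < K - 1 and p[k_new] <= target:
            k_new += 1
        z[i] = k_new
        n_dk[d, k_new] += 1
        n_kw[k_new, w] += 1
        n_k[k_new] += 1


@njit(cache=False)
def _foldin_sweep(tokens, doc_of, z, n_dk, phi, alpha, u):
    K = phi.shape[0]
    p = np.empty(K)
    for i in range(tokens.shape[0]):
        w = tokens[i]
        d = doc_of[i]
        k_old = z[i]
        n_dk[d, k_old] -= 1
        total = 0.0
        for k in range(K):
            total += (n_dk[d, k] + alpha) * phi[k, w]
            p[k] = total
        target = u[i] * total
        k_new = 0
        while k_new < K - 1 and p[k_new] <= target:
            k_new += 1
        z[i] = k_new
        n_dk[d, k_new] += 1


def _flatten(corpus: TokenizedCorpus):
    tokens = np.concatenate(corpus.documents) if corpus.documents else np.empty(0, np.int64)
    doc_of = np.concatenate(
        [np.full(len(doc), d, dtype=np.int64) for d, doc in enumerate(corpus.documents)]
    ) if corpus.documents else np.empty(0, np.int64)
    return tokens.astype(np.int64), doc_of


def _corpus_log_likelihood(state: TopicModelState) -> float:
    theta = state.theta_hat()
    phi = state.phi_hat()
    p = np.einsum("ik,ki->i", theta[state.doc_of], phi[:, state.tokens])
    return float(np.log(p).sum())


def fit_lda_gibbs(
    corpus: TokenizedCorpus,
    K: int,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    n_iters: int = 500,
    seed: int = 0,
    check_every: int = 0,
) -> TopicModelState:
    """Run the collapsed Gibbs sampler; deterministic given the seed.

    ``alpha`` defaults to 50/K. Per-sweep corpus log-likelihood (under the
    point estimates of theta and phi) is tracked in ``state.log_likelihood``.
    ``check_every`` > 0 re-verifies the count invariants every that many
    sweeps (always verified at the end).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    tokens, doc_of = _flatten(corpus)
    N = tokens.shape[0]
    if K > N:
        raise ValueError(f"K={K} exceeds total token count {N}")
    D = corpus.n_docs
    V = corpus.n_words
    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=N).astype(np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_kw, (z, tokens), 1)
    n_k = n_kw.sum(axis=1)
    state = TopicModelState(
        K=K,
        alpha=float(alpha),
        beta=float(beta),
        n_dk=n_dk,
        n_kw=n_kw,
        n_k=n_k,
        z=z,
        tokens=tokens,
        doc_of=doc_of,
        doc_lengths=n_dk.sum(axis=1),
        seed=seed,
    )
    for sweep in range(n_iters):
        u = rng.random(N)
        _gibbs_sweep(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta, u)
        state.iterations_run += 1
        state.log_likelihood.append(_corpus_log_likelihood(state))
        if check_every and (sweep + 1) % check_every == 0:
            state.check_invariants()
    state.check_invariants()
    return state


def perplexity(
    state: TopicModelState,
    heldout: TokenizedCorpus,
    n_foldin: int = 100,
    seed: Optional[int] = None,
) -> float:
    """Held-out perplexity exp(-mean log p(w)) with fold-in theta.

    Document-topic proportions for held-out documents are estimated by Gibbs
    sampling with the trained topic-word distributions frozen; out-of-
    vocabulary tokens are dropped and counted.
    """
    V = state.n_words
    docs = []
    n_oov = 0
    for doc in heldout.documents:
        kept = doc[doc < V]
        n_oov += len(doc) - len(kept)
        if len(kept):
            docs.append(kept)
    if n_oov:
        logger.info("dropped %d out-of-vocabulary held-out tokens", n_oov)
    if not docs:
        raise ValueError("empty held-out corpus")
    tokens = np.concatenate(docs).astype(np.int64)
    doc_of = np.concatenate(
        [np.full(len(doc), d, dtype=np.int64) for d, doc in enumerate(docs)]
    )
    N = tokens.shape[0]
    K = state.K
    phi = state.phi_hat()
    rng = np.random.default_rng(state.seed + 1 if seed is None else seed)
    z = rng.integers(0, K, size=N).astype(np.int64)
    n_dk = np.zeros((len(docs), K), dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    for _ in range(n_foldin):
        u = rng.random(N)
        _foldin_sweep(tokens, doc_of, z, n_dk, phi, state.alpha, u)
    lengths = n_dk.sum(axis=1)
    theta = (n_dk + state.alpha) / (lengths[:, None] + K * state.alpha)
    p = np.einsum("ik,ki->i", theta[doc_of], phi[:, tokens])
    return float(np.exp(-np.log(p).mean()))


def top_words(state: TopicModelState, topn: int = 20) -> list:
    """Per topic, the topn (token id, probability) pairs by phi-hat."""
    phi = state.phi_hat()
    out = []
    for k in range(state.K):
        order = np.argsort(-phi[k], kind="stable")[:topn]
        out.append([(int(w), float(phi[k, w])) for w in order])
    return out


def coherence_umass(
    state: TopicModelState, corpus: TokenizedCorpus, topn: int = 20
) -> np.ndarray:
    """UMass coherence per topic over document co-occurrence counts.

    C(k) = sum over ordered top-word pairs (i earlier than j) of
    log((D(w_i, w_j) + 1) / D(w_j)); pairs whose conditioning word never
    occurs are skipped and logged.
    """
    if topn > state.n_words:
        raise ValueError("topn exceeds vocabulary size")
    doc_sets = [set(np.unique(doc).tolist()) for doc in corpus.documents]
    df: Counter = Counter()
    for s in doc_sets:
        df.update(s)
    scores = np.zeros(state.K)
    n_skipped = 0
    for k, words in enumerate(top_words(state, topn)):
        ids = [w for w, _ in words]
        total = 0.0
        for i in range(1, len(ids)):
            for j in range(i):
                wi, wj = ids[i], ids[j]
                d_j = df.get(wj, 0)
                if d_j == 0:
                    n_skipped += 1
                    continue
                d_ij = sum(1 for s in doc_sets if wi in s and wj in s)
                total += math.log((d_ij + 1) / d_j)
        scores[k] = total
    if n_skipped:
        logger.info("skipped %d coherence pairs with zero document frequency", n_skipped)
    return scores


def _split_corpus(corpus: TokenizedCorpus, heldout_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    D = corpus.n_docs
    n_held = max(1, int(round(D * heldout_fraction)))
    held_idx = set(rng.choice(D, size=n_held, replace=False).tolist())
    train_docs = [corpus.documents[d] for d in range(D) if d not in held_idx]
    held_docs = [corpus.documents[d] for d in range(D) if d in held_idx]
    train = TokenizedCorpus(documents=train_docs, vocabulary=corpus.vocabulary)
    held = TokenizedCorpus(documents=held_docs, vocabulary=corpus.vocabulary)
    return train, held


def select_k(
    corpus: TokenizedCorpus,
    k_grid: Sequence[int],
    alpha: Optional[float] = None,
    beta: float = 0.01,
    n_iters: int = 200,
    seeds: Sequence[int] = (0,),
    heldout_fraction: float = 0.2,
    perplexity_tolerance: float = 0.10,
    topn: int = 20,
):
    """Grid model selection: held-out perplexity plus mean UMass coherence.

    K* is the grid value with the highest mean coherence among those whose
    mean perplexity lies within ``perplexity_tolerance`` (relative) of the
    grid minimum; the full per-(K, seed) diagnostics table is returned so
    callers can override.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    rows = []
    for K in k_grid:
        for seed in seeds:
            train, held = _split_corpus(corpus, heldout_fraction, seed)
            state = fit_lda_gibbs(
                train, K=K, alpha=alpha, beta=beta, n_iters=n_iters, seed=seed
            )
            perp = perplexity(state, held)
            coh = float(coherence_umass(state, train, topn=min(topn, train.n_words)).mean())
            rows.append({"K": K, "seed": seed, "perplexity": perp, "coherence": coh})
    mean_perp = {
        K: float(np.mean([r["perplexity"] for r in rows if r["K"] == K]))
        for K in k_grid
    }
    mean_coh = {
        K: float(np.mean([r["coherence"] for r in rows if r["K"] == K]))
        for K in k_grid
    }
    best_perp = min(mean_perp.values())
    eligible = [
        K for K in k_grid if mean_perp[K] <= best_perp * (1.0 + perplexity_tolerance)
    ]
    k_star = max(eligible, key=lambda K: (mean_coh[K], -K))
    return k_star, rows


@dataclass(frozen=True)
class TopicSummary:
    topic: int
    keywords: tuple  # (token, probability) pairs, descending


def topic_summaries(
    state: TopicModelState, corpus: TokenizedCorpus, topn: int = 20
) -> list:
    """Top-n keyword (and merged-bigram) summaries per topic."""
    summaries = []
    for k, words in enumerate(top_words(state, topn=min(topn, state.n_words))):
        keywords = tuple((corpus.vocabulary[w], p) for w, p in words)
        summaries.append(TopicSummary(topic=k, keywords=keywords))
    return summaries


def dominant_topic(state: TopicModelState, doc: int) -> int:
    """argmax of theta-hat for one document; ties go to the lowest topic id."""
    row = state.theta_hat()[doc]
    best = int(np.argmax(row))  # argmax returns the first (lowest) maximizer
    if (row == row[best]).sum() > 1:
        logger.info("dominant-topic tie in doc %d broken toward topic %d", doc, best)
    return best


def topic_shares(state: TopicModelState, doc_indices: Sequence[int]) -> np.ndarray:
    """Distribution of dominant topics over a document subset (sums to 1)."""
    doc_indices = list(doc_indices)
    if not doc_indices:
        raise ValueError("empty document subset")
    theta = state.theta_hat()
    dominant = np.argmax(theta[doc_indices], axis=1)
    counts = np.bincount(dominant, minlength=state.K)
    return counts / counts.sum()
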