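"""Dictionary-based naïve-Bayes sentiment classification.

A sentiment dictionary tabulates, for each of the nine coding categories
e_j, how often each word w_i occurs in comments carrying that label:
P(w_i | e_j) = C(w_i, e_j) / C(e_j), where C(e_j) is the total token count
of category j (Laplace-smoothed with a pseudo-count ``alpha`` so unseen
words never zero out a category).  A new comment of L tokens is scored per
category by the geometric-mean likelihood

    s_j = exp( (1/L) * sum_i log P(w_i | e_j) )

— the naïve-Bayes accumulation with a 1/L length factor that removes the
polarization long comments would otherwise suffer — and the scores are
normalized to q_j = s_j / sum_k s_k in [0, 1].  Labels are assigned by
thresholding q_j.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .categories import CATEGORIES, CATEGORY_INDEX, NA
from .types import CodedComment, Comment

Segmenter = Callable[[str], Sequence[str]]


def whitespace_segmenter(text: str) -> list[str]:
    return text.split()


def tokenize(
    text: str,
    segmenter: Segmenter = whitespace_segmenter,
    stopwords: Iterable[str] = (),
) -> list[str]:
    """Segment ``text`` into tokens and drop stopwords.

    The default segmenter splits on whitespace, which is what the synthetic
    corpora use; real Chinese text needs a word-segmentation callable (any
    ``str -> list[str]``) passed as ``segmenter``.
    """
    stop = set(stopwords)
    return [t for t in segmenter(text) if t not in stop]


@dataclass
class SentimentDictionary:
    """Per-category word counts with Laplace smoothing."""

    vocabulary: tuple[str, ...]
    counts: np.ndarray                 # shape (V, 9), C(w_i, e_j)
    alpha: float = 1.0
    stopwords: frozenset = frozenset()
    categories: tuple[str, ...] = CATEGORIES
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.vocabulary), len(self.categories)):
            raise ValueError("counts must be (vocabulary x categories)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    @property
    def totals(self) -> np.ndarray:
        """C(e_j): total token count per category."""
        return self.counts.sum(axis=0)

    def prob(self, word: str, category: str) -> float:
        """Smoothed P(word | category)."""
        j = CATEGORY_INDEX[category]
        v = len(self.vocabulary)
        c = self.counts[self._index[word], j] if word in self._index else 0.0
        denom = self.totals[j] + self.alpha * v
        if denom == 0:
            return 0.0
        return (c + self.alpha) / denom

    def log_prob_row(self, word: str) -> np.ndarray:
        """log P(word | e_j) for all categories at once."""
        v = len(self.vocabulary)
        c = self.counts[self._index[word]] if word in self._index else np.zeros(len(self.categories))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log((c + self.alpha)) - np.log(self.totals + self.alpha * v)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# alpha={self.alpha!r}\n")
            fh.write(f"# stopwords={','.join(sorted(self.stopwords))}\n")
            w = csv.writer(fh)
            w.writerow(["word", "category", "count"])
            for i, word in enumerate(self.vocabulary):
                for j, cat in enumerate(self.categories):
                    if self.counts[i, j]:
                        w.writerow([word, cat, int(self.counts[i, j])])

    @classmethod
    def load(cls, path) -> "SentimentDictionary":
        alpha, stop = 1.0, frozenset()
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("# alpha="):
                    alpha = float(line.split("=", 1)[1])
                elif line.startswith("# stopwords="):
                    raw = line.split("=", 1)[1].strip()
                    stop = frozenset(raw.split(",")) - {""} if raw else frozenset()
                elif line.strip() and not line.startswith("word,"):
                    word, cat, cnt = next(csv.reader([line]))
                    rows.append((word, cat, float(cnt)))
        vocab = tuple(sorted({r[0] for r in rows}))
        counts = np.zeros((len(vocab), len(CATEGORIES)))
        widx = {w: i for i, w in enumerate(vocab)}
        for word, cat, cnt in rows:
            counts[widx[word], CATEGORY_INDEX[cat]] = cnt
        return cls(vocabulary=vocab, counts=counts, alpha=alpha, stopwords=stop)


@dataclass
class SentimentScore:
    """Normalized per-category scores q_j for one comment."""

    q: np.ndarray                  # length 9, sums to 1
    length: int                    # informative token count L
    assigned: frozenset = frozenset()

    def top(self) -> str:
        return CATEGORIES[int(np.argmax(self.q))]

    def as_dict(self) -> dict[str, float]:
        return {c: float(v) for c, v in zip(CATEGORIES, self.q)}


def build_dictionary(
    coded: Sequence[tuple[Comment, CodedComment]] | Sequence[tuple[str, Iterable[str]]],
    alpha: float = 1.0,
    stopwords: Iterable[str] = (),
    segmenter: Segmenter = whitespace_segmenter,
) -> SentimentDictionary:
    """Count word occurrences per category over a hand-coded corpus.

    ``coded`` pairs each comment (or raw text) with its label set; a
    multi-label comment contributes its tokens to every label it carries.
    """
    stop = frozenset(stopwords)
    pair_list = []
    for item in coded:
        obj, lab = item
        text = obj.text if isinstance(obj, Comment) else str(obj)
        labels = lab.labels if isinstance(lab, CodedComment) else frozenset(lab)
        pair_list.append((text, labels))
    if not pair_list:
        raise ValueError("cannot build a dictionary from an empty corpus")
    counts: dict[str, np.ndarray] = {}
    for text, labels in pair_list:
        toks = tokenize(text, segmenter, stop)
        for tok in toks:
            row = counts.setdefault(tok, np.zeros(len(CATEGORIES)))
            for lab in labels:
                row[CATEGORY_INDEX[lab]] += 1
    vocab = tuple(sorted(counts))
    mat = np.array([counts[w] for w in vocab]) if vocab else np.zeros((0, len(CATEGORIES)))
    return SentimentDictionary(
        vocabulary=vocab, counts=mat, alpha=alpha, stopwords=stop
    )


def score_comment(
    dictionary: SentimentDictionary, tokens: Sequence[str]
) -> SentimentScore:
    """Score one tokenized comment against every category.

    Tokens carrying no information (stopwords; out-of-vocabulary words when
    alpha is 0) are ignored.  If nothing informative remains the scores are
    uniform and the comment is assigned N/A.
    """
    toks = [t for t in tokens if t not in dictionary.stopwords]
    if dictionary.alpha == 0:
        toks = [t for t in toks if t in dictionary._index]
    k = len(dictionary.categories)
    if not toks:
        return SentimentScore(q=np.full(k, 1.0 / k), length=0,
                              assigned=frozenset({NA}))
    logs = np.zeros(k)
    for t in toks:
        logs += dictionary.log_prob_row(t)
    logs /= len(toks)
    if np.all(np.isneginf(logs)):
        return SentimentScore(q=np.full(k, 1.0 / k), length=len(toks),
                              assigned=frozenset({NA}))
    # geometric-mean likelihood, normalized in a numerically safe way
    logs = logs - np.nanmax(logs[np.isfinite(logs)])
    s = np.exp(logs)
    q = s / s.sum()
    return SentimentScore(q=q, length=len(toks))


def classify(score: SentimentScore, tau: float = 0.5) -> frozenset:
    """Assign labels by thresholding the normalized scores.

    Every category with q_j >= tau is assigned; if none passes, or if all
    nine scores tie exactly (no information), the comment is N/A.  N/A
    itself is exclusive: it is dropped whenever a substantive label also
    passes.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    q = np.asarray(score.q)
    if float(q.max() - q.min()) < 1e-12:
        return frozenset({NA})
    passing = {c for c, v in zip(CATEGORIES, q) if v >= tau - 1e-12}
    if not passing:
        return frozenset({NA})
    if NA in passing and len(passing) > 1:
        passing.discard(NA)
    return frozenset(passing)


def score_and_classify(
    dictionary: SentimentDictionary,
    comment: Comment | str,
    tau: float = 0.5,
    segmenter: Segmenter = whitespace_segmenter,
) -> tuple[SentimentScore, frozenset]:
    text = comment.text if isinstance(comment, Comment) else str(comment)
    toks = tokenize(text, segmenter, dictionary.stopwords)
    score = score_comment(dictionary, toks)
    labels = score.assigned if score.assigned else classify(score, tau)
    score.assigned = labels
    return score, labels
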