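"""Homophone resolution and sentence decoding.

The dual-stream decoder outputs — a distribution over base syllables and one
over tones — are combined with a syllable-to-character dictionary into
character candidates with neural log-likelihoods; a trigram character
language model then drives a beam search over the per-position candidate
lattice. The hypothesis score is

    sum(neural log-likelihood) + lambda * sum(LM log-probability)

with sentence-boundary padding on the LM side. ``lambda`` defaults to 1.0
and is reported alongside every decode.

The LM uses recursive add-k (Lidstone) interpolation: the trigram estimate
backs off smoothly to the bigram and unigram estimates, so every conditional
distribution sums to one exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import json
import math

import numpy as np

from .core_io import CharacterDict, ValidationError

BOS = "<s>"
EOS = "</s>"


@dataclass
class NGram3LM:
    """Interpolated add-k trigram model over characters."""

    uni: Counter
    bi: Counter
    tri: Counter
    bi_ctx: Counter
    tri_ctx: Counter
    vocab: list[str]
    k: float = 0.1
    n_tokens: int = 0

    def _p_uni(self, c: str) -> float:
        v = len(self.vocab)
        return (self.uni[c] + self.k) / (self.n_tokens + self.k * v)

    def _p_bi(self, c: str, h1: str) -> float:
        return (self.bi[(h1, c)] + self.k * self._p_uni(c)) / \
            (self.bi_ctx[h1] + self.k)

    def cond_prob(self, c: str, h2: str, h1: str) -> float:
        """P(c | h2 h1); histories may include the BOS marker."""
        return (self.tri[(h2, h1, c)] + self.k * self._p_bi(c, h1)) / \
            (self.tri_ctx[(h2, h1)] + self.k)

    def cond_logprob(self, c: str, h2: str, h1: str) -> float:
        return math.log(self.cond_prob(c, h2, h1))

    def sentence_logprob(self, sentence: str) -> float:
        toks = [BOS, BOS] + list(sentence) + [EOS]
        return sum(self.cond_logprob(toks[i], toks[i - 2], toks[i - 1])
                   for i in range(2, len(toks)))

    def to_json(self, path) -> None:
        payload = {
            "k": self.k, "vocab": self.vocab, "n_tokens": self.n_tokens,
            "uni": dict(self.uni),
            "bi": [[a, b, n] for (a, b), n in self.bi.items()],
            "tri": [[a, b, c, n] for (a, b, c), n in self.tri.items()],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "NGram3LM":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        bi = Counter({(a, b): n for a, b, n in d["bi"]})
        tri = Counter({(a, b, c): n for a, b, c, n in d["tri"]})
        bi_ctx = Counter()
        for (a, _), n in bi.items():
            bi_ctx[a] += n
        tri_ctx = Counter()
        for (a, b, _), n in tri.items():
            tri_ctx[(a, b)] += n
        return cls(Counter(d["uni"]), bi, tri, bi_ctx, tri_ctx,
                   d["vocab"], d["k"], d["n_tokens"])


def train_3gram(corpus: list[str], k: float = 0.1) -> NGram3LM:
    """Count boundary-padded n-grams from a character-sentence corpus."""
    if not corpus:
        raise ValidationError("empty corpus")
    uni, bi, tri = Counter(), Counter(), Counter()
    bi_ctx, tri_ctx = Counter(), Counter()
    vocab = set()
    n_tokens = 0
    for sent in corpus:
        toks = [BOS, BOS] + list(sent) + [EOS]
        for c in sent:
            uni[c] += 1
            vocab.add(c)
        uni[EOS] += 1
        n_tokens += len(sent) + 1
        for i in range(2, len(toks)):
            tri[(toks[i - 2], toks[i - 1], toks[i])] += 1
            tri_ctx[(toks[i - 2], toks[i - 1])] += 1
            bi[(toks[i - 1], toks[i])] += 1
            bi_ctx[toks[i - 1]] += 1
    vocab = sorted(vocab) + [EOS]
    return NGram3LM(uni, bi, tri, bi_ctx, tri_ctx, vocab, k, n_tokens)


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

@dataclass
class CharCandidate:
    character: str
    log_likelihood: float           # neural log-likelihood
    base_syllable: str
    tone: int


def char_candidates(p_syll: np.ndarray, p_tone: np.ndarray,
                    chardict: CharacterDict, inventory,
                    top_k: int = 10) -> list[CharCandidate]:
    """Top-k characters by neural likelihood.

    score(char) = sum over tonal syllables mapping to it of
    p_syll(base) * p_tone(tone) * prior(char | tonal syllable), renormalized
    over the covered character mass. Ties break lexicographically.
    """
    p_syll = np.asarray(p_syll, dtype=float)
    p_tone = np.asarray(p_tone, dtype=float)
    scores: dict[str, float] = {}
    origin: dict[str, tuple[str, int]] = {}
    for (base, tone), entries in chardict.mapping.items():
        mass = p_syll[inventory.index(base)] * p_tone[tone - 1]
        if mass <= 0:
            continue
        for ch, prior in entries:
            s = mass * prior
            if s > scores.get(ch, 0.0):
                origin[ch] = (base, tone)
            scores[ch] = scores.get(ch, 0.0) + s
    if not scores:
        raise ValidationError("no character received probability mass")
    total = sum(scores.values())
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return [CharCandidate(ch, math.log(s / total), *origin[ch])
            for ch, s in ranked]


# ---------------------------------------------------------------------------
# Beam search
# ---------------------------------------------------------------------------

@dataclass
class BeamHypothesis:
    chars: tuple[str, ...]
    neural_ll: float
    lm_ll: float

    def score(self, lam: float) -> float:
        return self.neural_ll + lam * self.lm_ll


def beam_decode(candidates: list[list[CharCandidate]], lm: NGram3LM | None,
                lam: float = 1.0, beam_width: int = 10
                ) -> tuple[str, float]:
    """Beam search over per-position candidate lists.

    Returns the best complete character sequence and its joint score.
    Deterministic: ties break on the character sequence. With ``lam=0`` or
    ``lm=None`` the result is the per-position neural argmax.
    """
    if beam_width < 1:
        raise ValidationError("beam_width must be >=1")
    if any(len(c) == 0 for c in candidates):
        raise ValidationError("every position needs at least one candidate")
    use_lm = lm is not None and lam != 0.0
    beam = [BeamHypothesis((), 0.0, 0.0)]
    for pos in candidates:
        nxt = []
        for hyp in beam:
            h2 = hyp.chars[-2] if len(hyp.chars) >= 2 else BOS
            h1 = hyp.chars[-1] if len(hyp.chars) >= 1 else BOS
            for cand in pos:
                lm_ll = hyp.lm_ll + (lm.cond_logprob(cand.character, h2, h1)
                                     if use_lm else 0.0)
                nxt.append(BeamHypothesis(hyp.chars + (cand.character,),
                                          hyp.neural_ll + cand.log_likelihood,
                                          lm_ll))
        nxt.sort(key=lambda h: (-h.score(lam), h.chars))
        beam = nxt[:beam_width]
    if use_lm:
        for hyp in beam:
            h2 = hyp.chars[-2] if len(hyp.chars) >= 2 else BOS
            h1 = hyp.chars[-1] if len(hyp.chars) >= 1 else BOS
            hyp.lm_ll += lm.cond_logprob(EOS, h2, h1)
        beam.sort(key=lambda h: (-h.score(lam), h.chars))
    best = beam[0]
    return "".join(best.chars), best.score(lam)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def car(decoded: str, truth: str) -> float:
    """Character accuracy rate in percent: position-wise matches / len(truth).

    A length mismatch counts the unmatched positions as errors.
    """
    if len(truth) == 0:
        raise ValidationError("empty ground-truth sequence")
    correct = sum(1 for a, b in zip(decoded, truth) if a == b)
    return 100.0 * correct / len(truth)


def cpm(n_characters: int, elapsed_s: float) -> float:
    """Characters per minute."""
    if elapsed_s <= 0:
        raise ValidationError("elapsed time must be positive")
    return n_characters / (elapsed_s / 60.0)
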