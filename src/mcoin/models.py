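"""Probabilistic motif models and the Bayes-optimal site classifier.

A motif is modelled as a position weight matrix (PWM) ``theta1`` of
per-column nucleotide frequencies together with a background composition
``theta0`` and a prior probability ``lam`` that any given sequence window
is a motif occurrence (the two-component mixture, TCM, view of a sequence
set: every overlapping width-w window is either an occurrence or
background).  From such a model a log-odds scoring matrix and a score
threshold follow, and together they form a Bayes-optimal classifier of
windows into sites and background.

Conventions: natural logarithms for scores, likelihoods and BIC; base-2
logarithms (bits) for information content and Jensen-Shannon divergence.
Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr, xlogy

ALPHABET = "ACGT"
DEFAULT_PSEUDOCOUNT = 0.01

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_LN2 = math.log(2.0)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices into ACGT; ambiguous bases -> -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _check_distribution(v: np.ndarray, name: str, atol: float = 1e-9) -> None:
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    s = v.sum(axis=-1)
    if not np.allclose(s, 1.0, atol=max(atol, 1e-8)):
        raise ValueError(f"{name} does not sum to 1 (sums: {s})")


@dataclass(frozen=True)
class MotifModel:
    """TCM motif model: PWM ``theta1`` (w x 4), background ``theta0``, prior ``lam``."""

    theta1: np.ndarray
    theta0: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        theta1 = np.asarray(self.theta1, dtype=float)
        theta0 = np.asarray(self.theta0, dtype=float)
        if theta1.ndim != 2 or theta1.shape[1] != 4:
            raise ValueError("theta1 must be a (width, 4) matrix")
        if theta0.shape != (4,):
            raise ValueError("theta0 must be a length-4 vector")
        _check_distribution(theta1, "theta1 columns")
        _check_distribution(theta0, "theta0")
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"lam must lie in (0, 1), got {self.lam}")
        object.__setattr__(self, "theta1", theta1)
        object.__setattr__(self, "theta0", theta0)

    @property
    def width(self) -> int:
        return self.theta1.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background_counts: np.ndarray,
        lam: float,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "MotifModel":
        """Build a model from occurrence/background base counts with pseudocounts."""
        counts = np.asarray(counts, dtype=float) + pseudocount
        theta1 = counts / counts.sum(axis=1, keepdims=True)
        bg = np.asarray(background_counts, dtype=float) + pseudocount
        theta0 = bg / bg.sum()
        return cls(theta1=theta1, theta0=theta0, lam=lam)

    def consensus(self) -> str:
        return "".join(ALPHABET[k] for k in np.argmax(self.theta1, axis=1))


@dataclass(frozen=True)
class LogOddsClassifier:
    """Log-odds matrix ``lo`` and threshold ``t = ln((1-lam)/lam)``."""

    lo: np.ndarray
    threshold: float

    @property
    def width(self) -> int:
        return self.lo.shape[0]


@dataclass(frozen=True)
class Site:
    """A predicted motif occurrence (0-based start, half-open end at start+width)."""

    seq_index: int
    start: int
    strand: str
    score: float
    posterior: float


@dataclass
class SitePredictionSet:
    """Non-overlapping predicted occurrences of one model over a sequence set."""

    width: int
    sites: list[Site] = field(default_factory=list)

    @property
    def n_pred(self) -> int:
        return len(self.sites)

    def occurrences(self, sequences: list[str]) -> list[str]:
        return [sequences[s.seq_index][s.start : s.start + self.width] for s in self.sites]


def log_odds_matrix(model: MotifModel) -> LogOddsClassifier:
    """Log-odds scoring matrix LO[j,k] = ln(f_{j,k}/f_{0,k}) and t = ln((1-lam)/lam)."""
    zero_cols = np.where(~np.all(model.theta1 > 0, axis=1))[0]
    if zero_cols.size:
        raise ValueError(
            f"zero frequency in PWM column(s) {zero_cols.tolist()}; "
            "apply a pseudocount before building a classifier"
        )
    if not np.all(model.theta0 > 0):
        raise ValueError("zero frequency in background model")
    lo = np.log(model.theta1) - np.log(model.theta0)[None, :]
    t = math.log((1.0 - model.lam) / model.lam)
    return LogOddsClassifier(lo=lo, threshold=t)


def score_subsequence(clf: LogOddsClassifier, subseq: str) -> float:
    """Score one width-w window: s = sum_j LO[j, subseq[j]]."""
    idx = encode_sequence(subseq)
    if idx.shape[0] != clf.width:
        raise ValueError(f"subsequence length {idx.shape[0]} != width {clf.width}")
    if np.any(idx < 0):
        raise ValueError(f"ambiguous base in subsequence {subseq!r}")
    return float(clf.lo[np.arange(clf.width), idx].sum())


def window_scores(clf: LogOddsClassifier, encoded: np.ndarray) -> np.ndarray:
    """Scores of every window of one encoded sequence; NaN where ambiguous."""
    w = clf.width
    n = encoded.shape[0] - w + 1
    if n < 1:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        col = encoded[j : j + n]
        ok = col >= 0
        valid &= ok
        scores += clf.lo[j, np.where(ok, col, 0)]
    scores[~valid] = np.nan
    return scores


def window_posteriors(model: MotifModel, sequences: list[str]) -> list[np.ndarray]:
    """p(Z=1 | window, model) for every window of every sequence (NaN if ambiguous).

    The posterior is a sigmoid of the margin s - t, so scoring above
    threshold and posterior > 1/2 coincide.
    """
    clf = log_odds_matrix(model)
    out = []
    for seq in sequences:
        s = window_scores(clf, encode_sequence(seq))
        with np.errstate(over="ignore", invalid="ignore"):
            out.append(1.0 / (1.0 + np.exp(clf.threshold - s)))
    return out


def predict_sites(
    model: MotifModel,
    sequences: list[str],
    clf: LogOddsClassifier | None = None,
) -> SitePredictionSet:
    """All windows scoring above threshold, thinned to a non-overlapping set.

    Overlap resolution is greedy by descending score, leftmost window on
    ties, independently within each sequence.  Windows containing
    non-ACGT characters are skipped.
    """
    if clf is None:
        clf = log_odds_matrix(model)
    w = clf.width
    if all(len(seq) < w for seq in sequences):
        raise ValueError(f"no input sequence is at least {w} bp long")
    pred = SitePredictionSet(width=w)
    for i, seq in enumerate(sequences):
        if len(seq) < w:
            continue
        scores = window_scores(clf, encode_sequence(seq))
        cand = np.where(scores > clf.threshold)[0]
        if cand.size == 0:
            continue
        order = cand[np.lexsort((cand, -scores[cand]))]
        occupied = np.zeros(len(seq), dtype=bool)
        chosen = []
        for start in order:
            if not occupied[start : start + w].any():
                occupied[start : start + w] = True
                chosen.append(int(start))
        for start in sorted(chosen):
            s = float(scores[start])
            post = 1.0 / (1.0 + math.exp(min(clf.threshold - s, 700.0)))
            pred.sites.append(Site(i, start, "+", s, post))
    return pred


def log_likelihood(
    model: MotifModel, predictions: SitePredictionSet, sequences: list[str]
) -> float:
    """Mixture log-likelihood of the model given its predicted sites.

    sum_i ln[ p(x_i|theta1) lam + p(x_i|theta0) (1-lam) ] over predicted
    occurrences x_i only.
    """
    if predictions.n_pred == 0:
        raise ValueError("no predicted sites: log-likelihood undefined")
    lt1 = np.log(model.theta1)
    lt0 = np.log(model.theta0)
    w = predictions.width
    idx = np.array(
        [encode_sequence(occ) for occ in predictions.occurrences(sequences)], dtype=np.int64
    )
    if np.any(idx < 0):
        raise ValueError("ambiguous base inside a predicted site")
    logp1 = lt1[np.arange(w)[None, :], idx].sum(axis=1)
    logp0 = lt0[idx].sum(axis=1)
    ll = np.logaddexp(math.log(model.lam) + logp1, math.log1p(-model.lam) + logp0)
    return float(ll.sum())


def bic(log_likelihood_value: float, width: int, n_pred: int) -> float:
    """BIC = -2 logL + M ln(n_pred) with M = 3(w+1) free parameters."""
    if n_pred < 1:
        raise ValueError("BIC requires at least one predicted site")
    return -2.0 * log_likelihood_value + 3.0 * (width + 1) * math.log(n_pred)


def ic_per_col(model: MotifModel) -> float:
    """Mean information content per PWM column in bits, relative to theta0."""
    terms = xlogy(model.theta1, model.theta1 / model.theta0[None, :]) / _LN2
    return float(terms.sum() / model.width)


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in base-2 logs (bounded by [0, 1])."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    _check_distribution(p, "p", atol=1e-8)
    _check_distribution(q, "q", atol=1e-8)
    m = 0.5 * (p + q)
    js = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return max(float(js / _LN2), 0.0)  # guard the -1e-17 float-error case


@dataclass
class ScoredModel:
    """A motif model together with its predictions and selection statistics."""

    model: MotifModel
    predictions: SitePredictionSet
    log_likelihood: float
    bic: float
    ic_per_col: float
    converged: bool = True
    em_history: list[float] | None = None

    @property
    def width(self) -> int:
        return self.model.width

    @property
    def n_pred(self) -> int:
        return self.predictions.n_pred


def score_model(
    model: MotifModel,
    sequences: list[str],
    predictions: SitePredictionSet | None = None,
) -> ScoredModel:
    """Attach predicted sites, log-likelihood, BIC and IC/col to a model.

    By default the site set is the Bayes-optimal classifier's
    prediction; a caller that already knows the model's discovered
    occurrences (e.g. ground-truth-derived candidate models) may pass
    them instead.  A model with no sites gets BIC = +inf so that width
    selection can skip it.
    """
    if predictions is None:
        predictions = predict_sites(model, sequences)
    if predictions.n_pred == 0:
        ll = math.nan
        b = math.inf
    else:
        ll = log_likelihood(model, predictions, sequences)
        b = bic(ll, model.width, predictions.n_pred)
    return ScoredModel(
        model=model,
        predictions=predictions,
        log_likelihood=ll,
        bic=b,
        ic_per_col=ic_per_col(model),
    )
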