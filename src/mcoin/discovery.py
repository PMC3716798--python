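"""Candidate motif model fitting at a range of widths.

Two routes produce a :class:`CandidateModelSet`:

* :func:`em_fit_tcm` / :func:`run_over_widths` — expectation-maximisation
  on the two-component mixture over all overlapping width-w windows
  (a MEME-style core with data-window initialisation and multiple
  restarts).
* :func:`construct_perfect_models` — the "width determination without
  discovery" construction: candidate models built directly from the
  ground-truth occurrence alignment of a planted dataset, as if the
  discovery core had recovered the motif as well as possible at each
  candidate width.

Both complete each model into a ScoredModel (predicted sites,
log-likelihood, BIC, IC/col) via :func:`mcoin.models.score_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .models import (
    DEFAULT_PSEUDOCOUNT,
    MotifModel,
    ScoredModel,
    Site,
    SitePredictionSet,
    encode_sequence,
    log_odds_matrix,
    score_model,
    score_subsequence,
)
from .synthetic import PlantedDataset


@dataclass(frozen=True)
class EMConfig:
    """Knobs of the EM core (initialisation, restarts, stopping)."""

    max_iterations: int = 200
    tol: float = 1e-4
    n_starts: int = 5
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class CandidateModelSet:
    """One ScoredModel per candidate width over a contiguous width range."""

    models: dict[int, ScoredModel] = field(default_factory=dict)
    w_min: int = 0
    w_max: int = 0

    def __post_init__(self) -> None:
        if self.models:
            widths = sorted(self.models)
            if widths != list(range(self.w_min, self.w_max + 1)):
                raise ValueError("candidate widths must cover w_min..w_max contiguously")
            for w, sm in self.models.items():
                if sm.width != w:
                    raise ValueError(f"model keyed {w} has width {sm.width}")

    @property
    def widths(self) -> list[int]:
        return list(range(self.w_min, self.w_max + 1))

    def __getitem__(self, w: int) -> ScoredModel:
        return self.models[w]


def _window_matrix(sequences: list[str], width: int) -> np.ndarray:
    """All overlapping width-w windows as an (n_windows, width) index matrix."""
    rows = []
    for seq in sequences:
        enc = encode_sequence(seq)
        n = enc.shape[0] - width + 1
        if n < 1:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, width)
        valid = (win >= 0).all(axis=1)
        rows.append(win[valid])
    if not rows:
        raise ValueError(f"no sequence provides a width-{width} window")
    return np.concatenate(rows).astype(np.int64)


def em_fit_tcm(
    sequences: list[str], width: int, config: EMConfig = EMConfig()
) -> ScoredModel:
    """Fit the two-component mixture at one width by EM, best of several starts.

    Windows are treated as independent draws from the mixture
    ``lam * p(x|theta1) + (1-lam) * p(x|theta0)``.  theta1 is seeded from
    a random data window sharpened toward its observed letters; theta0
    from the overall base composition.  The observed-data log-likelihood
    is non-decreasing across iterations by the usual EM guarantee, and
    the iteration history is retained on the returned model.
    """
    X = _window_matrix(sequences, width)
    n_win = X.shape[0]
    counts_per_window = np.stack([(X == k).sum(axis=1) for k in range(4)], axis=1).astype(float)
    overall = counts_per_window.sum(axis=0)
    rng = np.random.default_rng(config.seed)
    lam_init = len(sequences) / (2.0 * n_win)
    pc = config.pseudocount

    best: tuple[float, MotifModel, list[float], bool] | None = None
    for _ in range(config.n_starts):
        seed_window = X[rng.integers(0, n_win)]
        theta1 = np.full((width, 4), 0.1)
        theta1[np.arange(width), seed_window] = 0.7
        theta0 = (overall + pc) / (overall + pc).sum()
        lam = lam_init
        history: list[float] = []
        converged = False
        for _it in range(config.max_iterations):
            lt1 = np.log(theta1)
            lt0 = np.log(theta0)
            logp1 = lt1[np.arange(width)[None, :], X].sum(axis=1)
            logp0 = counts_per_window @ lt0
            a = math.log(lam) + logp1
            b = math.log1p(-lam) + logp0
            ll = float(np.logaddexp(a, b).sum())
            z = 1.0 / (1.0 + np.exp(np.clip(b - a, -700, 700)))
            if history and ll - history[-1] < config.tol:
                history.append(ll)
                converged = True
                break
            history.append(ll)
            # M-step
            w_counts = np.stack(
                [np.bincount(X[:, j], weights=z, minlength=4) for j in range(width)]
            )
            theta1 = (w_counts + pc) / (w_counts + pc).sum(axis=1, keepdims=True)
            bg_counts = counts_per_window.T @ (1.0 - z)
            theta0 = (bg_counts + pc) / (bg_counts + pc).sum()
            lam = float(np.clip(z.mean(), 1.0 / (2.0 * n_win), 0.5))
        model = MotifModel(theta1=theta1, theta0=theta0, lam=lam)
        if best is None or history[-1] > best[0]:
            best = (history[-1], model, history, converged)

    _, model, history, converged = best
    scored = score_model(model, sequences)
    scored.em_history = history
    scored.converged = converged
    return scored


def run_over_widths(
    sequences: list[str],
    w_min: int,
    w_max: int,
    config: EMConfig = EMConfig(),
) -> CandidateModelSet:
    """Independent EM fits at every width in w_min..w_max."""
    if w_min < 2:
        raise ValueError("w_min must be >= 2")
    if w_max < w_min:
        raise ValueError("w_max must be >= w_min")
    if w_max >= min(len(s) for s in sequences):
        raise ValueError("w_max must be smaller than the shortest sequence")
    seeds = np.random.SeedSequence(config.seed).generate_state(w_max - w_min + 1) % (2**31)
    models = {}
    for w, s in zip(range(w_min, w_max + 1), seeds):
        cfg = EMConfig(
            max_iterations=config.max_iterations,
            tol=config.tol,
            n_starts=config.n_starts,
            pseudocount=config.pseudocount,
            seed=int(s),
        )
        models[w] = em_fit_tcm(sequences, w, cfg)
    return CandidateModelSet(models=models, w_min=w_min, w_max=w_max)


def _column_ic_profile(idx: np.ndarray) -> np.ndarray:
    """Per-column empirical IC (bits, vs uniform) of an alignment index matrix."""
    n = idx.shape[0]
    counts = np.stack([(idx == k).sum(axis=0) for k in range(4)], axis=1).astype(float)
    freqs = counts / n
    return (xlogy(freqs, 4.0 * freqs) / np.log(2.0)).sum(axis=1)


def best_subwindow(idx: np.ndarray, width: int) -> int:
    """Offset of the width-w contiguous sub-window maximising mean IC (leftmost tie)."""
    profile = _column_ic_profile(idx)
    sums = np.convolve(profile, np.ones(width), mode="valid")
    # leftmost maximum, with a tolerance so float summation order cannot
    # break ties between equal-IC windows
    return int(np.argmax(sums >= sums.max() - 1e-9))


def construct_perfect_models(
    dataset: PlantedDataset,
    w_min: int,
    w_max: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CandidateModelSet:
    """Candidate models built from the true occurrences, one per width.

    * at the true width: the empirical PWM of the planted occurrences;
    * below it: the centred width-w sub-window of the true alignment
      (columns trimmed alternately right then left).  A best-recovery
      sub-motif is offset-invariant in expectation because planted
      conservation is homogeneous across columns; selecting the
      empirically best (max-IC) sub-window instead would overfit column
      noise and systematically bias the longer/shorter information
      ratio that the width heuristic tests;
    * above it: the alignment extended into flanking sequence, adding
      columns alternately right then left (shifted inward at sequence
      boundaries).

    lam is the planted-site density among width-w windows and theta0 is
    estimated from all positions outside the width-w site footprints.

    Each candidate carries its construction sites as its discovered
    occurrence set x_pred (an ideal discovery run returns the model
    *and* its sites), so the likelihood/BIC of every width is evaluated
    on the same planted occurrences, trimmed or extended.  This keeps
    the BIC's preference for fewer parameters meaningful across widths;
    re-deriving x_pred from the threshold classifier instead would let
    site-count flicker at weak conservation dominate the BIC
    comparison.
    """
    w_true = dataset.width
    if not w_min <= w_true <= w_max:
        raise ValueError("true width must lie within [w_min, w_max]")
    seqs = dataset.sequences
    seq_len = [len(s) for s in seqs]
    true_idx = np.array([encode_sequence(o) for o in dataset.occurrences])

    models: dict[int, ScoredModel] = {}
    for w in range(w_min, w_max + 1):
        if w <= w_true:
            offset = (w_true - w) // 2  # trim right first, then left
            starts = [(i, start + offset) for i, start in dataset.true_sites]
        else:
            d = w - w_true
            left = d // 2
            starts = []
            for i, start in dataset.true_sites:
                s = start - left
                s = max(0, min(s, seq_len[i] - w))  # shift inward at boundaries
                starts.append((i, s))
        occ_idx = np.array(
            [encode_sequence(seqs[i][s : s + w]) for i, s in starts], dtype=np.int64
        )
        counts = np.stack([(occ_idx == k).sum(axis=0) for k in range(4)], axis=1)

        covered = [np.zeros(L, dtype=bool) for L in seq_len]
        for i, s in starts:
            covered[i][s : s + w] = True
        bg_counts = np.zeros(4)
        for i, seq in enumerate(seqs):
            enc = encode_sequence(seq)
            outside = enc[(~covered[i]) & (enc >= 0)]
            bg_counts += np.bincount(outside, minlength=4)

        n_windows = sum(max(L - w + 1, 0) for L in seq_len)
        lam = len(starts) / n_windows
        model = MotifModel.from_counts(counts, bg_counts, lam, pseudocount=pseudocount)
        clf = log_odds_matrix(model)
        pred = SitePredictionSet(width=w)
        for i, s in sorted(starts):
            score = score_subsequence(clf, seqs[i][s : s + w])
            post = 1.0 / (1.0 + math.exp(min(clf.threshold - score, 700.0)))
            pred.sites.append(Site(i, s, "+", score, post))
        models[w] = score_model(model, seqs, predictions=pred)
    return CandidateModelSet(models=models, w_min=w_min, w_max=w_max)
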