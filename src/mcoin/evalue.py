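"""E-value of the multiple alignment of predicted sites.

The baseline width estimator: for each candidate model, the predicted
sites are stacked into a multiple alignment; each column's
log-likelihood ratio against the background composition gets a p-value
under the multinomial null; the p-value of the *product* of column
p-values is computed by the QFAST closed form for a product of
independent uniforms; multiplying by the number of possible ways to
select that many site positions in the input gives the E-value — the
expected number of equally significant alignments under the background
null.  The estimator picks the width minimising the E-value.

All arithmetic is carried in log space; widths are compared on log E.

Column p-values are exact (enumeration over all multinomial count
vectors) for alignments of up to 30 sites and use a chi-square
approximation (3 df on 2*LLR) above that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .discovery import CandidateModelSet
from .models import (
    DEFAULT_PSEUDOCOUNT,
    ScoredModel,
    SitePredictionSet,
    encode_sequence,
    predict_sites,
)

EXACT_MAX_N = 30
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class AlignmentEvalue:
    """Per-column and aggregate significance of one predicted-site alignment."""

    column_llrs: tuple[float, ...]
    column_pvalues: tuple[float, ...]
    log_product_pvalue: float
    log_n_selections: float

    @property
    def log_evalue(self) -> float:
        return self.log_product_pvalue + self.log_n_selections


def _column_llr(counts: np.ndarray, theta0: np.ndarray, pseudocount: float) -> float:
    """LLR = sum_k c_k ln(f_hat_k / f0_k) with pseudocounted MLE frequencies."""
    n = counts.sum()
    f_hat = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return float((counts * (np.log(f_hat) - np.log(theta0))).sum())


@lru_cache(maxsize=64)
def _compositions(n: int) -> np.ndarray:
    """All count 4-vectors summing to n, as an (m, 4) array."""
    rows = [
        (a, b, c, n - a - b - c)
        for a in range(n + 1)
        for b in range(n - a + 1)
        for c in range(n - a - b + 1)
    ]
    return np.array(rows, dtype=np.int64)


def _null_llr_distribution(
    n: int, theta0: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """(llr values, probabilities) of the column LLR under Multinomial(n, theta0)."""
    comp = _compositions(n)
    log_theta0 = np.log(theta0)
    logpmf = (
        gammaln(n + 1)
        - gammaln(comp + 1).sum(axis=1)
        + (comp * log_theta0[None, :]).sum(axis=1)
    )
    f_hat = (comp + pseudocount) / (n + 4.0 * pseudocount)
    llrs = (comp * (np.log(f_hat) - log_theta0[None, :])).sum(axis=1)
    return llrs, np.exp(logpmf)


def column_llr_pvalue(
    counts: np.ndarray,
    theta0: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    _null: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """p-value of one alignment column's LLR under the multinomial background null.

    Exact tail probability Pr(LLR' >= LLR) by enumeration for n <= 30;
    chi-square(3 df) survival of 2*LLR otherwise.  Clamped to
    (1e-300, 1].
    """
    counts = np.asarray(counts, dtype=float)
    n = int(round(counts.sum()))
    if n < 1:
        raise ValueError("column p-value requires at least one site")
    theta0 = np.asarray(theta0, dtype=float)
    llr = _column_llr(counts, theta0, pseudocount)
    if n <= EXACT_MAX_N:
        if _null is None:
            _null = _null_llr_distribution(n, theta0, pseudocount)
        null_llrs, null_probs = _null
        p = float(null_probs[null_llrs >= llr - 1e-9].sum())
    else:
        p = float(chi2.sf(2.0 * max(llr, 0.0), df=3))
    return min(max(p, _P_FLOOR), 1.0)


def log_qfast_product_pvalue(pvalues: list[float] | np.ndarray) -> float:
    """ln of the p-value of a product of k independent uniform p-values.

    With rho the observed product, Pr(prod U_i <= rho) has the closed
    form rho * sum_{i=0}^{k-1} (-ln rho)^i / i!; evaluated in log space.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("empty p-value list")
    if np.any(pvalues <= 0) or np.any(pvalues > 1):
        raise ValueError("p-values must lie in (0, 1]")
    log_rho = float(np.log(pvalues).sum())
    if log_rho == 0.0:
        return 0.0
    k = pvalues.size
    x = -log_rho
    i = np.arange(k)
    log_terms = i * math.log(x) - gammaln(i + 1.0)
    return float(log_rho + logsumexp(log_terms))


def qfast_product_pvalue(pvalues: list[float] | np.ndarray) -> float:
    """Probability-scale QFAST p-value (see :func:`log_qfast_product_pvalue`)."""
    return math.exp(log_qfast_product_pvalue(pvalues))


def _log_binomial(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def alignment_evalue(
    scored: ScoredModel,
    sequences: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    predictions: SitePredictionSet | None = None,
) -> AlignmentEvalue:
    """E-value of the multiple alignment of a model's predicted sites.

    log E = ln(QFAST p-value of the column p-value product)
          + ln C(total width-w windows, n_pred).

    The alignment is built from the sites the model's Bayes-optimal
    classifier calls in the sequences (re-predicted here unless a
    prediction set is supplied): the statistic measures the significance
    of what the model finds in the data, whatever occurrence set the
    model was fitted from.
    """
    if predictions is None:
        predictions = predict_sites(scored.model, sequences)
    n_pred = predictions.n_pred
    if n_pred < 1:
        raise ValueError("alignment E-value requires at least one predicted site")
    w = scored.width
    n_windows = sum(max(len(s) - w + 1, 0) for s in sequences)
    if n_pred > n_windows:
        raise ValueError("more predicted sites than available windows")
    occ = np.array(
        [encode_sequence(o) for o in predictions.occurrences(sequences)],
        dtype=np.int64,
    )
    counts = np.stack([(occ == k).sum(axis=0) for k in range(4)], axis=1).astype(float)
    theta0 = scored.model.theta0
    null = (
        _null_llr_distribution(n_pred, theta0, pseudocount)
        if n_pred <= EXACT_MAX_N
        else None
    )
    llrs = tuple(_column_llr(counts[j], theta0, pseudocount) for j in range(w))
    pvals = tuple(
        column_llr_pvalue(counts[j], theta0, pseudocount, _null=null) for j in range(w)
    )
    return AlignmentEvalue(
        column_llrs=llrs,
        column_pvalues=pvals,
        log_product_pvalue=log_qfast_product_pvalue(pvals),
        log_n_selections=_log_binomial(n_windows, n_pred),
    )


def evalue_select(
    candidates: CandidateModelSet, sequences: list[str]
) -> tuple[int, dict[int, float]]:
    """Width of the minimum log E-value candidate (ties broken toward shorter)."""
    log_evalues: dict[int, float] = {}
    for w in candidates.widths:
        scored = candidates[w]
        predictions = predict_sites(scored.model, sequences)
        if predictions.n_pred < 1:
            continue
        log_evalues[w] = alignment_evalue(
            scored, sequences, predictions=predictions
        ).log_evalue
    if not log_evalues:
        raise ValueError("no candidate predicts any sites; E-value undefined")
    chosen = min(log_evalues, key=lambda w: (log_evalues[w], w))
    return chosen, log_evalues
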