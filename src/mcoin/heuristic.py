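"""The MCOIN width-selection heuristic.

Candidate motif models fitted at different widths that describe the same
underlying motif are redundant: a shorter model "contained" in a longer
one (its PWM matches a contiguous slice of the longer PWM, measured by
the mean root Jensen-Shannon divergence per column) can be discarded in
favour of the longer model — but only if the longer model carries
similar information per column, i.e. it has not merely absorbed
uninformative background columns.  The information test compares the
IC/col ratio of the longer to the shorter model against a best-case
threshold t_info that corresponds to extending a perfectly conserved
(2 bits/col) motif with best-case background columns of 1 bit each.
After a single pass of pairwise tests (the longest model is never
discarded), the surviving model with the lowest BIC is chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

from .discovery import CandidateModelSet
from .models import MotifModel, jensen_shannon

#: Similarity threshold minimising width RMSE on the synthetic benchmark.
DEFAULT_T_SIM = 0.32


@dataclass(frozen=True)
class MCOINConfig:
    t_sim: float = DEFAULT_T_SIM
    use_revcomp: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_sim <= 1.0:
            raise ValueError("t_sim must lie in [0, 1]")


@dataclass(frozen=True)
class PairStatistic:
    """Containment statistics for one (shorter, longer) candidate pair."""

    w_short: int
    w_long: int
    jsd_per_col: float
    offset: int
    strand: str
    ic_ratio: float
    t_info: float

    def discards(self, t_sim: float) -> bool:
        return self.jsd_per_col < t_sim and self.ic_ratio > self.t_info


@dataclass
class MCOINTrace:
    pairs: list[PairStatistic] = field(default_factory=list)
    discarded: list[int] = field(default_factory=list)
    survivors: list[int] = field(default_factory=list)
    chosen_width: int | None = None


def t_info(w1: int, w2: int) -> float:
    """Best-case IC/col ratio for extending a width-w1 motif to width w2.

    (2*w1 + (w2-w1)) / (2*w2): the added columns contribute at most
    1 bit/col against the 2 bits/col of a perfectly conserved motif.
    """
    if not 1 <= w1 < w2:
        raise ValueError(f"require w2 > w1 >= 1, got ({w1}, {w2})")
    return (2.0 * w1 + (w2 - w1)) / (2.0 * w2)


def reverse_complement_pwm(theta1: np.ndarray) -> np.ndarray:
    """PWM of the reverse-complement motif (reverse columns, swap A<->T, C<->G)."""
    return theta1[::-1, ::-1]


def _scan_offsets(short_pwm: np.ndarray, long_pwm: np.ndarray) -> tuple[float, int]:
    w, wl = short_pwm.shape[0], long_pwm.shape[0]
    best = (math.inf, -1)
    for offset in range(wl - w + 1):
        sl = long_pwm[offset : offset + w]
        m = 0.5 * (short_pwm + sl)
        js = (
            0.5 * rel_entr(short_pwm, m).sum(axis=1)
            + 0.5 * rel_entr(sl, m).sum(axis=1)
        ) / math.log(2.0)
        jsd = float(np.sqrt(np.clip(js, 0.0, None)).mean())
        if jsd < best[0]:
            best = (jsd, offset)
    return best


def containment_min_jsd(
    shorter: MotifModel | np.ndarray,
    longer: MotifModel | np.ndarray,
    use_revcomp: bool = False,
) -> tuple[float, int, str]:
    """Minimum mean root JS divergence per column over all alignment offsets.

    The shorter PWM is slid along the longer one; at each offset the mean
    over aligned columns of sqrt(JS) (base-2, so each term is in [0, 1])
    is taken, and the minimum over offsets (optionally also over the
    reverse-complemented longer PWM) is returned with its offset and
    strand.
    """
    p = shorter.theta1 if isinstance(shorter, MotifModel) else np.asarray(shorter)
    q = longer.theta1 if isinstance(longer, MotifModel) else np.asarray(longer)
    if p.shape[0] >= q.shape[0]:
        raise ValueError("shorter model must be strictly narrower than longer model")
    jsd, offset = _scan_offsets(p, q)
    strand = "+"
    if use_revcomp:
        jsd_rc, offset_rc = _scan_offsets(p, reverse_complement_pwm(q))
        if jsd_rc < jsd:
            jsd, offset, strand = jsd_rc, offset_rc, "-"
    return jsd, offset, strand


def pair_statistics(
    candidates: CandidateModelSet, use_revcomp: bool = False
) -> list[PairStatistic]:
    """Containment/information statistics for every (shorter, longer) width pair."""
    pairs = []
    for w1 in candidates.widths[:-1]:
        for w2 in candidates.widths:
            if w2 <= w1:
                continue
            jsd, offset, strand = containment_min_jsd(
                candidates[w1].model, candidates[w2].model, use_revcomp=use_revcomp
            )
            ic1 = candidates[w1].ic_per_col
            ic2 = candidates[w2].ic_per_col
            ratio = ic2 / ic1 if ic1 > 0 else math.inf
            pairs.append(
                PairStatistic(
                    w_short=w1,
                    w_long=w2,
                    jsd_per_col=jsd,
                    offset=offset,
                    strand=strand,
                    ic_ratio=ratio,
                    t_info=t_info(w1, w2),
                )
            )
    return pairs


def select_from_statistics(
    candidates: CandidateModelSet,
    pairs: list[PairStatistic],
    t_sim: float,
) -> MCOINTrace:
    """Apply the discard rule at a given t_sim and pick the min-BIC survivor."""
    discarded = set()
    for pair in pairs:
        if pair.discards(t_sim):
            discarded.add(pair.w_short)
    survivors = [w for w in candidates.widths if w not in discarded]
    # the longest model is always kept, by construction of the pair list
    trace = MCOINTrace(
        pairs=list(pairs), discarded=sorted(discarded), survivors=survivors
    )
    scorable = [w for w in survivors if math.isfinite(candidates[w].bic)]
    if not scorable:
        raise ValueError("no usable model: every surviving candidate has infinite BIC")
    trace.chosen_width = min(scorable, key=lambda w: (candidates[w].bic, w))
    return trace


def mcoin_select(
    candidates: CandidateModelSet, config: MCOINConfig = MCOINConfig()
) -> tuple[int, MCOINTrace]:
    """Run the full MCOIN heuristic and return (chosen width, decision trace)."""
    if not candidates.models:
        raise ValueError("empty candidate model set")
    if len(candidates.models) == 1:
        only = candidates.widths[0]
        if not math.isfinite(candidates[only].bic):
            raise ValueError("no usable model: the only candidate has infinite BIC")
        return only, MCOINTrace(survivors=[only], chosen_width=only)
    pairs = pair_statistics(candidates, use_revcomp=config.use_revcomp)
    trace = select_from_statistics(candidates, pairs, config.t_sim)
    return trace.chosen_width, trace
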