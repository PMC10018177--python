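"""Distribution dynamics: quantile states, (spatial) Markov chains, and the
Anderson–Goodman time-homogeneity test.

Continuous efficiency scores are discretized into k ordered quantile classes
(default k = 4: L, ML, MH, H — quartiles of the pooled distribution).  Unit
trajectories through these classes are summarized by transition count and
probability matrices; the spatial variant conditions each transition on the
quantile class of the unit's spatial lag (neighbor-weighted average) in the
origin year, asking whether neighbors' levels shape mobility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AlignmentError, SpatialWeights

log = logging.getLogger(__name__)

DEFAULT_LABELS = ("L", "ML", "MH", "H")


class DegenerateClassificationError(ValueError):
    """Quantile cut points collapsed (e.g. all scores identical)."""


class InsufficientDataError(ValueError):
    """Not enough observations to estimate the requested quantity."""


def state_labels(k: int) -> list[str]:
    if k == 4:
        return list(DEFAULT_LABELS)
    return [f"S{i + 1}" for i in range(k)]


@dataclass
class StatePanel:
    """Discrete unit x year state grid plus its provenance."""

    states: pd.DataFrame          # int codes 0..k-1 (NaN-free)
    scores: pd.DataFrame          # the continuous panel it came from
    cut_points: np.ndarray        # k-1 interior quantile cuts
    k: int

    @property
    def labels(self) -> list[str]:
        return state_labels(self.k)


def classify_states(scores: pd.DataFrame, k: int = 4,
                    pooling: str = "whole_period") -> StatePanel:
    """Quantile-discretize a units x years score panel.

    Cut points are the interior k-quantiles of the pooled scores (whole
    period by default, or per year).  Intervals are right-closed, so a score
    exactly on a cut takes the lower state.
    """
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    if k < 2:
        raise ValueError("k must be at least 2")
    if vals.size < k:
        raise InsufficientDataError(f"need at least k={k} scores, have {vals.size}")
    qs = np.arange(1, k) / k

    def _cuts(pool: np.ndarray) -> np.ndarray:
        cuts = np.quantile(pool, qs)
        if len(np.unique(cuts)) < len(cuts):
            raise DegenerateClassificationError(
                "quantile cut points collapse; scores are too concentrated"
            )
        return cuts

    if pooling == "whole_period":
        cuts = _cuts(vals.ravel())
        codes = np.searchsorted(cuts, vals, side="left")
    elif pooling == "per_year":
        cols = []
        cuts_list = []
        for j in range(vals.shape[1]):
            c = _cuts(vals[:, j])
            cuts_list.append(c)
            cols.append(np.searchsorted(c, vals[:, j], side="left"))
        codes = np.column_stack(cols)
        cuts = np.column_stack(cuts_list)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    states = pd.DataFrame(codes, index=scores.index, columns=scores.columns)
    return StatePanel(states=states, scores=scores.copy(), cut_points=cuts, k=k)


@dataclass
class TransitionModel:
    """Transition counts n_ij and row-stochastic probabilities M_ij = n_ij/n_i.

    Rows with no origin observations are *undefined*: their probability rows
    are NaN, never zero- or uniform-filled.
    """

    counts: np.ndarray            # (k, k) ints
    k: int
    condition: str | None = None  # neighborhood-state label, if conditioned
    period: str | None = None

    @property
    def n_i(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def probabilities(self) -> np.ndarray:
        n_i = self.n_i.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / n_i[:, None]
        p[n_i == 0] = np.nan
        return p

    def frame(self) -> pd.DataFrame:
        labels = state_labels(self.k)
        return pd.DataFrame(self.probabilities, index=labels, columns=labels)


def _pair_years(columns, lag_years: int = 1):
    years = list(columns)
    return [(years[i], years[i + lag_years])
            for i in range(len(years) - lag_years)]


def estimate_transitions(panel: StatePanel, years: list | None = None,
                         lag_years: int = 1,
                         period: str | None = None) -> TransitionModel:
    """Pool all (unit, t) -> (unit, t + lag) transitions into one matrix."""
    st = panel.states[years] if years is not None else panel.states
    if st.shape[1] < lag_years + 1:
        raise InsufficientDataError("need at least two years of states")
    counts = np.zeros((panel.k, panel.k), dtype=int)
    for a, b in _pair_years(st.columns, lag_years):
        for i, j in zip(st[a], st[b]):
            counts[int(i), int(j)] += 1
    return TransitionModel(counts=counts, k=panel.k, period=period)


def spatial_lag(values: np.ndarray, w: SpatialWeights) -> np.ndarray:
    """lag_i = Σ_j W_ij y_j; NaN where a unit has no neighbors."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != w.n:
        raise AlignmentError(f"{values.shape[0]} values for {w.n} units")
    lag = w.matrix @ values
    islands = w.matrix.sum(axis=1) == 0
    if islands.any():
        log.warning("spatial lag undefined for zero-neighbor units: %s",
                    [w.unit_ids[i] for i in np.nonzero(islands)[0]])
        lag[islands] = np.nan
    return lag


def spatial_markov(scores: pd.DataFrame, w: SpatialWeights, k: int = 4,
                   pooling: str = "whole_period") -> list[TransitionModel]:
    """Condition each transition on the origin-year class of the spatial lag.

    The lag panel is classified on its own pooled quantile scheme (same
    pooling rule as the scores).  The cell-wise sum of the k conditional
    count matrices equals the unconditional counts.
    """
    w = w.align_to(list(scores.index)).row_standardize() \
        if not w.standardized else w.align_to(list(scores.index))
    sp = classify_states(scores, k, pooling)
    lag_vals = pd.DataFrame(
        {yr: spatial_lag(scores[yr].to_numpy(), w) for yr in scores.columns},
        index=scores.index,
    )
    defined = ~lag_vals.isna().any(axis=1)
    if not defined.all():
        log.warning("excluding zero-neighbor units from spatial Markov: %s",
                    list(scores.index[~defined]))
    lp = classify_states(lag_vals[defined], k, pooling)

    labels = state_labels(k)
    counts = [np.zeros((k, k), dtype=int) for _ in range(k)]
    st = sp.states[defined]
    for a, b in _pair_years(st.columns):
        for u in st.index:
            cond = int(lp.states.loc[u, a])
            counts[cond][int(st.loc[u, a]), int(st.loc[u, b])] += 1
    out = []
    for c, cnt in enumerate(counts):
        tm = TransitionModel(counts=cnt, k=k, condition=labels[c])
        if cnt.sum() == 0:
            log.warning("no transitions under neighborhood state %s", labels[c])
        out.append(tm)
    return out


@dataclass
class HomogeneityTest:
    """Anderson–Goodman test of Markov time homogeneity."""

    chi2: float
    lr: float
    df: int
    p_chi2: float
    p_lr: float
    sub_models: list[TransitionModel]
    pooled: TransitionModel


def time_homogeneity_test(panel: StatePanel,
                          breakpoints: list | None = None) -> HomogeneityTest:
    """Test whether per-sub-period transition matrices differ from the pooled
    matrix.

    q  = Σ_t Σ_ij n_i(t) (M_ij(t) − M_ij)² / M_ij       over cells with M_ij > 0
    LR = 2 Σ_t Σ_ij n_ij(t) ln(M_ij(t) / M_ij)          over cells with n_ij(t) > 0
    df = (T_sub − 1) Σ_i (defined columns in pooled row i − 1), counting only
    rows observed in every sub-period.
    """
    years = list(panel.states.columns)
    if breakpoints is None:
        breakpoints = [years[len(years) // 2]]
    edges = [years[0]] + list(breakpoints) + [years[-1] + 1]
    sub_year_sets = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ys = [y for y in years if lo <= y < hi]
        if len(ys) < 2:
            raise InsufficientDataError(
                f"sub-period [{lo}, {hi}) has no transitions"
            )
        sub_year_sets.append(ys)

    subs = [estimate_transitions(panel, ys, period=f"{ys[0]}-{ys[-1]}")
            for ys in sub_year_sets]
    # the pooled matrix aggregates exactly the sub-period transitions, so the
    # null distribution of q is the reference χ²
    pooled = TransitionModel(counts=sum(tm.counts for tm in subs), k=panel.k)
    M = pooled.probabilities
    q = 0.0
    lr = 0.0
    for tm in subs:
        n_i = tm.n_i.astype(float)
        Mt = tm.probabilities
        for i in range(panel.k):
            if n_i[i] == 0:
                continue
            for j in range(panel.k):
                if np.isnan(M[i, j]) or M[i, j] <= 0:
                    continue
                q += n_i[i] * (Mt[i, j] - M[i, j]) ** 2 / M[i, j]
                if tm.counts[i, j] > 0:
                    lr += 2.0 * tm.counts[i, j] * np.log(Mt[i, j] / M[i, j])
    # df: rows present in all sub-periods, columns defined in the pooled matrix
    df = 0
    for i in range(panel.k):
        if all(tm.n_i[i] > 0 for tm in subs):
            cols = int((pooled.counts[i] > 0).sum())
            df += max(cols - 1, 0)
    df *= len(subs) - 1
    if df <= 0:
        raise InsufficientDataError("no degrees of freedom for homogeneity test")
    return HomogeneityTest(
        chi2=float(q), lr=float(lr), df=df,
        p_chi2=float(stats.chi2.sf(q, df)), p_lr=float(stats.chi2.sf(lr, df)),
        sub_models=subs, pooled=pooled,
    )
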