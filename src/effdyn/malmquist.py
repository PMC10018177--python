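"""Malmquist total factor productivity index and its decomposition.

For adjacent years t and t+1, with input-oriented radial distances
θ^a(b) = efficiency of a DMU's year-b data against the year-a frontier:

    TEC  = θ^{t+1}(t+1) / θ^t(t)                  (catch-up)
    TC   = sqrt[ θ^t(t+1)/θ^{t+1}(t+1) · θ^t(t)/θ^{t+1}(t) ]   (frontier shift)
    PTEC = same as TEC but under variable returns to scale
    SEC  = TEC / PTEC
    TFPC = TEC · TC

Multi-year horizons are chained as per-component geometric means over
adjacent pairs, so the identities TFPC = TEC·TC = (PTEC·SEC)·TC carry over
exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dea import SolverError, _check_data, _radial_one
from .panel import PanelDataset

log = logging.getLogger(__name__)

COMPONENTS = ["TEC", "TC", "PTEC", "SEC", "TFPC"]


def cross_period_distance(X_data, Y_data, X_frontier, Y_frontier,
                          dmu: int, vrs: bool = False) -> float:
    """Radial input-oriented efficiency of one DMU's (x, y) from the data
    period, measured against the frontier of another period.

    May exceed 1 when the data point dominates the old frontier.  Mixed-
    period VRS programs can be infeasible; that raises :class:`SolverError`
    and callers drop the pair from geometric means.
    """
    X_f, Y_f = _check_data(X_frontier, Y_frontier)
    X_d = np.atleast_2d(np.asarray(X_data, dtype=float))
    Y_d = np.atleast_2d(np.asarray(Y_data, dtype=float))
    theta, *_ = _radial_one(X_f, Y_f, X_d[:, dmu], Y_d[:, dmu], vrs,
                            who=f"cross-period {dmu}", frontier_only=True)
    return theta


def malmquist_index(panel: PanelDataset, t: int, t_plus_1: int,
                    input_class: str | None = None) -> pd.DataFrame:
    """Per-DMU Malmquist record between two years of a panel."""
    Xa, Ya = panel.dea_matrices(t, input_class)
    Xb, Yb = panel.dea_matrices(t_plus_1, input_class)
    n = Xa.shape[1]
    rows = []
    for o in range(n):
        d_tt = cross_period_distance(Xa, Ya, Xa, Ya, o)
        d_t1t1 = cross_period_distance(Xb, Yb, Xb, Yb, o)
        d_t_t1 = cross_period_distance(Xb, Yb, Xa, Ya, o)    # new data, old frontier
        d_t1_t = cross_period_distance(Xa, Ya, Xb, Yb, o)    # old data, new frontier
        tec = d_t1t1 / d_tt
        tc = np.sqrt((d_t_t1 / d_t1t1) * (d_tt / d_t1_t))
        try:
            v_tt = cross_period_distance(Xa, Ya, Xa, Ya, o, vrs=True)
            v_t1t1 = cross_period_distance(Xb, Yb, Xb, Yb, o, vrs=True)
            ptec = v_t1t1 / v_tt
        except SolverError:
            log.warning("VRS distance infeasible for %s; PTEC set to TEC",
                        panel.unit_ids[o])
            ptec = tec
        sec = tec / ptec
        tfpc = tec * tc
        if min(tec, tc, ptec, sec, tfpc) <= 0:
            raise ArithmeticError(
                f"non-positive Malmquist component for {panel.unit_ids[o]} "
                f"({t}->{t_plus_1}): TEC={tec}, TC={tc}, PTEC={ptec}"
            )
        rows.append({"unit": panel.unit_ids[o], "from": t, "to": t_plus_1,
                     "TEC": tec, "TC": tc, "PTEC": ptec, "SEC": sec,
                     "TFPC": tfpc})
    return pd.DataFrame(rows)


def chain_over_horizon(panel: PanelDataset, first_year: int, last_year: int,
                       input_class: str | None = None) -> pd.DataFrame:
    """Geometric-mean chaining of adjacent-year indices over a horizon.

    The multiplicative identities hold on the chained record because the
    geometric mean of products is the product of geometric means.
    """
    years = [y for y in panel.years if first_year <= y <= last_year]
    if len(years) < 2:
        raise ValueError(f"need at least two years in [{first_year}, {last_year}]")
    pieces = [malmquist_index(panel, a, b, input_class)
              for a, b in zip(years[:-1], years[1:])]
    stacked = pd.concat(pieces, ignore_index=True)
    out = (
        np.log(stacked.set_index("unit")[COMPONENTS])
        .groupby("unit").mean()
        .pipe(np.exp)
        .reindex(panel.unit_ids)
        .reset_index()
    )
    out.insert(1, "from", first_year)
    out.insert(2, "to", last_year)
    return out
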