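"""Linear-programming DEA engine.

Implements input-oriented radial models (CCR under constant returns to
scale, BCC under variable returns) with a two-stage solve — first the
radial contraction factor θ, then slack maximization at fixed θ — plus
Tone's non-oriented slack-based measure (SBM) and its super-efficiency
variant, which ranks efficient units by scores above 1.

All linear programs are solved with HiGHS through
:func:`scipy.optimize.linprog`.  Matrices are arranged with decision-making
units (DMUs) as columns: ``X`` is (m inputs x n units), ``Y`` is
(s outputs x n units).

Identities maintained per unit: TE = PTE x SE (technical = pure technical
x scale efficiency), and returns-to-scale labels derived from the sum of
the CCR reference weights Σλ (<1 increasing, >1 decreasing, else constant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import AlignmentError, PanelDataset

log = logging.getLogger(__name__)

#: score within this of 1, with zero slacks, counts as efficient
EFF_TOL = 1e-6
#: tolerance band on |Σλ - 1| for the CRS label
RTS_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP solver did not reach an optimal solution."""


@dataclass
class DEAResult:
    """Per-DMU efficiency scores, reference weights, and slacks."""

    unit_ids: list[str]
    theta: np.ndarray | None = None          # radial score (CCR: TE, BCC: PTE)
    rho: np.ndarray | None = None            # SBM / super-SBM score
    lambdas: np.ndarray | None = None        # (n, n): row = evaluated DMU
    input_slacks: np.ndarray | None = None   # (n, m)
    output_slacks: np.ndarray | None = None  # (n, s)
    rts: list[str] | None = None
    model: str = ""

    @property
    def scores(self) -> np.ndarray:
        return self.rho if self.rho is not None else self.theta

    def efficient(self, tol: float = EFF_TOL) -> np.ndarray:
        """Efficiency flags: score within ``tol`` of 1 and negligible slacks."""
        ok = self.scores >= 1.0 - tol
        if self.input_slacks is not None:
            slack = np.abs(self.input_slacks).sum(axis=1)
            slack += np.abs(self.output_slacks).sum(axis=1)
            ok = ok & (slack <= max(tol, 1e-5) * max(1.0, slack.max(initial=0.0)))
        return ok


def _check_data(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise AlignmentError(f"inputs have {X.shape[1]} DMUs, outputs {Y.shape[1]}")
    if (X < 0).any() or (Y < 0).any():
        raise ValueError("DEA data must be non-negative")
    if not ((X > 0).any(axis=0).all() and (Y > 0).any(axis=0).all()):
        raise ValueError("every DMU needs at least one positive input and output")
    return X, Y


def _lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None, what=""):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError(f"{what}: LP solver status {res.status} ({res.message})")
    return res


def _radial(X: np.ndarray, Y: np.ndarray, vrs: bool,
            unit_ids: list[str] | None = None) -> DEAResult:
    """Two-stage input-oriented radial solve for every DMU."""
    m, n = X.shape
    s = Y.shape[0]
    ids = unit_ids if unit_ids is not None else [str(j) for j in range(n)]
    theta = np.empty(n)
    lambdas = np.empty((n, n))
    s_in = np.empty((n, m))
    s_out = np.empty((n, s))
    for o in range(n):
        th, lam, si, so = _radial_one(X, Y, X[:, o], Y[:, o], vrs, who=ids[o])
        # efficient DMUs self-reference: among the alternate optima of the
        # slack stage this is the canonical one, and it makes Σλ = 1 (CRS)
        scale = max(np.abs(si).max(initial=0.0) / max(X[:, o].max(), 1e-12),
                    np.abs(so).max(initial=0.0) / max(Y[:, o].max(), 1e-12))
        if th >= 1.0 - EFF_TOL and scale <= 1e-7:
            lam = np.zeros(n)
            lam[o] = 1.0
            si, so = np.zeros(m), np.zeros(s)
        theta[o], lambdas[o], s_in[o], s_out[o] = th, lam, si, so
    return DEAResult(list(ids), theta=theta, lambdas=lambdas,
                     input_slacks=s_in, output_slacks=s_out,
                     model="BCC" if vrs else "CCR")


def _radial_one(X, Y, x0, y0, vrs, who="", frontier_only=False):
    """θ (and, unless frontier_only, slack-maximizing λ, s⁻, s⁺) for one DMU.

    Stage 1 variables: [θ, λ_1..λ_n];  min θ
      s.t.  Xλ − θ x0 ≤ 0,  −Yλ ≤ −y0,  (Σλ = 1 if VRS).
    Stage 2 at fixed θ*: max Σs⁻ + Σs⁺ with Xλ + s⁻ = θ* x0, Yλ − s⁺ = y0.
    """
    m, n = X.shape
    s = Y.shape[0]
    c = np.zeros(1 + n)
    c[0] = 1.0
    A_ub = np.zeros((m + s, 1 + n))
    A_ub[:m, 0] = -x0
    A_ub[:m, 1:] = X
    A_ub[m:, 1:] = -Y
    b_ub = np.concatenate([np.zeros(m), -y0])
    A_eq = b_eq = None
    if vrs:
        A_eq = np.zeros((1, 1 + n))
        A_eq[0, 1:] = 1.0
        b_eq = [1.0]
    bounds = [(None, None)] + [(0, None)] * n
    res = _lp(c, A_ub, b_ub, A_eq, b_eq, bounds, what=f"radial DMU {who}")
    theta = float(res.x[0])
    if frontier_only:
        return theta, None, None, None

    # stage 2: maximize total slack at θ fixed
    nv = n + m + s
    c2 = np.zeros(nv)
    c2[n:] = -1.0
    A2 = np.zeros((m + s, nv))
    A2[:m, :n] = X
    A2[:m, n:n + m] = np.eye(m)
    A2[m:, :n] = Y
    A2[m:, n + m:] = -np.eye(s)
    b2 = np.concatenate([theta * x0, y0])
    A2_full, b2_full = A2, b2
    if vrs:
        row = np.zeros((1, nv))
        row[0, :n] = 1.0
        A2_full = np.vstack([A2, row])
        b2_full = np.concatenate([b2, [1.0]])
    res2 = _lp(c2, A_eq=A2_full, b_eq=b2_full,
               bounds=[(0, None)] * nv, what=f"slack stage DMU {who}")
    lam = res2.x[:n]
    s_in = res2.x[n:n + m]
    s_out = res2.x[n + m:]
    return theta, lam, s_in, s_out


def solve_ccr(X, Y, unit_ids: list[str] | None = None) -> DEAResult:
    """Input-oriented CCR (constant returns) technical efficiency."""
    X, Y = _check_data(X, Y)
    res = _radial(X, Y, vrs=False, unit_ids=unit_ids)
    res.rts = classify_rts(res)
    return res


def solve_bcc(X, Y, unit_ids: list[str] | None = None) -> DEAResult:
    """Input-oriented BCC (variable returns) pure technical efficiency."""
    X, Y = _check_data(X, Y)
    return _radial(X, Y, vrs=True, unit_ids=unit_ids)


def compute_scale_efficiency(te: np.ndarray, pte: np.ndarray) -> np.ndarray:
    """SE = TE / PTE, clipped to (0, 1 + 1e-9]."""
    te = np.asarray(te, dtype=float)
    pte = np.asarray(pte, dtype=float)
    if te.shape != pte.shape:
        raise AlignmentError(f"score vectors differ in length: {te.shape} vs {pte.shape}")
    if (pte <= 0).any():
        raise ValueError("PTE must be positive")
    return np.clip(te / pte, None, 1.0 + 1e-9)


def classify_rts(ccr_result: DEAResult, tol: float = RTS_TOL) -> list[str]:
    """Returns-to-scale labels from Σλ at the CCR optimum."""
    if ccr_result.lambdas is None:
        raise ValueError("RTS classification needs CCR reference weights")
    sums = ccr_result.lambdas.sum(axis=1)
    labels = []
    for sl in sums:
        if abs(sl - 1.0) <= tol:
            labels.append("CRS")
        elif sl < 1.0:
            labels.append("IRS")
        else:
            labels.append("DRS")
    return labels


def solve_sbm(X, Y, unit_ids: list[str] | None = None) -> DEAResult:
    """Non-oriented slack-based measure (SBM) efficiency.

    For DMU o: ρ = min [1 − (1/m)Σ s⁻_i/x_io] / [1 + (1/s)Σ s⁺_r/y_ro]
    subject to x_o = Xλ + s⁻, y_o = Yλ − s⁺, λ, s⁻, s⁺ ≥ 0, solved via the
    Charnes–Cooper linearization with scaling variable t.
    """
    X, Y = _check_data(X, Y)
    m, n = X.shape
    s = Y.shape[0]
    ids = unit_ids if unit_ids is not None else [str(j) for j in range(n)]
    rho = np.empty(n)
    lambdas = np.empty((n, n))
    s_in = np.empty((n, m))
    s_out = np.empty((n, s))
    for o in range(n):
        x0, y0 = X[:, o], Y[:, o]
        if (x0 <= 0).any() or (y0 <= 0).any():
            bad = "input" if (x0 <= 0).any() else "output"
            raise ValueError(f"SBM requires strictly positive data; DMU {ids[o]} "
                             f"has a zero {bad}")
        # variables: [t, Λ (n), S⁻ (m), S⁺ (s)]
        nv = 1 + n + m + s
        c = np.zeros(nv)
        c[0] = 1.0
        c[1 + n:1 + n + m] = -1.0 / (m * x0)
        A_eq = np.zeros((1 + m + s, nv))
        b_eq = np.zeros(1 + m + s)
        A_eq[0, 0] = 1.0
        A_eq[0, 1 + n + m:] = 1.0 / (s * y0)
        b_eq[0] = 1.0
        A_eq[1:1 + m, 0] = -x0
        A_eq[1:1 + m, 1:1 + n] = X
        A_eq[1:1 + m, 1 + n:1 + n + m] = np.eye(m)
        A_eq[1 + m:, 0] = -y0
        A_eq[1 + m:, 1:1 + n] = Y
        A_eq[1 + m:, 1 + n + m:] = -np.eye(s)
        res = _lp(c, A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * nv,
                  what=f"SBM DMU {ids[o]}")
        t = res.x[0]
        rho[o] = float(res.fun)
        lambdas[o] = res.x[1:1 + n] / t
        s_in[o] = res.x[1 + n:1 + n + m] / t
        s_out[o] = res.x[1 + n + m:] / t
    return DEAResult(list(ids), rho=rho, lambdas=lambdas,
                     input_slacks=s_in, output_slacks=s_out, model="SBM")


def _super_sbm_one(X, Y, o, ids) -> float:
    """Non-oriented super-SBM score for one SBM-efficient DMU.

    δ = min [(1/m)Σ x̄_i/x_io] / [(1/s)Σ ȳ_r/y_ro] over the reference set
    excluding o, with x̄ ≥ X₋ₒλ, x̄ ≥ x_o, 0 ≤ ȳ ≤ Y₋ₒλ, ȳ ≤ y_o.
    Returns +inf when the reduced reference set is empty or the LP is
    infeasible (the DMU dominates in a way no peer combination can span).
    """
    m, n = X.shape
    s = Y.shape[0]
    x0, y0 = X[:, o], Y[:, o]
    others = [j for j in range(n) if j != o]
    if not others:
        return np.inf
    Xr, Yr = X[:, others], Y[:, others]
    k = len(others)
    # variables after Charnes-Cooper: [t, Λ (k), X̄ (m), Ȳ (s)]
    nv = 1 + k + m + s
    c = np.zeros(nv)
    c[1 + k:1 + k + m] = 1.0 / (m * x0)
    A_eq = np.zeros((1, nv))
    A_eq[0, 1 + k + m:] = 1.0 / (s * y0)
    b_eq = [1.0]
    rows = []
    rhs = []
    # XrΛ − X̄ ≤ 0
    blk = np.zeros((m, nv))
    blk[:, 1:1 + k] = Xr
    blk[:, 1 + k:1 + k + m] = -np.eye(m)
    rows.append(blk); rhs.append(np.zeros(m))
    # Ȳ − YrΛ ≤ 0
    blk = np.zeros((s, nv))
    blk[:, 1:1 + k] = -Yr
    blk[:, 1 + k + m:] = np.eye(s)
    rows.append(blk); rhs.append(np.zeros(s))
    # t x0 − X̄ ≤ 0  (x̄ ≥ x0)
    blk = np.zeros((m, nv))
    blk[:, 0] = x0
    blk[:, 1 + k:1 + k + m] = -np.eye(m)
    rows.append(blk); rhs.append(np.zeros(m))
    # Ȳ − t y0 ≤ 0  (ȳ ≤ y0)
    blk = np.zeros((s, nv))
    blk[:, 0] = -y0
    blk[:, 1 + k + m:] = np.eye(s)
    rows.append(blk); rhs.append(np.zeros(s))
    A_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)
    try:
        res = _lp(c, A_ub, b_ub, A_eq, b_eq, bounds=[(0, None)] * nv,
                  what=f"super-SBM DMU {ids[o]}")
    except SolverError:
        log.warning("super-SBM LP infeasible for DMU %s; reporting +inf", ids[o])
        return np.inf
    if res.x[0] <= 1e-12:
        log.warning("super-SBM degenerate scaling for DMU %s; reporting +inf", ids[o])
        return np.inf
    return float(res.fun)


def solve_super_sbm(X, Y, unit_ids: list[str] | None = None,
                    tol: float = EFF_TOL) -> DEAResult:
    """Super-SBM scores: >1 for SBM-efficient DMUs, SBM score otherwise."""
    X, Y = _check_data(X, Y)
    sbm = solve_sbm(X, Y, unit_ids)
    scores = sbm.rho.copy()
    for o in np.nonzero(sbm.rho >= 1.0 - tol)[0]:
        scores[o] = max(_super_sbm_one(X, Y, o, sbm.unit_ids), 1.0)
    return DEAResult(list(sbm.unit_ids), rho=scores, lambdas=sbm.lambdas,
                     input_slacks=sbm.input_slacks, output_slacks=sbm.output_slacks,
                     model="superSBM")


def rank_by_super_sbm(scores) -> np.ndarray:
    """Descending ranks 1..n; exact ties broken by stable input order."""
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def solve_year(panel: PanelDataset, year: int,
               input_class: str | None = None) -> pd.DataFrame:
    """TE/PTE/SE/RTS/SBM/rank table for all units in one year."""
    X, Y = panel.dea_matrices(year, input_class)
    ccr = solve_ccr(X, Y, panel.unit_ids)
    bcc = solve_bcc(X, Y, panel.unit_ids)
    sup = solve_super_sbm(X, Y, panel.unit_ids)
    se = compute_scale_efficiency(ccr.theta, bcc.theta)
    return pd.DataFrame({
        "unit": panel.unit_ids,
        "year": year,
        "TE": ccr.theta,
        "PTE": bcc.theta,
        "SE": se,
        "RTS": ccr.rts,
        "SBM": sup.rho,
        "rank": rank_by_super_sbm(sup.rho),
    })


def count_efficient_per_year(panel: PanelDataset, tol: float = EFF_TOL,
                             input_class: str | None = None) -> pd.DataFrame:
    """Per-year counts of units with TE, PTE, and SE equal to 1 (within tol)."""
    rows = []
    for year in panel.years:
        try:
            tab = solve_year(panel, year, input_class)
        except Exception as exc:  # incomplete year
            log.warning("year %s skipped: %s", year, exc)
            continue
        rows.append({
            "year": year,
            "TE": int((tab["TE"] >= 1 - tol).sum()),
            "PTE": int((tab["PTE"] >= 1 - tol).sum()),
            "SE": int((tab["SE"] >= 1 - tol).sum()),
        })
    return pd.DataFrame(rows)
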