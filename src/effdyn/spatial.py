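"""Global Moran's I and local (LISA) spatial autocorrelation.

Global statistic:  I = (n / S0) · Σ_ij w_ij z_i z_j / Σ_i z_i²  with
z = x − x̄ and S0 = Σ_ij w_ij.  Under randomization E[I] = −1/(n−1).
Inference is by random permutation of the values over the units
(two-sided pseudo p-value by default).

Local statistic:  LISA_i = z̃_i Σ_j w_ij z̃_j with z̃ standardized by the
population standard deviation, so that Σ_i LISA_i = n·I when W is
row-standardized.  Per-unit inference holds unit i fixed and permutes the
remaining values among its neighbors (conditional permutation).  Quadrants
HH/LL/HL/LH come from the signs of (z_i, lag_i); significant quadrants map
to diffusion / lagging / polarization / centrifugal effect labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import spatial_lag
from .panel import AlignmentError, SpatialWeights

QUADRANT_EFFECTS = {
    "HH": "diffusion",
    "LL": "lagging",
    "HL": "polarization",
    "LH": "centrifugal",
}


@dataclass
class MoranResult:
    I: float
    expected: float            # −1/(n−1)
    p_value: float
    n_perm: int
    seed: int | None
    perm_values: np.ndarray | None = None


@dataclass
class LisaResult:
    unit_ids: list[str]
    lisa: np.ndarray
    quadrant: list[str]
    p_values: np.ndarray
    n_perm: int
    seed: int | None


def _prepare(values, w: SpatialWeights):
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(x) != w.n:
        raise AlignmentError(f"{len(x)} values for {w.n} units")
    if len(x) < 3:
        raise ValueError("need at least 3 units")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: values have zero variance")
    s0 = w.matrix.sum()
    if s0 <= 0:
        raise ValueError("weights have zero total weight")
    return x, s0


def _moran_stat(x: np.ndarray, w: np.ndarray, s0: float) -> float:
    z = x - x.mean()
    return len(x) / s0 * float(z @ w @ z) / float(z @ z)


def global_morans_i(values, w: SpatialWeights, n_perm: int = 999,
                    seed: int | None = 20130101,
                    alternative: str = "two-sided") -> MoranResult:
    """Moran's I with permutation inference."""
    x, s0 = _prepare(values, w)
    n = len(x)
    i_obs = _moran_stat(x, w.matrix, s0)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    z = x - x.mean()
    Z = np.array([rng.permutation(z) for _ in range(n_perm)])
    perms = n / s0 * ((Z @ w.matrix) * Z).sum(axis=1) / float(z @ z)
    if alternative == "two-sided":
        hi = (np.sum(perms >= i_obs) + 1) / (n_perm + 1)
        lo = (np.sum(perms <= i_obs) + 1) / (n_perm + 1)
        p = min(2 * min(hi, lo), 1.0)
    elif alternative == "greater":
        p = (np.sum(perms >= i_obs) + 1) / (n_perm + 1)
    elif alternative == "less":
        p = (np.sum(perms <= i_obs) + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MoranResult(I=float(i_obs), expected=expected, p_value=float(p),
                       n_perm=n_perm, seed=seed, perm_values=perms)


def local_morans_i(values, w: SpatialWeights, n_perm: int = 999,
                   seed: int | None = 20130101) -> LisaResult:
    """Per-unit LISA with conditional permutation p-values.

    Units without neighbors get NaN statistics and p-values.
    """
    x, _ = _prepare(values, w)
    n = len(x)
    z = (x - x.mean()) / x.std()          # population sd: Σ LISA = n·I
    wm = w.matrix
    lag_z = wm @ z
    lisa = z * lag_z
    islands = wm.sum(axis=1) == 0
    quadrant = []
    for zi, li, isl in zip(z, lag_z, islands):
        if isl:
            quadrant.append("NA")
        else:
            quadrant.append(("H" if zi > 0 else "L") + ("H" if li > 0 else "L"))

    rng = np.random.default_rng(seed)
    p = np.full(n, np.nan)
    for i in range(n):
        nbrs = np.nonzero(wm[i])[0]
        if nbrs.size == 0:
            lisa[i] = np.nan
            continue
        others = np.delete(np.arange(n), i)
        zo = z[others]
        wi = wm[i, nbrs]
        k = nbrs.size
        # draw k values for i's neighbors from the other units, n_perm times
        sims = np.empty(n_perm)
        for b in range(n_perm):
            pick = rng.choice(zo, size=k, replace=False)
            sims[b] = z[i] * float(wi @ pick)
        hi = (np.sum(sims >= lisa[i]) + 1) / (n_perm + 1)
        lo = (np.sum(sims <= lisa[i]) + 1) / (n_perm + 1)
        p[i] = min(2 * min(hi, lo), 1.0)
    return LisaResult(unit_ids=list(w.unit_ids), lisa=lisa, quadrant=quadrant,
                      p_values=p, n_perm=n_perm, seed=seed)


def label_effects(lisa: LisaResult, alpha: float = 0.05) -> list[str]:
    """Map significant LISA quadrants to spatial-effect labels."""
    out = []
    for quad, p in zip(lisa.quadrant, lisa.p_values):
        if quad in QUADRANT_EFFECTS and np.isfinite(p) and p <= alpha:
            out.append(QUADRANT_EFFECTS[quad])
        else:
            out.append("none")
    return out


def moran_by_year(scores: dict[str, pd.DataFrame], w: SpatialWeights,
                  n_perm: int = 999, seed: int | None = 20130101) -> pd.DataFrame:
    """Global Moran's I per year for each named score series.

    ``scores`` maps a series name (e.g. total / human / nonhuman efficiency)
    to a units x years frame aligned with ``w``.
    """
    rows = []
    for series, frame in scores.items():
        wa = w.align_to(list(frame.index))
        for year in frame.columns:
            res = global_morans_i(frame[year].to_numpy(), wa,
                                  n_perm=n_perm, seed=seed)
            rows.append({"year": year, "series": series,
                         "I": res.I, "p": res.p_value})
    return pd.DataFrame(rows)
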