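"""Synthetic data generators with known ground truth.

Every analysis stage in the pipeline has a matching generator here, so its
estimators can be exercised against known truth without any external data:

* production-frontier panels with multiplicative inefficiency (DEA),
* spatially autoregressive fields with tunable strength ρ (Moran's I),
* discrete state sequences from a known transition matrix, optionally
  coupled to neighbors' states (spatial Markov),
* censored linear-model outcomes with known coefficients (Tobit).

Generators are pure functions of their parameters and seed, and each
returns a :class:`SyntheticTruth` record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import StatePanel
from .panel import PanelDataset, SpatialWeights, VariableInfo


@dataclass
class SyntheticTruth:
    """Ground truth carried with every generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    efficiencies: pd.DataFrame | None = None       # units x years exp(-u)
    transition_matrix: np.ndarray | None = None
    rho: float | None = None
    alpha: float | None = None
    beta: np.ndarray | None = None
    sigma: float | None = None


def _unit_names(n: int) -> list[str]:
    return [f"U{i + 1:02d}" for i in range(n)]


def generate_frontier_panel(
    n_units: int = 31, n_years: int = 8, m_inputs: int = 2, s_outputs: int = 1,
    inefficiency_sd: float = 0.2, tech_drift: float = 0.0, seed: int = 0,
    first_year: int = 2013, vrs: bool = False,
) -> tuple[PanelDataset, SyntheticTruth]:
    """Cobb–Douglas frontier panel with half-normal inefficiency.

    Inputs are log-normal; the frontier output is the geometric mean of the
    inputs raised to equal exponents summing to 1 (constant returns; with
    ``vrs`` the exponents sum to 0.8), scaled by (1 + tech_drift) per year.
    Each unit's outputs are the frontier level times exp(−u) with
    u ~ half-normal(inefficiency_sd); truth records exp(−u) per unit-year.
    """
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if min(n_years, m_inputs, s_outputs) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    units = _unit_names(n_units)
    years = [first_year + t for t in range(n_years)]
    expo = (0.8 if vrs else 1.0) / m_inputs
    rows = []
    eff = np.empty((n_units, n_years))
    for t, year in enumerate(years):
        X = rng.lognormal(mean=1.0, sigma=0.4, size=(m_inputs, n_units))
        u = np.abs(rng.normal(0.0, inefficiency_sd, size=n_units))
        eff[:, t] = np.exp(-u)
        frontier = (1.0 + tech_drift) ** t * np.prod(X ** expo, axis=0)
        # split the frontier level evenly across output dimensions
        Y = np.tile(frontier * eff[:, t] / s_outputs, (s_outputs, 1))
        for i, unit in enumerate(units):
            for a in range(m_inputs):
                rows.append((unit, year, f"input_{a + 1}", X[a, i]))
            for b in range(s_outputs):
                rows.append((unit, year, f"output_{b + 1}", Y[b, i]))
    schema = {f"input_{a + 1}": VariableInfo("input", "non_human" if a % 2 else "human")
              for a in range(m_inputs)}
    schema |= {f"output_{b + 1}": VariableInfo("output", "other")
               for b in range(s_outputs)}
    panel = PanelDataset(
        pd.DataFrame(rows, columns=["unit", "year", "variable", "value"]), schema
    )
    truth = SyntheticTruth(
        generator="frontier", seed=seed,
        params=dict(n_units=n_units, n_years=n_years, m_inputs=m_inputs,
                    s_outputs=s_outputs, inefficiency_sd=inefficiency_sd,
                    tech_drift=tech_drift, vrs=vrs),
        efficiencies=pd.DataFrame(eff, index=units, columns=years),
    )
    return panel, truth


def generate_sar_field(
    w: SpatialWeights, rho: float = 0.0, n_reps: int = 1, seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Simultaneous-autoregressive fields x = (I − ρW)⁻¹ ε, ε ~ N(0, 1).

    Returns an (n_reps, n) array.  W is row-standardized internally, so the
    stability condition is |ρ| < 1.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for a row-standardized W")
    ws = w if w.standardized else w.row_standardize()
    rng = np.random.default_rng(seed)
    n = ws.n
    A = np.linalg.inv(np.eye(n) - rho * ws.matrix)
    eps = rng.standard_normal((n_reps, n))
    fields = eps @ A.T
    truth = SyntheticTruth(generator="sar", seed=seed, rho=rho,
                           params=dict(n_reps=n_reps))
    return fields, truth


def generate_markov_states(
    n_units: int = 31, n_years: int = 8, M_true: np.ndarray | None = None,
    spatial_coupling: float = 0.0, w: SpatialWeights | None = None,
    seed: int = 0, first_year: int = 2013,
) -> tuple[StatePanel, SyntheticTruth]:
    """Evolve unit states by a known transition matrix.

    With probability ``spatial_coupling`` a unit's transition row is blended
    half-and-half with a point mass on its modal neighbor state, inducing
    the kind of neighborhood conditioning a spatial Markov chain detects.
    """
    if M_true is None:
        M_true = np.full((4, 4), 0.1) + np.eye(4) * 0.6
    M_true = np.asarray(M_true, dtype=float)
    k = M_true.shape[0]
    if M_true.shape != (k, k) or (M_true < 0).any() or \
            np.abs(M_true.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("M_true must be a row-stochastic square matrix")
    if not 0 <= spatial_coupling <= 1:
        raise ValueError("spatial_coupling must be in [0, 1]")
    if spatial_coupling > 0 and w is None:
        raise ValueError("spatial coupling needs a weights matrix")
    rng = np.random.default_rng(seed)
    units = _unit_names(n_units)
    years = [first_year + t for t in range(n_years)]
    states = np.empty((n_units, n_years), dtype=int)
    states[:, 0] = rng.integers(0, k, size=n_units)
    for t in range(1, n_years):
        for i in range(n_units):
            row = M_true[states[i, t - 1]]
            if spatial_coupling > 0 and rng.random() < spatial_coupling:
                nbrs = np.nonzero(w.matrix[i])[0]
                if nbrs.size:
                    modal = np.bincount(states[nbrs, t - 1], minlength=k).argmax()
                    tilt = np.zeros(k)
                    tilt[modal] = 1.0
                    row = 0.5 * row + 0.5 * tilt
            states[i, t] = rng.choice(k, p=row)
    frame = pd.DataFrame(states, index=units, columns=years)
    sp = StatePanel(states=frame, scores=frame.astype(float),
                    cut_points=np.arange(1, k) - 0.5, k=k)
    truth = SyntheticTruth(
        generator="markov", seed=seed, transition_matrix=M_true,
        params=dict(n_units=n_units, n_years=n_years,
                    spatial_coupling=spatial_coupling),
    )
    return sp, truth


def generate_tobit_data(
    n: int = 2000, alpha: float = 0.0, beta=(1.0, -0.5), sigma: float = 0.5,
    censor_bounds: tuple = (0.0, None), covariate_law: str = "normal",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Latent y* = α + Xβ + ε clipped at the censoring bounds."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    p = len(beta)
    if covariate_law == "normal":
        X = rng.standard_normal((n, p))
    elif covariate_law == "uniform":
        X = rng.uniform(0, 1, size=(n, p))
    else:
        raise ValueError(f"unknown covariate law {covariate_law!r}")
    y_star = alpha + X @ beta + rng.normal(0, sigma, size=n)
    lower, upper = censor_bounds
    y = y_star.copy()
    if lower is not None and np.isfinite(lower):
        y = np.maximum(y, lower)
    if upper is not None:
        y = np.minimum(y, upper)
    data = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
    data["y"] = y
    data["y_star"] = y_star
    truth = SyntheticTruth(generator="tobit", seed=seed, alpha=alpha,
                           beta=beta, sigma=sigma,
                           params=dict(n=n, censor_bounds=censor_bounds))
    return data, truth


def paper_scale_scenario(seed: int = 0):
    """The bundled 31-unit x 8-year x 5-input x 5-output scenario used for
    end-to-end runs: frontier panel plus a random planar-ish contiguity."""
    panel, truth = generate_frontier_panel(
        n_units=31, n_years=8, m_inputs=5, s_outputs=5,
        inefficiency_sd=0.2, tech_drift=0.02, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    n = 31
    # ring plus random chords: connected, sparse, symmetric
    wmat = np.zeros((n, n))
    for i in range(n):
        wmat[i, (i + 1) % n] = wmat[(i + 1) % n, i] = 1.0
    for _ in range(n):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            wmat[i, j] = wmat[j, i] = 1.0
    w = SpatialWeights(panel.unit_ids, wmat)
    return panel, w, truth
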