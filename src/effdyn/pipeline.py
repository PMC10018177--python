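"""End-to-end orchestration of the efficiency-dynamics workflow.

Stage order (each stage writes a CSV/text artifact and is recorded in the
run manifest):

1. ``dea``         — per-year TE/PTE/SE/RTS/super-SBM scores for the total,
                     human-input, and non-human-input series
2. ``malmquist``   — chained Malmquist decomposition over the horizon
3. ``transitions`` — quantile states, per-period Markov matrices, and the
                     spatially conditioned matrices
4. ``homogeneity`` — Anderson–Goodman time-homogeneity test report
5. ``moran``       — global Moran's I per year and series
6. ``lisa``        — local statistics and effect labels for the final year
7. ``tobit``       — censored regression of efficiency on (normalized)
                     panel inputs

A stage failure halts its dependents but completed artifacts are kept and
flagged in the manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dea, dynamics, malmquist, spatial, tobit
from .panel import PanelDataset, SpatialWeights, read_panel, read_schema, read_weights
from .synthetic import paper_scale_scenario

log = logging.getLogger(__name__)

SERIES_CLASSES = {"total": None, "human": "human", "nonhuman": "non_human"}


class ConfigError(ValueError):
    """The run configuration is invalid (exit code 2)."""


@dataclass
class RunConfig:
    out_dir: str
    panel: str | None = None
    schema: str | None = None
    weights: str | None = None
    scenario: str | None = None
    seed: int = 0
    k: int = 4
    n_perm: int = 199
    breakpoint: int | None = None          # first year of the second period
    series: list[str] = field(default_factory=lambda: ["total", "human", "nonhuman"])
    tobit_response: str = "TE"
    tobit_normalize: str = "minmax"
    tobit_censor: tuple = (0.0, None)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        cfg = cls(**raw)
        if isinstance(cfg.tobit_censor, list):
            cfg.tobit_censor = tuple(cfg.tobit_censor)
        return cfg

    def validate(self) -> None:
        if self.scenario is None:
            for key in ("panel", "schema", "weights"):
                val = getattr(self, key)
                if val is None:
                    raise ConfigError(f"config needs {key} (or a scenario)")
                if not Path(val).exists():
                    raise ConfigError(f"{key} file not found: {val}")
        elif self.scenario != "paper-scale":
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if any(s not in SERIES_CLASSES for s in self.series):
            raise ConfigError(f"series must be among {list(SERIES_CLASSES)}")


def _load_inputs(cfg: RunConfig) -> tuple[PanelDataset, SpatialWeights]:
    if cfg.scenario == "paper-scale":
        panel, w, _truth = paper_scale_scenario(seed=cfg.seed)
        return panel, w
    panel = read_panel(cfg.panel, read_schema(cfg.schema))
    fmt = "gal" if str(cfg.weights).endswith(".gal") else "dense_csv"
    w = read_weights(cfg.weights, format=fmt).align_to(panel.unit_ids)
    return panel, w


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({k: getattr(cfg, k) for k in cfg.__dataclass_fields__}, fh)

    manifest: dict = {"stages": {}, "seed": cfg.seed, "outputs": []}

    def record(stage, status, path=None, t0=None, error=None):
        manifest["stages"][stage] = {
            "status": status,
            "seconds": round(time.perf_counter() - t0, 3) if t0 else None,
            "output": str(path) if path else None,
            "error": error,
        }
        if path:
            manifest["outputs"].append(str(path))

    panel, w = _load_inputs(cfg)
    ws = w.row_standardize()

    score_frames: dict[str, pd.DataFrame] = {}
    failed = False

    # --- stage 1: DEA per year and series -------------------------------
    t0 = time.perf_counter()
    try:
        tables = []
        for series in cfg.series:
            cls = SERIES_CLASSES[series]
            per_year = [dea.solve_year(panel, y, cls) for y in panel.years]
            tab = pd.concat(per_year, ignore_index=True)
            tab.insert(0, "series", series)
            tables.append(tab)
            score_frames[series] = tab.pivot(index="unit", columns="year",
                                             values="SBM").loc[panel.unit_ids]
        dea_path = out / "dea_scores.csv"
        pd.concat(tables, ignore_index=True).to_csv(dea_path, index=False)
        record("dea", "ok", dea_path, t0)
    except Exception as exc:
        log.exception("DEA stage failed")
        record("dea", "failed", error=str(exc), t0=t0)
        failed = True

    # --- stage 2: Malmquist ---------------------------------------------
    t0 = time.perf_counter()
    if failed:
        record("malmquist", "skipped")
    else:
        try:
            mq = malmquist.chain_over_horizon(panel, panel.years[0], panel.years[-1])
            mq_path = out / "malmquist.csv"
            mq.to_csv(mq_path, index=False)
            record("malmquist", "ok", mq_path, t0)
        except Exception as exc:
            log.exception("Malmquist stage failed")
            record("malmquist", "failed", error=str(exc), t0=t0)

    # --- stages 3-4: distribution dynamics ------------------------------
    t0 = time.perf_counter()
    if failed:
        record("transitions", "skipped")
        record("homogeneity", "skipped")
    else:
        try:
            bp = cfg.breakpoint or panel.years[len(panel.years) // 2]
            rows = []
            homo_lines = []
            for series, scores in score_frames.items():
                sp = dynamics.classify_states(scores, k=cfg.k)
                for years, label in (
                    ([y for y in panel.years if y < bp], f"{panel.years[0]}-{bp - 1}"),
                    ([y for y in panel.years if y >= bp], f"{bp}-{panel.years[-1]}"),
                ):
                    tm = dynamics.estimate_transitions(sp, years, period=label)
                    rows += _transition_rows(tm, series, label, condition="all")
                for tm in dynamics.spatial_markov(scores, ws, k=cfg.k):
                    rows += _transition_rows(tm, series, "all", tm.condition)
                ht = dynamics.time_homogeneity_test(sp, breakpoints=[bp])
                homo_lines.append(
                    f"{series}: chi2={ht.chi2:.3f} (p={ht.p_chi2:.4f}), "
                    f"LR={ht.lr:.3f} (p={ht.p_lr:.4f}), df={ht.df}"
                )
            tr_path = out / "transitions.csv"
            pd.DataFrame(rows).to_csv(tr_path, index=False)
            record("transitions", "ok", tr_path, t0)
            t0 = time.perf_counter()
            homo_path = out / "homogeneity.txt"
            homo_path.write_text("\n".join(homo_lines) + "\n")
            record("homogeneity", "ok", homo_path, t0)
        except Exception as exc:
            log.exception("dynamics stage failed")
            record("transitions", "failed", error=str(exc), t0=t0)
            record("homogeneity", "skipped")

    # --- stage 5: Moran per year ----------------------------------------
    t0 = time.perf_counter()
    if failed:
        record("moran", "skipped")
        record("lisa", "skipped")
    else:
        try:
            mt = spatial.moran_by_year(score_frames, ws, n_perm=cfg.n_perm,
                                       seed=cfg.seed)
            moran_path = out / "moran.csv"
            mt.to_csv(moran_path, index=False)
            record("moran", "ok", moran_path, t0)
            t0 = time.perf_counter()
            last = panel.years[-1]
            lisa_rows = []
            for series, scores in score_frames.items():
                lr = spatial.local_morans_i(scores[last].to_numpy(), ws,
                                            n_perm=cfg.n_perm, seed=cfg.seed)
                effects = spatial.label_effects(lr)
                for u, li, quad, p, eff in zip(lr.unit_ids, lr.lisa,
                                               lr.quadrant, lr.p_values, effects):
                    lisa_rows.append({"series": series, "unit": u, "year": last,
                                      "lisa": li, "quadrant": quad, "p": p,
                                      "effect": eff})
            lisa_path = out / "lisa.csv"
            pd.DataFrame(lisa_rows).to_csv(lisa_path, index=False)
            record("lisa", "ok", lisa_path, t0)
        except Exception as exc:
            log.exception("spatial stage failed")
            record("moran", "failed", error=str(exc), t0=t0)
            record("lisa", "skipped")

    # --- stage 6: Tobit --------------------------------------------------
    t0 = time.perf_counter()
    if failed:
        record("tobit", "skipped")
    else:
        try:
            resp_series = "total" if "total" in score_frames else cfg.series[0]
            resp = score_frames[resp_series].stack()
            resp_units = resp.index.get_level_values(0)
            xvars = panel.variables_by("input")
            design = panel.data.pivot_table(
                index=["unit", "year"], columns="variable", values="value"
            )[xvars].loc[resp.index]
            norm, _rec = tobit.normalize_design(design, cfg.tobit_normalize)
            lower, upper = cfg.tobit_censor
            fit = tobit.fit_tobit(norm, resp.to_numpy(),
                                  lower=lower if lower is not None else -np.inf,
                                  upper=upper, names=xvars,
                                  cluster=resp_units.to_numpy())
            table = tobit.report_fit(fit, digits=4)
            table.loc[len(table)] = {"variable": "LR", "coef": round(fit.lr, 4)}
            table.loc[len(table)] = {"variable": "pseudo_R2",
                                     "coef": round(fit.pseudo_r2, 4)}
            tob_path = out / "tobit.csv"
            table.to_csv(tob_path, index=False)
            record("tobit", "ok", tob_path, t0)
        except Exception as exc:
            log.exception("tobit stage failed")
            record("tobit", "failed", error=str(exc), t0=t0)

    manifest["ok"] = all(v["status"] == "ok" for v in manifest["stages"].values())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _transition_rows(tm: dynamics.TransitionModel, series, period, condition):
    labels = dynamics.state_labels(tm.k)
    probs = tm.probabilities
    rows = []
    for i in range(tm.k):
        for j in range(tm.k):
            rows.append({
                "series": series, "period": period, "condition": condition,
                "from": labels[i], "to": labels[j],
                "count": int(tm.counts[i, j]),
                "prob": None if np.isnan(probs[i, j]) else round(probs[i, j], 6),
            })
    return rows


def summarize_run(manifest: dict) -> str:
    """Human-readable report over a completed (or partial) run manifest."""
    lines = ["# Run summary", ""]
    incomplete = [s for s, v in manifest["stages"].items() if v["status"] != "ok"]
    if incomplete:
        lines.append(f"Incomplete stages: {', '.join(incomplete)}")
        lines.append("")
    for stage, info in manifest["stages"].items():
        lines.append(f"## {stage}: {info['status']}"
                     + (f" ({info['seconds']}s)" if info.get("seconds") else ""))
        path = info.get("output")
        if info["status"] != "ok" or not path:
            if info.get("error"):
                lines.append(f"error: {info['error']}")
            lines.append("")
            continue
        p = Path(path)
        if p.suffix == ".csv":
            df = pd.read_csv(p)
            lines.append(f"{len(df)} rows x {len(df.columns)} cols from {p.name}")
            if stage == "dea":
                eff = df[df["TE"] >= 1 - 1e-6].groupby("year")["unit"].count()
                lines.append("efficient units per year (total series): "
                             + ", ".join(f"{y}:{c}" for y, c in eff.items()))
            if stage == "malmquist":
                means = df[malmquist.COMPONENTS].mean()
                lines.append("geometric-mean components: "
                             + ", ".join(f"{k}={v:.3f}" for k, v in means.items()))
        elif p.exists():
            lines.append(p.read_text().strip())
        lines.append("")
    return "\n".join(lines)
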