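"""Monte Carlo parameter sweeps coupling decisions to epidemic outcomes.

A sweep runs the decision dynamics to steady state over a grid of
(cost ratio r, conformity rate p, initial willingness w0, reproduction
number R0) cells, with independent replicates per cell, and then feeds the
cell's mean vaccination coverage into the SIR module to obtain the disease
attack rate.

Reproducibility: every replicate's RNG is seeded from
``numpy.random.SeedSequence(base_seed, spawn_key=(ri, pi, wi, Ri, rep))``
where the indices are the cell's positions in the grids, so any cell can
be recomputed in isolation and identical specs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epidemic
from .decision import DecisionParams, _Workspace, run
from .epidemic import SIRParams, integrate_sir
from .network import (
    HIGHSCHOOL,
    ContactNetwork,
    GeneratorSpec,
    generate_synthetic,
    read_edge_list,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "coverage_phase_profile",
    "write_results",
    "load_config",
]

log = logging.getLogger(__name__)

RAW_COLUMNS = ["r", "p", "w0", "R0", "replicate", "coverage", "termination_reason"]


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a Monte Carlo sweep.

    ``beta_perc=None`` (default) derives the perceived transmission rate
    from each cell's R0 as ``R0 * gamma`` (perception matches the actual
    disease), so decision dynamics are re-run per R0; a fixed number
    decouples perception from R0 and the same decision runs serve every
    R0.
    """

    r_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    p_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    w0_levels: tuple[float, ...] = (0.3, 0.5, 0.7)
    R0_list: tuple[float, ...] = (epidemic.DEFAULT_R0,)
    replicates: int = 50
    base_seed: int = 0
    network_path: str | None = None
    generator: GeneratorSpec = HIGHSCHOOL
    gamma: float = epidemic.DEFAULT_GAMMA
    beta_perc: float | None = None
    kappa: float = 0.1
    sit_exponent: float = 0.5
    max_iters: int = 200
    window: int = 50
    i0_fraction: float = 1e-4
    per_replicate_attack: bool = False

    def __post_init__(self):
        for name, grid, lo, hi in [
            ("r_grid", self.r_grid, 0.0, 1.0),
            ("p_grid", self.p_grid, 0.0, 1.0),
            ("w0_levels", self.w0_levels, 0.0, 1.0),
        ]:
            if len(grid) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(not lo <= g <= hi for g in grid):
                raise ValueError(f"{name} values must lie in [{lo}, {hi}]")
        if len(self.R0_list) == 0 or any(R <= 0 for R in self.R0_list):
            raise ValueError("R0_list must be non-empty and positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def network(self) -> ContactNetwork:
        if self.network_path is not None:
            return read_edge_list(self.network_path)
        return generate_synthetic(self.generator, seed=self.base_seed)

    def cell_rng(
        self, ri: int, pi: int, wi: int, Ri: int, rep: int
    ) -> np.random.Generator:
        """Independently reproducible RNG for one replicate of one cell."""
        seq = np.random.SeedSequence(
            self.base_seed, spawn_key=(ri, pi, wi, Ri, rep)
        )
        return np.random.default_rng(seq)


@dataclass
class SweepResult:
    """Raw per-replicate rows and per-cell aggregates of a sweep."""

    raw: pd.DataFrame
    aggregated: pd.DataFrame
    spec: SweepSpec
    elapsed_seconds: float = 0.0


def _decision_params(spec: SweepSpec, r: float, p: float, w0: float, R0: float
                     ) -> DecisionParams:
    beta = spec.beta_perc if spec.beta_perc is not None else R0 * spec.gamma
    return DecisionParams(
        r=r,
        p=p,
        beta_perc=min(1.0, beta),
        kappa=spec.kappa,
        w0=w0,
        sit_exponent=spec.sit_exponent,
        max_iters=spec.max_iters,
        window=spec.window,
    )


def _attack_rate(spec: SweepSpec, R0: float, coverage: float) -> float:
    i0 = spec.i0_fraction
    V = min(coverage, 1.0 - i0)
    params = SIRParams(beta=R0 * spec.gamma, gamma=spec.gamma, N=1.0, V=V, I0=i0)
    return integrate_sir(params).attack_rate


def run_sweep(spec: SweepSpec, network: ContactNetwork | None = None) -> SweepResult:
    """Run the full sweep; every replicate is logged-on-failure rather than
    silently dropped, and failed cells carry NaN coverage."""
    t_start = time.perf_counter()
    net = network if network is not None else spec.network()
    ws = _Workspace(net)
    shared_decisions = spec.beta_perc is not None
    rows = []
    for ri, r in enumerate(spec.r_grid):
        for pi, p in enumerate(spec.p_grid):
            for wi, w0 in enumerate(spec.w0_levels):
                for Ri, R0 in enumerate(spec.R0_list):
                    if shared_decisions and Ri > 0:
                        # decisions do not depend on R0: reuse the Ri=0 rows
                        base = [row for row in rows
                                if row[:4] == (r, p, w0, spec.R0_list[0])]
                        rows.extend(
                            (r, p, w0, R0, rep, cov, reason)
                            for (_, _, _, _, rep, cov, reason) in base
                        )
                        continue
                    params = _decision_params(spec, r, p, w0, R0)
                    t_cell = time.perf_counter()
                    for rep in range(spec.replicates):
                        rng = spec.cell_rng(ri, pi, wi, 0 if shared_decisions else Ri, rep)
                        try:
                            res = run(net, params, rng, workspace=ws)
                            rows.append(
                                (r, p, w0, R0, rep, res.coverage,
                                 res.termination_reason)
                            )
                        except Exception:
                            log.exception(
                                "replicate failed at r=%s p=%s w0=%s R0=%s rep=%d",
                                r, p, w0, R0, rep,
                            )
                            rows.append((r, p, w0, R0, rep, np.nan, "failed"))
                    log.info(
                        "cell r=%.2f p=%.2f w0=%.2f R0=%.2f: %d replicates in %.2fs",
                        r, p, w0, R0, spec.replicates,
                        time.perf_counter() - t_cell,
                    )
    raw = pd.DataFrame(rows, columns=RAW_COLUMNS)
    aggregated = _aggregate(raw, spec)
    return SweepResult(
        raw=raw,
        aggregated=aggregated,
        spec=spec,
        elapsed_seconds=time.perf_counter() - t_start,
    )


def _aggregate(raw: pd.DataFrame, spec: SweepSpec) -> pd.DataFrame:
    groups = raw.groupby(["r", "p", "w0", "R0"], sort=True)
    out = []
    for (r, p, w0, R0), g in groups:
        cov = g["coverage"].dropna()
        mean_cov = float(cov.mean()) if len(cov) else np.nan
        se = float(cov.std(ddof=1) / np.sqrt(len(cov))) if len(cov) > 1 else 0.0
        if spec.per_replicate_attack:
            attack = float(
                np.mean([_attack_rate(spec, R0, c) for c in cov])
            ) if len(cov) else np.nan
        else:
            attack = _attack_rate(spec, R0, mean_cov) if np.isfinite(mean_cov) else np.nan
        reasons = g["termination_reason"].value_counts().to_dict()
        if reasons.get("max_iters", 0) and all(g["p"] == 0):
            log.warning("non-converged p=0 cell at r=%s w0=%s", r, w0)
        out.append(
            {
                "r": r, "p": p, "w0": w0, "R0": R0,
                "mean_coverage": mean_cov,
                "coverage_se": se,
                "attack_rate": attack,
                "n_replicates": int(len(g)),
                "n_fixed_point": int(reasons.get("fixed_point", 0)),
                "n_two_cycle": int(reasons.get("two_cycle", 0)),
                "n_max_iters": int(reasons.get("max_iters", 0)),
                "n_failed": int(reasons.get("failed", 0)),
            }
        )
    return pd.DataFrame(out)


def coverage_phase_profile(
    result: SweepResult, p_fixed: float = 1.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Coverage as a function of initial willingness at a fixed conformity
    rate (default: absolute social followers).

    Returns ``(w0 values, mean coverage per w0, transition point)`` where
    the transition point is the midpoint of the largest jump between
    adjacent w0 levels — the estimated location of the critical phase
    transition in coverage.
    """
    agg = result.aggregated
    sel = agg[np.isclose(agg["p"], p_fixed)]
    if sel.empty:
        raise ValueError(f"sweep contains no p = {p_fixed} cells")
    prof = sel.groupby("w0")["mean_coverage"].mean()
    w0 = prof.index.to_numpy(dtype=float)
    cov = prof.to_numpy(dtype=float)
    if len(w0) < 2:
        return w0, cov, float(w0[0])
    jumps = np.abs(np.diff(cov))
    k = int(np.argmax(jumps))
    return w0, cov, float((w0[k] + w0[k + 1]) / 2.0)


def write_results(result: SweepResult, out_dir: str | Path) -> None:
    """Write ``sweep_raw.csv``, ``sweep_agg.csv`` and a reproducibility
    manifest; identical specs produce identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.raw.to_csv(out / "sweep_raw.csv", index=False)
    result.aggregated.to_csv(out / "sweep_agg.csv", index=False)
    from . import __version__

    spec_dict = dataclasses.asdict(result.spec)
    manifest = {
        "package": "vaxgame",
        "version": __version__,
        "base_seed": result.spec.base_seed,
        "seed_scheme": "SeedSequence(base_seed, spawn_key=(ri, pi, wi, Ri, rep))",
        "spec": spec_dict,
        "elapsed_seconds": round(result.elapsed_seconds, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
        fh.write("\n")


def load_config(path: str | Path) -> SweepSpec:
    """Build a :class:`SweepSpec` from a flat YAML config with optional
    ``network``, ``decision``, ``epidemic``, ``sweep`` and ``output``
    sections; unknown keys raise."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    net = cfg.get("network", {})
    if "path" in net:
        kwargs["network_path"] = net["path"]
    gen_keys = {k: net[k] for k in
                ("n_nodes", "mean_degree", "mean_weight", "weight_sigma",
                 "topology", "rewire") if k in net}
    if gen_keys:
        kwargs["generator"] = GeneratorSpec(**gen_keys)
    dec = cfg.get("decision", {})
    for k in ("kappa", "sit_exponent", "max_iters", "window", "beta_perc"):
        if k in dec:
            kwargs[k] = dec[k]
    epi = cfg.get("epidemic", {})
    if "gamma" in epi:
        kwargs["gamma"] = epi["gamma"]
    if "i0_fraction" in epi:
        kwargs["i0_fraction"] = epi["i0_fraction"]
    sweep = cfg.get("sweep", {})
    for src_key, dst_key in [
        ("r_grid", "r_grid"), ("p_grid", "p_grid"),
        ("w0_levels", "w0_levels"), ("R0_list", "R0_list"),
        ("replicates", "replicates"), ("base_seed", "base_seed"),
        ("per_replicate_attack", "per_replicate_attack"),
    ]:
        if src_key in sweep:
            val = sweep[src_key]
            kwargs[dst_key] = tuple(val) if isinstance(val, list) else val
    known = {"network", "decision", "epidemic", "sweep", "output"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return SweepSpec(**kwargs)
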