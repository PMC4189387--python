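"""Sweep orchestration: ISI feature tables over (model, current, area) grids.

Reproduces the comparison protocol of the simulation study: for a fixed
current the noise level is swept through the membrane area (noise s.d.
proportional to area^-1/2), and for a fixed area the deterministic drive
is swept through the applied current.  Each grid cell runs its own
deterministically derived child seed, so cells can execute in any order
with identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .common import SimConfig, child_seed, get_simulator
from .isi import extract_features
from .params import HHParameters

__all__ = ["SweepSpec", "run_sweep", "compare_models"]

COLUMNS = [
    "model", "I", "area", "NK", "NNa",
    "tail_exponent", "tail_se", "run_probability",
    "peak_location", "bump_spacing", "t_cut", "t0",
    "n_isi", "seed", "error",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid of (model, current, area) cells with a pooled ISI target per cell."""

    models: tuple[str, ...]
    currents: tuple[float, ...]
    areas: tuple[float, ...]
    n_isis: int = 1000
    dt: float = 0.005
    seed: int = 0
    ensemble: int = 4
    base_params: HHParameters = field(default_factory=HHParameters)

    def __post_init__(self) -> None:
        if self.n_isis < 500:
            raise ValueError("per-cell ISI target must be >= 500")


def _cell_seed(spec: SweepSpec, model: str, I: float, area: float) -> int:
    return child_seed(spec.seed, model, int(round(I * 1000)), int(round(area * 1000)))


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Simulate every grid cell to the ISI target and extract features.

    Failures in a cell are recorded in its ``error`` column and the sweep
    continues.  Fully reproducible given the master seed.
    """
    rows = []
    for model in spec.models:
        for I in spec.currents:
            for area in spec.areas:
                params = spec.base_params.with_area(area)
                seed = _cell_seed(spec, model, I, area)
                row = {
                    "model": model, "I": I, "area": area,
                    "NK": params.NK, "NNa": params.NNa,
                    "seed": seed, "error": "",
                }
                try:
                    sim = get_simulator(model)
                    cfg = SimConfig(
                        I=I, params=params, dt=spec.dt, seed=seed,
                        target_isis=spec.n_isis, ensemble=spec.ensemble,
                    )
                    res = sim(cfg)
                    f = extract_features(res.isis)
                    row.update(
                        tail_exponent=f.tail_exponent, tail_se=f.tail_se,
                        run_probability=f.run_probability,
                        peak_location=f.peak_location,
                        bump_spacing=f.bump_spacing,
                        t_cut=f.t_cut, t0=f.t0, n_isi=f.n_isi,
                    )
                except Exception as exc:  # cell failure stays in-table
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def compare_models(tables: dict[str, pd.DataFrame], reference: str) -> pd.DataFrame:
    """Per-cell differences of tail exponent and run probability vs a
    reference model's table, with pooled Monte-Carlo uncertainty.

    All tables must cover the same (I, area) grid.
    """
    if reference not in tables:
        raise ValueError(f"reference model {reference!r} not among tables")
    ref = tables[reference].set_index(["I", "area"]).sort_index()
    out = []
    for name, tab in tables.items():
        t = tab.set_index(["I", "area"]).sort_index()
        if not t.index.equals(ref.index):
            raise ValueError(
                f"grid of {name!r} does not match reference {reference!r}"
            )
        d = pd.DataFrame(index=t.index)
        d["model"] = name
        d["d_tail_exponent"] = t["tail_exponent"] - ref["tail_exponent"]
        d["d_run_probability"] = t["run_probability"] - ref["run_probability"]
        d["d_tail_se"] = np.sqrt(t["tail_se"] ** 2 + ref["tail_se"] ** 2)
        n = t["n_isi"].astype(float)
        p1, p0 = t["run_probability"], ref["run_probability"]
        d["d_run_se"] = np.sqrt(p1 * (1 - p1) / n + p0 * (1 - p0) / ref["n_isi"].astype(float))
        d["available"] = ~(t["error"].astype(bool) | ref["error"].astype(bool))
        out.append(d.reset_index())
    return pd.concat(out, ignore_index=True)
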