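"""Simulation-study generator: clean PKPD curves plus Gaussian-noise replicates.

The default :class:`SimulationDesign` reproduces the validation study the
method was tested on: six conditions — one null (e_max = 0) and five
responsive tissues with EC50 in {0.25, 0.6, 2, pi, 7.5} at e_max = 10 —
driven by four unit-peak doses at 0/10/20/30 min (t_half = 41 min,
t_shift = 0.5 min, Hill n = 1), a quadratic baseline 1000 + 0.05 t, and
eight noise SD levels spanning 0.01*e_max to 2*e_max, with 1000 noisy
replicates per (condition, noise) cell: 48,000 noisy curves plus the 6
clean ones.

Noise is reproducible and order-independent: a master seed spawns one
dedicated RNG substream per (condition, noise level, replicate) triple.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .model import (
    BaselineParams,
    DoseSchedule,
    EffectParams,
    KineticParams,
    TimeCourse,
    model_signal,
)

__all__ = [
    "DEFAULT_EC50S",
    "DEFAULT_NOISE_SDS",
    "default_schedule",
    "SimulationDesign",
    "generate_clean_curve",
    "iter_noisy_curves",
    "generate_noisy_curves",
    "write_dataset",
    "read_dataset",
    "design_to_dict",
    "design_from_dict",
]

DEFAULT_EC50S: tuple[float, ...] = (0.25, 0.6, 2.0, math.pi, 7.5)
#: eight approximately log-spaced SDs covering 0.01*e_max .. 2*e_max for e_max=10
DEFAULT_NOISE_SDS: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


def default_schedule() -> DoseSchedule:
    """Four unit-peak doses at 0, 10, 20 and 30 minutes."""
    return DoseSchedule(dose_peaks=(1.0, 1.0, 1.0, 1.0), dose_times=(0.0, 10.0, 20.0, 30.0))


@dataclass
class SimulationDesign:
    """Full specification of a simulation study."""

    ec50_values: tuple[float, ...] = DEFAULT_EC50S
    include_null: bool = True
    e_max: float = 10.0
    noise_sds: tuple[float, ...] = DEFAULT_NOISE_SDS
    replicates: int = 1000
    grid: tuple[float, float, float] = (0.0, 40.0, 0.25)  # (t0, t_end, dt)
    schedule: DoseSchedule = field(default_factory=default_schedule)
    kin: KineticParams = field(default_factory=KineticParams)
    baseline: BaselineParams = field(default_factory=lambda: BaselineParams(1000.0, 0.05, 0.0))
    seed: int = 0

    def __post_init__(self) -> None:
        self.ec50_values = tuple(float(x) for x in self.ec50_values)
        self.noise_sds = tuple(float(s) for s in self.noise_sds)
        if any(x <= 0 for x in self.ec50_values):
            raise ValueError("ec50_values must be positive")
        if any(s <= 0 for s in self.noise_sds):
            raise ValueError("noise_sds must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def times(self) -> np.ndarray:
        t0, t_end, dt = self.grid
        return np.arange(t0, t_end + dt / 2, dt)

    def conditions(self) -> list[tuple[str, EffectParams]]:
        """Ordered (label, effect-parameters) pairs; the null condition first."""
        out: list[tuple[str, EffectParams]] = []
        if self.include_null:
            out.append(("null", EffectParams(e_max=0.0, q=0.0)))
        for ec50 in self.ec50_values:
            out.append((f"ec50={ec50:g}", EffectParams.from_ec50(self.e_max, ec50)))
        return out

    @property
    def n_noisy(self) -> int:
        return len(self.conditions()) * len(self.noise_sds) * self.replicates


def _curve_rng(design: SimulationDesign, ci: int, ni: int, rep: int) -> np.random.Generator:
    # independent substream per (condition, noise level, replicate); stable
    # under any generation order or parallel partitioning
    ss = np.random.SeedSequence(entropy=int(design.seed), spawn_key=(ci, ni, rep))
    return np.random.default_rng(ss)


def generate_clean_curve(condition: EffectParams, design: SimulationDesign) -> TimeCourse:
    """Noise-free forward-model curve on the design's sampling grid."""
    t = design.times
    y = model_signal(t, design.schedule, design.kin, condition, design.baseline)
    meta = {
        "condition": "null" if condition.e_max == 0 else f"ec50={condition.ec50:g}",
        "e_max": condition.e_max,
        "ec50": None if condition.e_max == 0 else condition.ec50,
        "noise_sd": 0.0,
        "replicate": None,
    }
    return TimeCourse(times=t, values=np.asarray(y), meta=meta)


def iter_noisy_curves(
    design: SimulationDesign, include_clean: bool = False
) -> Iterator[TimeCourse]:
    """Yield every curve of the study (optionally the clean ones first)."""
    conditions = design.conditions()
    if include_clean:
        for _, eff in conditions:
            yield generate_clean_curve(eff, design)
    t = design.times
    for ci, (label, eff) in enumerate(conditions):
        clean = np.asarray(model_signal(t, design.schedule, design.kin, eff, design.baseline))
        for ni, sd in enumerate(design.noise_sds):
            for rep in range(design.replicates):
                rng = _curve_rng(design, ci, ni, rep)
                values = clean + rng.normal(0.0, sd, size=t.size)
                meta = {
                    "condition": label,
                    "e_max": eff.e_max,
                    "ec50": None if eff.e_max == 0 else eff.ec50,
                    "noise_sd": sd,
                    "replicate": rep,
                    "seed": design.seed,
                }
                yield TimeCourse(times=t, values=values, meta=meta)


def generate_noisy_curves(
    design: SimulationDesign, include_clean: bool = False
) -> list[TimeCourse]:
    """Materialize the whole study as a list (see :func:`iter_noisy_curves`)."""
    return list(iter_noisy_curves(design, include_clean=include_clean))


def _curve_id(tc: TimeCourse, index: int) -> str:
    meta = tc.meta or {}
    cond = meta.get("condition", "curve")
    sd = meta.get("noise_sd")
    rep = meta.get("replicate")
    parts = [f"{index:06d}", str(cond)]
    if sd is not None:
        parts.append(f"sd={sd:g}")
    if rep is not None:
        parts.append(f"rep={rep}")
    return "_".join(parts)


def design_to_dict(design: SimulationDesign) -> dict:
    """JSON-serializable record of a design (for dataset manifests)."""
    return {
        "ec50_values": list(design.ec50_values),
        "include_null": design.include_null,
        "e_max": design.e_max,
        "noise_sds": list(design.noise_sds),
        "replicates": design.replicates,
        "grid": list(design.grid),
        "schedule": {
            "dose_peaks": list(design.schedule.dose_peaks),
            "dose_times": list(design.schedule.dose_times),
        },
        "kin": {
            "t_half": design.kin.t_half,
            "t_shift": design.kin.t_shift,
            "hill": design.kin.hill,
        },
        "baseline": {"a0": design.baseline.a0, "a1": design.baseline.a1, "a2": design.baseline.a2},
        "seed": design.seed,
    }


def design_from_dict(d: dict) -> SimulationDesign:
    """Inverse of :func:`design_to_dict`."""
    return SimulationDesign(
        ec50_values=tuple(d["ec50_values"]),
        include_null=bool(d.get("include_null", True)),
        e_max=float(d.get("e_max", 10.0)),
        noise_sds=tuple(d["noise_sds"]),
        replicates=int(d["replicates"]),
        grid=tuple(d["grid"]),
        schedule=DoseSchedule(
            dose_peaks=tuple(d["schedule"]["dose_peaks"]),
            dose_times=tuple(d["schedule"]["dose_times"]),
        ),
        kin=KineticParams(**d["kin"]),
        baseline=BaselineParams(**d["baseline"]),
        seed=int(d.get("seed", 0)),
    )


def write_dataset(
    curves: list[TimeCourse], path: str | Path, design: SimulationDesign | None = None
) -> Path:
    """Write curves as a long-format CSV plus a JSON manifest sidecar.

    CSV columns: curve_id, time_min, value.  The sidecar (same stem, .json)
    records per-curve metadata so a round trip is lossless.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    ids = [_curve_id(tc, i) for i, tc in enumerate(curves)]
    if curves:
        frame = pd.concat(
            [
                pd.DataFrame({"curve_id": cid, "time_min": tc.times, "value": tc.values})
                for cid, tc in zip(ids, curves)
            ],
            ignore_index=True,
        )
    else:
        frame = pd.DataFrame(columns=["curve_id", "time_min", "value"])
    frame.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    manifest = {
        "n_curves": len(curves),
        "curves": [{"curve_id": cid, "meta": tc.meta} for cid, tc in zip(ids, curves)],
    }
    if design is not None:
        manifest["design"] = design_to_dict(design)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(path: str | Path) -> list[TimeCourse]:
    """Read a dataset written by :func:`write_dataset` (manifest optional)."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"curve_id", "time_min", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"dataset {path} missing columns {sorted(required - set(frame.columns))}")
    meta_by_id: dict[str, dict] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        manifest = json.loads(sidecar.read_text())
        meta_by_id = {rec["curve_id"]: rec.get("meta", {}) for rec in manifest.get("curves", [])}
    curves = []
    for cid, grp in frame.groupby("curve_id", sort=False):
        try:
            tc = TimeCourse(
                times=grp["time_min"].to_numpy(),
                values=grp["value"].to_numpy(),
                meta=meta_by_id.get(str(cid), {"curve_id": str(cid)}),
            )
        except ValueError as exc:
            raise ValueError(f"malformed record for curve {cid!r}: {exc}") from exc
        tc.meta.setdefault("curve_id", str(cid))
        curves.append(tc)
    return curves
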