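"""Simulation-study harness: run the fit engine over a study and summarize.

Produces the method's standard validation surfaces: per-cell sensitivity
(fraction of curves with prob(full) above threshold), mean model
probability vs SNR, false-positive counts over the null condition, and
EC50 accuracy (mean estimated/input ratio) vs SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .inference import McmcSettings, PriorSpec, QuadratureFitter, model_probabilities
from .model import peak_effect
from .simulate import SimulationDesign, iter_noisy_curves

__all__ = [
    "EvaluationSummary",
    "run_study",
    "sensitivity_surface",
    "accuracy_summary",
    "false_positive_count",
    "accuracy_snr_threshold",
    "summarize",
    "render_report",
]

#: columns of the per-cell summary CSV
CELL_COLUMNS = [
    "ec50", "noise_sd", "snr", "n", "sensitivity", "prob_mean", "prob_sd",
    "ec50_est_mean", "ec50_est_sd", "ratio_mean", "ratio_sd",
]


@dataclass
class EvaluationSummary:
    """Per-cell summary surfaces plus the global false-positive count."""

    cells: pd.DataFrame  # CELL_COLUMNS; null-condition cells have ec50 = NaN
    false_positives: int
    n_null_curves: int
    threshold: float


def _cell_snrs(design: SimulationDesign) -> dict[str, float]:
    """Peak noise-free effect per condition (numerator of every cell SNR)."""
    out = {}
    window = (design.grid[0], design.grid[1])
    for label, eff in design.conditions():
        out[label] = peak_effect(design.schedule, design.kin, eff, window)
    return out


def run_study(
    design: SimulationDesign,
    prior: PriorSpec | None = None,
    engine: Literal["quadrature", "mcmc"] = "quadrature",
    settings: McmcSettings | None = None,
    threshold: float = 0.5,
    checkpoint: str | Path | None = None,
    checkpoint_every: int = 500,
) -> pd.DataFrame:
    """Fit every curve of a simulated study; one row per curve.

    Deterministic given the design seed (and MCMC seed for the sampling
    engine).  Per-curve failures are recorded in the ``error`` column, not
    raised.  If ``checkpoint`` is given, partial results are flushed there
    periodically and already-fitted curves are skipped on rerun.
    """
    prior = prior or PriorSpec()
    peaks = _cell_snrs(design)
    done: set[str] = set()
    rows: list[dict] = []
    if checkpoint is not None and Path(checkpoint).exists():
        prev = pd.read_csv(checkpoint)
        rows = prev.to_dict("records")
        done = set(prev["curve_id"].astype(str))
    fitter = None
    if engine == "quadrature":
        fitter = QuadratureFitter(design.times, design.schedule, prior, threshold=threshold)

    def flush() -> None:
        if checkpoint is not None:
            pd.DataFrame(rows).to_csv(checkpoint, index=False)

    for i, tc in enumerate(iter_noisy_curves(design)):
        meta = tc.meta
        cid = f"{i:06d}_{meta['condition']}_sd={meta['noise_sd']:g}_rep={meta['replicate']}"
        if cid in done:
            continue
        row = {
            "curve_id": cid,
            "condition": meta["condition"],
            "ec50_true": meta["ec50"] if meta["ec50"] is not None else np.nan,
            "noise_sd": meta["noise_sd"],
            "replicate": meta["replicate"],
            "snr": peaks[meta["condition"]] / meta["noise_sd"],
            "error": "",
        }
        try:
            if engine == "quadrature":
                res = fitter.fit(tc)  # type: ignore[union-attr]
            else:
                res = model_probabilities(
                    tc, design.schedule, prior, engine=engine,
                    settings=settings, threshold=threshold,
                )
            row.update(
                prob_full=res.prob_full,
                prob_baseline=res.prob_baseline,
                prob_nosignal=res.prob_nosignal,
                preferred=res.preferred,
                residual_sd=res.residual_sd,
            )
            est = res.estimates
            for name in ("ec50", "q", "ts", "t_half", "e_max", "a0", "a1", "a2"):
                row[f"{name}_ml"] = est[name]["ml"] if est else np.nan
            row["ec50_mean"] = est["ec50"]["mean"] if est else np.nan
        except Exception as exc:  # per-curve failures are data, not crashes
            row["error"] = f"{type(exc).__name__}: {exc}"
            row.update(prob_full=np.nan, prob_baseline=np.nan, prob_nosignal=np.nan)
        rows.append(row)
        if checkpoint is not None and len(rows) % checkpoint_every == 0:
            flush()
    flush()
    return pd.DataFrame(rows)


def _group_cells(results: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return results.groupby(["condition", "noise_sd"], dropna=False, sort=True)


def sensitivity_surface(results: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Fraction of curves per (condition, noise) cell with prob(full) > threshold."""
    recs = []
    if results.empty:
        return pd.DataFrame(
            columns=["condition", "ec50", "noise_sd", "snr", "n", "n_accepted",
                     "sensitivity", "prob_mean", "prob_sd"]
        )
    for (cond, sd), grp in _group_cells(results):
        ok = grp["prob_full"].notna()
        acc = (grp.loc[ok, "prob_full"] > threshold).sum()
        recs.append(
            {
                "condition": cond,
                "ec50": grp["ec50_true"].iloc[0],
                "noise_sd": sd,
                "snr": grp["snr"].iloc[0],
                "n": int(ok.sum()),
                "n_accepted": int(acc),
                "sensitivity": acc / max(int(ok.sum()), 1),
                "prob_mean": grp.loc[ok, "prob_full"].mean(),
                "prob_sd": grp.loc[ok, "prob_full"].std(ddof=0),
            }
        )
    return pd.DataFrame(recs)


def accuracy_summary(results: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """EC50 accuracy per cell over accepted curves (prob(full) > threshold).

    ``ratio_mean`` is the arithmetic mean of estimated/input EC50; cells
    with no accepted curve get NaN (undefined, not zero).
    """
    sig = results[results["ec50_true"].notna()] if not results.empty else results
    recs = []
    if sig.empty:
        return pd.DataFrame(
            columns=["condition", "ec50", "noise_sd", "snr", "n", "n_accepted",
                     "ec50_est_mean", "ec50_est_sd", "ratio_mean", "ratio_sd"]
        )
    for (cond, sd), grp in _group_cells(sig):
        acc = grp[(grp["prob_full"] > threshold) & grp["ec50_ml"].notna()]
        ec50_true = grp["ec50_true"].iloc[0]
        rec = {
            "condition": cond,
            "ec50": ec50_true,
            "noise_sd": sd,
            "snr": grp["snr"].iloc[0],
            "n": len(grp),
            "n_accepted": len(acc),
            "ec50_est_mean": np.nan,
            "ec50_est_sd": np.nan,
            "ratio_mean": np.nan,
            "ratio_sd": np.nan,
        }
        if len(acc):
            est = acc["ec50_ml"]
            ratio = est / ec50_true
            rec.update(
                ec50_est_mean=est.mean(),
                ec50_est_sd=est.std(ddof=0),
                ratio_mean=ratio.mean(),
                ratio_sd=ratio.std(ddof=0),
            )
        recs.append(rec)
    return pd.DataFrame(recs)


def false_positive_count(results: pd.DataFrame, threshold: float = 0.5) -> int:
    """Number of null-condition (e_max = 0) curves with prob(full) > threshold."""
    null = results[results["ec50_true"].isna()]
    if null.empty:
        warnings.warn("no null-condition curves in results; false positives = 0")
        return 0
    return int((null["prob_full"] > threshold).sum())


def accuracy_snr_threshold(
    accuracy: pd.DataFrame, band: tuple[float, float] = (2 / 3, 3 / 2)
) -> float:
    """Smallest cell SNR above which every cell's mean EC50 ratio is in band.

    Cells with no accepted curves contribute no accuracy point.  Returns
    ``inf`` if even the highest-SNR cell falls outside the band.
    """
    cells = accuracy[accuracy["ratio_mean"].notna()].sort_values("snr", ascending=False)
    best = np.inf
    for _, row in cells.iterrows():
        if band[0] <= row["ratio_mean"] <= band[1]:
            best = float(row["snr"])
        else:
            break
    return best


def summarize(results: pd.DataFrame, threshold: float = 0.5) -> EvaluationSummary:
    """Combine sensitivity and accuracy surfaces into one per-cell table."""
    sens = sensitivity_surface(results, threshold)
    acc = accuracy_summary(results, threshold)
    merged = sens.merge(
        acc[["condition", "noise_sd", "ec50_est_mean", "ec50_est_sd", "ratio_mean", "ratio_sd"]],
        on=["condition", "noise_sd"],
        how="left",
    )
    cells = merged[CELL_COLUMNS + ["condition", "n_accepted"]]
    null = results[results["ec50_true"].isna()]
    return EvaluationSummary(
        cells=cells,
        false_positives=false_positive_count(results, threshold) if len(null) else 0,
        n_null_curves=len(null),
        threshold=threshold,
    )


def render_report(summary: EvaluationSummary, outdir: str | Path) -> list[Path]:
    """Write the per-cell summary CSV and the four standard figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = outdir / "summary.csv"
    summary.cells.to_csv(csv_path, index=False)
    written.append(csv_path)

    cells = summary.cells
    sig = cells[cells["ec50"].notna()]
    if not sig.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        for ec50, grp in sig.groupby("ec50"):
            g = grp.sort_values("noise_sd")
            ax.plot(g["noise_sd"], g["sensitivity"], "o-", label=f"EC50={ec50:g}")
        ax.set(xscale="log", xlabel="noise SD", ylabel="fraction prob(full) > thr",
               title="Sensitivity")
        ax.legend(fontsize=8)
        fig.savefig(outdir / "sensitivity.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(outdir / "sensitivity.png")

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.errorbar(sig["snr"], sig["prob_mean"], yerr=sig["prob_sd"], fmt="o", ms=4)
        ax.set(xscale="log", xlabel="SNR", ylabel="mean prob(full)",
               title="Model probability vs SNR")
        fig.savefig(outdir / "prob_vs_snr.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(outdir / "prob_vs_snr.png")

        acc = sig[sig["ratio_mean"].notna()]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(acc["ec50"], acc["ec50_est_mean"], s=10 + 4 * acc["snr"].clip(0, 30))
        lim = (acc["ec50"].min() / 2, acc["ec50"].max() * 2) if not acc.empty else (0.1, 10)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set(xscale="log", yscale="log", xlabel="input EC50",
               ylabel="mean estimated EC50", title="Accuracy (marker size ~ SNR)")
        fig.savefig(outdir / "accuracy_vs_input.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(outdir / "accuracy_vs_input.png")

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.errorbar(acc["snr"], acc["ratio_mean"], yerr=acc["ratio_sd"], fmt="o", ms=4)
        for yv in (1.0, 1.5, 2 / 3):
            ax.axhline(yv, color="k", lw=0.8, ls=":" if yv != 1 else "-")
        ax.set(xscale="log", xlabel="SNR", ylabel="estimated / input EC50",
               title="Accuracy ratio vs SNR")
        fig.savefig(outdir / "ratio_vs_snr.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(outdir / "ratio_vs_snr.png")
    return written
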