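"""Publication-style outputs: results tables, trace/CEAC exports, manifests.

Display formatting (whole-dollar rounding, "Dominant" flags) is kept apart
from data exports, which are full-precision CSV.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .psa import CUAResult, DOMINANT, DOMINATED, UNDEFINED
from .states import ARM_ACCELERATED, ARM_STANDARD

__all__ = [
    "results_to_frame",
    "render_results_table",
    "parse_results_table",
    "export_trace",
    "import_trace",
    "export_ceac",
    "import_ceac",
    "RunManifest",
]

_NUMERIC_COLS = [
    "cost_mean",
    "cost_sd",
    "qaly_mean",
    "qaly_sd",
    "delta_cost",
    "delta_cost_sd",
    "delta_qaly",
    "delta_qaly_sd",
    "icer",
    "inmb",
    "inmb_cri_lo",
    "inmb_cri_hi",
]


def results_to_frame(results: dict[str, CUAResult]) -> pd.DataFrame:
    """Numeric results frame, two rows per analysis (accelerated, standard).

    Increments and the ICER/INMB sit on the standard row, mirroring how
    incremental results are conventionally tabulated against the comparator.
    A dominance/undefined ICER is NaN here (the flag column carries it).
    """
    rows = []
    for name, res in results.items():
        for arm in (ARM_ACCELERATED, ARM_STANDARD):
            a = res.arms[arm]
            row: dict = {
                "analysis": name,
                "arm": arm,
                "cost_mean": a["cost_mean"],
                "cost_sd": a["cost_sd"],
                "qaly_mean": a["qaly_mean"],
                "qaly_sd": a["qaly_sd"],
            }
            if arm == ARM_STANDARD:
                row.update(
                    delta_cost=res.delta_cost,
                    delta_cost_sd=res.delta_cost_sd,
                    delta_qaly=res.delta_qaly,
                    delta_qaly_sd=res.delta_qaly_sd,
                    icer=res.icer if isinstance(res.icer, float) else np.nan,
                    icer_flag="" if isinstance(res.icer, float) else res.icer,
                    inmb=res.inmb,
                    inmb_cri_lo=res.inmb_cri[0],
                    inmb_cri_hi=res.inmb_cri[1],
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _fmt_money(v: float) -> str:
    return f"{v:,.0f}".replace(",", " ")


def render_results_table(
    results: dict[str, CUAResult], path: str | Path | None = None, fmt: str = "markdown"
) -> str:
    """Render the results as a formatted table (markdown) or data CSV.

    ``fmt="markdown"`` gives the display layout — cost and QALY means with
    SDs, incremental columns, "Dominant"/"Dominated" in the ICER cell where
    applicable, INMB with its 95% credible interval, currency to whole
    dollars.  ``fmt="csv"`` writes the full-precision numeric frame.
    """
    df = results_to_frame(results)
    if fmt == "csv":
        text = df.to_csv(index=False)
    elif fmt == "markdown":
        lines = [
            "| Analysis | Group | Cost, mean (SD), $ | QALYs, mean (SD) | "
            "Incr. cost, $ | Incr. QALYs | ICER, $/QALY | INMB (95% CrI), $ |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for _, r in df.iterrows():
            cost = f"{_fmt_money(r['cost_mean'])} ({_fmt_money(r['cost_sd'])})"
            qaly = f"{r['qaly_mean']:.2f} ({r['qaly_sd']:.2f})"
            if r["arm"] == ARM_STANDARD:
                dc = f"{_fmt_money(r['delta_cost'])} ({_fmt_money(r['delta_cost_sd'])})"
                dq = f"{r['delta_qaly']:.2f} ({r['delta_qaly_sd']:.2f})"
                flag = r.get("icer_flag", "")
                if flag in (DOMINANT, DOMINATED, UNDEFINED):
                    icer = flag.capitalize()
                else:
                    icer = _fmt_money(r["icer"])
                inmb = (
                    f"{_fmt_money(r['inmb'])} "
                    f"({_fmt_money(r['inmb_cri_lo'])} to {_fmt_money(r['inmb_cri_hi'])})"
                )
            else:
                dc = dq = icer = inmb = "NA"
            lines.append(
                f"| {r['analysis']} | {r['arm']} | {cost} | {qaly} | {dc} | {dq} | {icer} | {inmb} |"
            )
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV results table written by :func:`render_results_table`."""
    df = pd.read_csv(path)
    for col in _NUMERIC_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def export_trace(trace: np.ndarray, path: str | Path) -> None:
    """Write a Markov trace as CSV: cycle, then one column per state."""
    from .states import STATES

    df = pd.DataFrame(np.asarray(trace), columns=[s.name for s in STATES])
    df.insert(0, "cycle", np.arange(df.shape[0]))
    df.to_csv(path, index=False)


def import_trace(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["cycle"]).to_numpy(dtype=float)


def export_ceac(ceac: pd.DataFrame | CUAResult, path: str | Path) -> None:
    """Write the (λ, probability) acceptability curve as CSV."""
    df = ceac.ceac_frame() if isinstance(ceac, CUAResult) else ceac
    df.to_csv(path, index=False)


def import_ceac(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunManifest:
    """Everything needed to byte-reproduce a stochastic run."""

    config: dict
    seed: int | None
    n_sims: int
    calibration_factors: dict[str, float]
    diagnostics: dict = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = ""

    @classmethod
    def from_result(cls, result: CUAResult, config) -> "RunManifest":
        from . import __version__

        diag = dict(result.diagnostics)
        factors = diag.pop("calibration_factors", {})
        return cls(
            config=vars(config) if not isinstance(config, dict) else config,
            seed=result.seed,
            n_sims=result.n_sims,
            calibration_factors=factors,
            diagnostics=diag,
            software_version=f"krtcua {__version__} / python {platform.python_version()}",
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text
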