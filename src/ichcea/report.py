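"""Machine- and human-readable reports with provenance.

Every JSON artifact embeds a digest of the model inputs and an echo of the
economic settings so a result can always be traced back to what produced
it.  Markdown rendering mirrors the usual presentation of a
cost-effectiveness evaluation: per-arm discounted outcomes, increments,
iNMB/ICER, then threshold and scenario tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .analyses import ThresholdResult, TwoWayGrid
from .economics import CeaResult
from .inputs_io import EconSettings, ModelInputs


def inputs_digest(inputs: ModelInputs) -> str:
    """Stable short hash over every numeric input of the model."""
    h = hashlib.sha256()
    c = inputs.cohort
    h.update(repr((c.id, c.mean_entry_age, c.entry_time_months, c.counts)).encode())
    for arr in (inputs.transitions.phase_a, inputs.transitions.phase_b,
                inputs.utilities.mean, inputs.utilities.lower95, inputs.utilities.upper95,
                inputs.costs.mean, inputs.costs.lower95, inputs.costs.upper95,
                inputs.life_table.age, inputs.life_table.qx, inputs.excess.hr):
        h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    h.update(repr(dataclasses.astuple(inputs.econ)).encode())
    return h.hexdigest()[:16]


def settings_echo(inputs: ModelInputs) -> dict:
    return {
        "cohort": inputs.cohort.id,
        "mean_entry_age": inputs.cohort.mean_entry_age,
        "econ": dataclasses.asdict(inputs.econ),
        "excess_hr": [float(x) for x in inputs.excess.hr],
        "inputs_digest": inputs_digest(inputs),
    }


def cea_to_dict(result: CeaResult) -> dict:
    return {
        "usual_care": {"qalys": result.usual_care.qalys, "cost": result.usual_care.cost},
        "mis": {"qalys": result.mis.qalys, "cost": result.mis.cost},
        "delta_qalys": result.delta_qalys,
        "delta_cost": result.delta_cost,
        "inmb": result.inmb,
        "icer": result.icer,
        "dominant": result.dominant,
        "wtp": result.wtp,
    }


def threshold_to_dict(r: ThresholdResult) -> dict:
    return {"point": r.point, "lower95": r.lower95, "upper95": r.upper95,
            "feasible": r.feasible, "n_samples": r.n_samples,
            "n_infeasible": r.n_infeasible, "note": r.note}


def render_json(payload: dict) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    return json.dumps(payload, indent=2, default=default)


def _fmt(x, nd=3):
    if x is None:
        return "-"
    return f"{x:,.{nd}f}" if isinstance(x, float) else str(x)


def render_markdown(payload: dict) -> str:
    """Markdown report from a summary payload (see cli.execute)."""
    lines = [f"# Cost-effectiveness report ({payload.get('command', 'run')})", ""]
    echo = payload.get("settings", {})
    if echo:
        lines += [f"Cohort: {echo.get('cohort')} | inputs digest: {echo.get('inputs_digest')}", ""]
    cea = payload.get("cea")
    if cea:
        lines += ["| arm | QALYs | cost (EUR) |", "|---|---|---|"]
        for arm in ("usual_care", "mis"):
            if arm in cea:
                lines.append(f"| {arm} | {_fmt(cea[arm]['qalys'])} | {_fmt(cea[arm]['cost'], 0)} |")
        lines += ["",
                  f"dQALYs = {_fmt(cea.get('delta_qalys'), 4)}, dCost = {_fmt(cea.get('delta_cost'), 0)}, "
                  f"iNMB = {_fmt(cea.get('inmb'), 0)} at WTP {_fmt(cea.get('wtp'), 0)}", ""]
    thr = payload.get("thresholds")
    if thr:
        lines += ["| quantity | point | 2.5% | 97.5% |", "|---|---|---|---|"]
        for name, r in thr.items():
            if not r.get("feasible", True):
                lines.append(f"| {name} | {r.get('note') or 'infeasible'} | - | - |")
            else:
                lines.append(f"| {name} | {_fmt(r['point'], 4)} | {_fmt(r['lower95'], 4)} | {_fmt(r['upper95'], 4)} |")
        lines.append("")
    psa = payload.get("psa")
    if psa:
        if psa.get("n_samples", 0) == 0:
            lines += ["Deterministic-only run (no probabilistic samples).", ""]
        else:
            lines += [f"PSA with {psa['n_samples']} samples (seed {psa.get('seed')}).", ""]
            lines += ["| quantity | mean | 2.5% | 97.5% |", "|---|---|---|---|"]
            for name, trip in psa.get("summaries", {}).items():
                lines.append(f"| {name} | {_fmt(trip[0], 3)} | {_fmt(trip[1], 3)} | {_fmt(trip[2], 3)} |")
            lines.append("")
    return "\n".join(lines)


def render_report(payload: dict, format: str = "json") -> str:
    if format == "json":
        return render_json(payload)
    if format == "markdown":
        return render_markdown(payload)
    raise ValueError(f"unknown report format {format!r}")


def write_payload(payload: dict, outdir: str | Path, stem: str) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fmt, suffix in (("json", ".json"), ("markdown", ".md")):
        p = out / f"{stem}{suffix}"
        p.write_text(render_report(payload, fmt))
        paths[fmt] = p
    return paths


def plot_two_way(grid: TwoWayGrid, path: str | Path) -> Path:
    """Preferred-strategy map with the break-even curve (and CI band)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.pcolormesh(grid.effectiveness * 100, grid.cost / 1000,
                  (~grid.mis_preferred).T.astype(float), cmap="RdYlGn_r",
                  vmin=-0.2, vmax=1.2, shading="auto")
    ax.plot(grid.effectiveness * 100, np.clip(grid.threshold_cost, *[grid.cost[0], grid.cost[-1]]) / 1000,
            "k-", label="break-even cost")
    if grid.threshold_lower95 is not None:
        for band in (grid.threshold_lower95, grid.threshold_upper95):
            ax.plot(grid.effectiveness * 100, np.clip(band, grid.cost[0], grid.cost[-1]) / 1000, "k--", lw=0.8)
    ax.set_xlabel("absolute improvement to mRS 0-3 (%)")
    ax.set_ylabel("surgical cost (thousand EUR)")
    ax.set_title("Preferred strategy (green: MIS, red: usual care)")
    ax.legend(loc="lower right")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
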