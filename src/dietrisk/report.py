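"""Report rendering: formatted tables, simulation panels, histograms.

Rounding rules: EDI and MOE values in scientific notation at 3
significant figures; HQ and HI at 2 decimal places.  All internal
computation stays at full precision; rounding happens only here.
Machine outputs (CSV/JSON) use plain ``1.26e-05`` notation; the
human-readable text report uses ``1.26 x 10^-5``-style notation with a
proper multiplication sign.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .io import config_hash, write_json
from .montecarlo import SimulationResult
from .pipeline import AssessmentResult, SimulationReport


def round_sig(x: float, sig: int = 3) -> float:
    """Round to *sig* significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def fmt_sci(x: float, sig: int = 3, human: bool = False) -> str:
    """``1.26e-05`` (machine) or ``1.26 × 10⁻⁵``-style (human)."""
    if isinstance(x, str):  # the "unbounded" sentinel
        return x
    if not np.isfinite(x):
        return "unbounded"
    s = f"{x:.{sig - 1}e}"
    if not human:
        return s
    mant, exp = s.split("e")
    return f"{mant} × 10^{int(exp)}"


def fmt_fixed(x: float, decimals: int = 2) -> str:
    return f"{x:.{decimals}f}"


_EDI_COLS = ("edi_mean", "edi_min", "edi_max")
_MOE_COLS = ("moe_mean", "moe_min", "moe_max")
_HQ_COLS = ("hq_mean", "hq_min", "hq_max")


def _rounded_tables(result: AssessmentResult) -> dict[str, pd.DataFrame]:
    """Report tables with display rounding applied (shared by CSV/JSON)."""
    out: dict[str, pd.DataFrame] = {}
    res = result.residue_table.copy()
    for c in ("mean", "sd", "min", "max"):
        res[c] = res[c].map(lambda v: round_sig(v, 3))
    out["residues"] = res
    for name, table, cols, kind in (
        ("chronic_edi", result.chronic_edi_table, _EDI_COLS, "sci"),
        ("acute_edi", result.acute_edi_table, _EDI_COLS, "sci"),
        ("moe", result.moe_table, _MOE_COLS, "sci"),
        ("hq", result.hq_table, _HQ_COLS, "fixed"),
    ):
        t = table.copy()
        for c in cols:
            if c in t.columns:
                t[c] = t[c].map(
                    (lambda v: round_sig(v, 3)) if kind == "sci" else (lambda v: round(v, 2))
                )
        out[name] = t
    return out


def _text_block(title: str, df: pd.DataFrame, sci_cols: tuple[str, ...]) -> str:
    if df.empty:
        return f"== {title} ==\n(no consumers)\n"
    shown = df.copy()
    for c in sci_cols:
        if c in shown.columns:
            shown[c] = shown[c].map(lambda v: fmt_sci(v, 3, human=True))
    return f"== {title} ==\n{shown.to_string(index=False)}\n"


def render_simulation_summary(sim: SimulationResult) -> dict:
    """Figure-panel style summary block for one simulated metric."""
    s = sim.summary.as_dict()
    digits = 2 if sim.metric in ("hq", "hi", "fitted") and s["mean"] < 10 else None
    rounded = {
        k: (round(v, 2) if digits else round_sig(v, 4)) for k, v in s.items()
    }
    return {
        "metric": sim.metric,
        "horizon": sim.horizon,
        "n_iterations": sim.n_iterations,
        "seed": sim.seed,
        **rounded,
    }


def provenance(config, seed: int | None = None) -> dict:
    return {
        "package": "dietrisk",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "generated_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }


def plot_histogram(sim: SimulationResult, path: str | Path, bins: int = 60) -> None:
    """Histogram of output draws with the summary panel in the title."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(sim.draws, bins=bins, color="#4878a8", edgecolor="white")
    s = sim.summary
    ax.set_title(
        f"{sim.metric} ({sim.horizon}) — mean {fmt_sci(s.mean)} "
        f"[90% CI {fmt_sci(s.mean_ci90[0])}, {fmt_sci(s.mean_ci90[1])}]"
    )
    ax.set_xlabel(sim.metric)
    ax.set_ylabel("frequency")
    for q, ls in ((s.p50, ":"), (s.p95, "--")):
        ax.axvline(q, color="#a84848", linestyle=ls, linewidth=1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_tables(
    result: AssessmentResult,
    outdir: str | Path,
    simulation: SimulationReport | None = None,
    seed: int | None = None,
    histograms: bool = False,
) -> dict[str, Path]:
    """Write the full report surface to *outdir*.

    Emits per-table CSVs, a combined ``report.json`` with identical
    (display-rounded) values, a human-readable ``report.txt``, optional
    simulation histograms, and a provenance block.  Returns the paths
    written, keyed by artefact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tables = _rounded_tables(result)
    json_doc: dict = {"tables": {}}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        if df.empty:
            pd.DataFrame([{"commodity": "none", "scope": "no consumers"}]).to_csv(p, index=False)
            json_doc["tables"][name] = []
        else:
            df.to_csv(p, index=False)
            json_doc["tables"][name] = df.to_dict(orient="records")
        paths[name] = p

    text = ["dietrisk assessment report", ""]
    text.append(_text_block("Residue summary (mg/kg)", tables["residues"], ("mean", "sd", "min", "max")))
    text.append(_text_block("Chronic EDI (mg/kg bw/day)", tables["chronic_edi"], _EDI_COLS))
    text.append(_text_block("Acute EDI (mg/kg bw/day)", tables["acute_edi"], _EDI_COLS))
    text.append(_text_block("Chronic MOE", tables["moe"], _MOE_COLS))
    hq_txt = tables["hq"].copy()
    if not hq_txt.empty:
        for c in _HQ_COLS:
            hq_txt[c] = hq_txt[c].map(lambda v: fmt_fixed(v, 2))
    text.append(f"== Acute HQ ==\n{hq_txt.to_string(index=False) if not hq_txt.empty else '(no consumers)'}\n")

    if simulation is not None:
        json_doc["simulation"] = {}
        json_doc["sensitivity"] = {}
        for key, sim in simulation.results.items():
            block = render_simulation_summary(sim)
            json_doc["simulation"][key] = block
            text.append(f"== Simulation: {key} ==\n" + "\n".join(
                f"  {k}: {v}" for k, v in block.items()
            ) + "\n")
            ranking = simulation.sensitivities.get(key, [])
            json_doc["sensitivity"][key] = [
                {"input": lbl, "spearman_rho": round(r, 4)} for lbl, r in ranking
            ]
            if histograms:
                hp = outdir / f"hist_{key.replace(':', '_')}.png"
                plot_histogram(sim, hp)
                paths[f"hist_{key}"] = hp

    prov = provenance(result.config, seed)
    json_doc["provenance"] = prov

    p_json = outdir / "report.json"
    write_json(json_doc, p_json)
    paths["report.json"] = p_json
    p_txt = outdir / "report.txt"
    p_txt.write_text("\n".join(text), encoding="utf-8")
    paths["report.txt"] = p_txt
    return paths
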