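"""Relative-improvement analysis and run summaries.

As a search method closes in on an instance's known lower bound, equal
absolute energy gains become much harder to obtain, so raw energy
differences understate progress near the bound.  The relative improvement
(RI) of a target method ``t`` over a reference method ``r`` normalises
the gain by the remaining gap of the reference:

    RI = (E_t - E_r) / (E_1 - E_r) * 100%

where ``E_t`` and ``E_r`` are the average energies of target and
reference, and ``E_1`` is the instance's known lower bound of free
energy.  RI is 0% when the target merely ties the reference and 100% when
it closes the entire remaining gap; it is undefined when the lower bound
is unknown or when the reference already sits on the bound.

This module recomputes the published RI tables from the packaged
benchmark-energy fixtures (three comparisons: SS-Tabu vs LS-Mem, SS-Tabu
vs LS-Tabu, and SS-Tabu with vs without relay-restart) and provides the
small aggregation helpers for multi-run campaigns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "relative_improvement",
    "round_half_up",
    "RunSummary",
    "summarize_runs",
    "load_benchmark_table",
    "load_relay_restart_table",
    "load_printed_ri",
    "RITables",
    "reproduce_ri_tables",
    "format_ri_report",
]

#: Comparison name -> (energy table, target column, reference column)
COMPARISONS = {
    "ls_mem": ("benchmark", "sstabu_avg", "lsmem_avg"),
    "ls_tabu": ("benchmark", "sstabu_avg", "lstabu_avg"),
    "no_relay_restart": ("relay_restart", "rr_avg", "norr_avg"),
}


def relative_improvement(e_t: float, e_r: float, e_1: float) -> float:
    """Exact (unrounded) RI percentage; see the module docstring.

    Raises
    ------
    ValueError
        When any energy is missing/NaN or when ``e_1 == e_r`` (the
        reference already sits on the bound, leaving a zero denominator).
    """
    for name, value in (("E_t", e_t), ("E_r", e_r), ("E_1", e_1)):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"{name} is unknown; RI is not computable")
    if e_1 == e_r:
        raise ValueError("RI undefined: reference equals the lower bound")
    return (e_t - e_r) / (e_1 - e_r) * 100.0


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as the published tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RunSummary:
    """Best/average free energy over a multi-run campaign."""

    best: int
    average: float
    run_count: int
    seeds: Optional[Tuple[int, ...]] = None


def summarize_runs(
    best_energies: Sequence[int],
    seeds: Optional[Sequence[int]] = None,
) -> RunSummary:
    """Aggregate per-run best energies: best = min, average = mean."""
    if len(best_energies) == 0:
        raise ValueError("summarize_runs needs at least one run")
    if seeds is not None and len(seeds) != len(best_energies):
        raise ValueError("seeds and best_energies lengths differ")
    return RunSummary(
        best=min(best_energies),
        average=sum(best_energies) / len(best_energies),
        run_count=len(best_energies),
        seeds=tuple(seeds) if seeds is not None else None,
    )


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("spiralfold.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", na_values=["NA"])


def load_benchmark_table() -> pd.DataFrame:
    """The packaged benchmark-energy fixture (21 instances)."""
    df = _read_fixture("benchmark_energies.tsv")
    _check_energy_table(df, "benchmark_energies.tsv")
    return df


def load_relay_restart_table() -> pd.DataFrame:
    """The packaged relay-restart ablation fixture (12 instances)."""
    df = _read_fixture("relay_restart_energies.tsv")
    _check_energy_table(df, "relay_restart_energies.tsv")
    return df


def load_printed_ri() -> pd.DataFrame:
    """The RI columns exactly as published (with their rounding styles)."""
    return _read_fixture("printed_ri.tsv")


def _check_energy_table(df: pd.DataFrame, name: str) -> None:
    energy_cols = [
        c for c in df.columns
        if c.endswith(("_best", "_avg")) or c == "lb_free_energy"
    ]
    for _, row in df.iterrows():
        for col in energy_cols:
            value = row[col]
            if pd.notna(value) and value > 0:
                raise ValueError(
                    f"malformed fixture {name}: row {row['id']!r} has "
                    f"positive energy {col}={value}"
                )


@dataclass
class RITables:
    """Recomputed RI tables plus the per-comparison printed-range summary."""

    tables: Dict[str, pd.DataFrame]
    ranges: Dict[str, Tuple[float, float]]


def reproduce_ri_tables(
    benchmark: Optional[pd.DataFrame] = None,
    relay: Optional[pd.DataFrame] = None,
) -> RITables:
    """Recompute every RI column from the energy fixtures.

    For each comparison, rows lacking the reference average or the lower
    bound carry ``NaN`` RI (reported as not computable) and are excluded
    from the min/max range.  ``ri`` holds the exact percentage and
    ``ri_rounded`` the two-decimal half-up figure used for display and
    for the ranges.
    """
    benchmark = load_benchmark_table() if benchmark is None else benchmark
    relay = load_relay_restart_table() if relay is None else relay
    sources = {"benchmark": benchmark, "relay_restart": relay}

    tables: Dict[str, pd.DataFrame] = {}
    ranges: Dict[str, Tuple[float, float]] = {}
    for comparison, (source, t_col, r_col) in COMPARISONS.items():
        df = sources[source]
        rows = []
        for _, row in df.iterrows():
            e_t, e_r, e_1 = row[t_col], row[r_col], row["lb_free_energy"]
            try:
                ri = relative_improvement(e_t, e_r, e_1)
            except ValueError:
                ri = float("nan")
            rows.append(
                {
                    "id": row["id"],
                    "size": int(row["size"]),
                    "lb_free_energy": e_1,
                    "e_t": e_t,
                    "e_r": e_r,
                    "ri": ri,
                    "ri_rounded": (
                        round_half_up(ri) if not math.isnan(ri) else float("nan")
                    ),
                }
            )
        table = pd.DataFrame(rows)
        tables[comparison] = table
        known = table["ri_rounded"].dropna()
        if len(known):
            ranges[comparison] = (float(known.min()), float(known.max()))
    return RITables(tables=tables, ranges=ranges)


def format_ri_report(result: RITables) -> str:
    """Human-readable aligned report of the RI tables and their ranges."""
    lines: List[str] = []
    for comparison, table in result.tables.items():
        lines.append(f"Relative improvement: {comparison}")
        lines.append(
            f"{'id':<8}{'size':>6}{'E_lb':>8}{'E_t':>8}{'E_r':>8}{'RI %':>10}"
        )
        for _, row in table.iterrows():
            ri = (
                f"{row['ri_rounded']:.2f}"
                if not math.isnan(row["ri"])
                else "?"
            )
            lb = (
                f"{row['lb_free_energy']:.0f}"
                if pd.notna(row["lb_free_energy"])
                else "?"
            )
            er = f"{row['e_r']:.0f}" if pd.notna(row["e_r"]) else "n/a"
            lines.append(
                f"{row['id']:<8}{row['size']:>6}{lb:>8}"
                f"{row['e_t']:>8.0f}{er:>8}{ri:>10}"
            )
        if comparison in result.ranges:
            lo, hi = result.ranges[comparison]
            lines.append(f"range: {lo:.2f}% to {hi:.2f}%")
        lines.append("")
    return "\n".join(lines)
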