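"""Descriptive tables and forest-plot rendering of screening results.

Percentages are rounded half-up to one decimal for display, matching
the convention of regulatory-style baseline tables; machine-readable
output keeps full precision.  The forest renderer draws one panel per
event query (point = adjusted ROR, whiskers = 95% CI, reference line at
1) and emits the identical numbers as a plain table — the renderer never
recomputes anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .disproportionality import DisproportionalityResult, results_frame
from .faers_io import Report

__all__ = ["DescriptiveTable", "round_pct", "descriptive_summary", "render_forest"]


def round_pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total``, rounded half-up.

    Uses decimal arithmetic so 59.0076 -> 59.0 and 3.0534 -> 3.1 come
    out as printed tables do, immune to binary-float ties.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DescriptiveTable:
    """Counts and display percentages for one stratification."""

    variable: str
    total: int
    rows: List[Tuple[str, int, float]] = field(default_factory=list)  # label, n, pct

    @classmethod
    def from_counts(cls, variable: str, counts: Mapping[str, int], total: Optional[int] = None) -> "DescriptiveTable":
        total = total if total is not None else sum(counts.values())
        table = cls(variable=variable, total=total)
        for label, n in counts.items():
            table.rows.append((label, int(n), round_pct(int(n), total)))
        return table

    def pct(self, label: str) -> float:
        for lab, _, pct in self.rows:
            if lab == label:
                return pct
        raise KeyError(label)

    def count(self, label: str) -> int:
        for lab, n, _ in self.rows:
            if lab == label:
                return n
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=[self.variable, "n", "pct"])

    def pct_sum(self) -> float:
        return float(sum(p for _, _, p in self.rows))


_GROUPERS = {
    "age_class": lambda r: r.age_class,
    "sex": lambda r: r.sex,
    "reporter_type": lambda r: r.reporter_type,
    "country": lambda r: r.country,
    "reporting_year": lambda r: str(r.reporting_year) if r.reporting_year else "unknown",
    "outcome": None,  # multi-valued, handled separately
    "drug_role": None,
}


def descriptive_summary(
    reports: Sequence[Report],
    group_by: Sequence[str] = ("age_class", "sex", "reporter_type", "country", "reporting_year", "outcome", "drug_role"),
) -> Dict[str, DescriptiveTable]:
    """Stratified counts/percentages over a report set, plus age quartiles.

    ``outcome`` and ``drug_role`` strata count report-outcome and
    drug-line combinations respectively (a report can carry several);
    their percentages are taken over the report total, as baseline
    tables conventionally do.
    """
    total = len(reports)
    out: Dict[str, DescriptiveTable] = {}
    for variable in group_by:
        counts: Dict[str, int] = {}
        if variable == "outcome":
            for r in reports:
                for o in sorted(r.outcome):
                    counts[o] = counts.get(o, 0) + 1
        elif variable == "drug_role":
            for r in reports:
                for d in r.drugs:
                    counts[d.role] = counts.get(d.role, 0) + 1
            total_roles = sum(counts.values())
            out[variable] = DescriptiveTable.from_counts(variable, counts, total_roles)
            continue
        else:
            grouper = _GROUPERS[variable]
            for r in reports:
                label = grouper(r)
                counts[label] = counts.get(label, 0) + 1
        out[variable] = DescriptiveTable.from_counts(variable, counts, total)

    ages = np.array([r.age_years for r in reports if r.age_years is not None], dtype=float)
    if ages.size:
        q1, med, q3 = np.percentile(ages, [25, 50, 75], method="linear")
        out["age_summary"] = DescriptiveTable(
            variable="age_summary",
            total=int(ages.size),
            rows=[("median", int(ages.size), float(med)), ("q1", int(ages.size), float(q1)), ("q3", int(ages.size), float(q3))],
        )
    return out


def render_forest(
    results: Sequence[DisproportionalityResult],
    path: Optional[str] = None,
    round_display: int = 1,
):
    """Forest plot, one panel per SMQ, plus the matching plain table.

    Returns ``(figure, table)``; the table's numbers are copied verbatim
    from the results (displayed values rounded half-up to
    ``round_display`` decimals in the ``*_disp`` columns).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotted = [r for r in results if r.adjusted is not None]
    if not plotted:
        raise ValueError("no results with a computed adjusted ROR to render")
    smqs = sorted({r.smq_name for r in plotted})
    fig, axes = plt.subplots(len(smqs), 1, figsize=(6, 1.2 + 1.6 * len(smqs)), squeeze=False)
    for ax, smq_name in zip(axes.ravel(), smqs):
        rows = [r for r in plotted if r.smq_name == smq_name]
        y = np.arange(len(rows))[::-1]
        vals = [r.adjusted.value for r in rows]
        lows = [r.adjusted.ci_low for r in rows]
        highs = [r.adjusted.ci_high for r in rows]
        ax.errorbar(
            vals,
            y,
            xerr=[np.subtract(vals, lows), np.subtract(highs, vals)],
            fmt="s",
            color="black",
            ecolor="black",
            capsize=3,
        )
        for yi, r in zip(y, rows):
            if r.sdr:
                ax.plot([r.adjusted.value], [yi], marker="D", color="firebrick")
        ax.axvline(1.0, color="grey", linewidth=1, linestyle="--")
        ax.set_xscale("log")
        ax.set_yticks(y)
        ax.set_yticklabels([r.drug for r in rows])
        ax.set_title(smq_name, fontsize=9)
        ax.set_xlabel("adjusted ROR (log scale)", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)

    table = results_frame(plotted)
    for col in ("crude_ror", "adj_ror", "adj_ci_low", "adj_ci_high"):
        table[f"{col}_disp"] = [
            float(Decimal(str(v)).quantize(Decimal(1).scaleb(-round_display), rounding=ROUND_HALF_UP))
            if v is not None and np.isfinite(v)
            else None
            for v in table[col]
        ]
    return fig, table
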