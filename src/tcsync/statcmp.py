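"""Statistical layer: Wilcoxon rank-sum tests with Bonferroni correction.

Every group/condition contrast in the pipeline is an unpaired two-sided
Wilcoxon rank-sum (Mann-Whitney) test.  For small samples
(``n_a + n_b <= 12``) the p-value is exact, by enumeration of all rank
assignments with midranks for ties; larger samples use the normal
approximation with tie and continuity corrections (scipy).  When several
contrasts form a family, p-values are Bonferroni-corrected by multiplying
by the family size (clamped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

#: pooled size at or below which the exact enumeration branch is used
EXACT_MAX_N = 12


class StatError(ValueError):
    """Invalid samples or comparison specification."""


@dataclass
class RanksumResult:
    statistic: float  # rank sum W of sample a (midranks)
    pvalue: float
    n_a: int
    n_b: int
    method: str  # "exact" | "asymptotic"


def ranksum(a: np.ndarray, b: np.ndarray) -> RanksumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact by enumeration (midranks, two-sided via symmetry of the rank-sum
    statistic around its null mean) when ``n_a + n_b <= 12``; otherwise the
    tie- and continuity-corrected normal approximation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise StatError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    N = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = _stats.rankdata(pooled)  # midranks
    W = float(np.sum(ranks[:n_a]))

    if N <= EXACT_MAX_N:
        mean = n_a * (N + 1) / 2.0
        dev = abs(W - mean)
        hits = 0
        total = 0
        for idx in combinations(range(N), n_a):
            w = ranks[list(idx)].sum()
            if abs(w - mean) >= dev - 1e-9:
                hits += 1
            total += 1
        return RanksumResult(W, hits / total, n_a, n_b, "exact")

    res = _stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RanksumResult(W, float(res.pvalue), n_a, n_b, "asymptotic")


def bonferroni(p_raw: float, n_classes: int) -> float:
    """Multiply by the number of classes in the family, clamp at 1."""
    if n_classes < 1:
        raise StatError("n_classes must be >= 1")
    return float(min(1.0, p_raw * n_classes))


# ---------------------------------------------------------------------------
# comparison grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonSpec:
    """One contrast: measure plus the two cells' factor filters.

    A *cell* is a dict of column -> value filters applied to the measure's
    tidy sample table (e.g. ``{"group": "CR", "condition": "rest",
    "epoch_type": "rest"}``).  Cells sharing a ``family`` label are
    Bonferroni-corrected together.
    """

    measure: str  # FR | PLV | C | L
    cell_a: tuple[tuple[str, str], ...]
    cell_b: tuple[tuple[str, str], ...]
    family: str = "default"
    label: str = ""
    paired: bool = False  # always False in this design

    @staticmethod
    def make(measure, cell_a: dict, cell_b: dict, family="default", label=""):
        return ComparisonSpec(
            measure=measure,
            cell_a=tuple(sorted(cell_a.items())),
            cell_b=tuple(sorted(cell_b.items())),
            family=family,
            label=label,
        )


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    n_a: int
    n_b: int
    statistic: float
    p_raw: float
    p_corrected: float
    direction: str  # "+" if median(b) > median(a), "-" if lower, "0"/"skipped"
    skipped: bool = False
    reason: str = ""


def _select(table: pd.DataFrame, cell: tuple[tuple[str, str], ...]) -> np.ndarray:
    mask = np.ones(len(table), dtype=bool)
    for col, val in cell:
        if col not in table.columns:
            raise StatError(f"table lacks factor column {col!r}")
        mask &= (table[col] == val).to_numpy()
    return table.loc[mask, "value"].to_numpy(dtype=np.float64)


def run_comparison_grid(
    tables: dict[str, pd.DataFrame],
    grid: list[ComparisonSpec],
) -> list[ComparisonResult]:
    """Run every contrast; Bonferroni factor = size of its family.

    Each measure's table must be tidy with a ``value`` column plus factor
    columns.  Missing cells (absent table, empty or singleton sample) are
    reported as skipped, never silently dropped.
    """
    family_sizes: dict[str, int] = {}
    for spec in grid:
        family_sizes[spec.family] = family_sizes.get(spec.family, 0) + 1

    results = []
    for spec in grid:
        table = tables.get(spec.measure)
        if table is None or "value" not in getattr(table, "columns", []):
            results.append(
                ComparisonResult(spec, 0, 0, float("nan"), float("nan"), float("nan"),
                                 "skipped", True, f"no sample table for {spec.measure}")
            )
            continue
        a = _select(table, spec.cell_a)
        b = _select(table, spec.cell_b)
        if a.size < 2 or b.size < 2:
            results.append(
                ComparisonResult(spec, a.size, b.size, float("nan"), float("nan"),
                                 float("nan"), "skipped", True, "cell has < 2 observations")
            )
            continue
        rs = ranksum(a, b)
        diff = float(np.median(b) - np.median(a))
        if diff != 0:
            direction = "+" if diff > 0 else "-"
        else:
            # medians tie (common for discrete counts): fall back to the
            # test's own direction estimate, the mean-rank difference
            ranks = _stats.rankdata(np.concatenate([a, b]))
            rank_diff = ranks[a.size :].mean() - ranks[: a.size].mean()
            direction = "+" if rank_diff > 0 else ("-" if rank_diff < 0 else "0")
        results.append(
            ComparisonResult(
                spec=spec,
                n_a=rs.n_a,
                n_b=rs.n_b,
                statistic=rs.statistic,
                p_raw=rs.pvalue,
                p_corrected=bonferroni(rs.pvalue, family_sizes[spec.family]),
                direction=direction,
            )
        )
    return results


def results_table(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "measure": r.spec.measure,
                "label": r.spec.label,
                "family": r.spec.family,
                "cell_a": "; ".join(f"{k}={v}" for k, v in r.spec.cell_a),
                "cell_b": "; ".join(f"{k}={v}" for k, v in r.spec.cell_b),
                "n_a": r.n_a,
                "n_b": r.n_b,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "direction": r.direction,
                "skipped": r.skipped,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def render_report(results: list[ComparisonResult]) -> str:
    """Human-readable comparison report grouped by measure."""
    lines = []
    for measure in dict.fromkeys(r.spec.measure for r in results):
        lines.append(f"== {measure} ==")
        for r in results:
            if r.spec.measure != measure:
                continue
            if r.skipped:
                lines.append(f"  {r.spec.label or r.spec.family}: SKIPPED ({r.reason})")
                continue
            lines.append(
                f"  {r.spec.label or r.spec.family}: direction {r.direction}, "
                f"N = {r.n_a}+{r.n_b}, p = {r.p_raw:.4g} "
                f"(corrected {r.p_corrected:.4g}, family {r.spec.family!r})"
            )
        lines.append("")
    return "\n".join(lines)
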