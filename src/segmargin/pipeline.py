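"""Cohort-level orchestration and reporting.

Runs the full segmentation-accuracy and safety-margin analysis over a
cohort of cases and emits the standard tabular outputs:

* a per-candidate agreement-with-truth table (volumes, missed volume,
  HD, MDA, Dice, Jaccard, ellipsoid-formula estimate),
* a pairwise inter-candidate agreement table,
* a safety-margin table (expanded volume and residual missed volume at
  each margin, plus the minimum margin ensuring complete coverage),
* Wilcoxon comparisons (paired signed-rank within candidates across
  cases; unpaired rank-sum between candidate groups).

The union candidate (``seg4``) is derived per case from all available
(non-empty) candidates.  A case whose candidate is empty is excluded from
that candidate's summaries, mirroring how lesions not identified by a
reader are excluded from analysis.  Summary rows report
mean ± SD [median; min–max] per metric per candidate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import BinaryMask, SegmentationCase
from .metrics import dice, jaccard, hausdorff_mm, mda_mm, similarity_report
from .margins import DEFAULT_MARGINS_MM, margin_report, union_masks
from .extents import max_extents, ellipsoid_volume_ml

__all__ = [
    "CohortResult",
    "UNION_NAME",
    "analyze_case",
    "pairwise_agreement",
    "analyze_cohort",
    "wilcoxon_paired",
    "wilcoxon_unpaired",
    "compare_candidates",
    "summarize",
]

UNION_NAME = "seg4"
ALPHA = 0.05


def analyze_case(
    case: SegmentationCase,
    margins_mm: Sequence[float] = DEFAULT_MARGINS_MM,
) -> dict[str, dict]:
    """Per-candidate reports for one case, including the union candidate.

    Returns ``{candidate: {"similarity", "margin", "ellipsoid_ml",
    "excluded"}}``.  Empty candidates are recorded as excluded; the union
    is built from the non-empty candidates only (no ellipsoid estimate is
    reported for it, as it is not a drawn VOI).
    """
    out: dict[str, dict] = {}
    nonempty: list[BinaryMask] = []
    for name, cand in case.candidates.items():
        if cand.is_empty():
            out[name] = {"excluded": True}
            continue
        nonempty.append(cand)
        out[name] = {
            "excluded": False,
            "similarity": similarity_report(case.truth, cand),
            "margin": margin_report(case.truth, cand, margins_mm, name),
            "ellipsoid_ml": ellipsoid_volume_ml(max_extents(cand)),
        }
    if nonempty:
        combined = union_masks(nonempty)
        out[UNION_NAME] = {
            "excluded": False,
            "similarity": similarity_report(case.truth, combined),
            "margin": margin_report(case.truth, combined, margins_mm, UNION_NAME),
            "ellipsoid_ml": None,
        }
    return out


def pairwise_agreement(case: SegmentationCase) -> dict[tuple[str, str], dict]:
    """HD/MDA/Dice/Jaccard for every unordered pair of non-empty candidates."""
    names = [n for n, c in case.candidates.items() if not c.is_empty()]
    if len(names) < 2:
        return {}
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ma, mb = case.candidates[a], case.candidates[b]
            out[(a, b)] = {
                "dice": dice(ma, mb),
                "jaccard": jaccard(ma, mb),
                "hd_mm": hausdorff_mm(ma, mb),
                "mda_mm": mda_mm(ma, mb),
            }
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Exact null distribution for n <= 20 with no tied or zero differences,
    normal approximation with tie correction otherwise.  Zero differences
    are dropped (Wilcoxon's original rule); if every difference is zero
    the test carries no evidence and p = 1 is returned, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    flags = []
    if len(x) < 5:
        flags.append("underpowered")
    if nz.size == 0:
        return {"statistic": 0.0, "p_value": 1.0,
                "flags": flags + ["all-zero-differences"], "n": int(len(x))}
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 20 and not ties) else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", alternative="two-sided", method=method
    )
    # report the conventional W+ (sum of ranks of positive differences)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    return {"statistic": w_plus, "p_value": float(res.pvalue),
            "flags": flags, "n": int(len(x))}


def wilcoxon_unpaired(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test, unpaired."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    flags = []
    if min(len(x), len(y)) < 5:
        flags.append("underpowered")
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == 1:
        return {"statistic": float(len(x) * len(y) / 2), "p_value": 1.0,
                "flags": flags + ["all-equal"], "n": int(len(x) + len(y))}
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(len(x), len(y)) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "flags": flags, "n": int(len(x) + len(y))}


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------

_SIM_FIELDS = [
    "truth_volume_ml", "candidate_volume_ml", "missed_volume_ml",
    "missed_percent", "hd_mm", "mda_mm", "dice", "jaccard",
]


@dataclass
class CohortResult:
    """All per-case and aggregate outputs of a cohort analysis."""

    margins_mm: tuple[float, ...]
    per_case: dict[str, dict[str, dict]]
    agreement: dict[str, dict[tuple[str, str], dict]]
    accuracy_table: pd.DataFrame = field(repr=False, default=None)
    agreement_table: pd.DataFrame = field(repr=False, default=None)
    margin_table: pd.DataFrame = field(repr=False, default=None)
    tests: list[dict] = field(default_factory=list)

    def candidate_values(self, candidate: str, metric: str) -> np.ndarray:
        """Per-case values of one metric for one candidate (excluded cases
        dropped), ordered by case id."""
        vals = []
        for cid in sorted(self.per_case):
            rep = self.per_case[cid].get(candidate)
            if rep is None or rep.get("excluded"):
                continue
            vals.append(_metric_value(rep, self.margins_mm, metric))
        return np.asarray(vals, dtype=float)

    def paired_values(
        self, candidates: tuple[str, str], metric: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Metric values on cases where *both* candidates are present."""
        xs, ys = [], []
        for cid in sorted(self.per_case):
            reps = self.per_case[cid]
            ra, rb = reps.get(candidates[0]), reps.get(candidates[1])
            if not ra or not rb or ra.get("excluded") or rb.get("excluded"):
                continue
            xs.append(_metric_value(ra, self.margins_mm, metric))
            ys.append(_metric_value(rb, self.margins_mm, metric))
        return np.asarray(xs), np.asarray(ys)


def _metric_value(rep: dict, margins: tuple[float, ...], metric: str) -> float:
    """Resolve a metric name against a per-candidate case report.

    Similarity fields by name; ``ellipsoid_ml``; margin fields as
    ``missed_volume_ml@5`` / ``missed_percent@5`` / ``expanded_volume_ml@5``
    (any configured margin) and ``min_coverage_margin_mm``.
    """
    if metric in _SIM_FIELDS:
        return getattr(rep["similarity"], metric)
    if metric == "ellipsoid_ml":
        v = rep["ellipsoid_ml"]
        return np.nan if v is None else v
    if metric == "min_coverage_margin_mm":
        return rep["margin"].min_coverage_margin_mm
    if "@" in metric:
        base, m = metric.split("@")
        m = float(m)
        mr = rep["margin"]
        i = mr.margins_mm.index(m)
        return getattr(mr, base)[i]
    raise KeyError(f"unknown metric {metric!r}")


def _summary_row(vals: np.ndarray) -> dict:
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return {"n": 0, "mean": np.nan, "sd": np.nan, "median": np.nan,
                "min": np.nan, "max": np.nan}
    return {
        "n": int(vals.size),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "median": float(np.median(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def compare_candidates(
    results: CohortResult,
    metric: str,
    pair: tuple[str, str],
    paired: bool = True,
) -> dict:
    """Wilcoxon comparison of one metric between two candidates."""
    if paired:
        x, y = results.paired_values(pair, metric)
        test = wilcoxon_paired(x, y)
    else:
        x = results.candidate_values(pair[0], metric)
        y = results.candidate_values(pair[1], metric)
        test = wilcoxon_unpaired(x, y)
    return {"comparison": f"{pair[0]} vs {pair[1]}", "metric": metric,
            "paired": paired, "significant": test["p_value"] < ALPHA, **test}


def analyze_cohort(
    cases: Sequence[SegmentationCase],
    margins_mm: Sequence[float] = DEFAULT_MARGINS_MM,
    comparisons: Sequence[tuple[str, str, str, bool]] | None = None,
) -> CohortResult:
    """Run the complete analysis over a cohort.

    ``comparisons`` is a list of ``(metric, candidate_a, candidate_b,
    paired)``; when None, a default battery compares the union candidate's
    missed volume against every individual candidate (paired) and the
    readers' Dice against the PET candidate (unpaired).
    """
    margins = tuple(float(m) for m in margins_mm)
    per_case = {c.case_id: analyze_case(c, margins) for c in cases}
    agreement = {c.case_id: pairwise_agreement(c) for c in cases}
    result = CohortResult(margins_mm=margins, per_case=per_case,
                          agreement=agreement)

    candidates: list[str] = sorted({n for reps in per_case.values() for n in reps})

    # accuracy-vs-truth table
    acc_metrics = ["truth_volume_ml", "ellipsoid_ml", "candidate_volume_ml",
                   "missed_volume_ml", "missed_percent", "hd_mm", "mda_mm",
                   "dice", "jaccard"]
    rows = []
    for cand in candidates:
        for metric in acc_metrics:
            rows.append({"candidate": cand, "metric": metric,
                         **_summary_row(result.candidate_values(cand, metric))})
    result.accuracy_table = pd.DataFrame(rows)

    # inter-candidate agreement table
    rows = []
    pairs = sorted({p for ag in agreement.values() for p in ag})
    for p in pairs:
        for metric in ("hd_mm", "mda_mm", "dice", "jaccard"):
            vals = np.asarray([
                ag[p][metric] for ag in agreement.values() if p in ag
            ])
            rows.append({"pair": f"{p[0]} vs {p[1]}", "metric": metric,
                         **_summary_row(vals)})
    result.agreement_table = pd.DataFrame(rows)

    # margin table
    margin_metrics = [f"{base}@{m:g}" for m in margins
                      for base in ("expanded_volume_ml", "missed_volume_ml",
                                   "missed_percent")]
    margin_metrics.append("min_coverage_margin_mm")
    rows = []
    for cand in candidates:
        for metric in margin_metrics:
            rows.append({"candidate": cand, "metric": metric,
                         **_summary_row(result.candidate_values(cand, metric))})
    result.margin_table = pd.DataFrame(rows)

    # hypothesis tests
    if comparisons is None:
        comparisons = []
        parts = [c for c in candidates if c != UNION_NAME]
        for cand in parts:
            comparisons.append(("missed_volume_ml", UNION_NAME, cand, True))
        if "seg3" in candidates:
            for reader in ("seg1", "seg2"):
                if reader in candidates:
                    comparisons.append(("dice", reader, "seg3", False))
    for metric, a, b, paired in comparisons:
        try:
            result.tests.append(
                compare_candidates(result, metric, (a, b), paired=paired)
            )
        except ValueError as exc:  # e.g. too few overlapping cases
            warnings.warn(f"comparison {a} vs {b} on {metric} skipped: {exc}")
    return result


def summarize(result: CohortResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the three summary CSVs and the tests JSON to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "accuracy": out / "table_accuracy.csv",
        "agreement": out / "table_agreement.csv",
        "margins": out / "table_margins.csv",
        "tests": out / "tests.json",
    }
    result.accuracy_table.to_csv(paths["accuracy"], index=False)
    result.agreement_table.to_csv(paths["agreement"], index=False)
    result.margin_table.to_csv(paths["margins"], index=False)
    paths["tests"].write_text(json.dumps(result.tests, indent=2))
    return paths
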