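"""Cohort-level aggregation of benchmark review results.

Produces the four reporting products of a benchmark-case QA programme:

* a tally of unacceptable deviations by category and by structure,
* resubmission statistics (fraction of institutions needing more than one
  round; median and range of rounds),
* first-vs-final paired agreement statistics for structures that were
  rejected at their first submission (how much the review improved IOV),
* per-structure means/SDs of the final accepted volumes' DSI/HD and of the
  institutional dose metrics.

Conventions: per-pair differences are computed on unrounded values and only
rounded for display (DSI to 2 decimals, HD to 1), so the mean of per-pair
differences equals the difference of means exactly before rounding.  SDs are
sample SDs (n − 1 denominator).  Category percentages are apportioned with
the largest-remainder method so they sum to exactly 100; the resubmission
percentage is displayed truncated to an integer (65% for 23/35), with raw
fractions always retained in machine output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PairingError
from .geometry import AgreementResult
from .qa_rules import CATEGORIES, ConstraintRule, DeviationRecord, InstitutionHistory

__all__ = [
    "DeviationTally",
    "ResubmissionStats",
    "PairedAgreement",
    "CohortReport",
    "tally_deviations",
    "resubmission_stats",
    "paired_first_final",
    "final_volume_metrics",
    "dose_summary",
    "extract_pairs",
    "extract_final_agreements",
    "extract_final_dose_metrics",
    "build_report",
    "largest_remainder_percent",
    "values_with_moments",
]


def largest_remainder_percent(counts: Mapping[str, int]) -> dict[str, int]:
    """Integer percentages summing to exactly 100 (largest-remainder method).

    Reproduces published category breakdowns such as 40/27/9 of 76 ->
    53/35/12 (plain nearest-integer rounding would give 53/36/12 = 101).
    """
    total = sum(counts.values())
    if total == 0:
        return {k: 0 for k in counts}
    shares = {k: 100.0 * v / total for k, v in counts.items()}
    floors = {k: int(math.floor(s)) for k, s in shares.items()}
    missing = 100 - sum(floors.values())
    order = sorted(counts, key=lambda k: (-(shares[k] - floors[k]), k))
    for k in order[:missing]:
        floors[k] += 1
    return floors


@dataclass
class DeviationTally:
    """Counts and display percentages of unacceptable deviations."""

    total: int
    by_category: dict[str, int]
    by_structure: dict[str, int]
    category_percent: dict[str, int]       # largest remainder, sums to 100
    category_fraction: dict[str, float]    # raw fractions
    structure_percent: dict[str, int]      # nearest integer per structure
    structure_fraction: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "structure": s,
                "count": c,
                "percent": self.structure_percent[s],
                "fraction": self.structure_fraction[s],
            }
            for s, c in sorted(self.by_structure.items())
        ]
        return pd.DataFrame(rows, columns=["structure", "count", "percent", "fraction"])


def tally_deviations(records: Iterable[DeviationRecord]) -> DeviationTally:
    """Tally unacceptable deviations per category and per structure.

    Records with other severities are ignored, so the function may be fed a
    full review log.  An empty input yields a valid all-zero tally.
    """
    unacceptable = [r for r in records if r.severity == "unacceptable"]
    total = len(unacceptable)
    by_category = {c: 0 for c in CATEGORIES}
    by_structure: dict[str, int] = {}
    for r in unacceptable:
        by_category[r.category] += 1
        by_structure[r.structure_name] = by_structure.get(r.structure_name, 0) + 1
    return DeviationTally(
        total=total,
        by_category=by_category,
        by_structure=by_structure,
        category_percent=largest_remainder_percent(by_category),
        category_fraction={c: (v / total if total else 0.0) for c, v in by_category.items()},
        structure_percent={
            s: int(round(100.0 * v / total)) if total else 0 for s, v in by_structure.items()
        },
        structure_fraction={s: (v / total if total else 0.0) for s, v in by_structure.items()},
    )


@dataclass
class ResubmissionStats:
    n_institutions: int
    n_multiple: int
    fraction: float
    percent: int  # truncated display percentage
    median_rounds: float
    min_rounds: int
    max_rounds: int


def resubmission_stats(histories: Iterable[InstitutionHistory]) -> ResubmissionStats:
    """Fraction of institutions needing more than one round; median and range."""
    rounds = []
    for h in histories:
        if not h.accepted:
            raise PairingError(f"history of {h.institution_id} does not end accepted")
        rounds.append(h.n_rounds)
    n = len(rounds)
    if n == 0:
        return ResubmissionStats(0, 0, 0.0, 0, float("nan"), 0, 0)
    n_multi = sum(r > 1 for r in rounds)
    fraction = n_multi / n
    return ResubmissionStats(
        n_institutions=n,
        n_multiple=n_multi,
        fraction=fraction,
        percent=int(math.floor(100.0 * fraction)),
        median_rounds=float(np.median(rounds)),
        min_rounds=min(rounds),
        max_rounds=max(rounds),
    )


@dataclass(frozen=True)
class PairedAgreement:
    """First rejected and finally accepted agreement for one structure."""

    institution_id: str
    structure_name: str
    first: AgreementResult
    final: AgreementResult


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd


def paired_first_final(pairs: Sequence[PairedAgreement]) -> pd.DataFrame:
    """Per-structure first/final/difference statistics on unrounded values.

    Pairing is by institution; a (institution, structure) key may appear at
    most once.  Differences are final − first per pair; their mean equals
    mean(final) − mean(first) exactly.
    """
    seen = set()
    for p in pairs:
        key = (p.institution_id, p.structure_name)
        if key in seen:
            raise PairingError(f"duplicate pair for {key}")
        seen.add(key)
    rows = []
    by_structure: dict[str, list[PairedAgreement]] = {}
    for p in pairs:
        by_structure.setdefault(p.structure_name, []).append(p)
    for name in sorted(by_structure):
        ps = by_structure[name]
        row: dict[str, object] = {"structure": name, "n": len(ps)}
        for metric in ("dsi", "hd"):
            first = [getattr(p.first, metric) for p in ps]
            final = [getattr(p.final, metric) for p in ps]
            diff = [b - a for a, b in zip(first, final)]
            for label, vals in (("first", first), ("final", final), ("diff", diff)):
                mean, sd = _mean_sd(vals)
                row[f"{metric}_{label}_mean"] = mean
                row[f"{metric}_{label}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


def final_volume_metrics(
    finals: Iterable[tuple[str, AgreementResult]]
) -> pd.DataFrame:
    """Mean (SD) of DSI and HD across institutions' final accepted volumes.

    ``finals`` yields (institution_id, AgreementResult); one entry per
    institution per structure.
    """
    by_structure: dict[str, list[AgreementResult]] = {}
    seen = set()
    for inst, res in finals:
        key = (inst, res.structure_name)
        if key in seen:
            raise PairingError(f"duplicate final result for {key}")
        seen.add(key)
        by_structure.setdefault(res.structure_name, []).append(res)
    rows = []
    for name in sorted(by_structure):
        results = by_structure[name]
        dsi_mean, dsi_sd = _mean_sd([r.dsi for r in results])
        hd_mean, hd_sd = _mean_sd([r.hd for r in results])
        rows.append(
            {
                "structure": name,
                "n": len(results),
                "dsi_mean": dsi_mean,
                "dsi_sd": dsi_sd,
                "hd_mean": hd_mean,
                "hd_sd": hd_sd,
            }
        )
    return pd.DataFrame(rows)


def dose_summary(
    institution_metrics: Mapping[str, Mapping[str, Mapping[str, float]]],
    rules: Sequence[ConstraintRule],
) -> pd.DataFrame:
    """Mean (SD) of each protocol dose metric across accepted plans.

    ``institution_metrics`` maps institution -> structure -> metric label ->
    Gy.  The protocol requirement string is carried along for the report.
    """
    rows = []
    for rule in rules:
        values = [
            m[rule.structure_name][rule.metric.label]
            for m in institution_metrics.values()
            if rule.structure_name in m and rule.metric.label in m[rule.structure_name]
        ]
        if not values:
            continue
        mean, sd = _mean_sd(values)
        rows.append(
            {
                "structure": rule.structure_name,
                "metric": rule.metric.label,
                "n": len(values),
                "mean_Gy": mean,
                "sd_Gy": sd,
                "requirement": rule.requirement,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# extraction from benchmark histories
# ---------------------------------------------------------------------------

def extract_pairs(histories: Iterable[InstitutionHistory]) -> list[PairedAgreement]:
    """Pair each structure's first rejected submission with its final version.

    A structure enters the paired analysis when some round flagged it with an
    unacceptable delineation record and agreement metrics exist both for that
    round and for the institution's final accepted round (a structure that
    was absent in its rejected round has no first metric and is skipped).
    """
    pairs: list[PairedAgreement] = []
    for h in histories:
        if not h.rounds:
            continue
        final_round = h.rounds[-1]
        rejected_first: dict[str, AgreementResult] = {}
        for rnd in h.rounds:
            for rec in rnd.records:
                if (
                    rec.severity == "unacceptable"
                    and rec.category in ("oar_delineation", "target_delineation")
                    and rec.structure_name not in rejected_first
                    and rec.structure_name in rnd.agreements
                ):
                    rejected_first[rec.structure_name] = rnd.agreements[rec.structure_name]
        for name, first in rejected_first.items():
            final = final_round.agreements.get(name)
            if final is not None:
                pairs.append(PairedAgreement(h.institution_id, name, first, final))
    return pairs


def extract_final_agreements(
    histories: Iterable[InstitutionHistory],
) -> list[tuple[str, AgreementResult]]:
    out = []
    for h in histories:
        if h.rounds:
            for res in h.rounds[-1].agreements.values():
                out.append((h.institution_id, res))
    return out


def extract_final_dose_metrics(
    histories: Iterable[InstitutionHistory],
) -> dict[str, dict[str, dict[str, float]]]:
    """Dose metrics of each institution's last round that evaluated a plan."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for h in histories:
        for rnd in reversed(h.rounds):
            if rnd.dose_metrics is not None:
                out[h.institution_id] = rnd.dose_metrics
                break
    return out


@dataclass
class CohortReport:
    """Everything the benchmark programme reports about a cohort."""

    tally: DeviationTally
    resubmissions: ResubmissionStats
    paired: pd.DataFrame
    finals: pd.DataFrame
    doses: pd.DataFrame
    records: list[DeviationRecord] = field(default_factory=list)
    metrics_long: Optional[pd.DataFrame] = None

    def summary_dict(self) -> dict:
        return {
            "n_institutions": self.resubmissions.n_institutions,
            "n_needing_resubmission": self.resubmissions.n_multiple,
            "resubmission_fraction": self.resubmissions.fraction,
            "resubmission_percent": self.resubmissions.percent,
            "rounds_median": self.resubmissions.median_rounds,
            "rounds_min": self.resubmissions.min_rounds,
            "rounds_max": self.resubmissions.max_rounds,
            "unacceptable_total": self.tally.total,
            "unacceptable_by_category": self.tally.by_category,
            "category_percent": self.tally.category_percent,
            "category_fraction": self.tally.category_fraction,
            "unacceptable_by_structure": self.tally.by_structure,
            "structure_percent": self.tally.structure_percent,
            "hd_improved_gt10mm_structures": self.count_hd_improved(10.0),
        }

    def count_hd_improved(self, by_mm: float = 10.0) -> int:
        """Structures whose mean HD improved by more than ``by_mm`` (unrounded)."""
        if self.paired.empty:
            return 0
        return int((self.paired["hd_diff_mean"] < -by_mm).sum())


def build_report(histories: Mapping[str, InstitutionHistory], rules: Sequence[ConstraintRule]) -> CohortReport:
    """Aggregate evaluated benchmark histories into a cohort report."""
    hs = list(histories.values())
    records = [r for h in hs for r in h.all_records()]
    finals = extract_final_agreements(hs)
    long_rows = [
        {"structure": res.structure_name, "institution": inst, "metric": metric,
         "value": getattr(res, "dsi" if metric == "DSI" else "hd")}
        for inst, res in finals
        for metric in ("DSI", "HD")
    ]
    return CohortReport(
        tally=tally_deviations(records),
        resubmissions=resubmission_stats(hs),
        paired=paired_first_final(extract_pairs(hs)),
        finals=final_volume_metrics(finals),
        doses=dose_summary(extract_final_dose_metrics(hs), rules),
        records=records,
        metrics_long=pd.DataFrame(
            long_rows, columns=["structure", "institution", "metric", "value"]
        ).sort_values(["structure", "institution", "metric"], kind="stable").reset_index(drop=True),
    )


def values_with_moments(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` values with exactly the given sample mean and SD (ddof=1).

    Used to reconstruct per-pair observations from published summary
    statistics so the aggregation layer can be exercised on them; n = 1
    returns the mean itself.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([mean], dtype=float)
    z = rng.standard_normal(n)
    z = z - z.mean()
    norm = z.std(ddof=1)
    if norm < 1e-12:  # pathological draw; fall back to a deterministic pattern
        z = np.linspace(-1.0, 1.0, n)
        z = z - z.mean()
        norm = z.std(ddof=1)
    return mean + (sd if not math.isnan(sd) else 0.0) * z / norm
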