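"""Benchmark review rule engine: deviation classification and the
accept/resubmit workflow.

Every review criterion is classified on the three-tier Global Harmonization
Group scale:

* ``per_protocol`` — fully conformal (informational record),
* ``acceptable_variation`` — outside the strict protocol value but within the
  tolerance band the guidelines allow,
* ``unacceptable`` — blocks acceptance and triggers a resubmission request.

Dose constraints (category ``planning``) are evaluated with strict
inequalities exactly as the protocol prints them ("Dmax < 35 Gy": 35.0
violates).  Banded constraints such as "Dmean < 5–10 Gy" treat the strict
side as per-protocol and crossing the lenient side as unacceptable.

Delineation criteria (categories ``target_delineation`` /
``oar_delineation``) are configurable predicates against the gold standard:
structure presence, minimum DSI, maximum percentile HD, or a volume-ratio
band.  The supplementary protocol criterion list is not public, so the
shipped thresholds are explicit placeholders (DSI >= 0.7, HD95 <= 15 mm —
the IOV thresholds used in the benchmark analysis itself).

Review is sequenced: volumes are reviewed every round; a treatment plan may
only be reviewed once the volumes are approved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .dosimetry import DoseGrid, DoseMetricSpec, resample_dose, structure_dose_metric
from .errors import ConfigError, SequencingError
from .geometry import AgreementResult, Mask3D, compare_masks

__all__ = [
    "CATEGORIES",
    "SEVERITIES",
    "ConstraintRule",
    "DelineationRule",
    "DeviationRecord",
    "RoundInput",
    "SubmissionRound",
    "InstitutionHistory",
    "evaluate_dose_constraints",
    "evaluate_delineation",
    "decide_round",
    "run_benchmark",
    "load_rules",
    "default_rules",
]

log = logging.getLogger(__name__)

CATEGORIES = ("target_delineation", "oar_delineation", "planning")
SEVERITIES = ("per_protocol", "acceptable_variation", "unacceptable")

_ROLE_CATEGORY = {"target": "target_delineation", "oar": "oar_delineation"}


@dataclass(frozen=True)
class ConstraintRule:
    """One protocol dose requirement, e.g. thyroid ``Dmean < 25 Gy``."""

    structure_name: str
    metric: DoseMetricSpec
    comparator: str  # "<" or ">"
    per_protocol_limit: float
    acceptable_variation_limit: Optional[float] = None
    structure_role: str = "oar"  # decides the category of a missing-structure record

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">"):
            raise ConfigError(f"comparator must be '<' or '>', got {self.comparator!r}")
        if self.structure_role not in _ROLE_CATEGORY:
            raise ConfigError(f"structure_role must be target/oar, got {self.structure_role!r}")
        band = self.acceptable_variation_limit
        if band is not None:
            lenient_ok = band > self.per_protocol_limit if self.comparator == "<" else band < self.per_protocol_limit
            if not lenient_ok:
                raise ConfigError(
                    f"acceptable_variation_limit {band} is not on the lenient side of "
                    f"{self.comparator} {self.per_protocol_limit}"
                )

    @property
    def requirement(self) -> str:
        """Human-readable protocol requirement string for reports."""
        if self.acceptable_variation_limit is None:
            return f"{self.metric.label} {self.comparator} {self.per_protocol_limit:g} Gy"
        return (
            f"{self.metric.label} {self.comparator} {self.per_protocol_limit:g}"
            f"–{self.acceptable_variation_limit:g} Gy"
        )

    def classify(self, value: float) -> str:
        if self.comparator == "<":
            if value < self.per_protocol_limit:
                return "per_protocol"
            if self.acceptable_variation_limit is not None and value < self.acceptable_variation_limit:
                return "acceptable_variation"
        else:
            if value > self.per_protocol_limit:
                return "per_protocol"
            if self.acceptable_variation_limit is not None and value > self.acceptable_variation_limit:
                return "acceptable_variation"
        return "unacceptable"


_PREDICATES = ("presence", "dsi_min", "hd_max", "volume_ratio")


@dataclass(frozen=True)
class DelineationRule:
    """One configurable volume-review criterion against the gold standard."""

    structure_name: str
    criterion_id: str
    category: str  # target_delineation or oar_delineation
    predicate: str  # presence | dsi_min | hd_max | volume_ratio
    threshold: Optional[float] = None
    band: Optional[tuple[float, float]] = None  # volume_ratio (lo, hi)
    severity_when_violated: str = "unacceptable"

    def __post_init__(self) -> None:
        if self.category not in ("target_delineation", "oar_delineation"):
            raise ConfigError(f"bad delineation category {self.category!r}")
        if self.predicate not in _PREDICATES:
            raise ConfigError(f"unknown predicate {self.predicate!r}")
        if self.severity_when_violated not in ("acceptable_variation", "unacceptable"):
            raise ConfigError(f"bad severity {self.severity_when_violated!r}")
        if self.predicate in ("dsi_min", "hd_max") and self.threshold is None:
            raise ConfigError(f"{self.predicate} requires a threshold")
        if self.predicate == "volume_ratio" and self.band is None:
            raise ConfigError("volume_ratio requires a (lo, hi) band")


@dataclass(frozen=True)
class DeviationRecord:
    """Outcome of one review criterion for one structure in one round."""

    institution_id: str
    round_number: int
    structure_name: str
    criterion_id: str
    category: str
    severity: str
    observed_value: Optional[float] = None
    limit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(f"bad category {self.category!r}")
        if self.severity not in SEVERITIES:
            raise ConfigError(f"bad severity {self.severity!r}")
        if self.round_number < 1:
            raise ConfigError("round numbers start at 1")


@dataclass
class RoundInput:
    """What an institution submitted in one round."""

    structures: Mapping[str, Mask3D] = field(default_factory=dict)
    dose: Optional[DoseGrid] = None


@dataclass
class SubmissionRound:
    """One evaluated round: records, per-structure agreement, dose metrics."""

    institution_id: str
    round_number: int
    decision: str  # accepted | resubmission_required
    records: list[DeviationRecord]
    agreements: dict[str, AgreementResult]
    dose_metrics: Optional[dict[str, dict[str, float]]] = None


@dataclass
class InstitutionHistory:
    institution_id: str
    rounds: list[SubmissionRound]

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def accepted(self) -> bool:
        return bool(self.rounds) and self.rounds[-1].decision == "accepted"

    def all_records(self) -> list[DeviationRecord]:
        return [r for rnd in self.rounds for r in rnd.records]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_dose_constraints(
    plan_metrics: Mapping[str, Mapping[str, float]],
    rules: Sequence[ConstraintRule],
    institution_id: str = "",
    round_number: int = 1,
) -> list[DeviationRecord]:
    """Classify every dose constraint; one record per rule.

    ``plan_metrics`` maps structure name to ``{metric label: value Gy}``.
    A rule whose structure has no metrics yields an unacceptable
    missing-structure record in the structure's delineation category.
    """
    records: list[DeviationRecord] = []
    for rule in rules:
        metrics = plan_metrics.get(rule.structure_name)
        if metrics is None or rule.metric.label not in metrics:
            records.append(
                DeviationRecord(
                    institution_id,
                    round_number,
                    rule.structure_name,
                    "missing_structure",
                    _ROLE_CATEGORY[rule.structure_role],
                    "unacceptable",
                    None,
                    rule.requirement,
                )
            )
            continue
        value = float(metrics[rule.metric.label])
        records.append(
            DeviationRecord(
                institution_id,
                round_number,
                rule.structure_name,
                f"dose_{rule.metric.label}",
                "planning",
                rule.classify(value),
                value,
                rule.requirement,
            )
        )
    return records


def evaluate_delineation(
    structures: Mapping[str, Mask3D],
    gold: Mapping[str, Mask3D],
    rules: Sequence[DelineationRule],
    institution_id: str = "",
    round_number: int = 1,
    hd_percentile: float = 95.0,
) -> tuple[list[DeviationRecord], dict[str, AgreementResult]]:
    """Check every volume-review rule; return violations and agreement metrics.

    Only violated rules produce records.  A structure that is absent (or
    submitted empty) yields a single unacceptable ``absent_structure`` record
    and its remaining rules are skipped — there is nothing to measure.
    """
    for rule in rules:
        if rule.structure_name not in gold:
            raise ConfigError(f"gold standard lacks structure {rule.structure_name!r}")
    records: list[DeviationRecord] = []
    agreements: dict[str, AgreementResult] = {}
    by_structure: dict[str, list[DelineationRule]] = {}
    for rule in rules:
        by_structure.setdefault(rule.structure_name, []).append(rule)

    for name, srules in by_structure.items():
        sub = structures.get(name)
        if sub is None or sub.is_empty:
            records.append(
                DeviationRecord(
                    institution_id, round_number, name, "absent_structure",
                    srules[0].category, "unacceptable", None, "structure present",
                )
            )
            continue
        agreement = compare_masks(gold[name], sub, name, hd_percentile)
        agreements[name] = agreement
        for rule in srules:
            value: Optional[float]
            if rule.predicate == "presence":
                continue  # present, satisfied
            if rule.predicate == "dsi_min":
                value, ok, limit = agreement.dsi, agreement.dsi >= rule.threshold, f"DSI >= {rule.threshold:g}"
            elif rule.predicate == "hd_max":
                value, ok, limit = agreement.hd, agreement.hd <= rule.threshold, (
                    f"HD{hd_percentile:g} <= {rule.threshold:g} mm"
                )
            else:  # volume_ratio
                lo, hi = rule.band  # type: ignore[misc]
                value = sub.n_voxels / gold[name].n_voxels
                ok, limit = lo <= value <= hi, f"{lo:g} <= V/Vgold <= {hi:g}"
            if not ok:
                records.append(
                    DeviationRecord(
                        institution_id, round_number, name, rule.criterion_id,
                        rule.category, rule.severity_when_violated, value, limit,
                    )
                )
    return records, agreements


def decide_round(records: Iterable[DeviationRecord]) -> str:
    """Accepted iff no record is unacceptable; acceptable variations pass."""
    for r in records:
        if r.severity == "unacceptable":
            return "resubmission_required"
    return "accepted"


def _round_dose_metrics(
    dose: DoseGrid,
    contours: Mapping[str, Mask3D],
    rules: Sequence[ConstraintRule],
) -> dict[str, dict[str, float]]:
    metrics: dict[str, dict[str, float]] = {}
    for rule in rules:
        mask = contours.get(rule.structure_name)
        if mask is None or mask.is_empty:
            continue
        d = dose if dose.same_grid(mask) else resample_dose(dose, mask)
        metrics.setdefault(rule.structure_name, {})[rule.metric.label] = structure_dose_metric(
            d, mask, rule.metric
        )
    return metrics


def run_benchmark(
    submissions: Mapping[str, Sequence[RoundInput]],
    gold: Mapping[str, Mask3D],
    delineation_rules: Sequence[DelineationRule],
    constraint_rules: Sequence[ConstraintRule],
    hd_percentile: float = 95.0,
    dose_on_gold_contours: bool = False,
) -> dict[str, InstitutionHistory]:
    """Run the multi-round benchmark review for every institution.

    Volumes are reviewed in every round that contains structures.  A dose
    submitted while the volumes are not (yet) approved — neither in an
    earlier round nor in the current one — raises :class:`SequencingError`.
    Dose metrics are computed on the institution's own submitted contours by
    default (``dose_on_gold_contours`` switches to the gold standard).
    """
    histories: dict[str, InstitutionHistory] = {}
    for inst, rounds in submissions.items():
        evaluated: list[SubmissionRound] = []
        delineation_approved = False
        for number, rnd in enumerate(rounds, start=1):
            records: list[DeviationRecord] = []
            agreements: dict[str, AgreementResult] = {}
            delin_ok_now = delineation_approved
            if rnd.structures:
                drecords, agreements = evaluate_delineation(
                    rnd.structures, gold, delineation_rules, inst, number, hd_percentile
                )
                records.extend(drecords)
                delin_ok_now = not any(r.severity == "unacceptable" for r in drecords)
            dose_metrics = None
            if rnd.dose is not None:
                if not delin_ok_now:
                    raise SequencingError(
                        f"{inst} round {number}: treatment plan submitted before "
                        "volume approval"
                    )
                contours = gold if dose_on_gold_contours else rnd.structures
                dose_metrics = _round_dose_metrics(rnd.dose, contours, constraint_rules)
                records.extend(
                    evaluate_dose_constraints(dose_metrics, constraint_rules, inst, number)
                )
            decision = decide_round(records)
            if delin_ok_now:
                delineation_approved = True
            for r in records:
                if r.severity != "per_protocol":
                    log.info(
                        "%s round %d: %s %s [%s/%s] value=%s limit=%s",
                        inst, number, r.structure_name, r.criterion_id,
                        r.category, r.severity, r.observed_value, r.limit,
                    )
            evaluated.append(
                SubmissionRound(inst, number, decision, records, agreements, dose_metrics)
            )
        histories[inst] = InstitutionHistory(inst, evaluated)
    return histories


# ---------------------------------------------------------------------------
# rule configuration
# ---------------------------------------------------------------------------

def _parse_rule_dicts(doc: Mapping) -> tuple[list[DelineationRule], list[ConstraintRule]]:
    delineation = []
    for d in doc.get("delineation", []):
        band = d.get("band")
        delineation.append(
            DelineationRule(
                structure_name=d["structure"],
                criterion_id=d.get("criterion", d["predicate"]),
                category=d["category"],
                predicate=d["predicate"],
                threshold=d.get("threshold"),
                band=tuple(band) if band else None,
                severity_when_violated=d.get("severity", "unacceptable"),
            )
        )
    constraints = []
    for d in doc.get("dose_constraints", []):
        constraints.append(
            ConstraintRule(
                structure_name=d["structure"],
                metric=DoseMetricSpec.parse(d["metric"]),
                comparator=d["comparator"],
                per_protocol_limit=float(d["per_protocol_limit"]),
                acceptable_variation_limit=(
                    float(d["acceptable_variation_limit"])
                    if d.get("acceptable_variation_limit") is not None
                    else None
                ),
                structure_role=d.get("role", "oar"),
            )
        )
    return delineation, constraints


def load_rules(path) -> tuple[list[DelineationRule], list[ConstraintRule]]:
    """Load delineation + dose-constraint rules from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"rule file {path} is not a mapping")
    return _parse_rule_dicts(doc)


def default_rules() -> tuple[list[DelineationRule], list[ConstraintRule]]:
    """The shipped head-and-neck benchmark rule set (EORTC 1420-like)."""
    ref = resources.files("rtqa_bench.data") / "eortc1420_rules.yaml"
    with resources.as_file(ref) as path:
        return load_rules(path)
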