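"""Published benchmark summary inputs and their reconstruction.

The EORTC 1420 benchmark programme published only summary statistics of its
81 clinical submissions (deviation counts per structure and category;
per-structure first/final agreement means and SDs), not the underlying
volumes.  This module ships those printed numbers as package data and
reconstructs observation sets with exactly the printed sample moments, so
the aggregation layer can be exercised end-to-end on the published inputs.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .cohort import PairedAgreement, values_with_moments
from .geometry import AgreementResult
from .qa_rules import DeviationRecord, InstitutionHistory, SubmissionRound

__all__ = [
    "published_deviation_records",
    "published_first_final_summary",
    "reconstruct_pairs",
    "round_count_histories",
]


def _data_path(name: str):
    return resources.files("rtqa_bench.data") / name


def published_deviation_records() -> list[DeviationRecord]:
    """The 76 unacceptable deviations of the published benchmark breakdown."""
    with resources.as_file(_data_path("eortc1420_deviation_counts.csv")) as p:
        df = pd.read_csv(p)
    records = []
    i = 0
    for _, row in df.iterrows():
        for _ in range(int(row["count"])):
            i += 1
            records.append(
                DeviationRecord(
                    institution_id=f"PUB-{i:02d}",
                    round_number=1,
                    structure_name=str(row["structure"]),
                    criterion_id="published",
                    category=str(row["category"]),
                    severity="unacceptable",
                )
            )
    return records


def published_first_final_summary() -> pd.DataFrame:
    """Per-structure first/final DSI and HD summary (n, mean, SD)."""
    with resources.as_file(_data_path("eortc1420_first_final_summary.csv")) as p:
        return pd.read_csv(p)


def _bounded_moment_values(
    n: int, mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Moment-exact values constrained to a metric's valid range."""
    for _ in range(1000):
        v = values_with_moments(n, mean, float(sd) if not np.isnan(sd) else 0.0, rng)
        if v.min() >= lo and v.max() <= hi:
            return v
    raise RuntimeError(f"cannot realise mean={mean}, sd={sd} within [{lo}, {hi}]")


def reconstruct_pairs(seed: int = 0) -> list[PairedAgreement]:
    """Per-institution first/final observations with the printed moments.

    For every structure row, draws ``n`` first and final DSI/HD values whose
    sample mean and SD equal the printed ones exactly (DSI in [0, 1], HD
    non-negative).  Per-pair differences then average to exactly the printed
    difference of means.
    """
    df = published_first_final_summary()
    pairs: list[PairedAgreement] = []
    rng = np.random.default_rng([int(seed) % (2**31), 1420])
    for row in df.itertuples():
        n = int(row.n)
        dsi_first = _bounded_moment_values(n, row.dsi_first_mean, row.dsi_first_sd, 0.0, 1.0, rng)
        dsi_final = _bounded_moment_values(n, row.dsi_final_mean, row.dsi_final_sd, 0.0, 1.0, rng)
        hd_first = _bounded_moment_values(n, row.hd_first_mean, row.hd_first_sd, 0.0, np.inf, rng)
        hd_final = _bounded_moment_values(n, row.hd_final_mean, row.hd_final_sd, 0.0, np.inf, rng)
        for i in range(n):
            first = AgreementResult(row.structure, dsi_first[i], hd_first[i], 95.0,
                                    hd_first[i], hd_first[i])
            final = AgreementResult(row.structure, dsi_final[i], hd_final[i], 95.0,
                                    hd_final[i], hd_final[i])
            pairs.append(PairedAgreement(f"PUB-{row.structure}-{i + 1}", row.structure, first, final))
    return pairs


def round_count_histories(n_multiple: int = 23, n_total: int = 35) -> list[InstitutionHistory]:
    """Minimal accepted histories realising a published resubmission count."""
    histories = []
    for i in range(n_total):
        inst = f"PUB-{i + 1:02d}"
        n_rounds = 2 if i < n_multiple else 1
        rounds = [
            SubmissionRound(inst, r + 1,
                            "accepted" if r + 1 == n_rounds else "resubmission_required",
                            [], {})
            for r in range(n_rounds)
        ]
        histories.append(InstitutionHistory(inst, rounds))
    return histories
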