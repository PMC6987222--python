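"""ddCq relative quantification against a multi-gene reference panel.

Fold change = 2^(-ddCq), with dCq = Cq(target) - Cq(reference panel) per
sample and ddCq = dCq(sample) - dCq(calibrator).  The panel Cq is the
geometric mean of the reference genes' relative quantities 2^(-Cq), which
in Cq space is simply their arithmetic mean.  Amplification efficiency is
fixed at 2 per cycle; technical replicates are averaged (arithmetic mean of
Cq) before normalization.

The default panel is GAPDH / B2M / RPLP0 with the MCF7 breast cancer cell
line as calibrator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_GENES = ("GAPDH", "B2M", "RPLP0")


@dataclass(frozen=True)
class FoldChangeResult:
    sample_id: str
    delta_cq: float
    delta_delta_cq: float
    fold_change: float


def reference_cq(cq_by_gene: Mapping[str, float],
                 reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES) -> float:
    """Panel Cq: arithmetic mean of the reference genes' Cq values.

    Equivalent to the geometric mean of their relative quantities 2^(-Cq)
    expressed back in Cq space.
    """
    missing = [g for g in reference_genes if g not in cq_by_gene]
    if missing:
        raise KeyError(f"missing reference gene(s): {', '.join(missing)}")
    return float(np.mean([cq_by_gene[g] for g in reference_genes]))


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to one mean Cq per (sample, gene).

    Expects long-format columns ``sample``, ``gene``, ``cq`` (``replicate``
    optional); non-finite Cq values are rejected.
    """
    required = {"sample", "gene", "cq"}
    if not required.issubset(table.columns):
        raise ValueError(f"Cq table needs columns {sorted(required)}")
    if not np.isfinite(table["cq"]).all():
        raise ValueError("non-finite Cq values in table")
    return table.groupby(["sample", "gene"], as_index=False)["cq"].mean()


def ddcq_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    calibrator: str,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
) -> list[FoldChangeResult]:
    """Compute per-sample fold changes relative to the calibrator sample.

    The calibrator's fold change is exactly 1 by construction.  Results
    follow the table's sample order of first appearance.
    """
    averaged = average_replicates(table)
    samples = list(dict.fromkeys(averaged["sample"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")

    delta_cq: dict[str, float] = {}
    for sample in samples:
        sub = averaged[averaged["sample"] == sample]
        cq_by_gene = dict(zip(sub["gene"], sub["cq"]))
        if target_gene not in cq_by_gene:
            raise ValueError(f"sample {sample!r} lacks target gene {target_gene!r}")
        delta_cq[sample] = cq_by_gene[target_gene] - reference_cq(cq_by_gene, reference_genes)

    cal_dcq = delta_cq[calibrator]
    results = []
    for sample in samples:
        ddcq = delta_cq[sample] - cal_dcq
        results.append(
            FoldChangeResult(
                sample_id=sample,
                delta_cq=delta_cq[sample],
                delta_delta_cq=ddcq,
                fold_change=float(2.0 ** (-ddcq)),
            )
        )
    return results


def fold_change_table(results: Sequence[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "delta_cq": [r.delta_cq for r in results],
            "delta_delta_cq": [r.delta_delta_cq for r in results],
            "fold_change": [r.fold_change for r in results],
        }
    )
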