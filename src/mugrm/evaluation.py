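"""Recovery metrics for the simulation study.

For each item parameter, RMSD and bias are computed across replications
(estimate minus generating value), and 10% trimmed means of those per-item
measures are then taken across the items of each parameter class:

* ``alpha_subscale1`` / ``alpha_subscale2`` — discriminations of the first
  and second subscale's items;
* ``delta_1`` / ``delta_2`` — first and second threshold of every item,
  pooled over both subscales;
* ``rho`` — the single intertrait correlation, aggregated across
  replications only (no trimming).

Trimming drops floor(proportion * n) values from each tail after sorting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import StudyCondition

__all__ = [
    "RecoveryCell",
    "rmsd_per_item",
    "bias_per_item",
    "trimmed_mean",
    "condition_cells",
    "assemble_recovery_table",
    "render_recovery_table",
]

PARAMETER_CLASSES = ("alpha_subscale1", "alpha_subscale2", "delta_1", "delta_2", "rho")


@dataclass(frozen=True)
class RecoveryCell:
    """Trimmed-mean RMSD and bias for one (condition, method, class)."""

    condition: StudyCondition
    method: str
    parameter_class: str
    rmsd: float
    bias: float


def rmsd_per_item(estimates: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared difference across replications for one parameter."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.size == 0 or estimates.shape != truth.shape:
        raise ValueError("estimates and truth must be equal-length and non-empty")
    return float(np.sqrt(np.mean(np.square(estimates - truth))))


def bias_per_item(estimates: np.ndarray, truth: np.ndarray) -> float:
    """Signed mean difference (estimate - truth) across replications."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.size == 0 or estimates.shape != truth.shape:
        raise ValueError("estimates and truth must be equal-length and non-empty")
    return float(np.mean(estimates - truth))


def trimmed_mean(values: Sequence[float], proportion: float = 0.10) -> float:
    """Mean after dropping floor(proportion * n) values from each tail."""
    if not 0 <= proportion < 0.5:
        raise ValueError("proportion must lie in [0, 0.5)")
    v = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(proportion * v.size))
    if v.size - 2 * k <= 0:
        raise ValueError("all values would be trimmed")
    return float(v[k : v.size - k].mean())


def _class_indices(condition: StudyCondition, parameter_class: str):
    """(kind, selector) describing which parameters a class collects."""
    design = condition.design
    if parameter_class == "alpha_subscale1":
        return "alpha", design.items_on(0)
    if parameter_class == "alpha_subscale2":
        return "alpha", design.items_on(1)
    if parameter_class == "delta_1":
        return "delta", 0
    if parameter_class == "delta_2":
        return "delta", 1
    if parameter_class == "rho":
        return "rho", None
    raise ValueError(f"unknown parameter class {parameter_class!r}")


def condition_cells(
    condition: StudyCondition,
    method: str,
    truths: Iterable[dict],
    estimates: Iterable[dict],
    trim: float = 0.10,
    per_subscale_thresholds: bool = False,
) -> list[RecoveryCell]:
    """Recovery cells for one (condition, method) from per-replication
    parameter dicts with keys ``alpha`` (K,), ``thresholds`` (K, C-1) and
    ``rho`` (scalar).

    RMSD/bias are taken per item across replications first, then 10%
    trimmed means across the items of each class; rho is aggregated across
    replications without trimming.  ``per_subscale_thresholds`` switches
    the threshold classes from pooled-over-all-items to per-subscale
    (delta_1/delta_2 then read subscale-1/subscale-2 thresholds).
    """
    truths = list(truths)
    estimates = list(estimates)
    if len(truths) != len(estimates) or not truths:
        raise ValueError("need equal, non-empty truth and estimate lists")
    est_alpha = np.stack([np.asarray(e["alpha"], dtype=float) for e in estimates])
    tru_alpha = np.stack([np.asarray(t["alpha"], dtype=float) for t in truths])
    est_delta = np.stack([np.asarray(e["thresholds"], dtype=float) for e in estimates])
    tru_delta = np.stack([np.asarray(t["thresholds"], dtype=float) for t in truths])
    est_rho = np.array([float(e["rho"]) for e in estimates])
    tru_rho = np.array([float(t["rho"]) for t in truths])

    design = condition.design
    cells = []
    for pc in PARAMETER_CLASSES:
        kind, sel = _class_indices(condition, pc)
        if kind == "alpha":
            per_item_rmsd = [
                rmsd_per_item(est_alpha[:, j], tru_alpha[:, j]) for j in sel
            ]
            per_item_bias = [
                bias_per_item(est_alpha[:, j], tru_alpha[:, j]) for j in sel
            ]
            cells.append(
                RecoveryCell(
                    condition,
                    method,
                    pc,
                    trimmed_mean(per_item_rmsd, trim),
                    trimmed_mean(per_item_bias, trim),
                )
            )
        elif kind == "delta":
            if per_subscale_thresholds:
                items = design.items_on(sel)
                pairs = [(j, c) for j in items for c in range(est_delta.shape[2])]
            else:
                pairs = [(j, sel) for j in range(design.n_items)]
            per_item_rmsd = [
                rmsd_per_item(est_delta[:, j, c], tru_delta[:, j, c]) for j, c in pairs
            ]
            per_item_bias = [
                bias_per_item(est_delta[:, j, c], tru_delta[:, j, c]) for j, c in pairs
            ]
            cells.append(
                RecoveryCell(
                    condition,
                    method,
                    pc,
                    trimmed_mean(per_item_rmsd, trim),
                    trimmed_mean(per_item_bias, trim),
                )
            )
        else:  # rho: single parameter, across replications, no trimming
            cells.append(
                RecoveryCell(
                    condition,
                    method,
                    pc,
                    rmsd_per_item(est_rho, tru_rho),
                    bias_per_item(est_rho, tru_rho),
                )
            )
    return cells


def assemble_recovery_table(cells: Iterable[RecoveryCell]) -> pd.DataFrame:
    """Long-format table keyed by (condition, method, parameter_class,
    metric); raises listing the gaps when a (condition, method) block is
    missing a parameter class."""
    rows = []
    for cell in cells:
        for metric, value in (("rmsd", cell.rmsd), ("bias", cell.bias)):
            rows.append(
                {
                    "n_persons": cell.condition.n_persons,
                    "n_items": cell.condition.n_items,
                    "rho_true": cell.condition.rho,
                    "method": cell.method,
                    "parameter_class": cell.parameter_class,
                    "metric": metric,
                    "value": value,
                }
            )
    if not rows:
        raise ValueError("no recovery cells supplied")
    df = pd.DataFrame(rows)
    gaps = []
    for keys, block in df.groupby(["n_persons", "n_items", "rho_true", "method"]):
        missing = set(PARAMETER_CLASSES) - set(block["parameter_class"])
        if missing:
            gaps.append((keys, sorted(missing)))
    if gaps:
        raise ValueError(f"incomplete recovery table; missing cells: {gaps}")
    return df.sort_values(
        ["n_persons", "n_items", "rho_true", "method", "parameter_class", "metric"]
    ).reset_index(drop=True)


def render_recovery_table(df: pd.DataFrame) -> str:
    """Human-readable block rendering: per condition, methods in columns,
    RMSD rows (with bias rows beneath) per parameter class."""
    out = []
    for (n, k, rho), block in df.groupby(["n_persons", "n_items", "rho_true"]):
        out.append(f"N={n}, K={k}, true rho={rho:g}")
        pivot = block.pivot_table(
            index=["parameter_class", "metric"],
            columns="method",
            values="value",
            sort=False,
        )
        pivot = pivot.reindex(
            [(pc, m) for pc in PARAMETER_CLASSES for m in ("rmsd", "bias")]
        )
        out.append(pivot.round(3).to_string())
        out.append("")
    return "\n".join(out)
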