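"""Synthetic-data generation for the parameter-recovery study.

Study conditions: N in {500, 1000} persons answer K in {20, 40} three-category
Likert items split evenly over two subscales; the two latent traits follow a
bivariate standard normal with correlation rho in {0.2, 0.5, 0.8}.  Item
discriminations are drawn U(0, 2); each item's two thresholds are the order
statistics of two independent standard-normal draws.  Responses follow the
probit multi-unidimensional GRM.

Each (condition, replication) pair owns an independent RNG stream derived
from the master seed, so any single replication can be regenerated in
isolation and in any order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grm_core import (
    ItemParameters,
    TestDesign,
    TraitCorrelation,
    padded_thresholds,
    validate_responses,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyCondition",
    "TruthBundle",
    "replication_rng",
    "generate_item_parameters",
    "generate_traits",
    "generate_responses",
    "generate_dataset",
    "write_bundle",
    "read_bundle",
]


@dataclass(frozen=True)
class StudyCondition:
    """One cell of the N x K x rho factorial design."""

    n_persons: int
    n_items: int
    rho: float
    n_categories: int = 3
    n_dims: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.n_items % self.n_dims:
            raise ValueError("items must split evenly across subscales")

    @property
    def design(self) -> TestDesign:
        return TestDesign.simple_structure(self.n_items, self.n_dims, self.n_categories)

    def label(self) -> str:
        return f"N{self.n_persons}_K{self.n_items}_rho{self.rho:g}"


@dataclass
class TruthBundle:
    """A generated dataset together with its generating parameters."""

    condition: StudyCondition
    design: TestDesign
    params: ItemParameters
    theta: np.ndarray
    Y: np.ndarray
    n_regenerated: int = 0


def replication_rng(condition: StudyCondition, replication: int = 0) -> np.random.Generator:
    """Independent stream for one (condition, replication) pair.

    The stream key mixes the condition's master seed with its design fields
    and the replication index, so reruns of any subset of the factorial
    reproduce the same data bit-for-bit.
    """
    key = (
        int(condition.seed),
        condition.n_persons,
        condition.n_items,
        int(round(condition.rho * 1000)) & 0x7FFFFFFF,
        condition.n_categories,
        int(replication),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_item_parameters(
    condition: StudyCondition, rng: np.random.Generator
) -> ItemParameters:
    """alpha_vj ~ U(0, 2); thresholds = sorted pair of N(0, 1) draws."""
    K = condition.n_items
    alpha = rng.uniform(0.0, 2.0, size=K)
    while (alpha == 0.0).any():  # open interval: a zero slope is not identified
        alpha[alpha == 0.0] = rng.uniform(0.0, 2.0, size=(alpha == 0.0).sum())
    draws = rng.standard_normal((K, condition.n_categories - 1))
    thresholds = np.sort(draws, axis=1)
    return ItemParameters(alpha, list(thresholds))


def generate_traits(condition: StudyCondition, rng: np.random.Generator) -> np.ndarray:
    """N draws from N_m(0, P) with unit variances and correlation rho."""
    P = TraitCorrelation.from_rho(condition.rho, condition.n_dims)
    z = rng.standard_normal((condition.n_persons, condition.n_dims))
    return z @ P.cholesky().T


def generate_responses(
    theta: np.ndarray,
    params: ItemParameters,
    design: TestDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ordinal responses from the probit GRM, vectorised via the
    cumulative representation P(Y > c) = Phi(alpha*theta - delta_c)."""
    from scipy.special import ndtr

    N = theta.shape[0]
    D = padded_thresholds(params, design.max_categories)
    eta = theta[:, design.loading] * params.alpha  # (N, K)
    # survivor values S_c = P(Y > c) at the interior cut-points, (N, K, C-1)
    S = ndtr(eta[:, :, None] - D[None, :, 1:-1])
    u = rng.uniform(size=(N, design.n_items))
    Y = 1 + (u[:, :, None] < S).sum(axis=2)
    # entries for padded categories have S = 0 and never count
    return Y.astype(np.intp)


def _all_categories_observed(Y: np.ndarray, design: TestDesign) -> bool:
    for j in range(design.n_items):
        if np.unique(Y[:, j]).size < design.n_categories[j]:
            return False
    return True


def generate_dataset(
    condition: StudyCondition,
    replication: int = 0,
    max_attempts: int = 20,
) -> TruthBundle:
    """Full generative pipeline for one replication.

    Item parameters, traits and responses are all drawn afresh per
    replication.  On the rare event of an item with an unobserved category
    (all estimators need every category seen), the whole draw is repeated
    with the stream's next sub-seed and the event is logged.
    """
    design = condition.design
    rng = replication_rng(condition, replication)
    for attempt in range(max_attempts):
        params = generate_item_parameters(condition, rng)
        theta = generate_traits(condition, rng)
        Y = generate_responses(theta, params, design, rng)
        if _all_categories_observed(Y, design):
            return TruthBundle(condition, design, params, theta, Y, attempt)
        logger.info(
            "degenerate dataset (unobserved category) at %s rep %d, attempt %d; regenerating",
            condition.label(),
            replication,
            attempt,
        )
    raise RuntimeError("could not generate a dataset with all categories observed")


# ---------------------------------------------------------------------------
# Truth-bundle IO: three CSVs plus a JSON sidecar
# ---------------------------------------------------------------------------


def write_bundle(directory: str | Path, bundle: TruthBundle, replication: int = 0) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    design_df = bundle.design.to_frame()
    item_ids = [f"item{j}" for j in design_df["item_id"]]
    pd.DataFrame(bundle.Y, columns=item_ids).to_csv(directory / "responses.csv", index=False)
    bundle.params.to_frame().to_csv(directory / "item_parameters.csv", index=False)
    theta_cols = [f"theta{v + 1}" for v in range(bundle.design.n_dims)]
    pd.DataFrame(bundle.theta, columns=theta_cols).to_csv(directory / "traits.csv", index=False)
    design_df.to_csv(directory / "design.csv", index=False)
    sidecar = {
        "condition": asdict(bundle.condition),
        "replication": replication,
        "n_regenerated": bundle.n_regenerated,
    }
    (directory / "condition.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_bundle(directory: str | Path) -> TruthBundle:
    directory = Path(directory)
    sidecar = json.loads((directory / "condition.json").read_text())
    condition = StudyCondition(**sidecar["condition"])
    design = TestDesign.from_frame(pd.read_csv(directory / "design.csv"))
    params = ItemParameters.from_frame(pd.read_csv(directory / "item_parameters.csv"))
    theta = pd.read_csv(directory / "traits.csv").to_numpy(dtype=float)
    Y = pd.read_csv(directory / "responses.csv").to_numpy(dtype=np.intp)
    validate_responses(Y, design)
    return TruthBundle(condition, design, params, theta, Y, sidecar.get("n_regenerated", 0))
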