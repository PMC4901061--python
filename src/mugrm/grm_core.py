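"""Core data structures and probability computations for the
multi-unidimensional graded response model (GRM).

The model: a K-item instrument is partitioned into m subscales, each item
loading on exactly one latent dimension (simple structure).  For person i,
item j on dimension v with discrimination ``alpha`` and ordered thresholds
``delta_1 < ... < delta_{C-1}``, the probability of responding in category
c (coded 1..C) is

    P(Y = c | theta, alpha, delta) = F(alpha*theta - delta_{c-1})
                                     - F(alpha*theta - delta_c),

with the boundary conventions delta_0 = -inf and delta_C = +inf, and F the
standard-normal (probit) or logistic CDF.  The unidimensional GRM is the
m = 1 special case.

Category codes are 1-based at the interfaces (matching the conventional
c = 1..C notation); any 0-based indexing is internal and confined to the
``padded_thresholds`` boundary-lookup helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

Link = Literal["probit", "logistic"]

__all__ = [
    "Link",
    "TestDesign",
    "ItemParameters",
    "TraitCorrelation",
    "link_cdf",
    "category_probability",
    "log_likelihood",
    "padded_thresholds",
    "response_logprob_matrix",
    "validate_responses",
]


def link_cdf(x: np.ndarray | float, link: Link = "probit"):
    """CDF of the chosen response function (no logistic scaling constant)."""
    if link == "probit":
        return ndtr(x)
    if link == "logistic":
        return expit(x)
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestDesign:
    """Simple-structure loading map: which dimension each item measures.

    Parameters
    ----------
    n_items : int
        Number of items K.
    n_dims : int
        Number of subscales / latent dimensions m.
    loading : array of int, shape (K,)
        0-based dimension index of each item.
    n_categories : array of int, shape (K,)
        Number of ordered response categories per item (C_j >= 2).
    """

    n_items: int
    n_dims: int
    loading: np.ndarray
    n_categories: np.ndarray

    def __post_init__(self) -> None:
        loading = np.asarray(self.loading, dtype=np.intp)
        ncat = np.asarray(self.n_categories, dtype=np.intp)
        object.__setattr__(self, "loading", loading)
        object.__setattr__(self, "n_categories", ncat)
        if loading.shape != (self.n_items,):
            raise ValueError("loading must have one entry per item")
        if ncat.shape != (self.n_items,):
            raise ValueError("n_categories must have one entry per item")
        if loading.min(initial=0) < 0 or (self.n_items and loading.max() >= self.n_dims):
            raise ValueError("loading indices must lie in [0, n_dims)")
        counts = np.bincount(loading, minlength=self.n_dims)
        if (counts == 0).any():
            raise ValueError("every dimension must receive at least one item")
        if (ncat < 2).any():
            raise ValueError("every item needs at least two categories")

    @classmethod
    def simple_structure(
        cls, n_items: int, n_dims: int = 2, n_categories: int = 3
    ) -> "TestDesign":
        """Items split into ``n_dims`` contiguous equal blocks (first half on
        trait 1, second half on trait 2, ...)."""
        if n_items % n_dims:
            raise ValueError("n_items must divide evenly across dimensions")
        per = n_items // n_dims
        loading = np.repeat(np.arange(n_dims), per)
        return cls(n_items, n_dims, loading, np.full(n_items, n_categories))

    @property
    def max_categories(self) -> int:
        return int(self.n_categories.max())

    def items_on(self, dim: int) -> np.ndarray:
        return np.flatnonzero(self.loading == dim)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": np.arange(1, self.n_items + 1),
                "dimension": self.loading + 1,
                "n_categories": self.n_categories,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TestDesign":
        df = df.sort_values("item_id")
        loading = df["dimension"].to_numpy(dtype=np.intp) - 1
        return cls(len(df), int(loading.max()) + 1, loading, df["n_categories"].to_numpy())


@dataclass
class ItemParameters:
    """Discriminations and ordered category thresholds for all items.

    ``alpha`` is strictly positive (the reflection of each latent axis is
    identified by forcing positive slopes).  ``thresholds[j]`` holds the
    C_j - 1 strictly increasing interior cut-points of item j; the infinite
    boundary cut-points are implicit and applied by :func:`padded_thresholds`.
    """

    alpha: np.ndarray
    thresholds: list[np.ndarray]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        self.validate()

    def validate(self) -> None:
        if len(self.thresholds) != self.alpha.shape[0]:
            raise ValueError("one threshold vector per item required")
        if (self.alpha <= 0).any():
            raise ValueError("all discriminations must be positive")
        for j, t in enumerate(self.thresholds):
            if t.size and (np.diff(t) <= 0).any():
                raise ValueError(f"thresholds of item {j} are not strictly increasing")

    @property
    def n_items(self) -> int:
        return self.alpha.shape[0]

    def n_categories(self) -> np.ndarray:
        return np.array([t.size + 1 for t in self.thresholds], dtype=np.intp)

    def thresholds_matrix(self) -> np.ndarray:
        """Dense (K, C-1) threshold matrix; requires a homogeneous C."""
        sizes = {t.size for t in self.thresholds}
        if len(sizes) != 1:
            raise ValueError("items have heterogeneous category counts")
        return np.vstack(self.thresholds)

    def copy(self) -> "ItemParameters":
        return ItemParameters(self.alpha.copy(), [t.copy() for t in self.thresholds])

    def to_frame(self) -> pd.DataFrame:
        cmax = max(t.size for t in self.thresholds)
        data = {"item_id": np.arange(1, self.n_items + 1), "alpha": self.alpha}
        for c in range(cmax):
            data[f"delta_{c + 1}"] = [
                t[c] if c < t.size else np.nan for t in self.thresholds
            ]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemParameters":
        df = df.sort_values("item_id")
        cols = sorted(
            (c for c in df.columns if c.startswith("delta_")),
            key=lambda c: int(c.split("_")[1]),
        )
        thresholds = [
            row[~np.isnan(row)] for row in df[cols].to_numpy(dtype=float)
        ]
        return cls(df["alpha"].to_numpy(dtype=float), thresholds)


@dataclass(frozen=True)
class TraitCorrelation:
    """m x m intertrait correlation matrix P (symmetric, unit diagonal, PD)."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if not np.allclose(P, P.T):
            raise ValueError("P must be symmetric")
        if not np.allclose(np.diag(P), 1.0):
            raise ValueError("P must have a unit diagonal")
        try:
            np.linalg.cholesky(P)
        except np.linalg.LinAlgError as exc:
            raise ValueError("P must be positive definite") from exc

    @classmethod
    def from_rho(cls, rho: float, m: int = 2) -> "TraitCorrelation":
        if m == 2:
            return cls(np.array([[1.0, rho], [rho, 1.0]]))
        P = np.full((m, m), rho, dtype=float)
        np.fill_diagonal(P, 1.0)
        return cls(P)

    @property
    def m(self) -> int:
        return self.P.shape[0]

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.P)


# ---------------------------------------------------------------------------
# Probability computations
# ---------------------------------------------------------------------------


def padded_thresholds(params: ItemParameters, max_categories: int | None = None) -> np.ndarray:
    """Threshold boundary table D of shape (K, Cmax + 1).

    D[j, 0] = -inf, D[j, c] = delta_{j,c} for interior cut-points, and
    D[j, c] = +inf for c >= C_j, so the category-c interval of item j is
    (D[j, c-1], D[j, c]) for every valid 1-based c.
    """
    cmax = max_categories or int(max(t.size + 1 for t in params.thresholds))
    D = np.full((params.n_items, cmax + 1), np.inf)
    D[:, 0] = -np.inf
    for j, t in enumerate(params.thresholds):
        D[j, 1 : 1 + t.size] = t
    return D


def category_probability(
    theta_v: float | np.ndarray,
    alpha_j: float,
    thresholds_j: Sequence[float] | np.ndarray,
    c: int,
    link: Link = "probit",
) -> float | np.ndarray:
    """P(Y = c | theta, alpha, delta) for one item, vectorised over theta.

    ``c`` is 1-based; the infinite boundary thresholds are applied
    automatically.
    """
    t = np.asarray(thresholds_j, dtype=float)
    if t.size and (np.diff(t) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    n_cat = t.size + 1
    if not 1 <= c <= n_cat:
        raise ValueError(f"category {c} out of range 1..{n_cat}")
    eta = alpha_j * np.asarray(theta_v, dtype=float)
    upper = 1.0 if c == 1 else link_cdf(eta - t[c - 2], link)
    lower = 0.0 if c == n_cat else link_cdf(eta - t[c - 1], link)
    return upper - lower


def validate_responses(Y: np.ndarray, design: TestDesign) -> np.ndarray:
    """Check an N x K ordinal response matrix (1-based codes) against a design."""
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[1] != design.n_items:
        raise ValueError("response matrix must be N x n_items")
    if not np.issubdtype(Y.dtype, np.integer):
        raise ValueError("responses must be integer category codes")
    if (Y < 1).any() or (Y > design.n_categories[None, :]).any():
        raise ValueError("response codes outside 1..C_j found")
    return Y


def response_logprob_matrix(
    Y: np.ndarray,
    theta: np.ndarray,
    params: ItemParameters,
    design: TestDesign,
    link: Link = "probit",
    D: np.ndarray | None = None,
) -> np.ndarray:
    """Elementwise log P(Y_ij) as an (N, K) matrix; -inf where the model
    assigns zero probability."""
    if D is None:
        D = padded_thresholds(params, design.max_categories)
    eta = theta[:, design.loading] * params.alpha  # (N, K)
    cols = np.arange(design.n_items)
    lower = D[cols, Y - 1]  # delta_{c-1}, (N, K)
    upper = D[cols, Y]  # delta_c
    prob = link_cdf(eta - lower, link) - link_cdf(eta - upper, link)
    with np.errstate(divide="ignore"):
        return np.log(prob)


def log_likelihood(
    Y: np.ndarray,
    theta: np.ndarray,
    params: ItemParameters,
    design: TestDesign,
    link: Link = "probit",
) -> float:
    """Joint log-likelihood sum_{i,j} log P(Y_ij | theta_i, alpha_j, delta_j).

    Returns ``-inf`` (rather than raising) when any observed cell has zero
    probability under the parameters.
    """
    Y = validate_responses(Y, design)
    lp = response_logprob_matrix(Y, theta, params, design, link)
    if np.isneginf(lp).any():
        return -np.inf
    return float(lp.sum())
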