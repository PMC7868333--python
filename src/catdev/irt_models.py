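"""Polytomous item response models: category probabilities, likelihoods, information.

Four unidimensional models for ordered (or nominal) categorical responses are
supported on a common latent-trait metric theta:

* GRM  -- graded response model (cumulative logits); a dichotomous item is its
  K = 2 special case with a single threshold.
* GPCM -- generalized partial credit model (adjacent-category logits with a
  per-item slope).
* PCM  -- partial credit model; the GPCM with the slope fixed at 1.
* NRM  -- nominal response model; per-category slopes/intercepts with the
  first category anchored at zero.

All probabilities use the pure logistic metric (scaling constant D = 1).
Category codes are 0-based; the missing-response sentinel is :data:`MISSING`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .errors import InvalidItemError, InvalidResponseError, MissingItemError

#: Sentinel for a missing response code. Never a valid category.
MISSING: int = -1

#: Probability floor applied before logarithms and divisions so that
#: likelihood and information stay finite at extreme theta.
PROB_FLOOR: float = 1e-10

MODELS = ("GRM", "GPCM", "PCM", "NRM")
SOURCE_SCALES = ("SPQ", "REF", "FFSI", "synthetic")


@dataclass(frozen=True)
class ItemParameters:
    """A single polytomous item.

    Parameters
    ----------
    item_id : str
        Unique identifier within a bank.
    n_categories : int
        Number of response categories K >= 2 (codes 0..K-1).
    slope : float
        Discrimination *a*. Unused for NRM; fixed at 1 for PCM.
    thresholds : tuple of float
        K-1 location/step parameters b_1..b_{K-1} on the logit metric.
        Strictly increasing for the GRM.
    nrm_slopes, nrm_intercepts : tuple of float
        Per-category NRM parameters (length K, first entry 0).
    source_scale : str
        Instrument of origin ("SPQ", "REF", "FFSI", or "synthetic").
    criterion : str
        Diagnostic-criterion content label, or "unknown".
    """

    item_id: str
    n_categories: int
    slope: float = 1.0
    thresholds: tuple = ()
    model: str = "GRM"
    nrm_slopes: tuple = ()
    nrm_intercepts: tuple = ()
    source_scale: str = "synthetic"
    criterion: str = "unknown"

    def __post_init__(self):
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        object.__setattr__(self, "nrm_slopes", tuple(float(v) for v in self.nrm_slopes))
        object.__setattr__(
            self, "nrm_intercepts", tuple(float(v) for v in self.nrm_intercepts)
        )
        self.validate()

    def validate(self) -> None:
        K = self.n_categories
        if self.model not in MODELS:
            raise InvalidItemError(f"{self.item_id}: unknown model {self.model!r}")
        if K < 2:
            raise InvalidItemError(f"{self.item_id}: n_categories must be >= 2, got {K}")
        if not np.isfinite(self.slope):
            raise InvalidItemError(f"{self.item_id}: slope must be finite")
        if self.model == "PCM" and self.slope != 1.0:
            raise InvalidItemError(f"{self.item_id}: PCM requires slope == 1")
        if self.model == "NRM":
            if len(self.nrm_slopes) != K or len(self.nrm_intercepts) != K:
                raise InvalidItemError(
                    f"{self.item_id}: NRM needs {K} per-category slopes/intercepts"
                )
            if self.nrm_slopes[0] != 0.0 or self.nrm_intercepts[0] != 0.0:
                raise InvalidItemError(
                    f"{self.item_id}: NRM first-category parameters must be anchored at 0"
                )
        else:
            if len(self.thresholds) != K - 1:
                raise InvalidItemError(
                    f"{self.item_id}: expected {K - 1} thresholds, got {len(self.thresholds)}"
                )
            if self.model == "GRM" and K > 2:
                diffs = np.diff(self.thresholds)
                if not np.all(diffs > 0):
                    raise InvalidItemError(
                        f"{self.item_id}: GRM thresholds must be strictly increasing"
                    )


def _as_grid(theta) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(theta, dtype=float))
    return arr, np.ndim(theta) == 0


def _grm_cumulative(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Cumulative endorsement curves P*_k(theta), shape (T, K-1)."""
    b = np.asarray(item.thresholds)
    return expit(item.slope * (theta[:, None] - b[None, :]))


def _probs_grid(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Category probabilities on a theta grid, shape (T, K)."""
    T, K = theta.shape[0], item.n_categories
    if item.model == "GRM":
        star = _grm_cumulative(theta, item)
        full = np.concatenate(
            [np.ones((T, 1)), star, np.zeros((T, 1))], axis=1
        )
        return full[:, :-1] - full[:, 1:]
    if item.model in ("GPCM", "PCM"):
        a = item.slope
        b = np.asarray(item.thresholds)
        # log-numerator for category k: sum_{v<=k} a (theta - b_v), empty sum = 0
        steps = a * (theta[:, None] - b[None, :])            # (T, K-1)
        lognum = np.concatenate([np.zeros((T, 1)), np.cumsum(steps, axis=1)], axis=1)
        lognum -= lognum.max(axis=1, keepdims=True)
        num = np.exp(lognum)
        return num / num.sum(axis=1, keepdims=True)
    # NRM
    ak = np.asarray(item.nrm_slopes)
    ck = np.asarray(item.nrm_intercepts)
    logits = theta[:, None] * ak[None, :] + ck[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    num = np.exp(logits)
    return num / num.sum(axis=1, keepdims=True)


def _dprobs_grid(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Analytic derivatives dP_k/dtheta on a grid, shape (T, K)."""
    T = theta.shape[0]
    if item.model == "GRM":
        star = _grm_cumulative(theta, item)
        dstar = item.slope * star * (1.0 - star)
        full = np.concatenate([np.zeros((T, 1)), dstar, np.zeros((T, 1))], axis=1)
        return full[:, :-1] - full[:, 1:]
    P = _probs_grid(theta, item)
    if item.model in ("GPCM", "PCM"):
        k = np.arange(item.n_categories, dtype=float)
        kbar = P @ k
        return item.slope * P * (k[None, :] - kbar[:, None])
    ak = np.asarray(item.nrm_slopes)
    abar = P @ ak
    return P * (ak[None, :] - abar[:, None])


def category_probs(theta, item: ItemParameters) -> np.ndarray:
    """Probability of each response category at ``theta``.

    For the GRM the category-k probability is the difference of adjacent
    cumulative logistic curves, P*_k - P*_{k+1} with P*_0 = 1 and P*_K = 0.
    Returns a length-K vector summing to 1 (for scalar theta), or a (T, K)
    array for an array of thetas.
    """
    grid, scalar = _as_grid(theta)
    if not np.all(np.isfinite(grid)):
        raise ValueError("theta must be finite")
    P = _probs_grid(grid, item)
    return P[0] if scalar else P


def item_information(theta, item: ItemParameters):
    """Fisher information of one item, I_j(theta) = sum_k P'_k(theta)^2 / P_k(theta).

    Uses analytic derivatives of the category probabilities; a probability
    floor keeps the quotient finite for near-zero categories.
    """
    grid, scalar = _as_grid(theta)
    P = np.maximum(_probs_grid(grid, item), PROB_FLOOR)
    dP = _dprobs_grid(grid, item)
    info = np.sum(dP * dP / P, axis=1)
    return float(info[0]) if scalar else info


class ItemBank:
    """An ordered, uniquely keyed collection of :class:`ItemParameters`.

    Caches array views of GRM parameters so that bank-level probability,
    information, and likelihood evaluations are vectorized over items;
    mixed-model banks fall back to per-item loops.
    """

    def __init__(self, items: Iterable[ItemParameters]):
        self.items: list[ItemParameters] = list(items)
        self._index: dict[str, int] = {}
        for i, it in enumerate(self.items):
            if it.item_id in self._index:
                raise InvalidItemError(f"duplicate item id {it.item_id!r}")
            self._index[it.item_id] = i
        self._all_grm = all(it.model == "GRM" for it in self.items)
        self._build_arrays()

    def _build_arrays(self) -> None:
        if not self.items or not self._all_grm:
            self._a = self._B = self._K = None
            return
        J = len(self.items)
        Kmax = max(it.n_categories for it in self.items)
        a = np.array([it.slope for it in self.items])
        K = np.array([it.n_categories for it in self.items])
        B = np.full((J, Kmax - 1), np.nan)
        for j, it in enumerate(self.items):
            B[j, : it.n_categories - 1] = it.thresholds
        self._a, self._B, self._K = a, B, K
        self._pad = np.arange(Kmax - 1)[None, :] >= (K - 1)[:, None]  # (J, Kmax-1)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        try:
            return self.items[self._index[item_id]]
        except KeyError:
            raise MissingItemError(f"item {item_id!r} not in bank") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def position(self, item_id: str) -> int:
        try:
            return self._index[item_id]
        except KeyError:
            raise MissingItemError(f"item {item_id!r} not in bank") from None

    def subset(self, item_ids: Sequence[str]) -> "ItemBank":
        return ItemBank([self[i] for i in item_ids])

    def max_categories(self) -> int:
        return max(it.n_categories for it in self.items) if self.items else 0

    # -- vectorized evaluations ---------------------------------------------
    def _cum_grid(self, grid: np.ndarray) -> np.ndarray:
        """GRM cumulative curves, shape (T, J, Kmax-1); padded entries are 0."""
        star = expit(self._a[None, :, None] * (grid[:, None, None] - self._B[None, :, :]))
        star[:, self._pad] = 0.0
        return star

    def prob_tensor(self, grid) -> np.ndarray:
        """Category probabilities for every item, shape (T, J, Kmax), padded with 0."""
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        T, J, Kmax = grid.shape[0], len(self.items), self.max_categories()
        out = np.zeros((T, J, Kmax))
        if self._all_grm:
            star = self._cum_grid(grid)
            full = np.concatenate(
                [np.ones((T, J, 1)), star, np.zeros((T, J, 1))], axis=2
            )
            diff = full[:, :, :-1] - full[:, :, 1:]
            # last real category per item absorbs the padded tail of the diff
            for j, it in enumerate(self.items):
                K = it.n_categories
                out[:, j, :K] = diff[:, j, :K]
                out[:, j, K - 1] = full[:, j, K - 1]
            return out
        for j, it in enumerate(self.items):
            out[:, j, : it.n_categories] = _probs_grid(grid, it)
        return out

    def log_prob_tensor(self, grid) -> np.ndarray:
        """log category probabilities (floored), padded categories = -inf."""
        P = self.prob_tensor(grid)
        with np.errstate(divide="ignore"):
            logP = np.log(np.maximum(P, PROB_FLOOR))
        for j, it in enumerate(self.items):
            logP[:, j, it.n_categories:] = -np.inf
        return logP

    def information_matrix(self, grid) -> np.ndarray:
        """Item information for every item on a theta grid, shape (T, J)."""
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        out = np.empty((grid.shape[0], len(self.items)))
        for j, it in enumerate(self.items):
            out[:, j] = item_information(grid, it)
        return out

    def information_at(self, theta: float, positions=None) -> np.ndarray:
        """Per-item information at a single theta (vectorized over items)."""
        if self._all_grm and self.items:
            a, B = self._a, self._B
            if positions is not None:
                a, B, pad = a[positions], B[positions], self._pad[positions]
            else:
                pad = self._pad
            star = expit(a[:, None] * (theta - B))
            star = np.where(pad, 0.0, star)
            dstar = a[:, None] * star * (1.0 - star)
            J = a.shape[0]
            full = np.concatenate([np.ones((J, 1)), star, np.zeros((J, 1))], axis=1)
            dfull = np.concatenate([np.zeros((J, 1)), dstar, np.zeros((J, 1))], axis=1)
            P = np.maximum(full[:, :-1] - full[:, 1:], PROB_FLOOR)
            dP = dfull[:, :-1] - dfull[:, 1:]
            return np.sum(dP * dP / P, axis=1)
        idx = range(len(self.items)) if positions is None else positions
        return np.array([item_information(theta, self.items[j]) for j in idx])

    def expected_scores(self, grid) -> np.ndarray:
        """Model-implied expected item scores E[x_j | theta], shape (T, J)."""
        P = self.prob_tensor(grid)
        k = np.arange(self.max_categories(), dtype=float)
        return P @ k


def test_information(theta: float, bank: ItemBank, subset: Iterable[str]) -> float:
    """Test information: the sum of item information over ``subset`` at ``theta``.

    Additive over disjoint subsets; an empty subset carries zero information.
    """
    positions = [bank.position(i) for i in subset]
    if not positions:
        return 0.0
    return float(np.sum(bank.information_at(float(theta), np.asarray(positions))))


def response_loglik(pattern: Sequence[int], bank: ItemBank, theta: float) -> float:
    """Log-likelihood of a response pattern at ``theta``.

    ``pattern`` is aligned with the bank's item order; entries equal to
    :data:`MISSING` contribute nothing. Codes outside [0, K_j - 1] raise
    :class:`InvalidResponseError`.
    """
    total = 0.0
    grid = np.array([float(theta)])
    for code, item in zip(pattern, bank):
        if code == MISSING:
            continue
        if not (0 <= code < item.n_categories):
            raise InvalidResponseError(
                f"code {code} invalid for item {item.item_id!r} with "
                f"{item.n_categories} categories"
            )
        p = _probs_grid(grid, item)[0, code]
        total += float(np.log(max(p, PROB_FLOOR)))
    return total


def rescale_item(item: ItemParameters, shift: float) -> ItemParameters:
    """Return a copy of ``item`` with every threshold shifted by ``shift``."""
    if item.model == "NRM":
        ck = tuple(
            c - a * shift for a, c in zip(item.nrm_slopes, item.nrm_intercepts)
        )
        return replace(item, nrm_intercepts=ck)
    return replace(item, thresholds=tuple(b + shift for b in item.thresholds))
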