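"""Variable-length adaptive test loop.

The test starts from a randomly drawn item, scores the examinee after every
response by expected-a-posteriori (EAP) quadrature, selects the next item by
maximum Fisher information (MFI) at the interim estimate, and stops once the
trait standard error falls under a threshold (or a maximum test length / an
exhausted pool forces termination).

Key identities used throughout: SE(theta_hat) = 1 / sqrt(sum_j I_j(theta_hat))
over administered items, and reliability = 1 - SE^2 = 1 - 1/I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import QuadraturePrior, ResponseMatrix
from .errors import InvalidResponseError, MissingItemError
from .irt_models import MISSING, ItemBank

__all__ = [
    "ThetaEstimate",
    "CATConfig",
    "CATRecord",
    "select_first_item",
    "eap_estimate",
    "select_next_item",
    "stop_check",
    "administer",
    "simulate_cat",
    "SE_FOR_RELIABILITY",
]

#: SE stopping thresholds corresponding to reliability targets 0.80/0.85/0.90
#: through reliability = 1 - SE^2.
SE_FOR_RELIABILITY = {0.80: 0.447, 0.85: 0.386, 0.90: 0.316}


@dataclass(frozen=True)
class ThetaEstimate:
    """An EAP trait estimate with its information-based precision summaries.

    ``se = 1/sqrt(information)`` and ``reliability = 1 - se**2``; with zero
    information (nothing administered) the SE is undefined and reported as
    ``inf`` with ``se_defined`` False.
    """

    theta: float
    information: float
    n_administered: int

    @property
    def se(self) -> float:
        return 1.0 / math.sqrt(self.information) if self.information > 0 else math.inf

    @property
    def reliability(self) -> float:
        return 1.0 - self.se ** 2 if self.information > 0 else -math.inf

    @property
    def se_defined(self) -> bool:
        return self.information > 0


@dataclass
class CATConfig:
    """Adaptive-test settings: SE stopping threshold, length cap, seed, prior.

    ``se_threshold=None`` disables precision stopping (the "no stopping rule"
    condition: every available item is administered, up to ``max_items``).
    """

    se_threshold: float | None = 0.316
    max_items: int = 50
    seed: int = 0
    prior: QuadraturePrior = field(default_factory=QuadraturePrior.normal)

    def __post_init__(self):
        if self.se_threshold is not None and self.se_threshold <= 0:
            raise ValueError("se_threshold must be positive")
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")


@dataclass
class CATRecord:
    """Full per-person trace of one adaptive administration."""

    person_id: str
    administered: list
    responses: list
    interim: list
    final: ThetaEstimate
    stop_reason: str            # "se_met" | "max_items" | "pool_exhausted"
    high_missingness: bool = False


def select_first_item(bank: ItemBank, rng: np.random.Generator,
                      candidates: Sequence[str] | None = None) -> str:
    """Uniform random draw of the starting item (reproducible under the rng seed)."""
    pool = list(candidates) if candidates is not None else bank.item_ids
    if not pool:
        raise MissingItemError("cannot select a first item from an empty bank")
    return pool[int(rng.integers(len(pool)))]


def _pattern_to_pairs(pattern, bank: ItemBank):
    if isinstance(pattern, Mapping):
        return [(bank.position(i), int(c)) for i, c in pattern.items() if c != MISSING]
    return [(j, int(c)) for j, c in enumerate(pattern) if c != MISSING]


def eap_estimate(pattern, bank: ItemBank,
                 prior: QuadraturePrior | None = None) -> ThetaEstimate:
    """EAP score of a (partial) response pattern.

    theta_hat = sum_h Z_h L(Z_h) W(Z_h) / sum_h L(Z_h) W(Z_h) over the prior
    grid; the information (and hence SE) is the administered-set test
    information evaluated at theta_hat. ``pattern`` is either a mapping
    ``item_id -> code`` or a bank-aligned sequence with missing sentinels.
    """
    prior = prior or QuadraturePrior.normal()
    pairs = _pattern_to_pairs(pattern, bank)
    if not pairs:
        return ThetaEstimate(theta=prior.mean, information=0.0, n_administered=0)
    logP = bank.log_prob_tensor(prior.points)
    L = np.zeros_like(prior.points)
    for j, code in pairs:
        K = bank.items[j].n_categories
        if not (0 <= code < K):
            raise InvalidResponseError(
                f"code {code} invalid for item {bank.items[j].item_id!r}")
        L += logP[:, j, code]
    lp = L + np.log(prior.weights)
    lp -= lp.max()
    post = np.exp(lp)
    post /= post.sum()
    theta = float(post @ prior.points)
    positions = np.array([j for j, _ in pairs])
    info = float(np.sum(bank.information_at(theta, positions)))
    return ThetaEstimate(theta=theta, information=info, n_administered=len(pairs))


def select_next_item(theta_hat: float, bank: ItemBank, used) -> str | None:
    """MFI selection: the unused item with maximum information at ``theta_hat``.

    Ties break toward the earlier bank position. Returns ``None`` when the
    pool is exhausted (all items used).
    """
    used = set(used)
    unknown = used - set(bank.item_ids)
    if unknown:
        raise MissingItemError(f"unknown item ids in used set: {sorted(unknown)}")
    positions = np.array([j for j, iid in enumerate(bank.item_ids) if iid not in used])
    if positions.size == 0:
        return None
    info = bank.information_at(float(theta_hat), positions)
    return bank.item_ids[int(positions[int(np.argmax(info))])]


def stop_check(estimate: ThetaEstimate, config: CATConfig,
               remaining: int) -> tuple[bool, str | None]:
    """Termination test, checked after each administered item.

    Precedence: SE under threshold ("se_met"), then length cap ("max_items"),
    then an empty remaining pool ("pool_exhausted").
    """
    if (config.se_threshold is not None and estimate.se_defined
            and estimate.se <= config.se_threshold):
        return True, "se_met"
    if estimate.n_administered >= config.max_items:
        return True, "max_items"
    if remaining <= 0:
        return True, "pool_exhausted"
    return False, None


def administer(full_responses, bank: ItemBank, config: CATConfig,
               rng: np.random.Generator | None = None,
               person_id: str = "") -> CATRecord:
    """Post-hoc simulated CAT for one person.

    ``full_responses`` is the person's complete stored response vector aligned
    with the bank (mapping or sequence); each adaptively selected item's
    answer is looked up there. Items the person never answered are excluded
    from selection (their response cannot be looked up), and a person missing
    more than half of the bank is flagged on the record.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if isinstance(full_responses, Mapping):
        vec = np.full(len(bank), MISSING, dtype=int)
        for iid, c in full_responses.items():
            vec[bank.position(iid)] = c
    else:
        vec = np.asarray(full_responses, dtype=int)
        if vec.shape[0] != len(bank):
            raise ValueError("response vector must align with the bank")
    available = [j for j in range(len(bank)) if vec[j] != MISSING]
    high_missing = len(available) < 0.5 * len(bank)

    prior = config.prior
    logP = bank.log_prob_tensor(prior.points)
    logw = np.log(prior.weights)
    L = np.zeros_like(prior.points)

    administered: list[str] = []
    responses: list[int] = []
    interim: list[ThetaEstimate] = []
    used_positions: list[int] = []
    avail_ids = [bank.item_ids[j] for j in available]
    first = select_first_item(bank, rng, candidates=avail_ids)
    next_pos: int | None = bank.position(first)

    while next_pos is not None:
        j = next_pos
        code = int(vec[j])
        K = bank.items[j].n_categories
        if not (0 <= code < K):
            raise InvalidResponseError(
                f"code {code} invalid for item {bank.items[j].item_id!r}")
        administered.append(bank.item_ids[j])
        responses.append(code)
        used_positions.append(j)
        L += logP[:, j, code]
        lp = L + logw
        lp = lp - lp.max()
        post = np.exp(lp)
        post /= post.sum()
        theta = float(post @ prior.points)
        info = float(np.sum(bank.information_at(theta, np.asarray(used_positions))))
        est = ThetaEstimate(theta=theta, information=info,
                            n_administered=len(administered))
        interim.append(est)
        remaining = [p for p in available if p not in set(used_positions)]
        stop, reason = stop_check(est, config, len(remaining))
        if stop:
            return CATRecord(person_id=person_id, administered=administered,
                             responses=responses, interim=interim, final=est,
                             stop_reason=reason, high_missingness=high_missing)
        cand = np.asarray(remaining)
        info_cand = bank.information_at(theta, cand)
        next_pos = int(cand[int(np.argmax(info_cand))])
    raise RuntimeError("adaptive loop ended without a stop reason")  # pragma: no cover


def simulate_cat(responses: ResponseMatrix, bank: ItemBank,
                 config: CATConfig) -> list[CATRecord]:
    """Run :func:`administer` for every person; per-person rngs derive from the seed."""
    cols = [responses.item_ids.index(i) for i in bank.item_ids]
    records = []
    for p, pid in enumerate(responses.person_ids):
        rng = np.random.default_rng([config.seed, p])
        records.append(administer(responses.codes[p, cols], bank, config,
                                  rng=rng, person_id=str(pid)))
    return records
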