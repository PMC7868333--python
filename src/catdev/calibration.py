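"""Marginal-maximum-likelihood (MML) calibration of polytomous IRT models.

Item parameters are estimated by an EM algorithm under a standard-normal
latent-trait prior discretized on a quadrature grid:

* E-step: each person's posterior weight on every quadrature point, and from
  those the expected per-item category counts at each point.
* M-step: per-item maximization of the expected complete-data log-likelihood
  (quasi-Newton with analytic gradients; GRM threshold ordering is enforced
  through a log-gap reparameterization).

Test-level fit is summarized by -2LL / AIC / BIC, and :func:`select_model`
picks the best-fitting of several candidate models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .errors import CalibrationError
from .irt_models import MISSING, PROB_FLOOR, ItemBank, ItemParameters

__all__ = [
    "QuadraturePrior",
    "ResponseMatrix",
    "ModelFit",
    "ModelSelection",
    "EMControls",
    "fit_model",
    "fit_indices",
    "select_model",
    "eap_scores",
    "n_parameters",
]


@dataclass(frozen=True)
class QuadraturePrior:
    """Latent-trait quadrature grid: points Z_h with prior weights W(Z_h)."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        if pts.ndim != 1 or pts.shape != wts.shape:
            raise ValueError("points and weights must be matching 1-d arrays")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("quadrature points must be strictly increasing")
        if np.any(wts < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts / wts.sum())

    @classmethod
    def normal(cls, n_points: int = 61, bounds: tuple = (-4.0, 4.0)) -> "QuadraturePrior":
        """Equally spaced grid with standard-normal density weights, renormalized."""
        z = np.linspace(bounds[0], bounds[1], n_points)
        return cls(z, norm.pdf(z))

    @property
    def mean(self) -> float:
        return float(self.points @ self.weights)


@dataclass
class ResponseMatrix:
    """Persons x items integer category codes with an explicit missing marker.

    ``codes`` uses 0-based categories; :data:`catdev.irt_models.MISSING` (-1)
    marks a missing response. ``groups`` optionally carries a per-person
    label (e.g. a gender- or region-like binary grouping) for DIF analysis.
    """

    person_ids: list
    item_ids: list
    codes: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("codes shape must be (n_persons, n_items)")
        if np.any(self.codes < MISSING):
            raise ValueError("codes must be category indices >= 0 or the missing sentinel")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != len(self.person_ids):
                raise ValueError("groups must align with persons")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def column(self, item_id: str) -> np.ndarray:
        return self.codes[:, self.item_ids.index(item_id)]

    def observed_categories(self) -> list[int]:
        """Number of observed categories per item (max code + 1)."""
        out = []
        for j in range(self.n_items):
            col = self.codes[:, j]
            obs = col[col != MISSING]
            out.append(int(obs.max()) + 1 if obs.size else 0)
        return out

    def subset_items(self, item_ids) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            list(self.person_ids), list(item_ids), self.codes[:, idx], self.groups
        )


@dataclass(frozen=True)
class ModelFit:
    """Test-level fit of one calibrated model: -2LL with AIC/BIC penalties."""

    model: str
    minus2LL: float
    n_params: int
    n_persons: int
    AIC: float = field(init=False)
    BIC: float = field(init=False)
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        object.__setattr__(self, "AIC", self.minus2LL + 2 * self.n_params)
        object.__setattr__(
            self, "BIC", self.minus2LL + self.n_params * float(np.log(self.n_persons))
        )


@dataclass(frozen=True)
class ModelSelection:
    """Winner of an information-criterion comparison among candidate models."""

    model: str
    indices_agree: bool
    implied_params: dict


@dataclass
class EMControls:
    """Convergence settings for the EM calibration."""

    max_iter: int = 500
    tol: float = 1e-4          # max absolute parameter change
    m_step_maxiter: int = 25


def fit_indices(minus2LL: float, n_params: int, n_persons: int, model: str = "GRM") -> ModelFit:
    """Build a :class:`ModelFit` from -2LL: AIC = -2LL + 2p, BIC = -2LL + p ln(n)."""
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    return ModelFit(model=model, minus2LL=float(minus2LL), n_params=int(n_params),
                    n_persons=int(n_persons))


def select_model(fits: list) -> ModelSelection:
    """Pick the best-fitting model: smallest AIC, ties broken by BIC then -2LL.

    ``implied_params`` reports, per model, the parameter count implied by
    (AIC - (-2LL)) / 2 -- a consistency check on the indices.
    """
    if not fits:
        raise ValueError("select_model needs at least one ModelFit")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].AIC, fits[i].BIC, fits[i].minus2LL))
    best = fits[order[0]]
    by_aic = min(fits, key=lambda f: f.AIC).model
    by_bic = min(fits, key=lambda f: f.BIC).model
    by_ll = min(fits, key=lambda f: f.minus2LL).model
    implied = {f.model: (f.AIC - f.minus2LL) / 2.0 for f in fits}
    return ModelSelection(model=best.model, indices_agree=(by_aic == by_bic == by_ll),
                          implied_params=implied)


def n_parameters(model: str, n_categories: int) -> int:
    """Free parameters of one item: GRM/GPCM K, PCM K-1, NRM 2(K-1)."""
    K = n_categories
    if model in ("GRM", "GPCM"):
        return K
    if model == "PCM":
        return K - 1
    if model == "NRM":
        return 2 * (K - 1)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Per-item M-step objectives (expected complete-data negative log-likelihood)
# ---------------------------------------------------------------------------

def _grm_unpack(x: np.ndarray, K: int) -> tuple[float, np.ndarray]:
    """x = [a, b1, log-gaps...] -> (a, ordered thresholds)."""
    a = x[0]
    if K == 2:
        return a, x[1:2]
    b = np.empty(K - 1)
    b[0] = x[1]
    b[1:] = x[1] + np.cumsum(np.exp(x[2:]))
    return a, b


def _grm_pack(a: float, b: np.ndarray) -> np.ndarray:
    if len(b) == 1:
        return np.array([a, b[0]])
    gaps = np.diff(b)
    return np.concatenate([[a, b[0]], np.log(np.maximum(gaps, 1e-3))])


def _grm_negQ(x, z, r, K):
    a, b = _grm_unpack(x, K)
    S = expit(a * (z[:, None] - b[None, :]))                    # (q, K-1)
    full = np.concatenate([np.ones((len(z), 1)), S, np.zeros((len(z), 1))], axis=1)
    P = np.maximum(full[:, :-1] - full[:, 1:], PROB_FLOOR)
    negQ = -float(np.sum(r * np.log(P)))
    # gradient in (a, b) space
    ratio = r / P                                               # (q, K)
    dS = S * (1.0 - S)
    e = (z[:, None] - b[None, :]) * dS                          # dS/da pieces
    # dP_k/da = e_k - e_{k+1} with e_0 = e_K = 0 (1-based threshold index)
    efull = np.concatenate([np.zeros((len(z), 1)), e, np.zeros((len(z), 1))], axis=1)
    g_a = -float(np.sum(ratio * (efull[:, :-1] - efull[:, 1:])))
    d = a * dS                                                  # (q, K-1)
    g_b = -np.sum(d * (ratio[:, :-1] - ratio[:, 1:]), axis=0)   # dQ/db_m
    if K == 2:
        return negQ, np.array([g_a, g_b[0]])
    g = np.empty(len(x))
    g[0] = g_a
    g[1] = g_b.sum()
    csum = np.cumsum(g_b[::-1])[::-1]                           # sums over m >= l
    g[2:] = np.exp(x[2:]) * csum[1:]
    return negQ, g


def _gpcm_negQ(x, z, r, K, free_slope):
    a = x[0] if free_slope else 1.0
    b = x[1:] if free_slope else x
    steps = a * (z[:, None] - b[None, :])
    T = np.concatenate([np.zeros((len(z), 1)), np.cumsum(steps, axis=1)], axis=1)
    T -= T.max(axis=1, keepdims=True)
    num = np.exp(T)
    P = num / num.sum(axis=1, keepdims=True)
    negQ = -float(np.sum(r * np.log(np.maximum(P, PROB_FLOOR))))
    Rtot = r.sum(axis=1)
    g_b = np.empty(K - 1)
    for v in range(1, K):
        Rge = r[:, v:].sum(axis=1)
        Cge = P[:, v:].sum(axis=1)
        g_b[v - 1] = -float(np.sum(a * (Rtot * Cge - Rge)))
    if not free_slope:
        return negQ, g_b
    U = np.concatenate(
        [np.zeros((len(z), 1)), np.cumsum(z[:, None] - b[None, :], axis=1)], axis=1
    )
    g_a = -float(np.sum(r * U) - np.sum(Rtot * np.sum(P * U, axis=1)))
    return negQ, np.concatenate([[g_a], g_b])


def _nrm_negQ(x, z, r, K):
    ak = np.concatenate([[0.0], x[: K - 1]])
    ck = np.concatenate([[0.0], x[K - 1:]])
    logits = z[:, None] * ak[None, :] + ck[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    num = np.exp(logits)
    P = num / num.sum(axis=1, keepdims=True)
    negQ = -float(np.sum(r * np.log(np.maximum(P, PROB_FLOOR))))
    Rtot = r.sum(axis=1)
    resid = r - Rtot[:, None] * P                               # (q, K)
    g_a = -(z[:, None] * resid).sum(axis=0)[1:]
    g_c = -resid.sum(axis=0)[1:]
    return negQ, np.concatenate([g_a, g_c])


def _start_values(col: np.ndarray, K: int, model: str) -> np.ndarray:
    obs = col[col != MISSING]
    exceed = np.array([(obs >= k).mean() for k in range(1, K)])
    q = np.clip(exceed, 0.01, 0.99)
    b = np.log((1 - q) / q)                                     # logit^-1 at theta=0
    b = np.maximum.accumulate(b + 1e-6 * np.arange(K - 1))      # enforce order
    b += 1e-3 * np.arange(K - 1)
    if model == "GRM":
        return _grm_pack(1.0, b)
    if model == "GPCM":
        return np.concatenate([[1.0], b])
    if model == "PCM":
        return b
    # NRM: ordered slopes 0.5*k, intercepts from category frequencies
    counts = np.array([(obs == k).sum() for k in range(K)], dtype=float) + 0.5
    ck = np.log(counts[1:] / counts[0])
    return np.concatenate([0.5 * np.arange(1, K), ck])


def _make_item(item_id: str, model: str, K: int, x: np.ndarray,
               template: ItemParameters | None) -> ItemParameters:
    src = template.source_scale if template else "synthetic"
    crit = template.criterion if template else "unknown"
    if model == "GRM":
        a, b = _grm_unpack(x, K)
        return ItemParameters(item_id, K, float(a), tuple(b), "GRM",
                              source_scale=src, criterion=crit)
    if model == "GPCM":
        return ItemParameters(item_id, K, float(x[0]), tuple(x[1:]), "GPCM",
                              source_scale=src, criterion=crit)
    if model == "PCM":
        return ItemParameters(item_id, K, 1.0, tuple(x), "PCM",
                              source_scale=src, criterion=crit)
    ak = (0.0, *x[: K - 1])
    ck = (0.0, *x[K - 1:])
    return ItemParameters(item_id, K, 1.0, (), "NRM", nrm_slopes=ak,
                          nrm_intercepts=ck, source_scale=src, criterion=crit)


def _person_logliks(codes: np.ndarray, logP: np.ndarray) -> np.ndarray:
    """Log-likelihood of every person at every quadrature point, (n, q)."""
    n, J = codes.shape
    q = logP.shape[0]
    L = np.zeros((n, q))
    for j in range(J):
        col = codes[:, j]
        m = col != MISSING
        if m.any():
            L[m, :] += logP[:, j, col[m]].T
    return L


def fit_model(responses: ResponseMatrix, model: str = "GRM",
              prior: QuadraturePrior | None = None,
              controls: EMControls | None = None,
              template: ItemBank | None = None) -> tuple[ItemBank, ModelFit]:
    """Estimate item parameters by MML-EM under a standard-normal prior.

    Missing responses are ignored in both E- and M-steps (missing-at-random).
    Non-convergence within ``controls.max_iter`` cycles yields a flagged
    (``converged=False``) result rather than an exception; an item with a
    single observed category raises :class:`CalibrationError` naming it.

    Returns the calibrated :class:`ItemBank` and its :class:`ModelFit`.
    """
    prior = prior or QuadraturePrior.normal()
    controls = controls or EMControls()
    codes = responses.codes
    n, J = codes.shape
    if n < 50:
        warnings.warn(f"calibration sample is small (n={n})", stacklevel=2)
    Ks = responses.observed_categories()
    for j, K in enumerate(Ks):
        col = codes[:, j]
        obs = col[col != MISSING]
        if obs.size < 2:
            raise CalibrationError(
                f"item {responses.item_ids[j]!r} has fewer than 2 observed responses")
        if np.unique(obs).size < 2:
            raise CalibrationError(
                f"item {responses.item_ids[j]!r} has a single observed category")

    z, w = prior.points, prior.weights
    logw = np.log(w)
    params = [_start_values(codes[:, j], Ks[j], model) for j in range(J)]
    onehots = []
    for j in range(J):
        col = codes[:, j]
        m = col != MISSING
        oh = np.zeros((int(m.sum()), Ks[j]))
        oh[np.arange(int(m.sum())), col[m]] = 1.0
        onehots.append((m, oh))

    def build_bank(ps):
        return ItemBank([
            _make_item(responses.item_ids[j], model, Ks[j], ps[j],
                       template[responses.item_ids[j]] if template and
                       responses.item_ids[j] in template else None)
            for j in range(J)
        ])

    objectives = {
        "GRM": lambda x, zz, r, K: _grm_negQ(x, zz, r, K),
        "GPCM": lambda x, zz, r, K: _gpcm_negQ(x, zz, r, K, True),
        "PCM": lambda x, zz, r, K: _gpcm_negQ(x, zz, r, K, False),
        "NRM": lambda x, zz, r, K: _nrm_negQ(x, zz, r, K),
    }
    negQ = objectives[model]

    loglik_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, controls.max_iter + 1):
        bank = build_bank(params)
        logP = bank.log_prob_tensor(z)
        L = _person_logliks(codes, logP)
        lp = L + logw[None, :]
        lse = logsumexp(lp, axis=1)
        loglik_trace.append(float(lse.sum()))
        post = np.exp(lp - lse[:, None])                        # (n, q)
        max_change = 0.0
        new_params = []
        for j in range(J):
            m, oh = onehots[j]
            r = post[m].T @ oh                                  # (q, K_j)
            res = minimize(negQ, params[j], args=(z, r, Ks[j]), jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": controls.m_step_maxiter})
            new_params.append(res.x)
            max_change = max(max_change, float(np.max(np.abs(res.x - params[j]))))
        params = new_params
        if max_change < controls.tol:
            converged = True
            break

    bank = build_bank(params)
    logP = bank.log_prob_tensor(z)
    L = _person_logliks(codes, logP)
    final_ll = float(logsumexp(L + logw[None, :], axis=1).sum())
    loglik_trace.append(final_ll)
    p_total = sum(n_parameters(model, K) for K in Ks)
    fit = ModelFit(model=model, minus2LL=-2.0 * final_ll, n_params=p_total,
                   n_persons=n, converged=converged, n_iter=it)
    fit_obj = fit
    object.__setattr__(fit_obj, "loglik_trace", tuple(loglik_trace))
    return bank, fit_obj


def eap_scores(responses: ResponseMatrix, bank: ItemBank,
               prior: QuadraturePrior | None = None) -> np.ndarray:
    """Vectorized EAP trait estimates for every person in a response matrix.

    theta_hat_i = sum_h Z_h L_i(Z_h) W(Z_h) / sum_h L_i(Z_h) W(Z_h).
    """
    prior = prior or QuadraturePrior.normal()
    cols = [bank.position(i) for i in responses.item_ids]
    logP = bank.log_prob_tensor(prior.points)[:, cols, :]
    L = _person_logliks(responses.codes, logP)
    lp = L + np.log(prior.weights)[None, :]
    lp -= lp.max(axis=1, keepdims=True)
    post = np.exp(lp)
    post /= post.sum(axis=1, keepdims=True)
    return post @ prior.points
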