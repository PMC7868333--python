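"""Six-step item-pool screening battery for adaptive-test development.

The battery applies, in order, the measurement requirements an item must
meet to stay in the pool:

1. unidimensionality (first-factor loading >= 0.3; pool passes when the
   first/second eigenvalue ratio is >= 4 and the first factor explains at
   least 20% of total variance),
2. model selection (handled by :mod:`catdev.calibration`; no removals),
3. local independence (Yen's Q3 residual correlations, |Q3| > 0.36 flags a
   pair; the member with the larger cumulative |Q3| is removed),
4. item fit (Orlando-Thissen S-X^2 via summed-score recursions; p < 0.01
   removes the item),
5. discrimination (a < 0.5 removes; a > 2.5 is flagged but retained),
6. differential item functioning (ordinal-logistic DIF; McFadden pseudo-R^2
   change > 0.02 between the trait-only and trait+group+interaction models
   removes the item).

Any removal triggers recalibration before the next step, and the whole
battery repeats on the survivors until a full pass removes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .calibration import (EMControls, QuadraturePrior, ResponseMatrix,
                          eap_scores, fit_model, n_parameters)
from .errors import ScreeningError
from .irt_models import MISSING, ItemBank

__all__ = [
    "ScreeningConfig",
    "ScreeningReport",
    "unidimensionality_screen",
    "q3_screen",
    "s_x2_screen",
    "discrimination_screen",
    "dif_screen",
    "screen_pool",
]


@dataclass
class ScreeningConfig:
    """Thresholds of the screening battery (defaults are the conventional
    published cutoffs)."""

    loading_cutoff: float = 0.3
    eigen_ratio_min: float = 4.0
    variance_min: float = 0.20
    q3_cutoff: float = 0.36
    sx2_alpha: float = 0.01
    a_low: float = 0.5
    a_high: float = 2.5
    dif_delta_r2: float = 0.02
    max_outer_passes: int = 5


@dataclass
class UnidimResult:
    loadings: dict
    eigen_ratio: float
    variance_prop: float
    removed: list
    passed: bool


@dataclass
class Q3Result:
    matrix: pd.DataFrame
    flagged_pairs: list          # [(id_a, id_b, q3)]
    cumulative: dict
    removed: list


@dataclass
class SX2Result:
    table: pd.DataFrame          # item_id, statistic, df, p, untestable
    removed: list


@dataclass
class DIFResult:
    table: pd.DataFrame          # item_id, r2_base, r2_full, delta_r2
    removed: list


@dataclass
class ScreeningReport:
    """Outcome of the full battery: who was removed at which step, and the
    diagnostics of the final (clean) pass."""

    input_items: list
    removals: list = field(default_factory=list)   # [(item_id, step_label)]
    surviving: ItemBank | None = None
    n_passes: int = 0
    unidimensionality: UnidimResult | None = None
    q3: Q3Result | None = None
    s_x2: SX2Result | None = None
    discrimination_flags: dict = field(default_factory=dict)
    dif: DIFResult | None = None

    @property
    def removed_ids(self) -> list:
        return [iid for iid, _ in self.removals]

    def removed_by_step(self) -> dict:
        out: dict = {}
        for iid, step in self.removals:
            out.setdefault(step, []).append(iid)
        return out


# ---------------------------------------------------------------------------
# Step 1: unidimensionality
# ---------------------------------------------------------------------------

def unidimensionality_screen(responses: ResponseMatrix,
                             loading_cutoff: float = 0.3) -> UnidimResult:
    """Eigenvalue/loading screen on the item inter-correlation matrix.

    Pearson correlations on raw category codes; first-factor loadings are
    the leading eigenvector scaled by sqrt(lambda_1). Items loading under
    the cutoff are removed; the pool-level pass flag requires
    lambda_1/lambda_2 >= 4 and lambda_1 / J >= 20%.
    """
    if responses.n_items < 3:
        raise ScreeningError("unidimensionality screen needs >= 3 items")
    if responses.n_persons < 50:
        warnings.warn("unidimensionality screen on < 50 persons", stacklevel=2)
    X = responses.codes.astype(float)
    X[responses.codes == MISSING] = np.nan
    for j, iid in enumerate(responses.item_ids):
        col = X[:, j]
        if np.nanstd(col) == 0:
            raise ScreeningError(f"item {iid!r} is constant; correlation matrix singular")
    C = pd.DataFrame(X).corr().values
    if np.isnan(C).any():
        bad = responses.item_ids[int(np.argmax(np.isnan(C).any(axis=0)))]
        raise ScreeningError(f"correlation undefined around item {bad!r}")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    v1 = vecs[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    loadings = v1 * np.sqrt(max(vals[0], 0.0))
    removed = [iid for iid, ld in zip(responses.item_ids, loadings)
               if ld < loading_cutoff]
    ratio = float(vals[0] / vals[1]) if vals[1] > 0 else float("inf")
    varprop = float(vals[0] / C.shape[0])
    return UnidimResult(
        loadings=dict(zip(responses.item_ids, map(float, loadings))),
        eigen_ratio=ratio, variance_prop=varprop, removed=removed,
        passed=(ratio >= 4.0 and varprop >= 0.20),
    )


# ---------------------------------------------------------------------------
# Step 3: local independence (Q3)
# ---------------------------------------------------------------------------

def q3_screen(responses: ResponseMatrix, bank: ItemBank, thetas,
              cutoff: float = 0.36) -> Q3Result:
    """Yen's Q3: correlations of score residuals x_j - E[x_j | theta_hat].

    Pairs with |Q3| above the cutoff are flagged; from each flagged pair the
    member with the larger cumulative |Q3| (summed over all its pairings) is
    removed.
    """
    thetas = np.asarray(thetas, dtype=float)
    cols = [bank.position(i) for i in responses.item_ids]
    expected = bank.expected_scores(thetas)[:, cols]
    resid = responses.codes.astype(float) - expected
    resid[responses.codes == MISSING] = np.nan
    ids = responses.item_ids
    dropped = [iid for j, iid in enumerate(ids) if np.nanstd(resid[:, j]) == 0]
    if dropped:
        warnings.warn(f"zero-variance residuals, pairs skipped for: {dropped}",
                      stacklevel=2)
    Q3 = pd.DataFrame(resid, columns=ids).corr()
    np.fill_diagonal(Q3.values, np.nan)
    absq = Q3.abs()
    cumulative = absq.sum(axis=1, skipna=True).to_dict()
    flagged = []
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            q = Q3.iat[a_i, b_i]
            if np.isfinite(q) and abs(q) > cutoff:
                flagged.append((ids[a_i], ids[b_i], float(q)))
    removed: list = []
    for a_id, b_id, _ in flagged:
        worse = a_id if cumulative[a_id] >= cumulative[b_id] else b_id
        if worse not in removed:
            removed.append(worse)
    return Q3Result(matrix=Q3, flagged_pairs=flagged, cumulative=cumulative,
                    removed=removed)


# ---------------------------------------------------------------------------
# Step 4: item fit (S-X^2)
# ---------------------------------------------------------------------------

def _summed_score_dists(P: np.ndarray, Ks, skip: int | None = None) -> np.ndarray:
    """Summed-score likelihoods via the Lord-Wingersky recursion.

    ``P`` is the (q, J, Kmax) category-probability tensor on the quadrature
    grid; returns (q, S+1) where S is the maximum total score over the items
    (optionally excluding ``skip``).
    """
    q = P.shape[0]
    dist = np.ones((q, 1))
    for j, K in enumerate(Ks):
        if j == skip:
            continue
        S_prev = dist.shape[1]
        new = np.zeros((q, S_prev + K - 1))
        for k in range(K):
            new[:, k:k + S_prev] += dist * P[:, j, k][:, None]
        dist = new
    return dist


def _collapse_row(obs: np.ndarray, exp: np.ndarray, min_expected: float = 1.0):
    """Merge adjacent category cells of one score row until every retained
    cell has expected count >= ``min_expected``; rows reduced to a single
    cell carry no information and are dropped."""
    keep = exp > 0
    o, e = obs[keep], exp[keep]
    if e.size == 0:
        return None
    merged_o, merged_e = [], []
    acc_o = acc_e = 0.0
    for oo, ee in zip(o, e):
        acc_o += oo
        acc_e += ee
        if acc_e >= min_expected:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if merged_e:
            merged_o[-1] += acc_o
            merged_e[-1] += acc_e
        else:
            return None
    if len(merged_e) < 2:
        return None
    return np.array(merged_o), np.array(merged_e)


def s_x2_screen(responses: ResponseMatrix, bank: ItemBank,
                prior: QuadraturePrior | None = None,
                alpha: float = 0.01) -> SX2Result:
    """Orlando-Thissen S-X^2 item fit.

    Model-expected category proportions conditional on the total summed
    score are computed from summed-score recursions under the quadrature
    prior and compared with observed proportions by a Pearson chi-square
    over score x category cells (adjacent low-expectation cells collapsed).
    df = retained cells - rows - item parameter count, floored at 1. Items
    with p < ``alpha`` are removed; items with too few usable score levels
    are marked untestable and retained.
    """
    prior = prior or QuadraturePrior.normal()
    cols = [bank.position(i) for i in responses.item_ids]
    complete = ~np.any(responses.codes == MISSING, axis=1)
    if complete.sum() < 50:
        raise ScreeningError("S-X^2 needs >= 50 complete response vectors")
    codes = responses.codes[complete]
    n = codes.shape[0]
    Ks = [bank.items[c].n_categories for c in cols]
    P = bank.prob_tensor(prior.points)[:, cols, :]
    w = prior.weights
    total = codes.sum(axis=1)
    S_full = _summed_score_dists(P, Ks)
    denom = w @ S_full                                   # P(total = s)

    rows = []
    removed = []
    for j, iid in enumerate(responses.item_ids):
        K = Ks[j]
        S_rest = _summed_score_dists(P, Ks, skip=j)      # (q, S_rest+1)
        S_rest_max = S_rest.shape[1] - 1
        S_max = S_full.shape[1] - 1
        # E_num[s, k] = sum_h w_h P_jk(h) S_rest(s-k | h)
        E_num = np.zeros((S_max + 1, K))
        for k in range(K):
            contrib = w @ (P[:, j, k][:, None] * S_rest)     # over rest scores
            E_num[k:k + S_rest_max + 1, k] = contrib
        x2 = 0.0
        cells = 0
        nrows = 0
        counts = np.bincount(total, minlength=S_max + 1)
        for s in range(S_max + 1):
            N_s = counts[s]
            if N_s == 0 or denom[s] <= 0:
                continue
            exp_prop = E_num[s] / denom[s]
            obs_cnt = np.bincount(codes[total == s, j], minlength=K).astype(float)
            res = _collapse_row(obs_cnt, N_s * exp_prop)
            if res is None:
                continue
            o, e = res
            x2 += float(np.sum((o - e) ** 2 / e))
            cells += len(e)
            nrows += 1
        p_item = n_parameters(bank.items[cols[j]].model, K)
        df = cells - nrows - p_item
        untestable = nrows < 2
        if untestable:
            warnings.warn(f"item {iid!r} untestable by S-X^2 (too few score levels)",
                          stacklevel=2)
            rows.append((iid, np.nan, 0, np.nan, True))
            continue
        df = max(df, 1)
        p = float(chi2.sf(x2, df))
        rows.append((iid, x2, df, p, False))
        if p < alpha:
            removed.append(iid)
    table = pd.DataFrame(rows, columns=["item_id", "statistic", "df", "p", "untestable"])
    return SX2Result(table=table, removed=removed)


# ---------------------------------------------------------------------------
# Step 5: discrimination
# ---------------------------------------------------------------------------

def discrimination_screen(bank: ItemBank, low: float = 0.5,
                          high: float = 2.5) -> tuple[list, dict]:
    """Remove items with slope strictly below ``low``; flag (but keep) items
    above ``high``. Boundary values are retained."""
    removed = [it.item_id for it in bank if it.slope < low]
    flags = {it.item_id: ("low" if it.slope < low else
                          "high" if it.slope > high else "ok")
             for it in bank}
    return removed, flags


# ---------------------------------------------------------------------------
# Step 6: DIF by ordinal logistic regression
# ---------------------------------------------------------------------------

def _mcfadden_models(y: np.ndarray, theta: np.ndarray, g: np.ndarray):
    """Log-likelihoods of the null, trait-only, and trait+group+interaction
    ordinal (or binary) logistic models."""
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    # recode to consecutive categories
    cats = np.unique(y)
    y = np.searchsorted(cats, y)
    K = cats.size
    counts = np.bincount(y, minlength=K).astype(float)
    ll_null = float(np.sum(counts[counts > 0] * np.log(counts[counts > 0] / y.size)))
    X0 = theta[:, None]
    X2 = np.column_stack([theta, g, theta * g])
    if K == 2:
        def ll(X):
            model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
            try:
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    raise RuntimeError
            except Exception:
                warnings.warn("separation in logistic DIF fit; penalized refit",
                              stacklevel=3)
                res = model.fit_regularized(alpha=1e-4, disp=0, maxiter=500)
            return float(res.llf)
        return ll_null, ll(X0), ll(X2)

    def llo(X, start=None):
        model = OrderedModel(y, X, distr="logit")
        res = model.fit(method="bfgs", disp=0, maxiter=500, start_params=start)
        return float(res.llf), np.asarray(res.params)
    ll0, p0 = llo(X0)
    start2 = np.concatenate([[p0[0], 0.0, 0.0], p0[1:]])
    ll2, _ = llo(X2, start=start2)
    if ll2 < ll0:                      # optimizer slipped; retry cold
        ll2b, _ = llo(X2)
        ll2 = max(ll2, ll2b)
    return ll_null, ll0, ll2


def dif_screen(responses: ResponseMatrix, group, thetas,
               delta_r2_cutoff: float = 0.02) -> DIFResult:
    """Differential item functioning by McFadden pseudo-R^2 change.

    Per item, a cumulative-logit (proportional-odds; plain logistic for
    dichotomous items) model in theta-hat alone is compared against the
    model adding group and its interaction with theta-hat:
    delta R^2 = (ll_full - ll_base) / (-ll_null). Items exceeding the cutoff
    are removed.
    """
    group = np.asarray(group)
    thetas = np.asarray(thetas, dtype=float)
    levels = np.unique(group)
    if levels.size != 2:
        raise ScreeningError("DIF grouping must be binary and non-constant")
    g = (group == levels[1]).astype(float)
    for lv in (0, 1):
        if (g == lv).sum() < 50:
            warnings.warn("a DIF group has < 50 persons", stacklevel=2)
    rows, removed = [], []
    for j, iid in enumerate(responses.item_ids):
        col = responses.codes[:, j]
        m = col != MISSING
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            ll_null, ll0, ll2 = _mcfadden_models(col[m], thetas[m], g[m])
        r2_0 = 1.0 - ll0 / ll_null
        r2_2 = 1.0 - ll2 / ll_null
        delta = max(r2_2 - r2_0, 0.0)
        rows.append((iid, r2_0, r2_2, delta))
        if delta > delta_r2_cutoff:
            removed.append(iid)
    table = pd.DataFrame(rows, columns=["item_id", "r2_base", "r2_full", "delta_r2"])
    return DIFResult(table=table, removed=removed)


# ---------------------------------------------------------------------------
# Full battery
# ---------------------------------------------------------------------------

def screen_pool(responses: ResponseMatrix, bank: ItemBank,
                groups=None, config: ScreeningConfig | None = None,
                prior: QuadraturePrior | None = None,
                controls: EMControls | None = None) -> ScreeningReport:
    """Run the six-step battery to a fixed point.

    Steps execute in order; every step that removes items triggers a
    recalibration (GRM) of the survivors before the next step. When a full
    pass removes nothing the battery stops; more than
    ``config.max_outer_passes`` passes aborts with a diagnostic.
    """
    config = config or ScreeningConfig()
    prior = prior or QuadraturePrior.normal()
    if groups is None and responses.groups is not None:
        groups = responses.groups
    report = ScreeningReport(input_items=list(responses.item_ids))
    current_ids = [i for i in responses.item_ids if i in bank]
    current_bank = bank.subset(current_ids)
    current_resp = responses.subset_items(current_ids)
    thetas = eap_scores(current_resp, current_bank, prior)

    def recalibrate():
        nonlocal current_bank, current_resp, thetas
        current_resp = responses.subset_items(current_ids)
        current_bank, _ = fit_model(current_resp, "GRM", prior, controls,
                                    template=bank)
        thetas = eap_scores(current_resp, current_bank, prior)

    def drop(ids, step):
        nonlocal current_ids
        if not ids:
            return False
        for iid in ids:
            report.removals.append((iid, step))
        current_ids = [i for i in current_ids if i not in set(ids)]
        if len(current_ids) < 3:
            raise ScreeningError("screening removed nearly the whole pool")
        recalibrate()
        return True

    for n_pass in range(1, config.max_outer_passes + 1):
        report.n_passes = n_pass
        any_removed = False

        uni = unidimensionality_screen(current_resp, config.loading_cutoff)
        report.unidimensionality = uni
        any_removed |= drop(uni.removed, "unidimensionality")

        q3 = q3_screen(current_resp, current_bank, thetas, config.q3_cutoff)
        report.q3 = q3
        any_removed |= drop(q3.removed, "local_dependence")

        sx2 = s_x2_screen(current_resp, current_bank, prior, config.sx2_alpha)
        report.s_x2 = sx2
        any_removed |= drop(sx2.removed, "item_fit")

        disc_removed, disc_flags = discrimination_screen(
            current_bank, config.a_low, config.a_high)
        report.discrimination_flags = disc_flags
        any_removed |= drop(disc_removed, "low_discrimination")

        if groups is not None:
            dif = dif_screen(current_resp, groups, thetas, config.dif_delta_r2)
            report.dif = dif
            any_removed |= drop(dif.removed, "dif")

        if not any_removed:
            report.surviving = current_bank
            return report
    raise ScreeningError(
        f"screening did not stabilize within {config.max_outer_passes} passes; "
        f"removed so far: {report.removals}")
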