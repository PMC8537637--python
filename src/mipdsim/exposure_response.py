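"""Sequential ordinal exposure-response model with bounded maxima.

Endoscopic disease severity (Mayo endoscopic subscore) improves stepwise
with increasing infliximab exposure (AUC to day 84).  Two transitions are
modelled, each with a hyperbolic Emax relation in AUC:

    p_32(AUC) = emax_32 * AUC^h / (auc50_32^h + AUC^h)   severe -> moderate
    p_21(AUC) = emax_21 * AUC^h / (auc50_21^h + AUC^h)   moderate -> improved

The maxima ``emax`` < 1 encode intrinsic non-responders: no exposure can
push the transition probability past the plateau.  ``auc50`` is the
exposure at half-maximal transition probability.  A patient starting at
subscore 3 must pass through the moderate state, so the probability of
endoscopic improvement (Mayo subscore <= 1) is the product p_32 * p_21;
a patient starting at subscore 2 needs only p_21.

The module also provides the likelihood of (AUC, outcome) records under
the sequential model, profile fitting of the two AUC50s at fixed maxima,
and the likelihood-profile surface over a grid of (emax_32, emax_21)
pairs with the chi-square(1) 95% contour (delta 2LL = 3.84).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: delta(-2 log L) cut-off of the 95% one-parameter profile bound.
DELTA2LL_95: float = float(stats.chi2.ppf(0.95, df=1))

#: Outcome coding for ER records: 1 means Mayo subscore <= 1 (improvement).
OUTCOME_CATEGORIES = (1, 2, 3)

_LOG_AUC50_BOUNDS = (np.log(1e-1), np.log(1e7))


@dataclass(frozen=True)
class ERParams:
    """Exposure-response parameters (fractions and mg*day/L)."""

    emax_32: float
    emax_21: float
    auc50_32: float
    auc50_21: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        for name in ("emax_32", "emax_21"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("auc50_32", "auc50_21", "hill"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def replace(self, **changes) -> "ERParams":
        return dataclasses.replace(self, **changes)


def transition_probability(auc, emax: float, auc50: float, hill: float = 1.0):
    """Hyperbolic Emax transition probability; vectorised over ``auc``."""
    auc = np.asarray(auc, dtype=float)
    if np.any(auc < 0):
        raise ValueError("auc must be non-negative")
    a_h = auc ** hill
    p = emax * a_h / (auc50 ** hill + a_h)
    return float(p) if p.ndim == 0 else p


def _p32_p21(auc, er: ERParams):
    p32 = transition_probability(auc, er.emax_32, er.auc50_32, er.hill)
    p21 = transition_probability(auc, er.emax_21, er.auc50_21, er.hill)
    return np.asarray(p32, dtype=float), np.asarray(p21, dtype=float)


def p_endoscopic_improvement(auc, baseline_mayo, er: ERParams):
    """Probability of reaching Mayo endoscopic subscore <= 1 at day 84.

    Baseline subscore 2 patients need one transition (p21); baseline 3
    patients need both (p32 * p21). Monotone non-decreasing in AUC and
    bounded by the corresponding plateau.
    """
    mayo = np.asarray(baseline_mayo)
    if not np.all(np.isin(mayo, (2, 3))):
        raise ValueError("baseline_mayo must be 2 or 3")
    p32, p21 = _p32_p21(auc, er)
    out = np.where(mayo == 3, p32 * p21, p21)
    return float(out) if out.ndim == 0 else out


def category_probabilities(auc, baseline_mayo, er: ERParams) -> np.ndarray:
    """Probabilities of the day-84 categories (<=1, =2, =3), shape (..., 3).

    Sequential model: from baseline 3, P(=3) = 1 - p32, P(=2) = p32 (1 - p21),
    P(<=1) = p32 p21; from baseline 2, P(=3) = 0, P(=2) = 1 - p21,
    P(<=1) = p21.
    """
    mayo = np.asarray(baseline_mayo)
    if not np.all(np.isin(mayo, (2, 3))):
        raise ValueError("baseline_mayo must be 2 or 3")
    p32, p21 = _p32_p21(auc, er)
    is3 = mayo == 3
    p_le1 = np.where(is3, p32 * p21, p21)
    p_eq2 = np.where(is3, p32 * (1.0 - p21), 1.0 - p21)
    p_eq3 = np.where(is3, 1.0 - p32, 0.0)
    return np.stack([p_le1, p_eq2, p_eq3], axis=-1)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"auc_d84", "baseline_mayo", "outcome_mayo_d84"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    mayo = records["baseline_mayo"].to_numpy()
    out = records["outcome_mayo_d84"].to_numpy()
    if not np.all(np.isin(mayo, (2, 3))):
        raise ValueError("baseline_mayo must be 2 or 3")
    if not np.all(np.isin(out, OUTCOME_CATEGORIES)):
        raise ValueError("outcome_mayo_d84 must be coded 1 (<=1), 2 or 3")
    if np.any((mayo == 2) & (out == 3)):
        raise ValueError("a baseline-2 patient cannot worsen to 3 in this model")
    if np.any(records["auc_d84"].to_numpy() < 0):
        raise ValueError("auc_d84 must be non-negative")
    return records


def neg2_log_likelihood(records: pd.DataFrame, er: ERParams) -> float:
    """-2 log-likelihood of outcome records under the sequential model.

    A record with zero model probability yields +inf (not an exception).
    """
    _validate_records(records)
    probs = category_probabilities(records["auc_d84"].to_numpy(),
                                   records["baseline_mayo"].to_numpy(), er)
    idx = records["outcome_mayo_d84"].to_numpy() - 1
    p_obs = np.take_along_axis(probs, idx[:, None], axis=-1)[:, 0]
    if np.any(p_obs <= 0):
        return float("inf")
    return float(-2.0 * np.sum(np.log(p_obs)))


# ---------------------------------------------------------------------------
# fitting
#
# The joint likelihood separates exactly: terms in p32 involve only the
# baseline-3 records (did the patient leave state 3?), terms in p21 involve
# the baseline-2 records plus the baseline-3 records that reached state <= 2
# (did the patient then reach improvement?). Each AUC50 is therefore fitted
# by a 1-D bounded search on the log scale.


def _binomial_parts(records: pd.DataFrame):
    """(auc, success) pairs for the 3->2 and 2->1 transitions."""
    auc = records["auc_d84"].to_numpy(dtype=float)
    mayo = records["baseline_mayo"].to_numpy()
    out = records["outcome_mayo_d84"].to_numpy()
    m3 = mayo == 3
    part32 = (auc[m3], (out[m3] <= 2))
    reached2 = m3 & (out <= 2)
    m2 = (mayo == 2) | reached2
    part21 = (auc[m2], (out[m2] == 1))
    return part32, part21


def _neg2ll_binomial(log_auc50: float, auc: np.ndarray, success: np.ndarray,
                     emax: float, hill: float) -> float:
    p = transition_probability(auc, emax, float(np.exp(log_auc50)), hill)
    with np.errstate(divide="ignore"):
        ll = np.where(success, np.log(p), np.log1p(-p))
    if np.any(~np.isfinite(ll)):
        return float("inf")
    return float(-2.0 * ll.sum())


def _fit_one_auc50(auc: np.ndarray, success: np.ndarray, emax: float,
                   hill: float) -> tuple[float, float, bool]:
    """Profile fit of one AUC50; returns (auc50, -2LL, identifiable)."""
    lo, hi = _LOG_AUC50_BOUNDS
    if len(auc) == 0 or success.all() or (~success).all():
        # all outcomes identical: the likelihood is monotone in auc50 and
        # the optimum sits at a bound
        f_lo = _neg2ll_binomial(lo, auc, success, emax, hill)
        f_hi = _neg2ll_binomial(hi, auc, success, emax, hill)
        return ((np.exp(lo), f_lo, False) if f_lo <= f_hi
                else (np.exp(hi), f_hi, False))
    # deterministic coarse grid, then bounded local refinement
    grid = np.linspace(lo, hi, 81)
    vals = np.array([_neg2ll_binomial(g, auc, success, emax, hill) for g in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _neg2ll_binomial, bounds=(a, b), method="bounded",
        args=(auc, success, emax, hill),
        options={"xatol": 1e-10})
    best_x, best_f = float(res.x), float(res.fun)
    if vals[i] < best_f:  # pragma: no cover - defensive
        best_x, best_f = float(grid[i]), float(vals[i])
    return float(np.exp(best_x)), best_f, True


@dataclass(frozen=True)
class Auc50Fit:
    auc50_32: float
    auc50_21: float
    neg2ll: float
    identifiable_32: bool
    identifiable_21: bool


def fit_auc50(records: pd.DataFrame, emax_32: float, emax_21: float,
              hill: float = 1.0) -> Auc50Fit:
    """Profile-maximum-likelihood AUC50s at a fixed (emax_32, emax_21) pair.

    Non-identifiable parts (all outcomes identical) are flagged and pinned
    at the search bound rather than raising.
    """
    _validate_records(records)
    (auc32, s32), (auc21, s21) = _binomial_parts(records)
    a32, f32, id32 = _fit_one_auc50(auc32, s32, emax_32, hill)
    a21, f21, id21 = _fit_one_auc50(auc21, s21, emax_21, hill)
    return Auc50Fit(auc50_32=a32, auc50_21=a21, neg2ll=f32 + f21,
                    identifiable_32=id32, identifiable_21=id21)


# ---------------------------------------------------------------------------
# likelihood profiling over the Emax pair


def _default_emax_grid() -> np.ndarray:
    # 0.70 .. 1.00 in steps of 0.02; brackets both published contour endpoints
    return np.round(np.arange(0.70, 1.0001, 0.02), 10)


def _interp_crossings(grid: np.ndarray, delta: np.ndarray,
                      cutoff: float) -> list[float]:
    """Linear interpolation of cutoff crossings along one grid axis."""
    xs: list[float] = []
    for i in range(len(grid) - 1):
        d0, d1 = delta[i], delta[i + 1]
        if (d0 - cutoff) * (d1 - cutoff) < 0:
            frac = (cutoff - d0) / (d1 - d0)
            xs.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    return xs


@dataclass(frozen=True)
class ProfileResult:
    """Likelihood-profile surface over (emax_32, emax_21) pairs."""

    table: pd.DataFrame  # emax_32, emax_21, auc50_32, auc50_21, delta2ll
    mle: tuple[float, float]  # grid argmin
    neg2ll_min: float
    cutoff: float
    emax_32_range: tuple[float, float]  # extent of the delta2ll <= cutoff region
    emax_21_range: tuple[float, float]
    contour_bracketed: bool  # False if the grid never crosses the cutoff


def likelihood_profile(records: pd.DataFrame,
                       emax_32_grid=None, emax_21_grid=None,
                       hill: float = 1.0,
                       cutoff: float = DELTA2LL_95) -> ProfileResult:
    """Delta(-2 log L) surface over an Emax grid, with profiled AUC50s.

    Exploits the separable likelihood: the surface is the outer sum of two
    1-D profiles, so each grid axis needs only one fit per grid value.
    The cutoff region's axis ranges (profile confidence intervals) are
    refined by linear interpolation along grid edges.
    """
    _validate_records(records)
    g32 = np.asarray(_default_emax_grid() if emax_32_grid is None else emax_32_grid,
                     dtype=float)
    g21 = np.asarray(_default_emax_grid() if emax_21_grid is None else emax_21_grid,
                     dtype=float)
    if np.any((g32 <= 0) | (g32 > 1)) or np.any((g21 <= 0) | (g21 > 1)):
        raise ValueError("emax grids must lie in (0, 1]")
    (auc32, s32), (auc21, s21) = _binomial_parts(records)
    fit32 = [_fit_one_auc50(auc32, s32, e, hill) for e in g32]
    fit21 = [_fit_one_auc50(auc21, s21, e, hill) for e in g21]
    f32 = np.array([f for _, f, _ in fit32])
    f21 = np.array([f for _, f, _ in fit21])
    surface = f32[:, None] + f21[None, :]
    neg2ll_min = float(surface.min())
    delta = surface - neg2ll_min
    i32, i21 = np.unravel_index(int(np.argmin(surface)), surface.shape)

    rows = []
    for i, e32 in enumerate(g32):
        for j, e21 in enumerate(g21):
            rows.append((e32, e21, fit32[i][0], fit21[j][0], delta[i, j]))
    table = pd.DataFrame(rows, columns=["emax_32", "emax_21", "auc50_32",
                                        "auc50_21", "delta2ll"])

    # the region {delta <= cutoff} factorises: delta(i,j) = d32[i] + d21[j]
    d32 = f32 - f32.min()
    d21 = f21 - f21.min()
    bracketed = bool(delta.max() > cutoff)

    def axis_range(grid, d):
        inside = grid[d <= cutoff]
        pts = list(inside) + _interp_crossings(grid, d, cutoff)
        return (float(min(pts)), float(max(pts)))

    return ProfileResult(
        table=table,
        mle=(float(g32[i32]), float(g21[i21])),
        neg2ll_min=neg2ll_min,
        cutoff=float(cutoff),
        emax_32_range=axis_range(g32, d32),
        emax_21_range=axis_range(g21, d21),
        contour_bracketed=bracketed,
    )


# ---------------------------------------------------------------------------
# calibration helper


def er_params_through(emax_32: float, emax_21: float,
                      anchor_2: tuple[float, float],
                      anchor_3: tuple[float, float],
                      hill: float = 1.0) -> ERParams:
    """Solve the AUC50 pair so the model passes through two operating points.

    ``anchor_2`` = (AUC, pEI) for a baseline-2 patient, ``anchor_3``
    likewise for baseline 3.  Closed form for hill = 1; general hill by
    the same algebra on AUC^hill.  Raises if an anchor probability is not
    attainable under the requested maxima.
    """
    auc2, p2 = anchor_2
    auc3, p3 = anchor_3
    if not (0 < p2 < emax_21):
        raise ValueError("anchor_2 probability must lie strictly below emax_21")
    a2h = auc2 ** hill
    auc50_21 = (a2h * (emax_21 / p2 - 1.0)) ** (1.0 / hill)
    p21_at3 = transition_probability(auc3, emax_21, auc50_21, hill)
    p32_needed = p3 / p21_at3
    if not (0 < p32_needed < emax_32):
        raise ValueError("anchor_3 probability not attainable under emax_32")
    a3h = auc3 ** hill
    auc50_32 = (a3h * (emax_32 / p32_needed - 1.0)) ** (1.0 / hill)
    return ERParams(emax_32=emax_32, emax_21=emax_21,
                    auc50_32=float(auc50_32), auc50_21=float(auc50_21),
                    hill=hill)
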