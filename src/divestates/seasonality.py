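"""Seasonality of state occupancy and its link to horizontal move persistence.

Monthly per-individual counts of dives in a focal state are modelled with a
binomial (logit link) regression on a cyclic cubic regression spline of
month — the basis is periodic, so January and December join smoothly — plus
per-individual intercepts capturing between-animal differences in baseline
occupancy.  The association between move-persistence class (localised vs
transiting) and behavioural state is tested with pairwise two-proportion
z-tests across states under a Holm correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError

__all__ = [
    "monthly_state_counts",
    "cyclic_spline_basis",
    "CyclicSplineModel",
    "fit_seasonal_binomial",
    "mp_state_association",
]

PERIOD = 12.0
MONTH_LO = 1.0  # basis is periodic on [1, 13)


def monthly_state_counts(decoded: pd.DataFrame, n_states: int = 4) -> pd.DataFrame:
    """Per individual x month: total dives and dives in each state.

    Months with zero dives for an individual are absent, not zero-filled.
    Expects columns ``id``, ``month`` and ``state`` (labels 1..n_states).
    """
    grp = decoded.groupby(["id", "month"])
    out = grp.size().rename("n_total").reset_index()
    for k in range(1, n_states + 1):
        nk = (
            decoded[decoded["state"] == k]
            .groupby(["id", "month"])
            .size()
            .rename(f"n_state_{k}")
            .reset_index()
        )
        out = out.merge(nk, on=["id", "month"], how="left")
    return out.fillna(0).astype({f"n_state_{k}": int for k in range(1, n_states + 1)})


def cyclic_spline_basis(months, knots: int = 6) -> np.ndarray:
    """Cyclic cubic regression spline basis on the month circle.

    ``knots`` positions are equally spaced on [1, 13] with the last wrapping
    onto the first, leaving ``knots - 1`` free columns.  Each column is the
    periodic natural cubic spline interpolating an indicator at one knot, so
    the basis (and its first two derivatives) is periodic and reproduces
    constants exactly.  Fractional months are allowed for prediction grids.
    """
    if knots < 4:
        raise ConfigurationError("need at least 4 knots for a cyclic cubic basis")
    m = knots - 1  # distinct knots
    h = PERIOD / m
    x = np.asarray(months, dtype=float)
    xw = MONTH_LO + np.mod(x - MONTH_LO, PERIOD)
    # periodic spline system B gamma = D y  (gamma: second derivatives at knots)
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for j in range(m):
        B[j, (j - 1) % m] += h / 6.0
        B[j, j] += 2.0 * h / 3.0
        B[j, (j + 1) % m] += h / 6.0
        D[j, (j - 1) % m] += 1.0 / h
        D[j, j] += -2.0 / h
        D[j, (j + 1) % m] += 1.0 / h
    F = np.linalg.solve(B, D)  # gamma = F y
    j_int = np.minimum((np.floor((xw - MONTH_LO) / h)).astype(int), m - 1)
    t = xw - (MONTH_LO + j_int * h)
    X = np.zeros((x.size, m))
    rows = np.arange(x.size)
    # value weights on knot values y_j, y_{j+1}
    X[rows, j_int] += (h - t) / h
    X[rows, (j_int + 1) % m] += t / h
    # curvature weights on gamma_j, gamma_{j+1}, mapped back to y via F
    cj = ((h - t) ** 3 / h - h * (h - t)) / 6.0
    cj1 = (t**3 / h - h * t) / 6.0
    G = np.zeros((x.size, m))
    G[rows, j_int] += cj
    G[rows, (j_int + 1) % m] += cj1
    X += G @ F
    return X


@dataclass
class CyclicSplineModel:
    """A fitted seasonal binomial model for one focal state."""

    focal_state: int
    knots: int
    params: np.ndarray  # spline coefficients then per-individual offsets
    individuals: list[str]
    deviance: float
    month_grid: np.ndarray  # 0.1-month grid on [1, 13]
    curve_reference: np.ndarray  # fitted proportion, reference individual
    curve_population: np.ndarray  # average over individuals
    converged: bool = True
    ridge_fallback: bool = False

    @property
    def peak_month(self) -> float:
        return float(self.month_grid[int(np.argmax(self.curve_population))])


def _design(months: np.ndarray, ids: np.ndarray, individuals: list[str], knots: int):
    Xs = cyclic_spline_basis(months, knots)
    dummies = np.column_stack(
        [(ids == ind).astype(float) for ind in individuals[1:]]
    ) if len(individuals) > 1 else np.empty((len(months), 0))
    return np.column_stack([Xs, dummies])


def fit_seasonal_binomial(
    counts: pd.DataFrame,
    focal_state: int = 1,
    knots: int = 6,
) -> CyclicSplineModel:
    """Binomial-logit fit of monthly focal-state proportions on the cyclic basis.

    Individuals enter as fixed intercept offsets (reference: first individual
    in the table).  Requires at least two individuals and six distinct
    months.  Complete separation or non-convergence falls back to a lightly
    ridge-penalised fit, flagged on the result.
    """
    col = f"n_state_{focal_state}"
    if col not in counts.columns:
        raise DataError(f"counts table lacks column {col}")
    individuals = list(pd.unique(counts["id"]))
    if len(individuals) < 2:
        raise DataError("need at least 2 individuals")
    if counts["month"].nunique() < 6:
        raise DataError("need at least 6 distinct months")
    months = counts["month"].to_numpy(float)
    ids = counts["id"].to_numpy()
    X = _design(months, ids, individuals, knots)
    endog = np.column_stack(
        [counts[col].to_numpy(float), (counts["n_total"] - counts[col]).to_numpy(float)]
    )
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    ridge = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        params = np.asarray(res.params)
        deviance = float(res.deviance)
        converged = bool(res.converged)
        if not converged or not np.all(np.isfinite(params)):
            raise ValueError("non-converged")
    except Exception:
        ridge = True
        res = model.fit_regularized(alpha=1e-6, L1_wt=0.0)
        params = np.asarray(res.params)
        mu_hat = model.predict(params)
        deviance = float(
            model.family.deviance(endog[:, 0] / endog.sum(axis=1), mu_hat,
                                  var_weights=endog.sum(axis=1))
        )
        converged = True
    grid = np.arange(1.0, 13.0 + 1e-9, 0.1)
    Xg = cyclic_spline_basis(grid, knots)
    eta_base = Xg @ params[: knots - 1]
    offsets = np.concatenate([[0.0], params[knots - 1 :]])
    curves = 1.0 / (1.0 + np.exp(-(eta_base[None, :] + offsets[:, None])))
    return CyclicSplineModel(
        focal_state=focal_state,
        knots=knots,
        params=params,
        individuals=[str(i) for i in individuals],
        deviance=deviance,
        month_grid=grid,
        curve_reference=curves[0],
        curve_population=curves.mean(axis=0),
        converged=converged,
        ridge_fallback=ridge,
    )


def mp_state_association(dives: pd.DataFrame, min_per_state: int = 2) -> dict:
    """Test whether localised-movement proportions differ across states.

    Per state, the proportion of dives whose linked move-persistence class is
    'localised'; all pairwise differences are tested with two-proportion
    z-tests and Holm-adjusted.  States with fewer dives than
    ``min_per_state`` are excluded and flagged.
    """
    if "state" not in dives.columns or "mp_class" not in dives.columns:
        raise DataError("need per-dive 'state' and 'mp_class' columns")
    df = dives.dropna(subset=["state", "mp_class"])
    tab = (
        df.assign(localised=df["mp_class"].eq("localised"))
        .groupby("state")["localised"]
        .agg(["sum", "count"])
        .rename(columns={"sum": "n_localised", "count": "n"})
    )
    tab["proportion_localised"] = tab["n_localised"] / tab["n"]
    small = tab.index[tab["n"] < min_per_state].tolist()
    usable = tab[tab["n"] >= min_per_state]
    rows = []
    for a, b in combinations(usable.index, 2):
        xa, na = int(usable.loc[a, "n_localised"]), int(usable.loc[a, "n"])
        xb, nb = int(usable.loc[b, "n_localised"]), int(usable.loc[b, "n"])
        pa, pb = xa / na, xb / nb
        pp = (xa + xb) / (na + nb)
        se = np.sqrt(pp * (1 - pp) * (1 / na + 1 / nb))
        z = (pa - pb) / se if se > 0 else 0.0
        p = 2.0 * norm.sf(abs(z))
        rows.append(
            {
                "comparison": f"state {a} - state {b}",
                "estimate": pa - pb,
                "se": se,
                "z": z,
                "p_raw": p,
            }
        )
    pairs = pd.DataFrame(rows)
    if len(pairs):
        pairs["p_adj"] = multipletests(pairs["p_raw"], method="holm")[1]
    return {
        "per_state": tab,
        "pairwise": pairs,
        "excluded_states": small,
    }
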