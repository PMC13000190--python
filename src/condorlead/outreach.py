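"""Extrapolating outreach levels to 56-day survival.

The chain has four steps. (1) A Cox proportional-hazards model links a
measured blood-lead value to the probability of surviving the following 56
days (S56), with lnPb the sole predictor; targeted samples and
wildfire-window deaths are censored out. (2) An outreach LMM predicts the
flock-wide mean lnPb for a scenario (outreach levels, peak bimonthly deer
hunt, seasonal-mean pig hunt, Targeted = 0). (3) Because S56 is nonlinear
in lnPb, the scenario's lnPb distribution — normal around the LMM
prediction with the model's unexplained variance — is discretised on a
grid and the survival curve averaged over it. (4) Sweeping a
Contacts x Boxes grid yields the survival response surface, summarised by
a planar regression with interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .exposure import FitResult


@dataclass
class CoxLink:
    """Fitted lnPb -> S56 link.

    S56(lnPb) = exp(-H0(56) * exp(coef * (lnPb - lnpb_mean))), with the
    baseline cumulative hazard taken at the sample-mean lnPb (lifelines'
    centring convention, recorded here explicitly).
    """
    coef: float
    coef_se: float
    baseline_cumhaz_56: float
    lnpb_mean: float
    n: int
    n_events: int

    def s56(self, lnpb):
        lnpb = np.asarray(lnpb, float)
        return np.exp(-self.baseline_cumhaz_56 *
                      np.exp(self.coef * (lnpb - self.lnpb_mean)))


def fit_cox_link(samples: pd.DataFrame) -> CoxLink:
    """Fit the Cox model for 56-day survival after a blood sample.

    ``samples`` needs ``lnPb``, ``days56`` (follow-up time, capped at 56),
    ``died56`` (event flag) and optionally ``Targeted`` and ``death_date``
    (for wildfire censoring). Ties are handled by the Breslow/Efron default
    of the partial-likelihood fitter; ties are rare in 56-day windows.
    """
    df = samples.copy()
    if "Targeted" in df.columns:
        df = df[df["Targeted"] == 0]
    if "death_date" in df.columns:
        lo, hi = pd.Timestamp("2020-08-01"), pd.Timestamp("2020-08-31")
        fire = df["died56"].astype(bool) & df["death_date"].notna() & \
            (df["death_date"] >= lo) & (df["death_date"] <= hi)
        df = df[~fire]
    if df["died56"].sum() == 0:
        raise ValueError("no deaths in the 56-day windows: the lnPb-"
                         "survival link is not estimable")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["days56", "died56", "lnPb"]], duration_col="days56",
                event_col="died56")
    ch = cph.baseline_cumulative_hazard_
    idx = ch.index.to_numpy(dtype=float)
    h56 = float(ch.iloc[np.searchsorted(idx, 56.0, side="right") - 1, 0]) \
        if (idx <= 56.0).any() else float(ch.iloc[-1, 0])
    return CoxLink(coef=float(cph.params_["lnPb"]),
                   coef_se=float(cph.standard_errors_["lnPb"]),
                   baseline_cumhaz_56=h56,
                   lnpb_mean=float(df["lnPb"].mean()),
                   n=len(df), n_events=int(df["died56"].sum()))


@dataclass
class LnPbDensity:
    """Discretised lnPb distribution for one scenario."""
    grid: np.ndarray
    probs: np.ndarray
    mean: float
    sd: float

    def __post_init__(self):
        if (self.probs < 0).any():
            raise ValueError("negative probabilities")
        s = self.probs.sum()
        if abs(s - 1.0) > 1e-12:
            self.probs = self.probs / s


def predict_lnpb_density(fit: FitResult, scenario: dict,
                         spread: str = "total", n_grid: int = 401,
                         half_width_sd: float = 4.0) -> LnPbDensity:
    """Scenario lnPb distribution from an outreach LMM fit.

    The mean is the fixed-effects prediction at the scenario covariates
    (Targeted = 0, hunt covariates at the scenario's levels). The spread is
    the model's unexplained variance: residual plus random-intercept
    variances by default (``spread='total'``, appropriate for a flock-wide
    prediction that marginalises the random effects), or residual-only
    (``spread='residual'``). Discretised on ``n_grid`` points spanning
    +/- ``half_width_sd`` standard deviations, normalised; the grid widens
    automatically until its pre-normalisation mass is within 1e-6 of 1.
    """
    coefs = fit.coefficients.set_index("term")["estimate"]
    mean = float(coefs["Intercept"])
    for term in fit.terms:
        parts = term.split(":")
        x = 1.0
        for p in parts:
            if p not in scenario:
                raise ValueError(f"scenario missing covariate {p!r}")
            x *= scenario[p]
        mean += float(coefs[term]) * x
    if spread == "total":
        var = float(sum(fit.vc.values()))
    elif spread == "residual":
        var = float(fit.vc["Residual"])
    else:
        raise ValueError("spread must be 'total' or 'residual'")
    sd = np.sqrt(var)
    if sd == 0:
        return LnPbDensity(np.array([mean]), np.array([1.0]), mean, 0.0)
    hw = half_width_sd
    while True:
        grid = np.linspace(mean - hw * sd, mean + hw * sd, n_grid)
        p = stats.norm.pdf(grid, mean, sd)
        p = p * (grid[1] - grid[0])
        if abs(p.sum() - 1.0) <= 1e-6:
            break
        hw *= 1.5  # widen until the tail mass is negligible
        if hw > 64:
            raise RuntimeError("lnPb grid failed to capture the density")
    return LnPbDensity(grid, p / p.sum(), mean, sd)


def weighted_s56(density: LnPbDensity, link: CoxLink) -> float:
    """Density-weighted average 56-day survival: sum_i p_i * S56(x_i)."""
    return float(np.sum(density.probs * link.s56(density.grid)))


@dataclass
class S56Surface:
    grid: pd.DataFrame          # Contacts, Boxes, s56 per cell
    coefficients: dict          # planar regression with interaction
    scenario: dict


def outreach_surface(fit: FitResult, link: CoxLink, contacts_grid,
                     boxes_grid, scenario: dict,
                     spread: str = "total") -> S56Surface:
    """Sweep Contacts x Boxes and average S56 per cell.

    ``scenario`` holds the non-outreach covariate levels (Targeted = 0,
    Bioyear/season-specific hunt levels etc.); Contacts and Boxes are
    overwritten per cell. The surface is summarised by the ordinary
    least-squares fit S56 ~ Contacts + Boxes + Contacts:Boxes.
    """
    contacts_grid = np.asarray(contacts_grid, float)
    boxes_grid = np.asarray(boxes_grid, float)
    if contacts_grid.size == 0 or boxes_grid.size == 0:
        raise ValueError("empty outreach grid")
    rows = []
    for c in contacts_grid:
        for b in boxes_grid:
            sc = dict(scenario)
            sc["Contacts"] = float(c)
            sc["Boxes"] = float(b)
            dens = predict_lnpb_density(fit, sc, spread=spread)
            rows.append({"Contacts": float(c), "Boxes": float(b),
                         "s56": weighted_s56(dens, link)})
    grid = pd.DataFrame(rows)
    X = np.column_stack([np.ones(len(grid)), grid["Contacts"],
                         grid["Boxes"], grid["Contacts"] * grid["Boxes"]])
    beta, *_ = np.linalg.lstsq(X, grid["s56"].to_numpy(), rcond=None)
    coefs = dict(zip(["Intercept", "Contacts", "Boxes", "Contacts:Boxes"],
                     beta.tolist()))
    return S56Surface(grid=grid, coefficients=coefs, scenario=dict(scenario))
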