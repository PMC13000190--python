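"""Linear mixed models of log blood lead, AICc model selection and the
year-effect decomposition.

The response is lnPb = ln(blood lead after detection-limit flooring).
Candidate fixed effects span sample context (Targeted), age and
time-since-release classes, behaviour (FreeFly, Proffered, Presence,
Coastal), season, hunt levels with ban-period interactions, and outreach
levels (Contacts, Boxes) with outreach-by-hunt interactions. Condor ID and
Bioyear enter as crossed random intercepts, except in year-effect
decomposition mode where Bioyear is a categorical fixed effect (baseline:
all years before the 2008 ban) and only the ID intercept remains.

Selection fits every admissible subset of a declared term universe
(marginality respected) by maximum likelihood, ranks by AICc, and reports
Akaike weights, per-term sum-of-weights importance, and model-averaged
standardised coefficients (partial-standard-deviation scaling).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

Z90 = stats.norm.ppf(0.95)  # Wald 90% CI half-width multiplier


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights over a model set (normalised relative likelihoods)."""
    a = np.asarray(aicc_values, float)
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


@dataclass
class FitResult:
    """One mixed-model fit.

    Coefficients are reported with SEs and Wald 90% CIs; variance
    components cover each random intercept plus the residual. ``k`` counts
    fixed effects plus variance parameters.
    """
    terms: tuple[str, ...]
    coefficients: pd.DataFrame
    vc: dict
    loglik: float
    k: int
    n: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    std_coefficients: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        if not np.isfinite(self.aicc):
            raise ValueError("non-finite AICc")


def _check_marginality(terms) -> None:
    mains = {t for t in terms if ":" not in t}
    for t in terms:
        if ":" in t:
            missing = [p for p in t.split(":") if p not in mains]
            if missing:
                raise ValueError(
                    f"interaction {t!r} requires main effects {missing}")


def _design_matrix(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Fixed-effects design (intercept + terms; ':' denotes products)."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        cols = t.split(":")
        x = data[cols[0]].to_numpy(float).copy()
        for c in cols[1:]:
            x = x * data[c].to_numpy(float)
        X[t] = x
    return X


def _partial_sd(X: np.ndarray, n: int) -> np.ndarray:
    """Partial standard deviation of each non-intercept column.

    sd(x) * sqrt(1/VIF) * sqrt((n-1)/(n-k)), the multicollinearity-adjusted
    scale used for standardised coefficients; VIF from regressing each
    column on the others (1.0 for a single predictor).
    """
    k = X.shape[1]  # includes intercept
    out = np.empty(k - 1)
    for j in range(1, k):
        x = X[:, j]
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, x, rcond=None)
        resid = x - others @ beta
        sst = np.sum((x - x.mean()) ** 2)
        vif = sst / np.sum(resid ** 2) if np.sum(resid ** 2) > 0 else np.inf
        sd = x.std(ddof=1)
        out[j - 1] = sd * np.sqrt(1.0 / vif) * np.sqrt((n - 1) / (n - k))
    return out


def fit_exposure_model(data: pd.DataFrame, terms,
                       response: str = "lnPb",
                       random: tuple[str, ...] = ("ID", "Bioyear"),
                       reml: bool = False) -> FitResult:
    """Fit one LMM for log blood lead.

    ``terms`` are column names in ``data`` (interactions as 'A:B');
    ``random`` names the crossed random-intercept grouping columns. Fits by
    maximum likelihood by default (the model-selection mode); set
    ``reml=True`` for a final fit.
    """
    terms = tuple(terms)
    _check_marginality(terms)
    X = _design_matrix(data, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns for the caller
        aliased = []
        cols = X.columns.tolist()
        for j in range(1, len(cols)):
            sub = X.iloc[:, :j + 1].to_numpy()
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                aliased.append(cols[j])
        raise ValueError(f"rank-deficient design; aliased columns {aliased}")

    df = data.copy()
    rhs = " + ".join([f"Q('{t.replace(':', '__x__')}')" for t in terms]) \
        if terms else "1"
    for t in terms:
        if ":" in t:
            df[t.replace(":", "__x__")] = X[t].to_numpy()
        else:
            df[t.replace(":", "__x__")] = df[t]
    formula = f"{response} ~ {rhs}"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(random) == 0:
            raise ValueError("at least one random intercept is required; "
                             "use year_effect_decomposition for fixed-year "
                             "models")
        if len(random) == 1:
            model = smf.mixedlm(formula, df, groups=df[random[0]])
            res = model.fit(reml=reml)
            vc = {random[0]: float(res.cov_re.iloc[0, 0])}
        else:
            df["_one"] = 1
            vcf = {r: f"0 + C({r})" for r in random}
            model = smf.mixedlm(formula, df, groups="_one",
                                vc_formula=vcf, re_formula="0")
            res = model.fit(reml=reml)
            vc = {r: float(res.vcomp[i]) for i, r in
                  enumerate(model.exog_vc.names)}
    vc["Residual"] = float(res.scale)

    fe = res.fe_params
    se = res.bse_fe
    names = ["Intercept"] + list(terms)
    coef = pd.DataFrame({
        "term": names,
        "estimate": np.asarray(fe),
        "se": np.asarray(se),
        "ci90_low": np.asarray(fe) - Z90 * np.asarray(se),
        "ci90_high": np.asarray(fe) + Z90 * np.asarray(se),
    })

    n = len(df)
    k = len(fe) + len(vc)  # fixed effects + variance components (+resid)
    ll = float(res.llf)
    Xm = X.to_numpy()
    fitted_fixed = Xm @ np.asarray(fe)
    var_f = float(np.var(fitted_fixed))
    var_re = float(sum(v for r, v in vc.items() if r != "Residual"))
    tot = var_f + var_re + vc["Residual"]
    r2m = var_f / tot
    r2c = (var_f + var_re) / tot

    std = None
    if terms:
        psd = _partial_sd(Xm, n)
        sdy = df[response].std(ddof=1)
        std = pd.DataFrame({
            "term": list(terms),
            "estimate": np.asarray(fe)[1:] * psd / sdy,
            "se": np.asarray(se)[1:] * psd / sdy,
        })
    return FitResult(terms=terms, coefficients=coef, vc=vc, loglik=ll, k=k,
                     n=n, aicc=aicc(ll, k, n), r2_marginal=r2m,
                     r2_conditional=r2c, std_coefficients=std)


def admissible_subsets(universe) -> list[tuple[str, ...]]:
    """All subsets of the term universe that respect marginality."""
    universe = list(universe)
    mains = [t for t in universe if ":" not in t]
    inters = [t for t in universe if ":" in t]
    out = []
    for r in range(len(mains) + 1):
        for ms in itertools.combinations(mains, r):
            ok_inters = [i for i in inters
                         if all(p in ms for p in i.split(":"))]
            for r2 in range(len(ok_inters) + 1):
                for is_ in itertools.combinations(ok_inters, r2):
                    out.append(tuple(ms) + tuple(is_))
    return out


def all_subsets(data: pd.DataFrame, universe, response: str = "lnPb",
                random: tuple[str, ...] = ("ID", "Bioyear"),
                max_models: int = 4096) -> pd.DataFrame:
    """Fit every admissible subset of the universe; rank by AICc.

    Returns the ranked model table with columns ``terms`` (tuple), ``k``,
    ``loglik``, ``aicc``, ``delta``, ``weight``, ``nested`` (True when a
    higher-ranked model's terms are a strict subset — extra parameters
    likely uninformative) and a ``fit`` column holding each
    :class:`FitResult`. The intercept-only model is always included.
    """
    subsets = admissible_subsets(universe)
    if len(subsets) > max_models:
        raise ValueError(
            f"{len(subsets)} admissible models exceed the cap {max_models}; "
            "reduce the term universe or raise max_models")
    rows = []
    for terms in subsets:
        fit = fit_exposure_model(data, terms, response=response,
                                 random=random, reml=False)
        rows.append({"terms": terms, "k": fit.k, "loglik": fit.loglik,
                     "aicc": fit.aicc, "fit": fit})
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]
    table["weight"] = akaike_weights(table["aicc"])
    nested = []
    for i, terms in enumerate(table["terms"]):
        tset = set(terms)
        nested.append(any(set(table["terms"].iloc[j]) < tset
                          for j in range(i)))
    table["nested"] = nested
    return table


def variable_importance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-term importance metrics from a ranked model table.

    * ``sum_weights``: summed Akaike weights of models containing the term.
    * ``ratio_full``: |model-averaged standardised coefficient| relative to
      the largest, averaging over all models with absent terms contributing
      zero (full averaging).
    * ``ratio_subset``: same ratio with averaging restricted to the models
      containing the term (conditional averaging).
    """
    if len(table) == 0:
        raise ValueError("empty model table")
    terms = sorted({t for ts in table["terms"] for t in ts})
    w = table["weight"].to_numpy()
    rows = []
    for t in terms:
        has = np.array([t in ts for ts in table["terms"]])
        sw = float(w[has].sum())
        coefs = np.zeros(len(table))
        for i, (ts, fit) in enumerate(zip(table["terms"], table["fit"])):
            if t in ts and fit.std_coefficients is not None:
                sc = fit.std_coefficients
                coefs[i] = float(
                    sc.loc[sc["term"] == t, "estimate"].iloc[0])
        full_avg = float(np.sum(w * coefs))
        subset_avg = float(np.sum(w[has] * coefs[has]) / w[has].sum()) \
            if has.any() else 0.0
        rows.append({"term": t, "sum_weights": sw, "coef_full": full_avg,
                     "coef_subset": subset_avg})
    out = pd.DataFrame(rows)
    for which in ("full", "subset"):
        mx = out[f"coef_{which}"].abs().max()
        out[f"ratio_{which}"] = out[f"coef_{which}"].abs() / mx \
            if mx > 0 else 0.0
    return out


def year_effect_decomposition(data: pd.DataFrame, specs: dict,
                              response: str = "lnPb",
                              baseline_before: int = 2008) -> pd.DataFrame:
    """Categorical year effects under successively richer models.

    ``specs`` maps a model label to its term list; models should be nested
    from a base (Targeted only) upward — a non-nested sequence triggers a
    warning but is still computed. Each model is fit with Bioyear as a
    categorical fixed effect (all years before ``baseline_before`` pooled
    as the reference level), a random ID intercept only, by ML. Returns a
    long table of per-Bioyear coefficients with Wald 90% CIs — the residual
    annual variation in lead exposure after the model's covariates are
    accounted for.
    """
    labels = list(specs)
    for a, b in zip(labels, labels[1:]):
        if not set(specs[a]) <= set(specs[b]):
            warnings.warn(f"model specs {a!r} -> {b!r} are not nested",
                          UserWarning, stacklevel=2)
    df = data.copy()
    yr = df["Bioyear"].astype(int)
    df["_yearcat"] = np.where(yr < baseline_before, "pre",
                              yr.astype(str)).astype(str)
    year_levels = sorted(lv for lv in df["_yearcat"].unique() if lv != "pre")
    rows = []
    for label in labels:
        terms = tuple(specs[label])
        _check_marginality(terms)
        X = _design_matrix(df, terms)
        for lv in year_levels:
            X[f"year_{lv}"] = (df["_yearcat"] == lv).astype(float)
        work = df.copy()
        rhs_cols = []
        for c in X.columns[1:]:
            nm = c.replace(":", "__x__")
            work[nm] = X[c].to_numpy()
            rhs_cols.append(nm)
        formula = f"{response} ~ " + " + ".join(
            f"Q('{c}')" for c in rhs_cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, work, groups=work["ID"]).fit(
                reml=False)
        for lv in year_levels:
            nm = f"Q('year_{lv}')"
            est = float(res.fe_params[nm])
            se = float(res.bse_fe[nm])
            rows.append({"model": label, "bioyear": int(lv),
                         "beta": est, "se": se,
                         "ci90_low": est - Z90 * se,
                         "ci90_high": est + Z90 * se})
    return pd.DataFrame(rows)
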