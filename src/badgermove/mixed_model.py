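"""Mixed-effects modelling of diffusion constants.

The diffusion constant c is positive with multiplicative covariate
effects, so the model acts on the log scale: fixed effects for calendar
month (reference January) and sex (reference male), a random intercept
for animals nested in sites, and optionally correlated per-site random
slopes for capture year.  Fitting delegates to statsmodels' linear
mixed-effects likelihood machinery applied to log c (the log-normal
formulation of a log-link normal model); exact agreement with any
particular penalised-likelihood solver is not a contract — the module is
validated by recovering known effects from synthetic studies.

A fixed effect beta on the log scale corresponds to the multiplicative
rate ratio exp(beta): exp(0.106) = 1.112 means an 11.2% faster diffusion.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .diffusion import DiffusionEstimate, estimates_frame

MONTH_NAMES = ["January", "February", "March", "April", "May", "June",
               "July", "August", "September", "October", "November",
               "December"]


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the diffusion mixed model.

    ``include_year_slopes`` adds correlated site-level random slopes for
    capture year (treated as an ordinal factor within site) on top of the
    animal-within-site random intercept.
    """

    include_month: bool = True
    include_sex: bool = True
    include_year_slopes: bool = True
    reference_month: int = 1    # January
    reference_sex: str = "male"

    def label(self) -> str:
        parts = []
        if self.include_month:
            parts.append("month")
        if self.include_sex:
            parts.append("sex")
        fixed = " + ".join(parts) if parts else "1"
        rand = "(1 | site:animal)"
        if self.include_year_slopes:
            rand += " + (year | site)"
        return f"log c ~ {fixed} + {rand}"


@dataclass
class FitResult:
    """Summary of one mixed-model fit."""

    spec: ModelSpec
    coefficients: pd.DataFrame      # term, estimate, se, t, ci_low, ci_high, p
    random_sd: dict                 # name -> SD
    random_corr: pd.DataFrame | None  # site-level intercept/slope correlations
    residual_sd: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    singular: bool
    warnings: list = dc_field(default_factory=list)
    data_hash: str = ""

    def coefficient(self, term: str) -> pd.Series:
        hit = self.coefficients[self.coefficients["term"] == term]
        if hit.empty:
            raise KeyError(f"no fixed effect named {term!r}")
        return hit.iloc[0]


def effect_multiplier(coefficient: float) -> float:
    """Multiplicative rate ratio implied by a log-scale coefficient."""
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return float(np.exp(coefficient))


def _prepare(estimates) -> pd.DataFrame:
    df = (estimates_frame(estimates)
          if estimates and isinstance(estimates[0], DiffusionEstimate)
          else pd.DataFrame(estimates).copy())
    if df.empty:
        raise ValueError("no estimates to fit")
    required = {"animal_id", "site", "sex", "month", "capture_year", "c"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"estimates lack required columns: {sorted(missing)}")
    if (df["c"] <= 0).any():
        raise ValueError("all c must be positive for the log-scale model")
    df = df.copy()
    df["log_c"] = np.log(df["c"].astype(float))
    df["month_name"] = df["month"].map(lambda m: MONTH_NAMES[int(m) - 1])
    df["animal"] = df["site"].astype(str) + ":" + df["animal_id"].astype(str)
    df["year"] = df["capture_year"].astype(int)
    return df


def _hash_data(df: pd.DataFrame) -> str:
    key = pd.util.hash_pandas_object(
        df[["animal", "month", "year", "log_c"]].sort_values(
            ["animal", "month", "year"]).reset_index(drop=True)
    ).to_numpy().tobytes()
    return hashlib.sha1(key).hexdigest()[:12]


def fit_glmm(estimates, spec: ModelSpec = ModelSpec()) -> FitResult:
    """Fit the diffusion mixed model.

    Degenerate designs degrade gracefully: with a single site (or a single
    capture year) the year random slopes are dropped with a warning rather
    than producing an unidentifiable fit.  Convergence failures and
    singular covariance estimates are flagged on the result, never
    silently ignored.
    """
    df = _prepare(estimates)
    notes: list[str] = []

    fixed_terms = ["1"]
    if spec.include_month and df["month"].nunique() > 1:
        ref = MONTH_NAMES[spec.reference_month - 1]
        fixed_terms.append(f"C(month_name, Treatment(reference='{ref}'))")
    if spec.include_sex and df["sex"].nunique() > 1:
        fixed_terms.append(f"C(sex, Treatment(reference='{spec.reference_sex}'))")
    formula = "log_c ~ " + " + ".join(fixed_terms)

    use_slopes = spec.include_year_slopes
    if use_slopes and (df["site"].nunique() < 2 or df["year"].nunique() < 2):
        notes.append("year random slopes dropped: needs >= 2 sites and "
                     ">= 2 capture years")
        use_slopes = False

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if use_slopes:
            model = smf.mixedlm(
                formula, df, groups="site",
                re_formula="1 + C(year)",
                vc_formula={"animal": "0 + C(animal)"},
            )
        else:
            model = smf.mixedlm(formula, df, groups="animal")
        fit = model.fit(reml=False)
    notes += [str(w.message) for w in caught
              if "converge" in str(w.message).lower()
              or "singular" in str(w.message).lower()
              or "boundary" in str(w.message).lower()]

    fe = fit.fe_params
    se = fit.bse_fe
    ci = fit.conf_int().loc[fe.index]
    coefs = pd.DataFrame({
        "term": [_clean_term(t) for t in fe.index],
        "estimate": fe.to_numpy(),
        "se": se.to_numpy(),
        "t": (fe / se).to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "p": 2 * stats.norm.sf(np.abs((fe / se).to_numpy())),
    }).reset_index(drop=True)

    random_sd, corr = _random_structure(fit, use_slopes)
    singular = bool(np.any([sd < 1e-8 for sd in random_sd.values()]))

    return FitResult(
        spec=spec,
        coefficients=coefs,
        random_sd=random_sd,
        random_corr=corr,
        residual_sd=float(np.sqrt(fit.scale)),
        aic=float(fit.aic),
        bic=float(fit.bic),
        n_obs=len(df),
        converged=bool(fit.converged),
        singular=singular,
        warnings=notes,
        data_hash=_hash_data(df),
    )


def _clean_term(term: str) -> str:
    """'C(month_name, Treatment(...))[T.February]' -> 'February'."""
    if "[T." in term:
        return term.split("[T.")[1].rstrip("]").capitalize()
    return "Intercept" if term == "Intercept" else term


def _random_structure(fit, use_slopes: bool):
    random_sd: dict[str, float] = {}
    corr = None
    if use_slopes:
        cov = np.asarray(fit.cov_re)
        names = list(fit.cov_re.index)
        names = [n.replace("C(year)[T.", "Year ").rstrip("]") if "C(year)" in n
                 else "Intercept" for n in names]
        sds = np.sqrt(np.clip(np.diag(cov), 0, None))
        for n, s in zip(names, sds):
            random_sd[f"site {n}"] = float(s)
        with np.errstate(divide="ignore", invalid="ignore"):
            cm = cov / np.outer(sds, sds)
        cm[~np.isfinite(cm)] = 0.0
        np.fill_diagonal(cm, 1.0)
        corr = pd.DataFrame(cm, index=names, columns=names)
        vc_names = list(fit.model.exog_vc.names)
        for name, var in zip(vc_names, np.atleast_1d(fit.vcomp)):
            random_sd[f"{name} intercept"] = float(np.sqrt(max(var, 0.0)))
    else:
        random_sd["animal intercept"] = float(
            np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
    return random_sd, corr


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the same data by AIC; flag AIC/BIC disagreement.

    Information criteria are only comparable across fits of identical
    data, so mismatched data hashes raise.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    if len({f.data_hash for f in fits}) > 1:
        raise ValueError("fits were computed on different data")
    table = pd.DataFrame({
        "model": [f.spec.label() for f in fits],
        "aic": [f.aic for f in fits],
        "bic": [f.bic for f in fits],
        "n_obs": [f.n_obs for f in fits],
        "converged": [f.converged for f in fits],
    })
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    aic_order = table.index.to_numpy()
    bic_order = table["bic"].rank(method="first").to_numpy() - 1
    table["aic_bic_disagree"] = bool((aic_order != bic_order).any())
    return table
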