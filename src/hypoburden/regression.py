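"""Multivariable logistic models of ICU mortality on hypotension duration.

The primary model regresses ICU death on the longest continuous
below-threshold episode (categorical duration bins, reference = never
below), adjusting for baseline MAP category, maximum norepinephrine-
equivalent dose bin, age band, sex, sepsis, SOFA band, hypertension,
baseline ventilation and RRT, and albumin/creatinine/lactate categories.
Missingness in baseline MAP and the three labs is modelled as an explicit
category, never dropped or imputed.

Estimation is maximum likelihood (Newton); inference is Wald (estimate, SE,
chi-square, two-sided p, odds ratio), matching the reporting layout of
retrospective ICU analyses. Perfect separation and rank deficiency are
surfaced as errors, never silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .episodes import NEVER_BELOW, bin_labels
from .errors import DataError, SeparationError
from .vasodose import DOSE_BIN_LABELS

# ---------------------------------------------------------------------------
# categorical coding of baseline covariates

AGE_CATS = ("<65", "65-74", "75-84", ">=85")
SOFA_CATS = ("<=4", ">4 to <=6", ">6 to <=8", ">8 to <=10", ">10")
ALBUMIN_CATS = (">=2.5", "<2.5", "missing")
CREATININE_CATS = ("<2.0", ">=2.0", "missing")
LACTATE_CATS = ("<2.0", ">=2.0", "missing")
MAP0_CATS = (">=65", "<65", "missing")


def age_category(age: float) -> str:
    if age < 65:
        return "<65"
    if age < 75:
        return "65-74"
    if age < 85:
        return "75-84"
    return ">=85"


def sofa_category(sofa: float) -> str:
    if sofa <= 4:
        return "<=4"
    if sofa <= 6:
        return ">4 to <=6"
    if sofa <= 8:
        return ">6 to <=8"
    if sofa <= 10:
        return ">8 to <=10"
    return ">10"


def _lab_category(value: float, cut: float, high_is_flagged: bool) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    if high_is_flagged:
        return f">={cut}" if value >= cut else f"<{cut}"
    return f"<{cut}" if value < cut else f">={cut}"


def albumin_category(v: float) -> str:
    return _lab_category(v, 2.5, high_is_flagged=False)


def creatinine_category(v: float) -> str:
    return _lab_category(v, 2.0, high_is_flagged=True)


def lactate_category(v: float) -> str:
    return _lab_category(v, 2.0, high_is_flagged=True)


def map0_category(v: float | None) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "missing"
    return "<65" if v < 65 else ">=65"


@dataclass
class DesignSpec:
    """Reference-cell dummy coding: ordered terms, categories, references."""

    terms: dict[str, tuple[tuple[str, ...], str]]  # name -> (categories, reference)

    def columns(self) -> list[str]:
        cols = ["const"]
        for name, (cats, ref) in self.terms.items():
            cols += [f"{name}[{c}]" for c in cats if c != ref]
        return cols

    def encode(self, cov: pd.DataFrame) -> pd.DataFrame:
        """Design matrix; raises DataError on an unseen category, naming the field."""
        n = len(cov)
        X = pd.DataFrame({"const": np.ones(n)}, index=cov.index)
        for name, (cats, ref) in self.terms.items():
            col = cov[name].astype(str)
            bad = set(col.unique()) - set(cats)
            if bad:
                raise DataError(f"unseen category for {name!r}: {sorted(bad)}")
            for c in cats:
                if c != ref:
                    X[f"{name}[{c}]"] = (col == c).astype(float)
        return X


def primary_design_spec(duration_cats: tuple[str, ...] | None = None,
                        duration_ref: str = NEVER_BELOW,
                        scheme: str = "2h") -> DesignSpec:
    """The full adjusted model's coding (duration bins swappable per threshold)."""
    if duration_cats is None:
        duration_cats = tuple(bin_labels(scheme))
    return DesignSpec(terms={
        "baseline_map": (MAP0_CATS, ">=65"),
        "duration": (duration_cats, duration_ref),
        "dose": (tuple(DOSE_BIN_LABELS), DOSE_BIN_LABELS[0]),
        "age": (AGE_CATS, "<65"),
        "sex": (("male", "female"), "male"),
        "sepsis": (("no", "yes"), "no"),
        "sofa": (SOFA_CATS, "<=4"),
        "hypertension": (("no", "yes"), "no"),
        "ventilated": (("no", "yes"), "no"),
        "rrt": (("no", "yes"), "no"),
        "albumin": (ALBUMIN_CATS, ">=2.5"),
        "creatinine": (CREATININE_CATS, "<2.0"),
        "lactate": (LACTATE_CATS, "<2.0"),
    })


def encode_covariates(baselines: pd.DataFrame, exposures: pd.DataFrame,
                      threshold: float = 65.0, scheme: str = "2h") -> pd.DataFrame:
    """Categorical covariate records (one row per stay) from raw baselines.

    ``baselines`` carries age_years, sex, sepsis/hypertension/ventilated/rrt
    flags, sofa, and raw lab values (NaN = not measured); ``exposures``
    carries the per-threshold burden columns, baseline_map_mmhg and max_ned.
    """
    from .episodes import duration_bin  # local import to avoid cycle at module load
    from .vasodose import dose_bin

    df = exposures.set_index("stay_id").join(baselines.set_index("stay_id"), how="inner")
    lc, ec = f"longest_{int(threshold)}", f"ever_{int(threshold)}"
    out = pd.DataFrame(index=df.index)
    out["baseline_map"] = df["baseline_map_mmhg"].map(map0_category)
    out["duration"] = [duration_bin(l, e, scheme) for l, e in zip(df[lc], df[ec])]
    out["dose"] = df["max_ned"].map(dose_bin)
    out["age"] = df["age_years"].map(age_category)
    out["sex"] = df["sex"]
    for flag in ("sepsis", "hypertension", "ventilated", "rrt"):
        out[flag] = np.where(df[flag].astype(bool), "yes", "no")
    out["sofa"] = df["sofa"].map(sofa_category)
    out["albumin"] = df["albumin"].map(albumin_category)
    out["creatinine"] = df["creatinine"].map(creatinine_category)
    out["lactate"] = df["lactate"].map(lactate_category)
    return out


# ---------------------------------------------------------------------------
# fitting

@dataclass
class ModelFit:
    """Wald summary table plus everything needed to predict afterwards."""

    table: pd.DataFrame          # index = design column; estimate/se/wald/p/or
    params: pd.Series
    spec: DesignSpec | None
    converged: bool
    llf: float
    n: int
    cov_params: pd.DataFrame = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        lin = X[self.params.index].to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lin))


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # greedy scan for the offending columns
        bad, kept = [], np.empty((A.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([kept, A[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(name)
        raise DataError(f"rank-deficient design; collinear terms: {bad}")


def fit_logistic(X: pd.DataFrame, y, spec: DesignSpec | None = None,
                 tol: float = 1e-10, maxiter: int = 100) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald inference.

    Raises SeparationError on degenerate outcomes or (quasi-)perfect
    separation, and DataError on rank-deficient designs — both conditions
    make the reported odds ratios meaningless, so they are never returned.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise DataError("outcome and design lengths differ")
    if len(X) <= X.shape[1]:
        raise DataError("fewer observations than model terms")
    if y.min() == y.max():
        raise SeparationError("degenerate outcome: all stays share one outcome value")
    _check_rank(X)
    model = sm.Logit(y, X)
    try:
        res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from exc
    params = res.params
    if not res.mle_retvals.get("converged", False):
        # diverging estimates with a flat likelihood are the signature of
        # quasi-separation; anything else is a genuine convergence failure
        if np.abs(params).max() > 15:
            raise SeparationError("quasi-separation: diverging estimates, flat likelihood")
        raise DataError("logistic fit did not converge")
    if np.abs(params).max() > 15:
        raise SeparationError("quasi-separation: diverging estimates")
    se = res.bse
    wald = (params / se) ** 2
    table = pd.DataFrame({
        "estimate": params, "se": se, "wald_chi2": wald,
        "p": res.pvalues, "odds_ratio": np.exp(params),
    })
    return ModelFit(table=table, params=params, spec=spec, converged=True,
                    llf=float(res.llf), n=len(y),
                    cov_params=pd.DataFrame(res.cov_params(),
                                            index=X.columns, columns=X.columns))


def fit_primary_model(cov: pd.DataFrame, y, scheme: str = "2h") -> ModelFit:
    """Encode the Table-style covariate scheme and fit the adjusted model."""
    spec = primary_design_spec(scheme=scheme)
    observed = tuple(c for c in spec.terms["duration"][0]
                     if c == NEVER_BELOW or (cov["duration"] == c).any())
    spec.terms["duration"] = (observed, NEVER_BELOW)
    # drop all-empty categories elsewhere too (a zero column is collinear noise)
    for name, (cats, ref) in list(spec.terms.items()):
        seen = tuple(c for c in cats if c == ref or (cov[name] == c).any())
        spec.terms[name] = (seen, ref)
    X = spec.encode(cov)
    return fit_logistic(X, y, spec=spec)


def threshold_sweep(baselines: pd.DataFrame, exposures: pd.DataFrame, y,
                    thresholds=(55.0, 60.0, 75.0, 80.0),
                    scheme: str = "2h") -> dict[float, ModelFit | None]:
    """Refit the full model swapping in each alternative threshold's bins.

    A threshold with no exposed stays, or whose fit separates, is reported
    as None (with the reason logged) rather than aborting the sweep.
    """
    import logging
    log = logging.getLogger(__name__)
    out: dict[float, ModelFit | None] = {}
    for thr in thresholds:
        cov = encode_covariates(baselines, exposures, threshold=thr, scheme=scheme)
        if (cov["duration"] == NEVER_BELOW).all():
            log.warning("threshold %s: no exposed stays; model skipped", thr)
            out[thr] = None
            continue
        try:
            out[thr] = fit_primary_model(cov, y, scheme=scheme)
        except (SeparationError, DataError) as exc:
            log.warning("threshold %s: %s; model skipped", thr, exc)
            out[thr] = None
    return out


def sweep_table(fits: dict[float, ModelFit | None], scheme: str = "2h") -> pd.DataFrame:
    """Threshold-sweep layout: duration-bin OR and p per threshold column."""
    rows = bin_labels(scheme, include_reference=False)
    data = {}
    for thr, fit in sorted(fits.items()):
        col_or, col_p = [], []
        for lab in rows:
            key = f"duration[{lab}]"
            if fit is not None and key in fit.table.index:
                col_or.append(fit.table.loc[key, "odds_ratio"])
                col_p.append(fit.table.loc[key, "p"])
            else:
                col_or.append(np.nan)
                col_p.append(np.nan)
        data[f"MAP <{int(thr)} OR"] = col_or
        data[f"MAP <{int(thr)} p"] = col_p
    return pd.DataFrame(data, index=rows)


def marginal_mortality(fit: ModelFit, cov: pd.DataFrame, term: str) -> pd.Series:
    """Predicted marginal probability per category of one term.

    Standardisation over the observed covariate distribution: every stay is
    counterfactually assigned the category, predictions are averaged.
    """
    if fit.spec is None or term not in fit.spec.terms:
        raise DataError(f"unknown model term: {term!r}")
    cats, _ = fit.spec.terms[term]
    out = {}
    for c in cats:
        cf = cov.copy()
        cf[term] = c
        out[c] = float(fit.predict(fit.spec.encode(cf)).mean())
    return pd.Series(out, name=f"marginal_mortality[{term}]")


# ---------------------------------------------------------------------------
# sensitivity analyses

def sensitivity_suite(baselines: pd.DataFrame, exposures: pd.DataFrame,
                      outcomes: pd.DataFrame, stays: pd.DataFrame
                      ) -> dict[str, ModelFit | None]:
    """Re-fit the primary model under each pre-specified variant.

    Variants: excluding deaths within 24 h of ICU admission; 28-day
    mortality as the outcome; 6-h duration bins; post-2008 admissions only.
    ``outcomes`` needs icu_death / day28_death / death_time columns,
    ``stays`` icu_in and era.
    """
    cov = encode_covariates(baselines, exposures)
    o = outcomes.set_index("stay_id").loc[cov.index]
    s = stays.set_index("stay_id").loc[cov.index]
    y = o["icu_death"].to_numpy(dtype=bool)

    results: dict[str, ModelFit | None] = {}

    def _try(name, cov_v, y_v, scheme="2h"):
        try:
            results[name] = fit_primary_model(cov_v, y_v, scheme=scheme)
        except (SeparationError, DataError) as exc:
            import logging
            logging.getLogger(__name__).warning("sensitivity %s: %s", name, exc)
            results[name] = None

    _try("primary", cov, y)

    early = (o["death_time"].notna()
             & (o["death_time"] <= s["icu_in"] + 24.0 + 1e-9)).to_numpy()
    _try("exclude_first_24h_deaths", cov[~early], y[~early])

    _try("day28_mortality", cov, o["day28_death"].to_numpy(dtype=bool))

    cov6 = encode_covariates(baselines, exposures, scheme="6h")
    _try("six_hour_bins", cov6, y, scheme="6h")

    post = (s["era"] == "post2008").to_numpy()
    _try("post2008_only", cov[post], y[post])
    return results


def sensitivity_table(results: dict[str, ModelFit | None]) -> pd.DataFrame:
    """Side-by-side duration-bin ORs across the sensitivity variants."""
    rows: dict[str, dict[str, float]] = {}
    for name, fit in results.items():
        if fit is None:
            continue
        for key in fit.table.index:
            if key.startswith("duration["):
                lab = key[len("duration["):-1]
                rows.setdefault(lab, {})[name] = fit.table.loc[key, "odds_ratio"]
    return pd.DataFrame.from_dict(rows, orient="index")
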