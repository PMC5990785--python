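"""Linear mixed-model tests of context effects on acoustic variables.

For each acoustic variable that is highly influential in the discriminant
analysis, a Gaussian LMM with identity link is fitted by maximum likelihood:
response ~ context + controls + (1 | subject).  Context is the test
predictor (treatment contrasts, alert as reference level); significance is
assessed by a likelihood-ratio test of the full model against a null model
without context, with Bonferroni control across the family of responses.
ML (not REML) estimation is used throughout because the compared models
differ in their fixed effects.

Model fitting is delegated to statsmodels' MixedLM behind this module's
interface; likelihood-ratio arithmetic, Bonferroni gating and the
leave-one-subject-out stability check are implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .call_table import FeatureMatrix

__all__ = [
    "LMMSpec",
    "LMMResult",
    "IdentifiabilityError",
    "FitError",
    "fit_lmm",
    "lrt",
    "fit_context_lrt",
    "bonferroni_gate",
    "stability_check",
]

#: Bonferroni-corrected significance threshold for the published family of
#: three response variables, rounded as conventionally reported.
BONFERRONI_ALPHA_3 = 0.017


class IdentifiabilityError(ValueError):
    """The fixed-effects design is rank deficient; aliased terms are listed."""

    def __init__(self, message: str, aliased: Sequence[str] = ()):
        super().__init__(message)
        self.aliased = list(aliased)


class FitError(RuntimeError):
    """The optimizer failed to converge."""


@dataclass(frozen=True)
class LMMSpec:
    """One mixed model: a transformed acoustic response, context as test
    predictor, optional controls, and a subject random intercept."""

    response: str
    test_predictor: str = "context"
    control_predictors: tuple[str, ...] = ("sex", "age_years", "observer", "device")
    random_intercept: str = "subject_id"
    reference_level: str = "alert"
    contexts: tuple[str, ...] | None = None  # restrict rows to these contexts


@dataclass
class LMMResult:
    fixed_effects: pd.DataFrame  # term, estimate, se, t
    random_intercept_variance: float
    log_likelihood: float
    n_obs: int
    n_subjects: int
    converged: bool
    spec: LMMSpec
    row_key: tuple  # identifies the exact rows used (for nesting checks)
    n_fixed_params: int
    lrt_terms: dict = field(default_factory=dict)  # term -> (chi2, df, p)
    full_null: tuple | None = None  # (chi2, df, p) for dropping context
    bonferroni_alpha: float | None = None
    stability: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "response": self.spec.response,
            "fixed_effects": [
                {
                    "term": r.term,
                    "estimate": round(float(r.estimate), 9),
                    "se": round(float(r.se), 9),
                    "t": round(float(r.t), 9),
                }
                for r in self.fixed_effects.itertuples()
            ],
            "random_intercept_variance": round(float(self.random_intercept_variance), 9),
            "log_likelihood": round(float(self.log_likelihood), 9),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
        }
        if self.full_null is not None:
            chi2, df, p = self.full_null
            d["full_null"] = {"chi2": round(float(chi2), 9), "df": int(df), "p": float(p)}
        if self.lrt_terms:
            d["lrt_terms"] = {
                t: {"chi2": round(float(c), 9), "df": int(df), "p": float(p)}
                for t, (c, df, p) in self.lrt_terms.items()
            }
        if self.bonferroni_alpha is not None:
            d["bonferroni_alpha"] = self.bonferroni_alpha
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _build_frame(fm: FeatureMatrix, spec: LMMSpec) -> pd.DataFrame:
    if spec.response not in fm.data.columns:
        raise ValueError(f"response {spec.response!r} is not an active variable")
    df = fm.records.loc[:, ["subject_id", "context", "sex", "age_years", "observer", "device"]].copy()
    df["_y"] = fm.data[spec.response].to_numpy(float)
    if spec.contexts is not None:
        df = df[df["context"].isin(list(spec.contexts))]
    df = df[np.isfinite(df["_y"])]
    return df.reset_index(drop=True)


def _formula(spec: LMMSpec, df: pd.DataFrame) -> str:
    terms = [f"C(context, Treatment({spec.reference_level!r}))"]
    for c in spec.control_predictors:
        if c == "age":
            c = "age_years"
        terms.append(c)
    return "_y ~ " + " + ".join(terms)


def _check_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify aliased columns via pivoted QR: tiny trailing R diagonals
        _, r, piv = scipy.linalg.qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        aliased = [names[j] for j in piv[diag < tol]] if (diag < tol).any() else list(
            names[rank:]
        )
        raise IdentifiabilityError(
            f"fixed-effects design is rank deficient (rank {rank} < {exog.shape[1]}); "
            f"aliased terms: {aliased}",
            aliased,
        )


def _ml_fit(formula: str, df: pd.DataFrame):
    model = smf.mixedlm(formula, df, groups=df["subject_id"])
    _check_rank(np.asarray(model.exog, float), list(model.exog_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # a boundary (zero) subject variance is a legitimate ML solution
        warnings.filterwarnings(
            "ignore", message=".*[Rr]andom effects covariance.*singular.*"
        )
        res = None
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            # a non-finite log-likelihood is a degenerate optimum, not a fit
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
        if res is None:
            raise FitError(f"mixed-model fit failed to converge for: {formula}")
    return model, res


def fit_lmm(fm: FeatureMatrix, spec: LMMSpec) -> LMMResult:
    """Maximum-likelihood fit of response ~ context + controls + (1 | subject).

    Rows with a missing response (e.g. absent inter-call interval) are
    dropped.  Raises :class:`IdentifiabilityError` if the fixed design is
    rank deficient and :class:`FitError` on non-convergence.
    """
    df = _build_frame(fm, spec)
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    formula = _formula(spec, df)
    model, res = _ml_fit(formula, df)

    fe_names = list(model.exog_names)
    fe = pd.DataFrame(
        {
            "term": fe_names,
            "estimate": [float(res.fe_params[t]) for t in fe_names],
            "se": [float(res.bse_fe[t]) for t in fe_names],
        }
    )
    fe["t"] = fe["estimate"] / fe["se"]
    return LMMResult(
        fixed_effects=fe,
        random_intercept_variance=float(np.asarray(res.cov_re)[0, 0]),
        log_likelihood=float(res.llf),
        n_obs=int(len(df)),
        n_subjects=int(df["subject_id"].nunique()),
        converged=bool(res.converged),
        spec=spec,
        row_key=tuple(df.index),
        n_fixed_params=len(fe_names),
    )


def lrt(full: LMMResult, reduced: LMMResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits on identical rows.

    chi2 = 2 (loglik_full - loglik_reduced) clipped at zero; d.f. = the
    difference in fixed-effect parameter count; p from the upper chi-square
    tail.
    """
    if full.row_key != reduced.row_key or full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted on different row sets")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 0:
        raise ValueError("reduced model has more fixed parameters than the full model")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = 1.0 if df == 0 else float(scipy.stats.chi2.sf(chi2, df))
    return chi2, df, p


def fit_context_lrt(
    fm: FeatureMatrix,
    spec: LMMSpec,
    drop_terms: bool = False,
) -> LMMResult:
    """Fit the full model and the no-context null; attach the full-vs-null LRT.

    With ``drop_terms`` each control predictor is additionally dropped in
    turn, yielding per-term likelihood-ratio tests.
    """
    df = _build_frame(fm, spec)
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    full = fit_lmm(fm, spec)

    null_formula = "_y ~ " + " + ".join(
        [c if c != "age" else "age_years" for c in spec.control_predictors]
    ) if spec.control_predictors else "_y ~ 1"
    _, null_res = _ml_fit(null_formula, df)
    n_ctx_terms = len([t for t in full.fixed_effects["term"] if t.startswith("C(context")])
    chi2 = max(0.0, 2.0 * (full.log_likelihood - float(null_res.llf)))
    p = float(scipy.stats.chi2.sf(chi2, n_ctx_terms))
    full.full_null = (chi2, n_ctx_terms, p)

    if drop_terms:
        for ctrl in spec.control_predictors:
            remaining = [c for c in spec.control_predictors if c != ctrl]
            red_spec = LMMSpec(
                response=spec.response,
                control_predictors=tuple(remaining),
                reference_level=spec.reference_level,
                contexts=spec.contexts,
            )
            reduced = fit_lmm(fm, red_spec)
            full.lrt_terms[ctrl] = lrt(full, reduced)
    return full


def bonferroni_gate(
    p_values: Sequence[float], n_tests: int | None = None, alpha: float = 0.05
) -> dict:
    """Bonferroni control: each test is significant iff p < alpha / n_tests
    (strict inequality).  With the conventional family of three responses the
    threshold is reported as 0.017."""
    p_values = list(p_values)
    if any(not (0 <= p <= 1) for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    n = n_tests if n_tests is not None else len(p_values)
    threshold = alpha / n
    reported = BONFERRONI_ALPHA_3 if (n == 3 and alpha == 0.05) else threshold
    return {
        "threshold": threshold,
        "reported_threshold": round(reported, 3),
        "significant": [p < threshold for p in p_values],
    }


def stability_check(
    fm: FeatureMatrix, spec: LMMSpec, threshold: float = 0.5
) -> tuple[pd.DataFrame, str]:
    """Leave-one-subject-out influence check.

    The model is refitted with each subject excluded.  A subject is
    influential if some fixed estimate changes by more than ``threshold``
    (default 50%) of the full-model magnitude *and* by more than one full-
    model standard error — the second condition keeps statistically
    negligible wobbles of near-zero estimates (an age slope of ~0) from
    triggering the flag.  Refit failures are recorded per subject, not
    fatal.
    """
    full = fit_lmm(fm, spec)
    base = full.fixed_effects.set_index("term")
    scale = np.maximum(np.abs(base["estimate"]), base["se"])
    rows = []
    for subject in sorted(fm.records["subject_id"].unique()):
        keep = fm.records["subject_id"] != subject
        sub_fm = FeatureMatrix(
            fm.records[keep],
            variables=fm.variables,
            data=fm.data[keep.to_numpy()],
            transforms=fm.transforms,
        )
        try:
            res = fit_lmm(sub_fm, spec)
        except Exception as exc:  # refit failure recorded, not fatal
            rows.append(
                {
                    "subject_id": subject,
                    "max_rel_change": np.nan,
                    "influential": False,
                    "error": str(exc),
                }
            )
            continue
        est = res.fixed_effects.set_index("term")["estimate"]
        common = base.index.intersection(est.index)
        delta = (est[common] - base.loc[common, "estimate"]).abs()
        rel = delta / scale[common]
        flag = bool(((rel > threshold) & (delta > base.loc[common, "se"])).any())
        rows.append(
            {
                "subject_id": subject,
                "max_rel_change": float(rel.max()),
                "influential": flag,
                "error": "",
            }
        )
    table = pd.DataFrame(rows)
    return table, ("influential" if table["influential"].any() else "stable")
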