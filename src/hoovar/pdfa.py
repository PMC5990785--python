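"""Permuted discriminant function analysis (pDFA) with a crossed design.

The inference at the heart of the package: a linear discriminant analysis
is fitted on a balanced training set (one randomly selected call per
eligible subject per context, eligible = the subject has calls in every
context), all remaining calls — including calls from subjects absent from
training — are cross-classified, and the whole procedure is averaged over
many random selections.  Significance is assessed against a permutation
null that respects repeated measures by shuffling context labels only
within subjects, so per-subject label multisets (and hence eligibility)
are preserved.

The LDA fit is implemented from first principles (pooled within-group
covariance with divisor N - g; discriminant coefficients from the
generalized eigenproblem of between- vs within-group scatter, scaled to
unit within-group variance of each discriminant score) so that loadings are
directly comparable with standard statistical practice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .call_table import AnalysisView

__all__ = [
    "DFAModel",
    "PDFAConfig",
    "PDFAResult",
    "TrainingSelection",
    "DegeneracyError",
    "DesignError",
    "fit_lda",
    "classify",
    "select_balanced_training",
    "cross_classification_rate",
    "permute_within_subjects",
    "run_pdfa",
    "loo_crossvalidated_rates",
]

logger = logging.getLogger(__name__)

#: pooled-covariance condition number beyond which the fit is refused
CONDITION_LIMIT = 1e10


class DegeneracyError(ValueError):
    """The pooled within-group covariance is (near-)singular."""

    def __init__(self, message: str, variables: Sequence[str] = ()):
        super().__init__(message)
        self.variables = list(variables)


class DesignError(ValueError):
    """The data cannot support the requested balanced design."""


@dataclass
class DFAModel:
    """Fitted linear discriminant functions."""

    group_labels: tuple[str, ...]
    group_means: np.ndarray  # groups x variables
    pooled_cov: np.ndarray  # variables x variables, divisor N - g
    loadings: np.ndarray  # variables x functions, unit within-group variance
    priors: np.ndarray  # per group
    centroids: np.ndarray  # groups x functions
    variables: tuple[str, ...] = ()

    @property
    def n_functions(self) -> int:
        return self.loadings.shape[1]


@dataclass
class PDFAConfig:
    n_selections: int = 100
    n_permutations: int = 10_000
    seed: int = 0
    priors_policy: str = "training-proportions"  # or "equal"
    variables: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_selections < 1 or self.n_permutations < 1:
            raise ValueError("n_selections and n_permutations must be >= 1")
        if self.priors_policy not in ("training-proportions", "equal"):
            raise ValueError(f"unknown priors_policy {self.priors_policy!r}")


@dataclass
class PDFAResult:
    """Observed cross-classification rate, permutation null and accounting."""

    observed_rate: float
    expected_rate: float
    p_value: float
    per_context_rates: dict[str, float]
    accounting: dict[str, int]
    config: PDFAConfig
    null_rates: np.ndarray | None = None
    notes: dict = field(default_factory=dict)

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed_rate": round(float(self.observed_rate), 9),
            "expected_rate": round(float(self.expected_rate), 9),
            "p_value": round(float(self.p_value), 9),
            "per_context_rates": {
                k: round(float(v), 9) for k, v in self.per_context_rates.items()
            },
            "accounting": {k: int(v) for k, v in self.accounting.items()},
            "config": {
                "n_selections": self.config.n_selections,
                "n_permutations": self.config.n_permutations,
                "seed": self.config.seed,
                "priors_policy": self.config.priors_policy,
                "variables": list(self.config.variables or ()),
            },
            "notes": self.notes,
        }
        if include_null and self.null_rates is not None:
            d["null_rates"] = [round(float(v), 9) for v in self.null_rates]
        return d

    def to_json(self, include_null: bool = False) -> str:
        return json.dumps(self.to_dict(include_null), indent=2, sort_keys=True)


@dataclass
class TrainingSelection:
    """A balanced-training partition of the rows of an analysis view."""

    train_idx: np.ndarray
    heldout_idx: np.ndarray  # held-out calls of training subjects
    novel_idx: np.ndarray  # all calls of ineligible subjects
    eligible_subjects: tuple[str, ...]


# ---------------------------------------------------------------------------
# LDA


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors_policy: str = "training-proportions",
    label_order: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
) -> DFAModel:
    """Fit linear discriminant functions.

    The pooled within-group covariance uses divisor N - g; coefficient
    vectors solve the symmetric generalized eigenproblem of the
    between-group scatter against the pooled covariance and are scaled so
    each discriminant score has unit pooled within-group variance.  Signs
    are fixed so the largest-magnitude coefficient of each function is
    positive.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, object)
    labels = tuple(label_order) if label_order is not None else tuple(dict.fromkeys(y))
    g = len(labels)
    n, p = X.shape
    if g < 2:
        raise DesignError("need at least 2 groups")
    if n < p + g:
        raise DesignError(f"too few rows ({n}) for {p} variables and {g} groups")

    means = np.empty((g, p))
    Sw = np.zeros((p, p))
    counts = np.empty(g, int)
    for i, lab in enumerate(labels):
        Xi = X[y == lab]
        if len(Xi) < 2:
            raise DesignError(f"group {lab!r} has fewer than 2 rows")
        counts[i] = len(Xi)
        means[i] = Xi.mean(axis=0)
        d = Xi - means[i]
        Sw += d.T @ d
    Sw /= n - g

    eigvals = scipy.linalg.eigvalsh(Sw)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > CONDITION_LIMIT:
        names = list(variables) if variables else [f"x{j}" for j in range(p)]
        vec = scipy.linalg.eigh(Sw)[1][:, 0]
        worst = [names[j] for j in np.argsort(-np.abs(vec))[: min(3, p)]]
        raise DegeneracyError(
            f"pooled within-group covariance is near-singular "
            f"(condition {eigvals[-1] / max(eigvals[0], 1e-300):.2e}); "
            f"collinear variables likely among {worst}",
            worst,
        )

    grand = counts @ means / n
    dm = means - grand
    Sb = (counts[:, None] * dm).T @ dm
    k = min(g - 1, p)
    w, V = scipy.linalg.eigh(Sb, Sw)  # eigenvectors with v' Sw v = 1
    order = np.argsort(w)[::-1][:k]
    L = V[:, order]
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]

    if priors_policy == "equal":
        priors = np.full(g, 1.0 / g)
    else:
        priors = counts / n
    return DFAModel(
        group_labels=labels,
        group_means=means,
        pooled_cov=Sw,
        loadings=L,
        priors=priors,
        centroids=(means - grand) @ L,
        variables=tuple(variables) if variables is not None else tuple(f"x{j}" for j in range(p)),
    )


#: relative score-gap below which two groups are flagged as tied
_TIE_RTOL = 1e-9


def classify(
    model: DFAModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each row to the group maximizing the equal-covariance Gaussian
    posterior (minimal Mahalanobis distance adjusted by log prior).

    Returns (predicted labels, posteriors summing to 1 per row, tie flags).
    Exact ties go to the first group in label order and are flagged.
    """
    X = np.asarray(X, float)
    if X.shape[1] != model.group_means.shape[1]:
        raise ValueError(
            f"variable mismatch: model has {model.group_means.shape[1]} variables, "
            f"data has {X.shape[1]}"
        )
    cho = scipy.linalg.cho_factor(model.pooled_cov, lower=True)
    scores = np.empty((X.shape[0], len(model.group_labels)))
    for i in range(len(model.group_labels)):
        d = (X - model.group_means[i]).T
        z = scipy.linalg.cho_solve(cho, d)
        maha = np.sum(d * z, axis=0)
        scores[:, i] = -0.5 * maha + np.log(model.priors[i])
    shift = scores.max(axis=1, keepdims=True)
    post = np.exp(scores - shift)
    post /= post.sum(axis=1, keepdims=True)
    best = np.argmax(scores, axis=1)
    sorted_scores = np.sort(scores, axis=1)
    gap = sorted_scores[:, -1] - sorted_scores[:, -2]
    scale = np.maximum(np.abs(sorted_scores[:, -1]), 1.0)
    ties = gap <= _TIE_RTOL * scale
    if ties.any():
        # tie broken to the first group in declared label order
        for r in np.flatnonzero(ties):
            tied = np.flatnonzero(scores[r] >= scores[r, best[r]] - _TIE_RTOL * scale[r])
            best[r] = tied.min()
        logger.debug("posterior ties broken to first label for %d rows", int(ties.sum()))
    pred = np.asarray(model.group_labels, object)[best]
    return pred, post, ties


# ---------------------------------------------------------------------------
# Balanced selection and permutation


def _subject_indices(subjects: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for i, s in enumerate(subjects):
        out.setdefault(s, []).append(i)
    return {s: np.asarray(v, int) for s, v in out.items()}


def eligible_subjects(
    y: np.ndarray, subjects: np.ndarray, contexts: Sequence[str]
) -> list[str]:
    """Subjects contributing at least one call to every requested context."""
    subj_idx = _subject_indices(np.asarray(subjects, object))
    out = []
    for s, idx in subj_idx.items():
        present = set(np.asarray(y, object)[idx])
        if all(c in present for c in contexts):
            out.append(s)
    return out


def select_balanced_training(
    y: np.ndarray,
    subjects: np.ndarray,
    contexts: Sequence[str],
    rng: np.random.Generator,
) -> TrainingSelection:
    """One uniformly chosen call per eligible subject per context.

    Held-out = remaining calls of eligible subjects; novel = all calls of
    ineligible subjects.  The three sets partition the rows exactly.
    """
    y = np.asarray(y, object)
    subjects = np.asarray(subjects, object)
    subj_idx = _subject_indices(subjects)
    eligible = [
        s for s, idx in subj_idx.items() if all((y[idx] == c).any() for c in contexts)
    ]
    if len(eligible) < 2:
        raise DesignError(
            f"only {len(eligible)} subject(s) have calls in every context {list(contexts)}"
        )
    train: list[int] = []
    for s in eligible:
        idx = subj_idx[s]
        for c in contexts:
            cand = idx[y[idx] == c]
            train.append(int(cand[rng.integers(len(cand))]))
    train_idx = np.asarray(sorted(train), int)
    eligible_set = set(eligible)
    train_set = set(train)
    heldout, novel = [], []
    for i, s in enumerate(subjects):
        if i in train_set:
            continue
        (heldout if s in eligible_set else novel).append(i)
    return TrainingSelection(
        train_idx=train_idx,
        heldout_idx=np.asarray(heldout, int),
        novel_idx=np.asarray(novel, int),
        eligible_subjects=tuple(eligible),
    )


def permute_within_subjects(
    y: np.ndarray, subjects: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly shuffle each subject's context labels among that subject's
    calls; the per-subject label multiset is conserved by construction and
    asserted."""
    y = np.asarray(y, object)
    out = y.copy()
    for idx in _subject_indices(np.asarray(subjects, object)).values():
        out[idx] = y[idx][rng.permutation(len(idx))]
        assert sorted(out[idx]) == sorted(y[idx])
    return out


# ---------------------------------------------------------------------------
# Cross-classification


def _one_selection_rate(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    contexts: Sequence[str],
    rng: np.random.Generator,
    priors_policy: str,
    variables: Sequence[str] | None = None,
) -> tuple[float, dict[str, float], TrainingSelection]:
    sel = select_balanced_training(y, subjects, contexts, rng)
    model = fit_lda(
        X[sel.train_idx], y[sel.train_idx], priors_policy, label_order=contexts,
        variables=variables,
    )
    rest = np.concatenate([sel.heldout_idx, sel.novel_idx])
    pred, _, _ = classify(model, X[rest])
    truth = y[rest]
    correct = pred == truth
    rate = float(correct.mean())
    per_ctx = {
        c: float(correct[truth == c].mean()) if (truth == c).any() else float("nan")
        for c in contexts
    }
    return rate, per_ctx, sel


def cross_classification_rate(
    view_or_X,
    y: np.ndarray | None = None,
    subjects: np.ndarray | None = None,
    contexts: Sequence[str] = (),
    n_selections: int = 100,
    rng: np.random.Generator | int | None = None,
    priors_policy: str = "training-proportions",
) -> tuple[float, dict[str, float], dict[str, int]]:
    """Average cross-classification rate over random balanced selections.

    Accepts either an :class:`AnalysisView` or explicit (X, y, subjects).
    Returns (mean rate, per-context mean rates, call accounting).
    """
    if isinstance(view_or_X, AnalysisView):
        X, y, subjects = view_or_X.X, view_or_X.labels, view_or_X.subjects
        variables = view_or_X.variables
    else:
        X = np.asarray(view_or_X, float)
        variables = None
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rates = np.empty(n_selections)
    per_ctx_acc = {c: [] for c in contexts}
    sel = None
    for i in range(n_selections):
        r, pc, sel = _one_selection_rate(X, y, subjects, contexts, rng, priors_policy, variables)
        rates[i] = r
        for c in contexts:
            per_ctx_acc[c].append(pc[c])
    accounting = {
        "n_total": int(len(y)),
        "n_eligible_subjects": len(sel.eligible_subjects),
        "n_training": int(len(sel.train_idx)),
        "n_heldout_same_subjects": int(len(sel.heldout_idx)),
        "n_novel_subjects_calls": int(len(sel.novel_idx)),
        "n_novel_subjects": int(
            len(set(np.asarray(subjects, object)) - set(sel.eligible_subjects))
        ),
    }
    per_ctx = {c: float(np.nanmean(per_ctx_acc[c])) for c in contexts}
    return float(rates.mean()), per_ctx, accounting


def run_pdfa(
    view: AnalysisView,
    contexts: Sequence[str],
    config: PDFAConfig,
    keep_null: bool = False,
) -> PDFAResult:
    """Full crossed pDFA: observed rate averaged over ``n_selections``
    balanced selections; null distribution from ``n_permutations``
    within-subject label shuffles, each evaluated with one fresh balanced
    selection (permutation variance dominates selection variance, so the
    null does not re-average over selections; the observed statistic keeps
    the full multi-selection average).

    p-value uses the add-one estimator (1 + #{null >= observed}) /
    (1 + n_permutations), never exactly zero.  Selection and permutation
    streams are derived independently from the config seed, so changing one
    count does not reshuffle the other.
    """
    contexts = tuple(contexts)
    X, y, subjects = view.X, view.labels, view.subjects
    ss = np.random.SeedSequence(config.seed)
    obs_ss, null_ss = ss.spawn(2)

    eligible_obs = set(eligible_subjects(y, subjects, contexts))
    if len(eligible_obs) < 2:
        raise DesignError(
            f"fewer than 2 subjects have calls in every context {list(contexts)}"
        )

    observed, per_ctx, accounting = cross_classification_rate(
        view,
        contexts=contexts,
        n_selections=config.n_selections,
        rng=np.random.default_rng(obs_ss),
        priors_policy=config.priors_policy,
    )

    null_rates = np.empty(config.n_permutations)
    null_children = null_ss.spawn(config.n_permutations)
    for i in range(config.n_permutations):
        rng_i = np.random.default_rng(null_children[i])
        y_perm = permute_within_subjects(y, subjects, rng_i)
        # eligibility is invariant under within-subject shuffles (per-subject
        # context counts are conserved); assert rather than assume
        assert set(eligible_subjects(y_perm, subjects, contexts)) == eligible_obs
        try:
            r, _, _ = _one_selection_rate(
                X, y_perm, subjects, contexts, rng_i, config.priors_policy, view.variables
            )
        except DegeneracyError:
            logger.error("degenerate fit in permutation %d (seed %s)", i, null_children[i])
            raise
        null_rates[i] = r

    expected = float(null_rates.mean())
    p = float((1 + np.sum(null_rates >= observed - 1e-12)) / (1 + config.n_permutations))
    return PDFAResult(
        observed_rate=observed,
        expected_rate=expected,
        p_value=p,
        per_context_rates=per_ctx,
        accounting=accounting,
        config=config,
        null_rates=null_rates if keep_null else None,
        notes={
            "null_selections_per_permutation": 1,
            "contexts": list(contexts),
        },
    )


def loo_crossvalidated_rates(
    X: np.ndarray,
    y: np.ndarray,
    priors_policy: str = "training-proportions",
    label_order: Sequence[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Leave-one-out cross-validation: each call is classified by a model
    fitted to all other calls.  Returns (per-context rates, overall rate)."""
    X = np.asarray(X, float)
    y = np.asarray(y, object)
    labels = tuple(label_order) if label_order is not None else tuple(dict.fromkeys(y))
    n = len(y)
    correct = np.zeros(n, bool)
    mask = np.ones(n, bool)
    for i in range(n):
        mask[i] = False
        model = fit_lda(X[mask], y[mask], priors_policy, label_order=labels)
        pred, _, _ = classify(model, X[i : i + 1])
        correct[i] = pred[0] == y[i]
        mask[i] = True
    per_ctx = {
        c: float(correct[y == c].mean()) if (y == c).any() else float("nan") for c in labels
    }
    return per_ctx, float(correct.mean())
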