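"""Synthetic hoo-call data with known ground truth.

Two generation paths:

* ``generate_feature_table`` produces a call feature table with the
  statistical structure the downstream analyses assume — a 29-subject
  roster with unbalanced call counts across the rest/travel/alert contexts,
  subject-level random intercepts, context effects on (log) duration,
  (log) maximum F0 and (sqrt) inter-call interval, observer-by-context and
  device-by-context imbalance, and bout structure in which rest hoos are
  almost always single calls.  Default effect sizes are the published
  mixed-model estimates; noise levels are field-plausible choices.

* ``generate_call_bout`` produces actual call bouts — rise–fall F0 contours
  with framewise harmonic spectra and Gamma-distributed silent gaps — and
  returns the exact ground truth for every acoustic variable, so the
  measurement code can be tested against construction.

A single master seed drives everything; all component generators derive
child streams from it deterministically.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acoustics import CallBout, F0Contour, SpectrumSeries, SyntheticCall
from .call_table import CONTEXTS, FeatureMatrix, _validate_row

__all__ = [
    "SyntheticTruth",
    "IdentifiabilityWarning",
    "paper_like_roster",
    "paper_like_truth",
    "null_truth",
    "generate_feature_table",
    "generate_call_bout",
    "generate_confound_scenario",
    "bout_waveform",
    "write_wav",
]


class IdentifiabilityWarning(UserWarning):
    """The fixed-effects design of a generated scenario is rank deficient."""


# ---------------------------------------------------------------------------
# Roster

# (subject, sex, age_class, n_alert, n_rest, n_travel); 29 subjects, 271 calls;
# 11 subjects contribute to all three contexts. Context totals: alert 40,
# rest 137, travel 94.
_ROSTER_ROWS = [
    ("BB", "male", "adult", 0, 2, 0),
    ("FD", "male", "adult", 0, 5, 5),
    ("FK", "male", "subadult", 0, 4, 5),
    ("HT", "female", "adult", 0, 1, 1),
    ("HW", "male", "adult", 7, 5, 0),
    ("JN", "female", "adult", 0, 6, 4),
    ("KA", "female", "subadult", 0, 2, 0),
    ("KL", "female", "adult", 3, 4, 5),
    ("KT", "male", "adult", 5, 9, 5),
    ("KU", "female", "adult", 0, 6, 5),
    ("KW", "female", "adult", 2, 8, 5),
    ("KY", "female", "adult", 0, 2, 2),
    ("KZ", "male", "subadult", 2, 12, 5),
    ("MK", "female", "adult", 0, 2, 0),
    ("ML", "female", "adult", 0, 5, 5),
    ("MS", "male", "adult", 1, 7, 5),
    ("NB", "female", "adult", 1, 7, 5),
    ("NK", "male", "adult", 2, 11, 5),
    ("NR", "female", "subadult", 0, 1, 1),
    ("OK", "female", "adult", 0, 0, 3),
    ("PS", "male", "subadult", 2, 6, 5),
    ("RE", "female", "subadult", 2, 4, 5),
    ("SQ", "male", "adult", 4, 7, 5),
    ("TK", "male", "adult", 0, 2, 1),
    ("VR", "female", "subadult", 0, 2, 0),
    ("ZF", "male", "adult", 7, 5, 0),
    ("ZG", "male", "subadult", 0, 1, 2),
    ("ZL", "male", "subadult", 2, 6, 5),
    ("ZM", "female", "adult", 0, 5, 5),
]

_ADULT_AGES = (16, 18, 20, 22, 25, 28)
_SUBADULT_AGES = (11, 12, 13)


def paper_like_roster() -> pd.DataFrame:
    """The default 29-subject roster with fixed (deterministic) ages."""
    rows = []
    n_adult = n_sub = 0
    for sid, sex, age_class, a, r, t in _ROSTER_ROWS:
        if age_class == "adult":
            age = _ADULT_AGES[n_adult % len(_ADULT_AGES)]
            n_adult += 1
        else:
            age = _SUBADULT_AGES[n_sub % len(_SUBADULT_AGES)]
            n_sub += 1
        rows.append(
            {
                "subject_id": sid,
                "sex": sex,
                "age_class": age_class,
                "age_years": float(age),
                "n_alert": a,
                "n_rest": r,
                "n_travel": t,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth

#: Variables the linear generator operates on, each on its analysis
#: (transformed) scale.
GEN_VARS = ("log_duration", "log_f0max", "sqrt_ici")


def _zero_effects() -> dict[str, float]:
    return {v: 0.0 for v in GEN_VARS}


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a generated call table.

    Continuous variables are Gaussian on the transformed scale (so the
    mixed-model stage's assumptions hold by construction); inter-call gaps
    in bout generation are Gamma distributed (positive, right skewed).
    ``context_means``, effects and SDs are on the transformed scales of
    log duration (s), log maximum F0 (Hz) and sqrt inter-call interval (s).
    """

    roster: pd.DataFrame = field(default_factory=paper_like_roster)
    context_means: dict = field(
        default_factory=lambda: {
            "log_duration": {"alert": -1.55, "rest": -0.92, "travel": -1.83},
            "log_f0max": {"alert": 5.80, "rest": 5.49, "travel": 5.38},
            "sqrt_ici": {"alert": 1.37, "rest": 2.10, "travel": 0.66},
        }
    )
    subject_sd: dict = field(
        default_factory=lambda: {"log_duration": 0.15, "log_f0max": 0.08, "sqrt_ici": 0.07}
    )
    residual_sd: dict = field(
        default_factory=lambda: {"log_duration": 0.35, "log_f0max": 0.15, "sqrt_ici": 0.40}
    )
    #: additive offset for observer TG (reference CC)
    observer_effect: dict = field(
        default_factory=lambda: {"log_duration": -0.24, "log_f0max": -0.13, "sqrt_ici": 0.0}
    )
    #: additive offsets per device (reference 'c', the camera-internal mic)
    device_effect: dict = field(
        default_factory=lambda: {
            "log_duration": {"cs": -0.12, "s": -0.10},
            "log_f0max": {"cs": -0.15, "s": 0.12},
            "sqrt_ici": {},
        }
    )
    #: additive offset for males (reference female)
    sex_effect: dict = field(
        default_factory=lambda: {"log_duration": 0.12, "log_f0max": 0.0, "sqrt_ici": 0.0}
    )
    #: per-year slopes on age
    age_slope: dict = field(default_factory=_zero_effects)
    #: probability that a call of a context is a single (bout of one)
    singles_fraction: dict = field(
        default_factory=lambda: {"rest": 134 / 137, "travel": 15 / 94, "alert": 2 / 40}
    )
    #: in-bout travel/alert calls whose interval could not be measured
    n_unmeasured_intervals: int = 5

    # secondary acoustic structure (raw scales)
    start_offset_mean_hz: float = 30.0
    start_offset_sd_hz: float = 12.0
    drop_sqrt_mean: float = 5.0
    drop_sqrt_sd: float = 3.0
    #: longer calls fall further: sqrt(F0 drop) gains this much per unit of
    #: (log duration - its pooled reference); gives the F0 drop / slope
    #: steepness pair its high correlation without tying drop to context
    drop_duration_coupling: float = 2.6
    drop_duration_reference: float = -1.35
    pos_f0max_logmean: float = float(np.log(0.30))
    pos_f0max_logsd: float = 0.15
    pos_peak_sqrt_mean: float = 0.63
    pos_peak_sqrt_sd: float = 0.08
    harmonic2_prob: float = 0.35
    peak_jitter_sd: float = 0.02

    # observer / device allocation
    rest_cc_prob: float = 0.5
    cc_device_probs: dict = field(default_factory=lambda: {"s": 0.85, "cs": 0.15})
    tg_device_probs: dict = field(default_factory=lambda: {"cs": 0.6, "c": 0.4})
    #: context -> observer probabilities; None = the default observer split
    observer_allocation: dict | None = None

    # bout generation (audio-level path)
    bout_duration_logmean: dict = field(
        default_factory=lambda: {"rest": -0.70, "travel": -1.10, "alert": -1.00}
    )
    bout_duration_logsd: float = 0.18
    bout_f0max_mean_hz: dict = field(
        default_factory=lambda: {"rest": 290.0, "travel": 270.0, "alert": 350.0}
    )
    bout_f0max_logsd: float = 0.08
    gap_mean_s: dict = field(
        default_factory=lambda: {"rest": 4.0, "travel": 0.45, "alert": 1.9}
    )
    gap_gamma_shape: float = 3.0

    seed: int = 0

    def replace(self, **kw) -> "SyntheticTruth":
        return dataclasses.replace(self, **kw)

    def validate(self) -> None:
        for d in (self.subject_sd, self.residual_sd):
            for v, sd in d.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {v}")
        counts = self.roster[["n_alert", "n_rest", "n_travel"]].to_numpy()
        if (counts < 0).any():
            raise ValueError("roster call counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("roster schedules no calls")


def paper_like_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The default study-like preset: Table-1 roster, published effect sizes."""
    return SyntheticTruth(seed=seed, **overrides)


def null_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """Same roster and subject structure but no feature-context association.

    Context means are equalised and the call-level observer/device effects
    are zeroed: observers are allocated by context, so nonzero observer or
    device effects would leak a real context signal into the features even
    with equal context means.  Subject-level structure (random intercepts,
    sex, age) is retained — the within-subject permutation null conserves it.
    """
    means = {
        "log_duration": {c: -1.35 for c in CONTEXTS},
        "log_f0max": {c: 5.60 for c in CONTEXTS},
        "sqrt_ici": {c: 1.0 for c in CONTEXTS},
    }
    zero = {v: 0.0 for v in GEN_VARS}
    defaults = dict(
        context_means=means,
        observer_effect=dict(zero),
        device_effect={v: {} for v in GEN_VARS},
    )
    defaults.update(overrides)
    return SyntheticTruth(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# Feature-table generation


def _choose(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def generate_feature_table(truth: SyntheticTruth) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Generate one call feature table under ``truth``.

    Each generated variable is context mean + subject intercept + observer/
    device/sex/age terms + Gaussian residual on its transformed scale, then
    mapped back to the raw scale and clipped to its domain; derived fields
    (F0 drop, slope, positions) are computed exactly so every call-record
    invariant holds.  Interval presence follows the per-context singles
    fractions, realised as exact counts; a configurable handful of in-bout
    travel/alert intervals is additionally marked unmeasurable.
    """
    truth.validate()
    ss = np.random.SeedSequence(truth.seed)
    rng_subj, rng_call, rng_struct = (np.random.default_rng(s) for s in ss.spawn(3))

    roster = truth.roster.reset_index(drop=True)
    intercepts = {
        row.subject_id: {
            v: rng_subj.normal(0.0, truth.subject_sd[v]) for v in GEN_VARS
        }
        for row in roster.itertuples()
    }

    mean_age = float(roster["age_years"].mean())
    rows: list[dict] = []
    for sub in roster.itertuples():
        for context, n_col in (("alert", "n_alert"), ("rest", "n_rest"), ("travel", "n_travel")):
            for k in range(int(getattr(sub, n_col))):
                if truth.observer_allocation is not None:
                    alloc = truth.observer_allocation[context]
                    observer = (
                        alloc if isinstance(alloc, str) else _choose(rng_call, alloc)
                    )
                elif context == "alert":
                    observer = "CC"
                elif context == "travel":
                    observer = "TG"
                else:
                    observer = "CC" if rng_call.random() < truth.rest_cc_prob else "TG"
                device = _choose(
                    rng_call,
                    truth.cc_device_probs if observer == "CC" else truth.tg_device_probs,
                )

                def lin(var: str) -> float:
                    v = truth.context_means[var][context]
                    v += intercepts[sub.subject_id][var]
                    if observer == "TG":
                        v += truth.observer_effect.get(var, 0.0)
                    v += truth.device_effect.get(var, {}).get(device, 0.0)
                    if sub.sex == "male":
                        v += truth.sex_effect.get(var, 0.0)
                    v += truth.age_slope.get(var, 0.0) * (sub.age_years - mean_age)
                    return v + rng_call.normal(0.0, truth.residual_sd[var])

                z_dur = lin("log_duration")
                duration = float(np.exp(z_dur))
                f0_max = float(np.exp(lin("log_f0max")))
                sqrt_ici = max(lin("sqrt_ici"), 0.2)  # interval value (used if in a bout)

                start_off = abs(rng_call.normal(truth.start_offset_mean_hz, truth.start_offset_sd_hz))
                f0_start = max(f0_max - start_off, 0.2 * f0_max)
                drop_sqrt = (
                    truth.drop_sqrt_mean
                    + truth.drop_duration_coupling * (z_dur - truth.drop_duration_reference)
                    + rng_call.normal(0.0, truth.drop_sqrt_sd)
                )
                drop = float(np.clip(drop_sqrt, 0.0, None) ** 2)
                drop = min(drop, 0.8 * f0_max)
                f0_end = f0_max - drop
                pos_f0max = float(
                    np.clip(
                        np.exp(rng_call.normal(truth.pos_f0max_logmean, truth.pos_f0max_logsd)),
                        0.02,
                        0.95,
                    )
                )
                t_f0max = pos_f0max * duration
                fall = duration - t_f0max
                slope = drop / fall if (drop > 0 and fall > 0) else 0.0
                harmonic = 2 if rng_call.random() < truth.harmonic2_prob else 1
                peak_freq = harmonic * f0_max * (1.0 + rng_call.normal(0.0, truth.peak_jitter_sd))
                pos_peak = float(
                    np.clip(
                        rng_call.normal(truth.pos_peak_sqrt_mean, truth.pos_peak_sqrt_sd) ** 2,
                        0.01,
                        0.99,
                    )
                )
                rows.append(
                    {
                        "call_id": f"{sub.subject_id}-{context}-{k + 1:02d}",
                        "subject_id": sub.subject_id,
                        "sex": sub.sex,
                        "age_years": sub.age_years,
                        "age_class": sub.age_class,
                        "context": context,
                        "observer": observer,
                        "device": device,
                        "bout_id": "",  # assigned below
                        "position_in_bout": 1,
                        "duration_s": duration,
                        "f0_start_hz": f0_start,
                        "f0_end_hz": f0_end,
                        "f0_max_hz": f0_max,
                        "f0_drop_hz": f0_max - f0_end,
                        "slope_steepness_hz_per_s": slope,
                        "peak_freq_hz": peak_freq,
                        "t_f0max_s": t_f0max,
                        "t_peakfreq_s": pos_peak * duration,
                        "pos_f0max": pos_f0max,
                        "pos_peakfreq": pos_peak,
                        "inter_call_interval_s": sqrt_ici**2,
                    }
                )

    df = pd.DataFrame(rows)

    # Bout structure: exact per-context single-call counts; remaining calls
    # are "in bout" and keep a measured interval to the (unmeasured) next
    # call.  Subjects contributing to all three contexts keep at least one
    # in-bout travel and alert call each, so the bout-level analysis retains
    # the same caller set as the three-context analysis.
    counts3 = roster[["n_alert", "n_rest", "n_travel"]].gt(0).all(axis=1)
    eligible3 = set(roster.loc[counts3, "subject_id"])
    protected = np.zeros(len(df), bool)
    for context in ("travel", "alert"):
        for sid in eligible3:
            idx = np.flatnonzero(
                ((df["context"] == context) & (df["subject_id"] == sid)).to_numpy()
            )
            if len(idx):
                protected[idx[0]] = True

    in_bout = np.zeros(len(df), bool)
    for context in CONTEXTS:
        idx = np.flatnonzero((df["context"] == context).to_numpy())
        if len(idx) == 0:
            continue
        frac = truth.singles_fraction.get(context, 1.0)
        n_singles = int(round(frac * len(idx)))
        cand = idx[~protected[idx]]
        n_singles = min(n_singles, len(cand))
        singles = rng_struct.choice(cand, size=n_singles, replace=False)
        mask = np.ones(len(idx), bool)
        mask[np.searchsorted(idx, np.sort(singles))] = False
        in_bout[idx[mask]] = True
    df.loc[~in_bout, "inter_call_interval_s"] = np.nan

    # a handful of in-bout travel/alert intervals are unmeasurable
    cand = np.flatnonzero(
        in_bout & ~protected & df["context"].isin(["travel", "alert"]).to_numpy()
    )
    n_um = min(truth.n_unmeasured_intervals, len(cand))
    if n_um > 0:
        um = rng_struct.choice(cand, size=n_um, replace=False)
        df.loc[um, "inter_call_interval_s"] = np.nan

    # bout ids: pair consecutive in-bout calls within subject x context
    bout_ids = []
    positions = []
    counters: dict[tuple, int] = {}
    open_bout: dict[tuple, tuple[str, int] | None] = {}
    for i, row in df.iterrows():
        key = (row["subject_id"], row["context"])
        if not in_bout[i]:
            counters[key] = counters.get(key, 0) + 1
            bout_ids.append(f"{key[0]}-{key[1]}-b{counters[key]:02d}")
            positions.append(1)
            continue
        cur = open_bout.get(key)
        if cur is None:
            counters[key] = counters.get(key, 0) + 1
            bid = f"{key[0]}-{key[1]}-b{counters[key]:02d}"
            open_bout[key] = (bid, 1)
            bout_ids.append(bid)
            positions.append(1)
        else:
            bid, _ = cur
            open_bout[key] = None
            bout_ids.append(bid)
            positions.append(2)
    df["bout_id"] = bout_ids
    df["position_in_bout"] = positions

    for i, row in df.iterrows():
        _validate_row(row.to_dict(), label=row["call_id"])
    return FeatureMatrix(df), truth


# ---------------------------------------------------------------------------
# Confound scenarios


def generate_confound_scenario(
    imbalance: Mapping[str, object],
    effects: Mapping[str, Mapping] | None,
    truth: SyntheticTruth,
) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Generate a table under a controlled observer-by-context allocation.

    ``imbalance`` maps each used context either to a single observer name or
    to a {observer: probability} mapping.  ``effects`` may carry known
    ``observer`` offsets (variable -> TG offset) and ``context`` means
    (variable -> context -> mean) to inject; anything not given keeps the
    values in ``truth``.  If every context is assigned exclusively to one
    observer the fixed-effects design of context + observer is rank
    deficient and an :class:`IdentifiabilityWarning` is emitted.
    """
    used_contexts = [c for c in CONTEXTS if _roster_context_total(truth.roster, c) > 0]
    for c in used_contexts:
        if c not in imbalance:
            raise ValueError(f"allocation missing context {c!r} which has scheduled calls")
    t = truth.replace(observer_allocation=dict(imbalance))
    if effects:
        if "observer" in effects:
            obs = dict(t.observer_effect)
            obs.update(effects["observer"])
            t = t.replace(observer_effect=obs)
        if "context" in effects:
            means = {k: dict(v) for k, v in t.context_means.items()}
            for var, per_ctx in effects["context"].items():
                means[var].update(per_ctx)
            t = t.replace(context_means=means)
    fm, t = generate_feature_table(t)

    # rank check on the intercept + context + observer dummy design
    rec = fm.records
    cols = [np.ones(len(rec))]
    for c in used_contexts[1:]:
        cols.append((rec["context"] == c).to_numpy(float))
    for o in ("TG",):
        cols.append((rec["observer"] == o).to_numpy(float))
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "observer is confounded with context: the fixed-effects design "
            "of context + observer is rank deficient",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return fm, t


def _roster_context_total(roster: pd.DataFrame, context: str) -> int:
    return int(roster[f"n_{context}"].sum())


# ---------------------------------------------------------------------------
# Bout generation (contours + spectra)


def _rise_fall_contour(
    onset: float,
    duration: float,
    f0_start: float,
    f0_max: float,
    f0_end: float,
    t_peak: float,
    step: float = 0.005,
) -> F0Contour:
    """Piecewise-linear contour: 0.05 s holds at both edges, rise to the peak,
    fall to the end value.  The peak time is included as a sample so the
    contour attains its maximum exactly."""
    hold = 0.05
    knots_t = np.array([0.0, hold, t_peak, duration - hold, duration])
    knots_f = np.array([f0_start, f0_start, f0_max, f0_end, f0_end])
    t = np.arange(0.0, duration, step)
    t = np.unique(np.concatenate([t, [t_peak, duration]]))
    f = np.interp(t, knots_t, knots_f)
    return F0Contour(times_s=onset + t, f0_hz=f)


def _harmonic_spectra(
    contour: F0Contour,
    t_peak_rel: float,
    weights: Sequence[float],
    n_frames: int,
    n_bins: int,
    max_freq_hz: float,
) -> SpectrumSeries:
    """Analytic framewise spectra of a harmonic stack under a Gaussian
    amplitude envelope peaking at ``t_peak_rel`` (seconds from call onset)."""
    t0 = contour.onset_s
    dur = contour.offset_s - t0
    frame_t = t0 + (np.arange(n_frames) + 0.5) * dur / n_frames
    f0 = np.interp(frame_t, contour.times_s, contour.f0_hz)
    freqs = np.linspace(0.0, max_freq_hz, n_bins)
    sigma_f = 25.0
    sigma_t = dur / 6.0
    env = np.exp(-0.5 * ((frame_t - (t0 + t_peak_rel)) / sigma_t) ** 2)
    amp = np.zeros((n_frames, n_bins))
    for k, w in enumerate(weights, start=1):
        amp += w * np.exp(-0.5 * ((freqs[None, :] - k * f0[:, None]) / sigma_f) ** 2)
    amp *= env[:, None]
    intensity = 10.0 * np.log10(np.sum(amp**2, axis=1) + 1e-12)
    return SpectrumSeries(
        frame_times_s=frame_t, freqs_hz=freqs, amplitude=amp, intensity_db=intensity
    )


#: relative harmonic amplitudes (first harmonic strongest by default)
HARMONIC_WEIGHTS = (1.0, 0.45, 0.2)


def generate_call_bout(
    context: str,
    truth: SyntheticTruth,
    rng: np.random.Generator | int | None = None,
    n_frames: int = 1000,
    n_bins: int = 256,
    max_freq_hz: float = 4000.0,
    with_spectra: bool = True,
) -> tuple[CallBout, list[dict]]:
    """Generate one bout of synthetic calls for ``context``.

    Returns the bout (contours, optionally spectra) and a list of per-call
    ground-truth dicts for every acoustic variable (the inter-call interval
    of the last call is NaN).  Bout length follows the per-context singles
    fraction (single with that probability, otherwise 2 + Poisson); gaps are
    Gamma distributed with the per-context mean.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(truth.seed if rng is None else int(rng))

    if rng.random() < truth.singles_fraction.get(context, 0.0):
        n_calls = 1
    else:
        n_calls = 2 + int(rng.poisson(1.0))

    gap_mean = truth.gap_mean_s[context]
    shape = truth.gap_gamma_shape
    calls: list[SyntheticCall] = []
    gtruths: list[dict] = []
    onset = 0.0
    for i in range(n_calls):
        duration = float(
            np.clip(
                np.exp(rng.normal(truth.bout_duration_logmean[context], truth.bout_duration_logsd)),
                0.24,
                None,
            )
        )
        f0_max = float(
            truth.bout_f0max_mean_hz[context] * np.exp(rng.normal(0.0, truth.bout_f0max_logsd))
        )
        f0_start = max(f0_max - abs(rng.normal(truth.start_offset_mean_hz, truth.start_offset_sd_hz)), 60.0)
        drop = float(np.clip(rng.normal(truth.drop_sqrt_mean, truth.drop_sqrt_sd), 0.0, None) ** 2)
        drop = min(drop, f0_max - 60.0)
        f0_end = f0_max - drop
        pos_target = float(
            np.clip(np.exp(rng.normal(truth.pos_f0max_logmean, truth.pos_f0max_logsd)), 0.05, 0.9)
        )
        t_peak = float(np.clip(pos_target * duration, 0.07, duration - 0.07))
        contour = _rise_fall_contour(onset, duration, f0_start, f0_max, f0_end, t_peak)

        h_peak = 2 if rng.random() < truth.harmonic2_prob else 1
        weights = list(HARMONIC_WEIGHTS)
        if h_peak == 2:
            weights[0], weights[1] = weights[1], weights[0]
        pos_pk = float(
            np.clip(rng.normal(truth.pos_peak_sqrt_mean, truth.pos_peak_sqrt_sd) ** 2, 0.1, 0.9)
        )
        t_pkfreq = pos_pk * duration
        spectra = (
            _harmonic_spectra(contour, t_pkfreq, weights, n_frames, n_bins, max_freq_hz)
            if with_spectra
            else None
        )
        f0_at_peak = float(np.interp(onset + t_pkfreq, contour.times_s, contour.f0_hz))
        fall = duration - t_peak
        gtruths.append(
            {
                "duration_s": duration,
                "f0_start_hz": f0_start,
                "f0_end_hz": f0_end,
                "f0_max_hz": f0_max,
                "f0_drop_hz": f0_max - f0_end,
                "slope_steepness_hz_per_s": drop / fall if (drop > 0 and fall > 0) else 0.0,
                "peak_freq_hz": h_peak * f0_at_peak,
                "t_f0max_s": t_peak,
                "t_peakfreq_s": t_pkfreq,
                "pos_f0max": t_peak / duration,
                "pos_peakfreq": pos_pk,
                "inter_call_interval_s": float("nan"),  # set below if a call follows
            }
        )
        calls.append(SyntheticCall(contour=contour, spectra=spectra))
        gap = float(rng.gamma(shape, gap_mean / shape))
        if i < n_calls - 1:
            gtruths[-1]["inter_call_interval_s"] = gap
        onset = onset + duration + gap

    return CallBout(calls=tuple(calls)), gtruths


# ---------------------------------------------------------------------------
# Audio synthesis

SAMPLE_RATE = 44100


def bout_waveform(bout: CallBout, sr: int = SAMPLE_RATE) -> np.ndarray:
    """Render a bout as 16-bit PCM samples: a harmonic stack following each
    call's F0 contour under a smooth amplitude envelope, silence in gaps."""
    total = bout.calls[-1].offset_s + 0.05
    out = np.zeros(int(np.ceil(total * sr)) + 1)
    for call in bout.calls:
        c = call.contour
        t0, t1 = c.onset_s, c.offset_s
        n = int(round((t1 - t0) * sr))
        tt = t0 + np.arange(n) / sr
        f0 = np.interp(tt, c.times_s, c.f0_hz)
        phase = 2 * np.pi * np.cumsum(f0) / sr
        dur = t1 - t0
        env = np.exp(-0.5 * ((tt - t0 - dur / 2) / (dur / 4)) ** 2)
        x = np.zeros(n)
        for k, w in enumerate(HARMONIC_WEIGHTS, start=1):
            x += w * np.sin(k * phase)
        start = int(round(t0 * sr))
        out[start : start + n] += x * env
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out / peak * 0.9
    return (out * 32767).astype(np.int16)


def write_wav(path, samples: np.ndarray, sr: int = SAMPLE_RATE) -> None:
    from scipy.io import wavfile

    wavfile.write(path, sr, np.asarray(samples, np.int16))
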