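"""End-to-end analysis pipeline: read -> transform -> screen -> pDFA1 ->
pDFA2 -> LMMs -> report, driven by one configuration and one seed.

A pipeline run is a pure function of (input, config, seed): the same
configuration and seed produce byte-identical JSON results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import simulate
from .call_table import (
    CANDIDATE_VARIABLES,
    FeatureMatrix,
    TransformSpec,
    apply_transforms,
    read_call_table,
    screen_correlations,
)
from .lmm import LMMSpec, bonferroni_gate, fit_context_lrt
from .pdfa import PDFAConfig, loo_crossvalidated_rates, run_pdfa

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

#: responses tested in the mixed-model stage when the config does not
#: override them: the variables highly influential in the discriminant
#: analysis (|loading| > 1), with the interval model using only sex and age
#: as controls and only the two contexts in which bouts occur.
DEFAULT_LMM_PLAN = (
    {"response": "f0_max_hz", "controls": ("sex", "age_years", "observer", "device"), "contexts": None},
    {"response": "duration_s", "controls": ("sex", "age_years", "observer", "device"), "contexts": None},
    {"response": "inter_call_interval_s", "controls": ("sex", "age_years"), "contexts": ("travel", "alert")},
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    input_csv: str | None = None  # path to a call table; None -> synthetic preset
    preset: str = "paper-like"  # 'paper-like' or 'null'
    transforms: str = "table"  # 'table' or 'positions-untransformed'
    r_threshold: float = 0.7
    vif_threshold: float = 2.0
    n_selections: int = 100
    n_permutations: int = 10_000
    priors_policy: str = "training-proportions"
    lmm_plan: tuple = DEFAULT_LMM_PLAN
    run_loo: bool = True
    seed: int = 0
    out_dir: str = "results"
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "lmm_plan" in raw:
            raw["lmm_plan"] = tuple(
                {
                    "response": p["response"],
                    "controls": tuple(p.get("controls", ("sex", "age_years", "observer", "device"))),
                    "contexts": tuple(p["contexts"]) if p.get("contexts") else None,
                }
                for p in raw["lmm_plan"]
            )
        return cls(**raw)

    def validate(self) -> None:
        if self.transforms not in ("table", "positions-untransformed"):
            raise PipelineError(f"unknown transforms preset {self.transforms!r}")
        if self.preset not in ("paper-like", "null"):
            raise PipelineError(f"unknown synthetic preset {self.preset!r}")
        for p in self.lmm_plan:
            if p["response"] not in CANDIDATE_VARIABLES and p["response"] != "peak_freq_hz":
                raise PipelineError(f"LMM response {p['response']!r} is not a known variable")


def _load_input(config: PipelineConfig) -> FeatureMatrix:
    if config.input_csv:
        logger.info("reading call table from %s", config.input_csv)
        return read_call_table(config.input_csv)
    logger.info("generating synthetic call table (preset=%s, seed=%d)", config.preset, config.seed)
    factory = simulate.paper_like_truth if config.preset == "paper-like" else simulate.null_truth
    fm, _ = simulate.generate_feature_table(factory(seed=config.seed))
    return fm


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the report bundle as a dict.

    Writes ``results.json``, ``report.md`` and ``screening.csv`` into the
    configured output directory.  Stage errors are re-raised as
    :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    config.validate()

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    fm = stage("input", lambda: _load_input(config))

    spec = (
        TransformSpec.table_defaults()
        if config.transforms == "table"
        else TransformSpec.positions_untransformed()
    )
    tfm = stage("transform", lambda: apply_transforms(fm, spec))

    screening = stage(
        "screening",
        lambda: screen_correlations(tfm, config.r_threshold, config.vif_threshold),
    )
    logger.info("screening retained %s (discarded %s)", screening.retained, screening.discarded)

    pdfa1_vars = [v for v in screening.retained if v != "inter_call_interval_s"]
    pdfa2_vars = list(screening.retained)

    def _pdfa(contexts, variables, seed_offset):
        view = tfm.analysis_view(variables=variables, contexts=contexts)
        excluded = len(tfm.analysis_view(variables=pdfa1_vars, contexts=contexts).index) - len(view.index)
        if excluded:
            logger.info(
                "excluding %d call(s) without a measurable inter-call interval", excluded
            )
        cfg = PDFAConfig(
            n_selections=config.n_selections,
            n_permutations=config.n_permutations,
            seed=config.seed + seed_offset,
            priors_policy=config.priors_policy,
            variables=tuple(variables),
        )
        return run_pdfa(view, contexts, cfg)

    pdfa1 = stage("pdfa1", lambda: _pdfa(("rest", "travel", "alert"), pdfa1_vars, 1))
    pdfa2 = stage("pdfa2", lambda: _pdfa(("travel", "alert"), pdfa2_vars, 2))

    loo = None
    if config.run_loo:
        def _loo():
            view = tfm.analysis_view(variables=pdfa1_vars)
            per_ctx, overall = loo_crossvalidated_rates(
                view.X, view.labels, config.priors_policy,
                label_order=("rest", "travel", "alert"),
            )
            return {"per_context": per_ctx, "overall": overall}

        loo = stage("loo", _loo)

    lmm_results = []
    for plan in config.lmm_plan:
        var = plan["response"]
        lspec = LMMSpec(
            response=var,
            control_predictors=tuple(plan["controls"]),
            contexts=plan["contexts"],
        )
        res = stage(f"lmm:{var}", lambda s=lspec: fit_context_lrt(tfm, s))
        lmm_results.append(res)
    gate = bonferroni_gate([r.full_null[2] for r in lmm_results], n_tests=len(lmm_results))

    bundle = {
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
                if k != "lmm_plan"
            },
            "lmm_plan": [
                {
                    "response": p["response"],
                    "controls": list(p["controls"]),
                    "contexts": list(p["contexts"]) if p["contexts"] else None,
                }
                for p in config.lmm_plan
            ],
        },
        "n_calls": len(fm),
        "n_subjects": int(fm.records["subject_id"].nunique()),
        "screening": json.loads(screening.to_json()),
        "pdfa1": pdfa1.to_dict(),
        "pdfa2": pdfa2.to_dict(),
        "loo": loo,
        "lmm": [r.to_dict() for r in lmm_results],
        "bonferroni": {
            "threshold": gate["threshold"],
            "reported_threshold": gate["reported_threshold"],
            "significant": gate["significant"],
        },
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    screening.to_frame().to_csv(out / "screening.csv", index=False)
    (out / "report.md").write_text(_render_report(bundle))
    logger.info("pipeline outputs written to %s", out)
    return bundle


def _render_report(bundle: dict) -> str:
    lines = ["# Hoo-variant analysis report", ""]
    lines.append(f"Calls: {bundle['n_calls']}; subjects: {bundle['n_subjects']}")
    lines.append("")
    lines.append("## Screening")
    lines.append(f"Retained: {', '.join(bundle['screening']['retained'])}")
    lines.append(f"Discarded: {', '.join(bundle['screening']['discarded'])}")
    lines.append("")
    for key, title in (("pdfa1", "pDFA 1 (rest / travel / alert)"), ("pdfa2", "pDFA 2 (travel / alert)")):
        r = bundle[key]
        lines.append(f"## {title}")
        lines.append(
            f"Observed cross-classification: {100 * r['observed_rate']:.1f}% | "
            f"expected under the within-subject permutation null: "
            f"{100 * r['expected_rate']:.1f}% | p = {r['p_value']:.4g}"
        )
        per = ", ".join(f"{c}: {100 * v:.1f}%" for c, v in r["per_context_rates"].items())
        lines.append(f"Per-context rates: {per}")
        a = r["accounting"]
        lines.append(
            f"Calls: {a['n_training']} training from {a['n_eligible_subjects']} subjects, "
            f"{a['n_heldout_same_subjects']} held-out from the same subjects, "
            f"{a['n_novel_subjects_calls']} from {a['n_novel_subjects']} novel subjects."
        )
        lines.append("")
    if bundle.get("loo"):
        per = ", ".join(
            f"{c}: {100 * v:.1f}%" for c, v in bundle["loo"]["per_context"].items()
        )
        lines.append("## Single cross-validated DFA (leave-one-out)")
        lines.append(f"Per-context correct classification: {per}")
        lines.append("")
    lines.append("## Mixed models (context as test predictor)")
    lines.append("")
    lines.append("| response | chi2 (full vs null) | d.f. | p | significant at corrected alpha |")
    lines.append("|---|---|---|---|---|")
    for r, sig in zip(bundle["lmm"], bundle["bonferroni"]["significant"]):
        fn = r["full_null"]
        lines.append(
            f"| {r['response']} | {fn['chi2']:.2f} | {fn['df']} | {fn['p']:.3g} | {sig} |"
        )
    lines.append("")
    lines.append(
        f"Bonferroni-corrected threshold: {bundle['bonferroni']['reported_threshold']}"
    )
    lines.append("")
    for r in bundle["lmm"]:
        lines.append(f"### {r['response']}")
        lines.append("")
        lines.append("| term | estimate | s.e. | t |")
        lines.append("|---|---|---|---|")
        for fe in r["fixed_effects"]:
            lines.append(
                f"| {fe['term']} | {fe['estimate']:.3f} | {fe['se']:.3f} | {fe['t']:.2f} |"
            )
        lines.append("")
    return "\n".join(lines)
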