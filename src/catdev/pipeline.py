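"""End-to-end pipeline: generate/ingest -> calibrate -> screen -> simulate
adaptive tests -> evaluate.

Every stage seed derives deterministically from one master seed, so a rerun
with the same configuration reproduces byte-identical JSON payloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as catio
from .calibration import (EMControls, QuadraturePrior, ResponseMatrix,
                          fit_model, select_model)
from .cat_engine import CATConfig, simulate_cat
from .cat_evaluation import criterion_validity, roc_analysis, summarize_cohort
from .calibration import eap_scores
from .pool_screening import ScreeningConfig, screen_pool
from .synthetic_data import Cohort, CohortSpec, generate_cohort

log = logging.getLogger("catdev.pipeline")

#: stopping rules: label -> SE threshold (None = administer the whole pool)
DEFAULT_RULES = {"0.80": 0.447, "0.85": 0.386, "0.90": 0.316, "none": None}


@dataclass
class PipelineConfig:
    """Configuration of the full development pipeline.

    Threshold defaults are the published cutoffs: loading 0.3, eigenvalue
    ratio 4, variance 20%, |Q3| 0.36, S-X^2 alpha 0.01, acceptable slope band
    [0.5, 2.5], DIF delta-R^2 0.02, SE stopping thresholds
    {0.447, 0.386, 0.316}, maximum test length 50.
    """

    seed: int = 0
    synthetic: dict = field(default_factory=dict)     # CohortSpec overrides
    screening: dict = field(default_factory=dict)     # ScreeningConfig overrides
    rules: dict = field(default_factory=lambda: dict(DEFAULT_RULES))
    max_items: int = 50
    quadrature_points: int = 61
    quadrature_bounds: tuple = (-4.0, 4.0)
    do_model_comparison: bool = False
    do_screening: bool = True
    calibration_split: float = 0.5
    em_max_iter: int = 500
    em_tol: float = 1e-4
    # optional external inputs (synthetic generation used when absent)
    responses_path: str | None = None
    bank_path: str | None = None
    groups_path: str | None = None
    labels_path: str | None = None
    criterion_path: str | None = None

    def __post_init__(self):
        self.quadrature_bounds = tuple(self.quadrature_bounds)
        self.rules = dict(self.rules)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = catio.read_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["quadrature_bounds"] = list(payload["quadrature_bounds"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def prior(self) -> QuadraturePrior:
        return QuadraturePrior.normal(self.quadrature_points,
                                      tuple(self.quadrature_bounds))

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed fan-out from the master seed."""
        return int(np.random.SeedSequence([self.seed, stage]).generate_state(1)[0]
                   % (2 ** 31))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _screening_payload(report):
    return {
        "n_passes": report.n_passes,
        "removals": [{"item_id": i, "step": s} for i, s in report.removals],
        "surviving": report.surviving.item_ids,
        "eigen_ratio": report.unidimensionality.eigen_ratio,
        "variance_prop": report.unidimensionality.variance_prop,
        "loadings": report.unidimensionality.loadings,
        "q3_flagged_pairs": report.q3.flagged_pairs,
        "s_x2": report.s_x2.table.to_dict(orient="records"),
        "discrimination_flags": report.discrimination_flags,
        "dif": (report.dif.table.to_dict(orient="records")
                if report.dif is not None else None),
    }


def _record_payload(rec):
    return {
        "person_id": rec.person_id,
        "administered": rec.administered,
        "responses": rec.responses,
        "theta": rec.final.theta,
        "se": rec.final.se if np.isfinite(rec.final.se) else None,
        "information": rec.final.information,
        "n_items": len(rec.administered),
        "stop_reason": rec.stop_reason,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and write artifacts into ``out_dir``.

    Returns the evaluation payload (also written to ``evaluation.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prior = config.prior()
    controls = EMControls(max_iter=config.em_max_iter, tol=config.em_tol)
    provenance = {"seed": config.seed, "stages": []}

    # stage 0: obtain data -------------------------------------------------
    if config.responses_path:
        responses = catio.read_responses(config.responses_path, config.groups_path)
        bank0 = catio.read_bank(config.bank_path) if config.bank_path else None
        labels = criterion = None
        if config.labels_path:
            _, labels = catio.read_person_column(config.labels_path, "label")
        if config.criterion_path:
            _, criterion = catio.read_person_column(config.criterion_path, "criterion")
        cohort = None
        provenance["stages"].append({"stage": "ingest",
                                     "responses": config.responses_path})
    else:
        spec = CohortSpec(seed=config.stage_seed(0), **config.synthetic)
        cohort = generate_cohort(spec)
        responses, bank0 = cohort.responses, cohort.bank
        labels, criterion = cohort.labels, cohort.criterion
        catio.write_responses(responses, out / "responses.csv",
                              out / "groups.csv")
        catio.write_bank(bank0, out / "true_bank.csv")
        provenance["stages"].append({"stage": "generate",
                                     "seed": spec.seed,
                                     "n_persons": spec.n_persons,
                                     "n_items": responses.n_items})

    # calibration/validation split ----------------------------------------
    n = responses.n_persons
    n_cal = int(round(n * config.calibration_split))
    cal = ResponseMatrix(responses.person_ids[:n_cal],
                         list(responses.item_ids),
                         responses.codes[:n_cal],
                         None if responses.groups is None
                         else responses.groups[:n_cal])
    val = ResponseMatrix(responses.person_ids[n_cal:],
                         list(responses.item_ids),
                         responses.codes[n_cal:],
                         None if responses.groups is None
                         else responses.groups[n_cal:])
    val_idx = slice(n_cal, None)

    # stage 1: model selection / calibration --------------------------------
    if config.do_model_comparison:
        fits = []
        for tag in ("GRM", "GPCM", "PCM", "NRM"):
            log.info("calibrating %s", tag)
            _, f = fit_model(cal, tag, prior, controls, template=bank0)
            fits.append(f)
        sel = select_model(fits)
        _dump({"fits": [{"model": f.model, "minus2LL": f.minus2LL,
                         "AIC": f.AIC, "BIC": f.BIC, "n_params": f.n_params,
                         "converged": f.converged} for f in fits],
               "selected": sel.model, "indices_agree": sel.indices_agree},
              out / "model_selection.json")
        provenance["stages"].append({"stage": "model_selection",
                                     "selected": sel.model})
    bank_cal, fit = fit_model(cal, "GRM", prior, controls, template=bank0)
    provenance["stages"].append({"stage": "calibrate",
                                 "minus2LL": fit.minus2LL,
                                 "converged": fit.converged})

    # stage 2: screening -----------------------------------------------------
    if config.do_screening:
        scfg = ScreeningConfig(**config.screening)
        report = screen_pool(cal, bank_cal, groups=cal.groups, config=scfg,
                             prior=prior, controls=controls)
        final_bank = report.surviving
        _dump(_screening_payload(report), out / "screening.json")
        provenance["stages"].append({"stage": "screen",
                                     "removed": report.removed_ids,
                                     "n_passes": report.n_passes})
    else:
        final_bank = bank_cal
        provenance["stages"].append({"stage": "screen", "skipped": True})
    catio.write_bank(final_bank, out / "bank.csv")

    # stage 3: simulated adaptive tests -------------------------------------
    val_final = val.subset_items(final_bank.item_ids)
    full_thetas = eap_scores(val_final, final_bank, prior)
    evaluation = {"rules": {}, "n_validation": val.n_persons,
                  "n_final_items": len(final_bank)}
    for label, threshold in config.rules.items():
        cfg = CATConfig(se_threshold=threshold,
                        max_items=(len(final_bank) if threshold is None
                                   else config.max_items),
                        seed=config.stage_seed(3), prior=prior)
        records = simulate_cat(val_final, final_bank, cfg)
        _dump([_record_payload(r) for r in records],
              out / f"records_{label.replace('.', '')}.json")
        summary = summarize_cohort(records, full_thetas)
        entry = {
            "se_threshold": threshold,
            "mean_items": summary.mean_items,
            "sd_items": summary.sd_items,
            "mean_se": summary.mean_se,
            "marginal_reliability": summary.marginal_reliability,
            "correlation_with_full": summary.correlation_with_full,
        }
        thetas_rule = np.array([r.final.theta for r in records])
        if criterion is not None:
            r, p = criterion_validity(thetas_rule,
                                      np.asarray(criterion)[val_idx])
            entry["criterion_validity_r"] = r
        if labels is not None and len(set(np.asarray(labels)[val_idx])) == 2:
            roc = roc_analysis(thetas_rule, np.asarray(labels)[val_idx])
            entry["roc"] = {"auc": roc.auc, "sensitivity": roc.sensitivity,
                            "specificity": roc.specificity,
                            "youden": roc.youden, "cutoff": roc.cutoff}
        evaluation["rules"][label] = entry
        provenance["stages"].append({"stage": f"cat_{label}",
                                     "seed": cfg.seed,
                                     "mean_items": summary.mean_items})
    _dump(evaluation, out / "evaluation.json")
    _dump(provenance, out / "run_log.json")
    return evaluation
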