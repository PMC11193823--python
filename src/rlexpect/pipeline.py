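"""End-to-end pipeline: simulate a cohort, fit the hierarchy, evaluate, test.

Configuration is a schema-validated JSON document; every stochastic stage
carries an explicit seed and unknown keys are rejected before any compute.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .behavior import aggregate_behavior
from .cohort import draw_cohort, make_scenario, simulate_cohort, truth_table
from .evaluation import model_accuracy, pointwise_loglik, posterior_predictive, psis_loo
from .hierarchical import HierarchicalRLModel
from .hypotheses import hypothesis_report
from .io import write_json, write_trial_table
from .priors import PriorConfig, SamplerConfig
from .task import TaskDesign, default_design

log = logging.getLogger("rlexpect")


def _check_keys(doc: dict, allowed: set, where: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    seeds: dict  # stage -> seed; simulate/fit/evaluate required
    out_dir: str
    scenario: dict = field(
        default_factory=lambda: {"preset": "inverted_u", "model_id": "SWo", "n_subjects": 30}
    )
    fit: dict = field(default_factory=dict)  # model_id, priors, scale, overrides
    evaluate: dict = field(default_factory=lambda: {"repeats": 20})
    hypotheses: dict = field(default_factory=lambda: {"rope": [-0.1, 0.1]})
    design: dict | None = None

    def __post_init__(self):
        for stage in ("simulate", "fit", "evaluate"):
            if stage not in self.seeds:
                raise ValueError(f"config must provide a seed for the {stage!r} stage")
        _check_keys(self.scenario, {"preset", "model_id", "n_subjects", "sigma", "peak_delta"}, "scenario")
        _check_keys(
            self.fit,
            {"model_id", "priors", "scale", "n_chains", "n_warmup", "n_sampling", "n_subject_refresh"},
            "fit",
        )
        _check_keys(self.evaluate, {"repeats", "loo_thin"}, "evaluate")
        _check_keys(self.hypotheses, {"rope", "parameters"}, "hypotheses")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        _check_keys(
            doc,
            {"seeds", "out_dir", "scenario", "fit", "evaluate", "hypotheses", "design"},
            "run config",
        )
        if "seeds" not in doc or "out_dir" not in doc:
            raise ValueError("run config requires 'seeds' and 'out_dir'")
        return cls(**doc)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def task_design(self) -> TaskDesign:
        if self.design is None:
            return default_design()
        return TaskDesign.from_json(json.dumps(self.design))

    def sampler_config(self) -> SamplerConfig:
        scale = self.fit.get("scale", "test")
        cfg = SamplerConfig.preset(scale, seed=self.seeds["fit"])
        overrides = {
            k: self.fit[k]
            for k in ("n_chains", "n_warmup", "n_sampling", "n_subject_refresh")
            if k in self.fit
        }
        if overrides:
            from dataclasses import replace

            cfg = replace(cfg, **overrides)
        return cfg


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> fit -> evaluate -> hypotheses, writing artifacts.

    Returns the artifact directory; any stage failure raises with a
    stage-tagged log entry.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    design = config.task_design()
    model_id = config.fit.get("model_id", config.scenario.get("model_id", "SWo"))

    try:
        # --- simulate
        t0 = time.perf_counter()
        scen_kwargs = {}
        if "sigma" in config.scenario:
            scen_kwargs["sigma"] = config.scenario["sigma"]
        if "peak_delta" in config.scenario:
            scen_kwargs["peak_delta"] = config.scenario["peak_delta"]
        scenario = make_scenario(
            config.scenario.get("preset", "inverted_u"),
            config.scenario.get("model_id", "SWo"),
            config.scenario.get("n_subjects", 30),
            **scen_kwargs,
        )
        cohort = draw_cohort(scenario, config.seeds["simulate"])
        table = simulate_cohort(cohort, design, seed=config.seeds["simulate"])
        write_trial_table(table, out / "trials.csv")
        truth_table(cohort, scenario.model_id).to_csv(out / "truth.csv", index=False)
        aggregate_behavior(table).to_csv(out / "behavior.csv", index=False)
        log.info("stage=simulate n_subjects=%d wall=%.2fs", len(cohort), time.perf_counter() - t0)

        # --- fit
        t0 = time.perf_counter()
        priors = None
        if "priors" in config.fit:
            priors = PriorConfig.from_variant(config.fit["priors"])
        model = HierarchicalRLModel(table, model_id=model_id, priors=priors, design=design)
        results = model.fit(config=config.sampler_config())
        results.save(str(out / "draws"))
        subject_means = results.subject_means()
        subject_means.to_csv(out / "subject_means.csv", index=False)
        bad = results.diagnostics.get("non_converged", [])
        log.info(
            "stage=fit model=%s retained=%d non_converged=%s wall=%.2fs",
            model_id,
            results.draws.n_retained,
            bad or "none",
            time.perf_counter() - t0,
        )

        # --- evaluate
        t0 = time.perf_counter()
        acc = model_accuracy(table, subject_means, model_id, design=design)
        loglik = pointwise_loglik(
            results.draws, table, model_id, design, thin=config.evaluate.get("loo_thin", 1)
        )
        loo = psis_loo(loglik, n_chains=results.draws.n_chains)
        pred = posterior_predictive(
            table,
            subject_means,
            model_id,
            repeats=config.evaluate.get("repeats", 20),
            seed=config.seeds["evaluate"],
            design=design,
        )
        pred.curve.to_csv(out / "predictive_curve.csv", index=False)
        write_json(
            {
                "model_accuracy": acc,
                "elpd_loo": loo.elpd_loo,
                "looic": loo.looic,
                "loo_se": loo.se,
                "n_high_pareto_k": loo.n_high_k,
            },
            out / "evaluation.json",
        )
        log.info("stage=evaluate accuracy=%.4f looic=%.1f wall=%.2fs", acc, loo.looic, time.perf_counter() - t0)

        # --- hypotheses
        t0 = time.perf_counter()
        rope = tuple(config.hypotheses.get("rope", (-0.1, 0.1)))
        report = hypothesis_report(
            results.draws, params=config.hypotheses.get("parameters"), rope=rope
        )
        write_json(report, out / "hypotheses.json")
        log.info("stage=hypotheses wall=%.2fs", time.perf_counter() - t0)
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
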