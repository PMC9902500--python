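"""End-to-end orchestration: generate/load -> select -> estimate -> model ->
economics -> sensitivity, driven by a single configuration object.

Every stage writes machine-readable outputs (YAML parameters, JSON results,
CSV traces) into the output directory, plus a run manifest recording the
package version, seed, a hash of the configuration and stage timings. Runs
are idempotent for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .economics import compute_icer
from .estimation import compare_arm_event_rates, estimate_params
from .markov import run_markov
from .params import ModelParams, ParamError, load_params, table1_params
from .selection import SelectionConfig, select_cohort
from .sensitivity import default_dsa_ranges, discount_sweep, one_way_dsa, run_psa
from .synthetic import CohortConfig, generate_cohort, read_cohort, write_cohort

log = logging.getLogger("afibcea")


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of input_dir / synthetic applies."""

    outdir: str | Path = "afibcea_run"
    input_dir: str | Path | None = None  # pre-existing cohort CSVs
    synthetic: CohortConfig | None = None  # or generate one
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    params: ModelParams | None = None  # skip estimation and use these
    run_base: bool = True
    run_dsa: bool = False
    run_psa: bool = False
    psa_reps: int = 10_000
    discount_rates: tuple[float, ...] = (0.0, 0.03, 0.07)
    seed: int = 0

    def validate(self) -> None:
        if self.input_dir is not None and self.synthetic is not None:
            raise ParamError("provide input_dir or a synthetic config, not both")

    def digest(self) -> str:
        blob = json.dumps(
            {
                "input_dir": str(self.input_dir),
                "synthetic": self.synthetic.to_dict() if self.synthetic else None,
                "selection": self.selection.__dict__,
                "params": self.params.to_dict() if self.params else None,
                "stages": [self.run_base, self.run_dsa, self.run_psa],
                "psa_reps": self.psa_reps,
                "discount_rates": list(self.discount_rates),
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return (and write) the run manifest.

    Any stage failure removes partial outputs and re-raises with the stage
    name attached.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": {},
    }
    stage = "setup"
    try:
        params = config.params
        if config.input_dir is not None or config.synthetic is not None:
            t0 = time.perf_counter()
            if config.synthetic is not None:
                stage = "simulate"
                log.info("[simulate] generating synthetic cohort")
                cohort_cfg = config.synthetic
                patients, events, disp = generate_cohort(cohort_cfg)
                write_cohort(outdir / "cohort", patients, events, disp, cohort_cfg)
            else:
                stage = "load"
                log.info("[load] reading cohort from %s", config.input_dir)
                patients, events, disp = read_cohort(config.input_dir)
            manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                         "n_patients": len(patients)}

            stage = "select"
            t0 = time.perf_counter()
            log.info("[select] applying inclusion/exclusion cascade")
            abl, aad, report = select_cohort(patients, events, disp, config.selection)
            report.save(outdir / "selection_report.json")
            abl.to_csv(outdir / "arm_ablation.csv", index=False)
            aad.to_csv(outdir / "arm_aads.csv", index=False)
            manifest["stages"]["select"] = {
                "seconds": time.perf_counter() - t0,
                **report.to_dict(),
            }

            if params is None:
                stage = "estimate"
                t0 = time.perf_counter()
                log.info("[estimate] deriving model parameters from records")
                params = estimate_params(abl, aad, events)
                manifest["stages"]["estimate"] = {"seconds": time.perf_counter() - t0}
        if params is None:
            params = table1_params()
        params.save(outdir / "model_params.yaml")

        if config.run_base:
            stage = "run"
            t0 = time.perf_counter()
            log.info("[run] base-case two-arm Markov model")
            results = {arm: run_markov(arm, params) for arm in ("ablation", "aads")}
            ce = compute_icer(results["ablation"], results["aads"], params.wtp)
            for arm, res in results.items():
                res.trace.to_csv(outdir / f"trace_{arm}.csv")
            base = {
                "ablation": results["ablation"].summary(),
                "aads": results["aads"].summary(),
                **ce.to_dict(),
                "verdict": ce.verdict(),
            }
            (outdir / "base_case.json").write_text(json.dumps(base, indent=2))
            compare_arm_event_rates(params).to_csv(
                outdir / "arm_rate_tests.csv", index=False
            )
            manifest["stages"]["run"] = {"seconds": time.perf_counter() - t0, **base}

        if config.run_dsa:
            stage = "dsa"
            t0 = time.perf_counter()
            log.info("[dsa] one-way tornado + discount sweep")
            tornado = one_way_dsa(params, default_dsa_ranges(params))
            tornado.to_csv(outdir / "tornado.csv", index=False)
            sweep = discount_sweep(params, config.discount_rates)
            (outdir / "discount_sweep.json").write_text(
                json.dumps({str(k): v for k, v in sweep.items()}, indent=2)
            )
            manifest["stages"]["dsa"] = {
                "seconds": time.perf_counter() - t0,
                "top_parameter": tornado.iloc[0]["parameter"],
                "discount_sweep": {str(k): v for k, v in sweep.items()},
            }

        if config.run_psa:
            stage = "psa"
            t0 = time.perf_counter()
            log.info("[psa] %d Monte-Carlo replicates", config.psa_reps)
            psa = run_psa(params, n_reps=config.psa_reps, seed=config.seed)
            psa.replicates.to_csv(outdir / "psa_replicates.csv", index=False)
            pd.Series(psa.ceac).rename_axis("wtp").rename("p_cost_effective").to_csv(
                outdir / "ceac.csv"
            )
            (outdir / "psa_summary.json").write_text(json.dumps(psa.to_dict(), indent=2))
            manifest["stages"]["psa"] = {
                "seconds": time.perf_counter() - t0,
                "quadrants": psa.quadrants,
                "ceac_at_wtp": psa.ceac.get(float(params.wtp)),
            }

        stage = "manifest"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest
    except Exception as exc:
        log.error("[%s] stage failed: %s — removing partial outputs", stage, exc)
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
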