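"""End-to-end orchestration: simulate -> cohort -> cases -> controls ->
exposure -> matched analysis.

Two entry points: :func:`run_study` runs the analysis stages in memory on
a bundle (the form tests and simulation experiments use), and
:func:`run_pipeline` is the file-based variant behind the CLI, writing
each stage's output plus a manifest that records configuration, seeds
and output hashes so a run is reproducible byte for byte.

All randomness flows from one root seed: the simulator consumes
``seed`` and the control sampler a fixed offset substream, so stages are
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from .bundle import ClaimsBundle, default_paths, read_claims_bundle, write_claims_bundle
from .clr import ClrFit, ExposureSummary, summarize_exposure_table
from .cohort import ExclusionReport, build_cohort
from .exposure import classify_matched_sets
from .matching import MatchingCriteria, SamplingLog, sample_all_controls
from .outcomes import identify_cases
from .simulate import SimulationConfig, simulate_bundle

#: Offset separating the sampler's substream from the simulator's.
_SAMPLER_SEED_OFFSET = 7919


class RunConfig(BaseModel):
    """Configuration of a full pipeline run (YAML-loadable)."""

    seed: int = 0
    lookback_days: int = 90
    gap_days: int = 180
    grace_days: int = 180
    charlson_max: int | None = Field(default=None)
    matching: dict = {}
    simulation: dict | None = None  # None = read claims from input_dir
    input_dir: str | None = None

    def matching_criteria(self) -> MatchingCriteria:
        kwargs = dict(self.matching)
        kwargs.setdefault("seed", (self.seed + _SAMPLER_SEED_OFFSET) % (2**31))
        return MatchingCriteria(**kwargs)


@dataclass
class StudyResult:
    """Everything the analysis stages produce for one bundle."""

    cohort: pd.DataFrame
    exclusion_report: ExclusionReport
    cases: pd.DataFrame
    matched_sets: pd.DataFrame  # classified long frame
    sampling_log: SamplingLog
    exposure_table: ExposureSummary | None

    @property
    def fit(self) -> ClrFit | None:
        return self.exposure_table.fit if self.exposure_table is not None else None


def run_study(
    bundle: ClaimsBundle,
    lookback_days: int = 90,
    gap_days: int = 180,
    grace_days: int = 180,
    charlson_max: int | None = None,
    criteria: MatchingCriteria | None = None,
) -> StudyResult:
    """Run cohort construction through matched analysis on a bundle."""
    cohort, report = build_cohort(
        bundle,
        lookback_days=lookback_days,
        gap_days=gap_days,
        grace_days=grace_days,
        charlson_max=charlson_max,
    )
    cases = identify_cases(cohort, bundle)
    sets, log = sample_all_controls(cases, cohort, bundle, criteria)
    sets = classify_matched_sets(sets, bundle)
    exposure_table = summarize_exposure_table(sets) if len(sets) else None
    return StudyResult(
        cohort=cohort,
        exclusion_report=report,
        cases=cases,
        matched_sets=sets,
        sampling_log=log,
        exposure_table=exposure_table,
    )


def run_replicate(
    seed: int,
    n_patients: int = 50_000,
    true_or_continuous: float = 0.65,
    true_or_irregular: float = 2.57,
    charlson_max: int | None = None,
    **sim_overrides,
) -> tuple[StudyResult, pd.DataFrame]:
    """One simulation replicate: generate a bundle and analyse it.

    Returns the study result and the generator's ground truth; the
    replicate is fully determined by ``seed``.
    """
    cfg = SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        true_or_continuous=true_or_continuous,
        true_or_irregular=true_or_irregular,
        **sim_overrides,
    )
    bundle, truth = simulate_bundle(cfg)
    criteria = MatchingCriteria(seed=(seed + _SAMPLER_SEED_OFFSET) % (2**31))
    result = run_study(bundle, charlson_max=charlson_max, criteria=criteria)
    return result, truth


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """File-based pipeline run; returns the run directory.

    Writes the claims tables (when simulating), ground_truth.csv,
    cohort.csv, exclusions.csv, cases.csv, matched_sets.csv, exposure_table.csv,
    fit.json, report.txt and manifest.json. Re-running with an identical
    config reproduces identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
        bundle, truth = simulate_bundle(sim_cfg)
        write_claims_bundle(bundle, default_paths(out))
        truth.to_csv(out / "ground_truth.csv", index=False)
    elif config.input_dir:
        bundle = read_claims_bundle(default_paths(config.input_dir))
    else:
        raise ValueError("RunConfig needs either simulation settings or input_dir")

    result = run_study(
        bundle,
        lookback_days=config.lookback_days,
        gap_days=config.gap_days,
        grace_days=config.grace_days,
        charlson_max=config.charlson_max,
        criteria=config.matching_criteria(),
    )

    result.cohort.to_csv(out / "cohort.csv", index=False)
    with open(out / "exclusions.csv", "w") as fh:
        fh.write("criterion,count\n")
        for k in sorted(result.exclusion_report.counts):
            fh.write(f"{k},{result.exclusion_report.counts[k]}\n")
        fh.write(f"retained,{result.exclusion_report.n_retained}\n")
    result.cases.to_csv(out / "cases.csv", index=False)
    result.matched_sets.to_csv(out / "matched_sets.csv", index=False)

    if result.exposure_table is not None:
        result.exposure_table.frame.to_csv(out / "exposure_table.csv", index=False)
        (out / "report.txt").write_text(result.exposure_table.report() + "\n")
        fit = result.exposure_table.fit
        if fit is not None:
            fit_payload = {
                "terms": list(fit.term_names),
                "log_or": [None if pd.isna(v) else v for v in fit.beta],
                "or": [None if pd.isna(v) else v for v in fit.or_estimates],
                "ci_95": [
                    [None if pd.isna(v) else v for v in row] for row in fit.wald_ci_95()
                ],
                "loglik": fit.loglik,
                "n_strata_used": fit.n_strata_used,
                "n_strata_dropped": fit.n_strata_dropped,
                "converged": fit.converged,
                "iterations": fit.iterations,
            }
            (out / "fit.json").write_text(json.dumps(fit_payload, indent=2) + "\n")

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "n_cases": int(len(result.cases)),
        "n_matched_sets": int(result.sampling_log.n_matched),
        "n_dropped_cases": len(result.sampling_log.dropped),
        "outputs": {
            p.name: _file_hash(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
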