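"""End-to-end orchestration: simulate/ingest -> cohort -> score -> validate.

Produces cohort.csv, scores.csv, report.json, figures and a run manifest
(config, seed, package version, input checksums). Fully deterministic for a
fixed seed and input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort import build_cohort, write_cohort
from .ehr import read_bundle, write_bundle
from .scoring import ScoreConfig, Windows, load_neq_factors, score_cohort, write_scores
from .simulate import SimParams, simulate_bundle
from .stats import EvalReport, run_validation, write_report

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]

_ALL_VARIANTS = ("original", "M2", "M3")


@dataclass
class RunConfig:
    """Settings for one end-to-end run (CLI flags mirror these fields)."""

    input_dir: str | None = None
    simulate: bool = False
    n_patients: int = 1000
    seed: int = 0
    output_dir: str = "cvsofa_out"
    variants: tuple[str, ...] = _ALL_VARIANTS
    pairing: str = "or"
    neq_aggregation: str = "sum"
    map_threshold: float = 70.0
    strict_hypotension: bool = True
    min_infusion_hours: float = 1.0
    neq_table: str | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        bad = set(self.variants) - set(_ALL_VARIANTS)
        if bad:
            raise ValueError(f"unknown variants: {sorted(bad)}")
        if not (self.simulate or self.input_dir):
            raise ValueError("either input_dir or simulate must be set")

    def score_config(self) -> ScoreConfig:
        factors = (
            load_neq_factors(self.neq_table) if self.neq_table else None
        )
        kwargs = dict(
            windows=Windows(min_infusion_hours=self.min_infusion_hours),
            neq_aggregation=self.neq_aggregation,
            map_threshold=self.map_threshold,
            strict_hypotension=self.strict_hypotension,
        )
        if factors is not None:
            kwargs["neq_factors"] = factors
        return ScoreConfig(**kwargs)

    def score_names(self) -> list[str]:
        names = []
        for v in ("original", "M2", "M3"):
            if v in self.variants:
                names.append(f"cv_{v.lower()}")
        names += [f"total_{v.lower()}" for v in self.variants if f"cv_{v.lower()}" in names]
        return names


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> EvalReport:
    """Execute the full study pipeline; returns the validation report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        log.info("stage simulate: n=%d seed=%d", config.n_patients, config.seed)
        params = SimParams(n_patients=config.n_patients, seed=config.seed)
        bundle, truth = simulate_bundle(params)
        input_dir = outdir / "bundle"
        write_bundle(bundle, input_dir)
        truth.to_csv(outdir / "truth.csv", index=False)
    else:
        input_dir = Path(config.input_dir)
        log.info("stage ingest: %s", input_dir)
        bundle = read_bundle(input_dir)

    log.info("stage cohort")
    cohort = build_cohort(bundle, pairing=config.pairing)
    write_cohort(cohort, outdir / "cohort.csv")

    log.info("stage score")
    scores = score_cohort(bundle, cohort, config.score_config())
    write_scores(scores, outdir / "scores.csv")

    log.info("stage validate")
    death = bundle.stays.set_index("stay_id")["hospital_death"]
    outcomes = scores["stay_id"].map(death).astype(int).to_numpy()
    report = run_validation(scores, outcomes, config.score_names())
    write_report(report, outdir)

    if config.make_plots:
        from .plots import make_figures

        make_figures(report, scores, outcomes, outdir)

    manifest = {
        "package": "cvsofa",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {
            p.name: _sha256(p) for p in sorted(Path(input_dir).glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("done: %s", outdir)
    return report
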