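"""Pipeline orchestration: config, stage seeding, outputs, provenance.

A run takes a kinetic model (the builtin surrogate or any SBML file), an
expression table, a gene->reaction map, one control subject and one or more
case subjects.  It computes Vmax ranges per subject, runs one ensemble per
subject with a stage seed derived deterministically from the master seed,
and writes per-case summary and comparison CSVs plus a JSON provenance
record.  Identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import __version__
from .compare import compare, comparison_frame
from .ensemble import EnsembleConfig, EnsembleSummary, run_ensemble
from .expression import (
    ExpressionMatrix,
    GeneEnzymeMap,
    VmaxRange,
    ranges_to_frame,
    vmax_ranges,
)
from .model import KineticModel, build_default_gsh_model, load_model


class PipelineError(Exception):
    """A stage failure, carrying the stage name and offending entity."""


@dataclass
class RunConfig:
    """Full pipeline configuration (mirrors the CLI flags)."""

    model: str = "builtin"  # "builtin" or path to an SBML file
    expression: str = ""  # path to a TSV/CSV expression table
    gene_map: str = ""  # path to a two-column gene->reaction TSV
    control: str = "H0002"
    cases: List[str] = field(default_factory=lambda: ["H0007", "H0008"])
    n_samples: int = 10_000
    seed: int = 0
    out_dir: str = "out"
    proportionality: float = 1.0

    def validate(self) -> None:
        if self.control in self.cases:
            raise PipelineError(
                f"config: control {self.control!r} also listed as a case"
            )
        for label, path in (("model", self.model), ("expression", self.expression),
                            ("gene map", self.gene_map)):
            if label == "model" and path == "builtin":
                continue
            if path and not os.path.exists(path):
                raise PipelineError(f"config: {label} path {path!r} does not exist")

    def to_dict(self) -> Dict[str, object]:
        return {
            "model": self.model,
            "expression": self.expression,
            "gene_map": self.gene_map,
            "control": self.control,
            "cases": list(self.cases),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "proportionality": self.proportionality,
        }


def stage_seed(master_seed: int, stage: str, case: str = "") -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{case}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunResult:
    summaries: Dict[str, EnsembleSummary]
    ranges: Dict[str, List[VmaxRange]]
    comparisons: Dict[str, object]
    run_record: Dict[str, object]


def run_pipeline(
    config: RunConfig,
    expression: Optional[ExpressionMatrix] = None,
    gene_map: Optional[GeneEnzymeMap] = None,
    model: Optional[KineticModel] = None,
    write_outputs: bool = True,
) -> RunResult:
    """Execute the full pipeline described by ``config``.

    In-memory objects may be passed directly (overriding the config paths),
    which is how the synthetic scenario and the tests drive the pipeline.
    """
    config.validate()
    try:
        if model is None:
            model = (build_default_gsh_model() if config.model == "builtin"
                     else load_model(config.model))
    except Exception as exc:
        raise PipelineError(f"stage 'model': {exc}") from exc
    try:
        if expression is None:
            expression = ExpressionMatrix.from_tsv(config.expression)
    except Exception as exc:
        raise PipelineError(
            f"stage 'expression': {config.expression!r}: {exc}") from exc
    try:
        if gene_map is None:
            gene_map = GeneEnzymeMap.from_tsv(config.gene_map)
        gene_map.validate_against(model)
    except Exception as exc:
        raise PipelineError(f"stage 'gene_map': {exc}") from exc

    subjects = [config.control] + list(config.cases)
    ranges: Dict[str, List[VmaxRange]] = {}
    summaries: Dict[str, EnsembleSummary] = {}
    for subject in subjects:
        try:
            ranges[subject] = vmax_ranges(
                expression, gene_map, model, subject, config.control,
                proportionality=config.proportionality,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'vmax_ranges' ({subject}): {exc}") from exc
        try:
            summaries[subject] = run_ensemble(
                model,
                ranges[subject],
                EnsembleConfig(
                    n_samples=config.n_samples,
                    seed=stage_seed(config.seed, "ensemble", subject),
                ),
                condition=subject,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'ensemble' ({subject}): {exc}") from exc

    comparisons: Dict[str, object] = {}
    for case in config.cases:
        try:
            comparisons[case] = compare(
                summaries[case], summaries[config.control],
                ranges[case], ranges[config.control],
            )
        except Exception as exc:
            raise PipelineError(f"stage 'compare' ({case}): {exc}") from exc

    run_record = {
        "config": config.to_dict(),
        "package_version": __version__,
        "model_hash": model.content_hash(),
        "stage_seeds": {
            s: stage_seed(config.seed, "ensemble", s) for s in subjects
        },
        "n_converged": {s: summaries[s].n_converged for s in subjects},
    }
    result = RunResult(summaries=summaries, ranges=ranges,
                       comparisons=comparisons, run_record=run_record)
    if write_outputs:
        _write_outputs(config, result)
    return result


def _write_outputs(config: RunConfig, result: RunResult) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    for subject, summary in result.summaries.items():
        sub_dir = os.path.join(config.out_dir, subject)
        os.makedirs(sub_dir, exist_ok=True)
        import pandas as pd

        frame = pd.concat(
            [
                summary.flux_frame().rename(columns={"reaction_id": "id"}).assign(
                    kind="flux"),
                summary.conc_frame().rename(columns={"species_id": "id"}).assign(
                    kind="concentration"),
            ],
            ignore_index=True,
        )[["kind", "id", "mean", "sd", "n"]]
        frame.to_csv(os.path.join(sub_dir, "summary.csv"), index=False)
        ranges_to_frame(result.ranges[subject]).to_csv(
            os.path.join(sub_dir, "vmax_ranges.csv"), index=False
        )
    for case, (comps, conc_ratios) in result.comparisons.items():
        comparison_frame(comps, conc_ratios).to_csv(
            os.path.join(config.out_dir, case, "comparison.csv"), index=False
        )
    with open(os.path.join(config.out_dir, "run.json"), "w") as fh:
        json.dump(result.run_record, fh, indent=2, sort_keys=True)
        fh.write("\n")
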