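"""Synthetic expression data and toy kinetic fixtures with known ground truth.

The expression generator emulates normalized bead-summary microarray
intensities for a small subject panel — by default one control and two
patients with two replicate hybridizations each, mirroring the study design
the pipeline is built for.  Each intensity is

    base_intensity * fold_change[subject, gene] * exp(eps),
    eps ~ Normal(0, sigma),  sigma = sqrt(log(1 + noise_cv**2))

so the multiplicative coefficient of variation equals ``noise_cv`` exactly
and intensities stay strictly positive.  It emulates residual post-
normalization noise only: no probe effects, background, or batch structure.

The toy fixtures have closed-form steady states (documented per fixture)
used as independent oracles for the solver, the ensemble engine, and the
end-to-end fold-change recovery check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import math

import numpy as np
import pandas as pd

from .compare import compare
from .ensemble import EnsembleConfig, run_ensemble
from .expression import ExpressionMatrix, GeneEnzymeMap, vmax_ranges
from .model import (
    IRREVERSIBLE_MM,
    MASS_ACTION,
    KineticModel,
    RateLaw,
    ReactionDef,
    SpeciesState,
    build_default_gsh_model,
)


@dataclass
class SyntheticSpec:
    """Specification of a synthetic expression matrix.

    ``fold_changes[subject][gene]`` multiplies the base intensity; the
    control subject's entries must all be 1 (its replicates differ only by
    noise).  ``noise_cv`` defaults to 0.05, a typical residual replicate CV
    for normalized bead-summary intensities.
    """

    genes: List[str]
    subjects: List[str]
    control_subject: str
    replicates_per_subject: int = 2
    fold_changes: Dict[str, Dict[str, float]] = field(default_factory=dict)
    noise_cv: float = 0.05
    base_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_subject not in self.subjects:
            raise ValueError("control subject must be listed in subjects")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        for gene, f in self.fold_changes.get(self.control_subject, {}).items():
            if f != 1.0:
                raise ValueError(
                    f"control fold change for {gene!r} must be 1, got {f}"
                )


def gen_expression(spec: SyntheticSpec) -> ExpressionMatrix:
    """Deterministically generate the expression matrix described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2))
    columns, data = [], []
    for subject in spec.subjects:
        fc = spec.fold_changes.get(subject, {})
        for rep in range(1, spec.replicates_per_subject + 1):
            columns.append(f"{subject}_{rep}")
            noise = rng.normal(0.0, sigma, size=len(spec.genes)) if sigma > 0 else (
                np.zeros(len(spec.genes))
            )
            col = [
                spec.base_intensity * fc.get(gene, 1.0) * math.exp(e)
                for gene, e in zip(spec.genes, noise)
            ]
            data.append(col)
    df = pd.DataFrame(np.array(data).T, index=spec.genes, columns=columns)
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Toy fixtures with closed-form steady states
# ---------------------------------------------------------------------------


def chain_model(k1: float = 1.0, vmax: float = 4.0, km: float = 2.0) -> KineticModel:
    """Constant input feeding one intermediate drained by irreversible MM.

    Closed form (requires vmax > k1):  flux = k1,  S* = km*k1/(vmax - k1).
    The steady flux is set entirely by the input — the drain enzyme's Vmax
    moves the intermediate concentration, not the flux.
    """
    species = [
        SpeciesState("SRC", "source", 1.0, is_boundary=True),
        SpeciesState("S", "intermediate", 0.1),
        SpeciesState("OUT", "sink", 0.0, is_boundary=True),
    ]
    reactions = [
        ReactionDef(
            "vin", "constant input",
            stoichiometry={"SRC": -1, "S": 1},
            rate_law=RateLaw(MASS_ACTION, k=k1, substrate_refs=[],
                             product_refs=["S"]),
        ),
        ReactionDef(
            "vdrain", "MM drain",
            gene_symbols=["DRAIN1"],
            stoichiometry={"S": -1, "OUT": 1},
            rate_law=RateLaw(IRREVERSIBLE_MM, vmax=vmax, km_substrate={"S": km},
                             substrate_refs=["S"], product_refs=["OUT"]),
        ),
    ]
    return KineticModel(species, reactions, name="chain_fixture")


def chain_steady_conc(k1: float, vmax: float, km: float) -> float:
    """Closed-form intermediate concentration of the chain fixture."""
    if vmax <= k1:
        raise ValueError("no steady state: vmax must exceed the input rate")
    return km * k1 / (vmax - k1)


def branch_model(k1: float = 1.0, v1: float = 2.0, v2: float = 3.0,
                 km: float = 0.5) -> KineticModel:
    """Constant input split between two MM drains sharing one Km.

    With equal Km both drains see the same saturation factor, so the split
    is exactly Vmax-weighted:  J_i = Vi * k1 / (v1 + v2), and
    S* = km*k1/(v1 + v2 - k1) (requires v1 + v2 > k1).
    """
    species = [
        SpeciesState("SRC", "source", 1.0, is_boundary=True),
        SpeciesState("S", "branch point", 0.1),
        SpeciesState("OUT1", "sink 1", 0.0, is_boundary=True),
        SpeciesState("OUT2", "sink 2", 0.0, is_boundary=True),
    ]
    reactions = [
        ReactionDef(
            "vin", "constant input",
            stoichiometry={"SRC": -1, "S": 1},
            rate_law=RateLaw(MASS_ACTION, k=k1, substrate_refs=[],
                             product_refs=["S"]),
        ),
        ReactionDef(
            "vb1", "branch 1",
            stoichiometry={"S": -1, "OUT1": 1},
            rate_law=RateLaw(IRREVERSIBLE_MM, vmax=v1, km_substrate={"S": km},
                             substrate_refs=["S"], product_refs=["OUT1"]),
        ),
        ReactionDef(
            "vb2", "branch 2",
            stoichiometry={"S": -1, "OUT2": 1},
            rate_law=RateLaw(IRREVERSIBLE_MM, vmax=v2, km_substrate={"S": km},
                             substrate_refs=["S"], product_refs=["OUT2"]),
        ),
    ]
    return KineticModel(species, reactions, name="branch_fixture")


def redox_model(total: float = 3.0, v_ox: float = 1.0, km_ox: float = 2.0,
                v_red: float = 2.0, km_red: float = 0.1) -> KineticModel:
    """Closed GSH/GSSG-like redox couple with a conserved moiety.

    2 RED -> OX (peroxidase-like) and OX -> 2 RED (reductase-like); the
    total RED + 2*OX is conserved at its initial value (``total`` with the
    default start RED = total, OX = 0... the constructor splits it as
    RED = total - 2*ox0 with ox0 = total/6).  Steady state solves
    v_ox*RED/(km_ox+RED) = v_red*OX/(km_red+OX) under the conservation
    constraint.
    """
    ox0 = total / 6.0
    species = [
        SpeciesState("RED", "reduced form", total - 2 * ox0, moiety_id="redox"),
        SpeciesState("OX", "oxidized form", ox0, moiety_id="redox"),
    ]
    reactions = [
        ReactionDef(
            "vox", "oxidation",
            stoichiometry={"RED": -2, "OX": 1},
            rate_law=RateLaw(IRREVERSIBLE_MM, vmax=v_ox, km_substrate={"RED": km_ox},
                             substrate_refs=["RED"], product_refs=["OX"]),
        ),
        ReactionDef(
            "vred", "reduction",
            stoichiometry={"OX": -1, "RED": 2},
            rate_law=RateLaw(IRREVERSIBLE_MM, vmax=v_red, km_substrate={"OX": km_red},
                             substrate_refs=["OX"], product_refs=["RED"]),
        ),
    ]
    return KineticModel(species, reactions, name="redox_fixture")


def supply_model(s0: float = 1.0, v_in: float = 1.0, km_in: float = 1.0,
                 v_drain: float = 10.0, km_drain: float = 1.0) -> KineticModel:
    """Boundary-fed MM input with a high-capacity MM drain.

    The input enzyme works at fixed substrate concentration ``s0``, so the
    chain flux is exactly proportional to its Vmax:

        J = v_in * s0 / (km_in + s0)

    (requires v_drain > J).  Scaling ``v_in`` by f scales the flux by f —
    the flux-follows-Vmax counterpart to the input-limited chain fixture.
    """
    species = [
        SpeciesState("SRC", "clamped substrate", s0, is_boundary=True),
        SpeciesState("S", "intermediate", 0.1),
        SpeciesState("OUT", "sink", 0.0, is_boundary=True),
    ]
    reactions = [
        ReactionDef(
            "vin", "MM input",
            gene_symbols=["SUPPLY1"],
            stoichiometry={"SRC": -1, "S": 1},
            rate_law=RateLaw(IRREVERSIBLE_MM, vmax=v_in, km_substrate={"SRC": km_in},
                             substrate_refs=["SRC"], product_refs=["S"]),
        ),
        ReactionDef(
            "vdrain", "MM drain",
            stoichiometry={"S": -1, "OUT": 1},
            rate_law=RateLaw(IRREVERSIBLE_MM, vmax=v_drain,
                             km_substrate={"S": km_drain},
                             substrate_refs=["S"], product_refs=["OUT"]),
        ),
    ]
    return KineticModel(species, reactions, name="supply_fixture")


def gen_toy_models() -> Dict[str, KineticModel]:
    """Named fixture set at reference parameters (fresh instances)."""
    return {
        "chain": chain_model(),
        "branch": branch_model(),
        "redox": redox_model(),
        "supply": supply_model(),
    }


# ---------------------------------------------------------------------------
# Study-shaped scenario
# ---------------------------------------------------------------------------

#: Programmed per-subject fold changes emulating the reported expression
#: contrasts: patient H0008 with 5-oxoprolinase up 1.86x and glutathione
#: synthetase up 1.26x; patient H0007 with DNA methyltransferase down 2.33x
#: and glutathione synthetase down 1.2x; both with modest peroxidase
#: up-regulation (1.3x, a representative value for an up-regulated GPX4).
STUDY_FOLD_CHANGES: Dict[str, Dict[str, float]] = {
    "H0007": {"DNMT1": 1 / 2.33, "GSS": 1 / 1.2, "GPX4": 1.3},
    "H0008": {"OPLAH": 1.86, "GSS": 1.26, "GPX4": 1.3},
}

STUDY_GENE_MAP: Dict[str, List[str]] = {
    "DNMT1": ["v11"],
    "GSS": ["vGS"],
    "GCLC": ["vGCS"],
    "OPLAH": ["v27"],
    "GPX4": ["vGPX"],
    "GSR": ["vGR"],
    "GSTA4": ["vGST"],
    "GSTM1": ["vGST"],
    "GSTM2": ["vGST"],
    "GSTT1": ["vGST"],
}


def study_scenario_spec(seed: int = 0, noise_cv: float = 0.05) -> SyntheticSpec:
    """Synthetic three-subject panel shaped like the study design."""
    genes = sorted(STUDY_GENE_MAP)
    return SyntheticSpec(
        genes=genes,
        subjects=["H0002", "H0007", "H0008"],
        control_subject="H0002",
        replicates_per_subject=2,
        fold_changes=STUDY_FOLD_CHANGES,
        noise_cv=noise_cv,
        seed=seed,
    )


def study_gene_map() -> GeneEnzymeMap:
    """Gene -> surrogate-model reaction map for the study scenario."""
    return GeneEnzymeMap({g: list(r) for g, r in STUDY_GENE_MAP.items()})


# ---------------------------------------------------------------------------
# End-to-end recovery
# ---------------------------------------------------------------------------


def end_to_end_recovery(
    spec: SyntheticSpec,
    model: KineticModel,
    gene_map: GeneEnzymeMap,
    case_subject: str,
    n_samples: int = 2000,
    seed: int = 1,
) -> Dict[str, object]:
    """Run the whole pipeline on synthetic data and report recovered ratios.

    Generates the expression matrix, derives Vmax ranges for the case and
    the control, runs both ensembles, and compares them.  Returns a dict
    with the comparison list, concentration ratios, and both summaries.
    """
    expr = gen_expression(spec)
    control = spec.control_subject
    case_ranges = vmax_ranges(expr, gene_map, model, case_subject, control)
    ctrl_ranges = vmax_ranges(expr, gene_map, model, control, control)
    case_summary = run_ensemble(
        model, case_ranges, EnsembleConfig(n_samples=n_samples, seed=seed),
        condition=case_subject,
    )
    ctrl_summary = run_ensemble(
        model, ctrl_ranges, EnsembleConfig(n_samples=n_samples, seed=seed + 1),
        condition=control,
    )
    comparisons, conc_ratios = compare(case_summary, ctrl_summary,
                                       case_ranges, ctrl_ranges)
    return {
        "comparisons": comparisons,
        "conc_ratios": conc_ratios,
        "case_summary": case_summary,
        "control_summary": ctrl_summary,
        "case_ranges": case_ranges,
        "control_ranges": ctrl_ranges,
    }


def default_gsh_scenario_model() -> KineticModel:
    """Convenience: the surrogate glutathione model used by the scenario."""
    return build_default_gsh_model()
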