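"""Patient-vs-control comparison of ensemble summaries.

For each reaction the case/control ratio of mean fluxes is set against the
ratio of the sampled Vmax ranges (midpoints), quantifying how far the flux
follows the transcript-driven change in enzyme capacity:

    agreement = log(flux_ratio) - log(vmax_ratio)

Zero means the flux tracks the Vmax change one-to-one; negative values mean
the pathway absorbs the capacity change (e.g. a supply-limited flux that
stays put while the enzyme is up-regulated).  The "effect" flag marks
reactions whose mean fluxes differ by more than the sum of the two ensemble
SDs — a separation heuristic over the parameter-uncertainty distributions,
not a statistical test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .ensemble import EnsembleSummary
from .expression import VmaxRange


class ComparisonError(Exception):
    """Raised for incompatible summaries (different underlying models)."""


@dataclass
class ConditionComparison:
    """Per-reaction case-vs-control record."""

    reaction_id: str
    flux_mean_case: float
    flux_sd_case: float
    flux_mean_control: float
    flux_sd_control: float
    flux_ratio: float
    vmax_ratio: float
    agreement: float
    effect: bool


def compare(
    case: EnsembleSummary,
    control: EnsembleSummary,
    case_ranges: Sequence[VmaxRange],
    control_ranges: Sequence[VmaxRange],
) -> Tuple[List[ConditionComparison], Dict[str, float]]:
    """Compare two ensembles reaction-by-reaction (plus concentration ratios).

    Both summaries must come from the same model (hashes are checked).
    Returns the comparison list in model reaction order and a species ->
    concentration-ratio dict.
    """
    if case.model_hash != control.model_hash:
        raise ComparisonError(
            f"model hash mismatch: case {case.model_hash} vs control "
            f"{control.model_hash}"
        )
    case_mid = {r.reaction_id: r.midpoint for r in case_ranges}
    ctrl_mid = {r.reaction_id: r.midpoint for r in control_ranges}
    out: List[ConditionComparison] = []
    for rid in case.flux_mean:
        mc, sc = case.flux_mean[rid], case.flux_sd[rid]
        m0, s0 = control.flux_mean[rid], control.flux_sd[rid]
        flux_ratio = mc / m0 if m0 != 0 else math.nan
        vmax_ratio = (
            case_mid[rid] / ctrl_mid[rid]
            if rid in case_mid and rid in ctrl_mid and ctrl_mid[rid] != 0
            else 1.0
        )
        agreement = (
            math.log(flux_ratio) - math.log(vmax_ratio)
            if flux_ratio > 0 and vmax_ratio > 0
            else math.nan
        )
        out.append(
            ConditionComparison(
                reaction_id=rid,
                flux_mean_case=mc,
                flux_sd_case=sc,
                flux_mean_control=m0,
                flux_sd_control=s0,
                flux_ratio=flux_ratio,
                vmax_ratio=vmax_ratio,
                agreement=agreement,
                effect=abs(mc - m0) > (sc + s0),
            )
        )
    conc_ratios = {
        sid: (case.conc_mean[sid] / control.conc_mean[sid]
              if control.conc_mean[sid] != 0 else math.nan)
        for sid in case.conc_mean
    }
    return out, conc_ratios


def flux_vmax_agreement_table(
    comparisons: Sequence[ConditionComparison],
) -> pd.DataFrame:
    """Reactions ordered by |agreement| descending (ties by reaction id).

    The top rows are the reactions whose flux least follows the imposed
    Vmax change — the cases where transcript ratios alone would mispredict
    the pathway response.
    """
    if not comparisons:
        raise ComparisonError("empty comparison list")
    ordered = sorted(
        comparisons,
        key=lambda c: (-(abs(c.agreement) if not math.isnan(c.agreement) else -1.0),
                       c.reaction_id),
    )
    return pd.DataFrame(
        {
            "reaction_id": [c.reaction_id for c in ordered],
            "vmax_ratio": [c.vmax_ratio for c in ordered],
            "flux_ratio": [c.flux_ratio for c in ordered],
            "agreement": [c.agreement for c in ordered],
        }
    )


def comparison_frame(
    comparisons: Sequence[ConditionComparison],
    conc_ratios: Dict[str, float],
) -> pd.DataFrame:
    """Full comparison table (one row per reaction, then one per species)."""
    rows = [
        {
            "kind": "flux",
            "id": c.reaction_id,
            "mean_case": c.flux_mean_case,
            "sd_case": c.flux_sd_case,
            "mean_control": c.flux_mean_control,
            "sd_control": c.flux_sd_control,
            "ratio": c.flux_ratio,
            "vmax_ratio": c.vmax_ratio,
            "agreement": c.agreement,
            "effect": c.effect,
        }
        for c in comparisons
    ]
    rows += [
        {"kind": "concentration", "id": sid, "ratio": ratio}
        for sid, ratio in conc_ratios.items()
    ]
    return pd.DataFrame(rows)
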