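"""Mapping replicate expression intensities to per-reaction Vmax ranges.

The analysis assumes a change in mRNA abundance translates one-to-one into
a change in the enzyme's maximal rate.  For each mapped reaction and each
replicate hybridization of a subject, a Vmax is computed as

    Vmax[replicate] = Vmax_ref * (intensity[replicate] / mean control intensity)

and the replicate values are collapsed to a [min, max] range that the
ensemble engine samples from.  The control subject itself gets a range from
the spread of its own replicates, so control ensembles carry replicate
uncertainty too.  Intensities are assumed already normalized (bead-summary
scale); preprocessing is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .model import IRREVERSIBLE_MM, REVERSIBLE_MM, KineticModel


class ExpressionError(Exception):
    """Lookup or domain error in expression data handling."""


class ExpressionMatrix:
    """Gene x sample table of normalized intensities, grouped by subject.

    Columns are named ``<subject>_<replicate>`` (e.g. ``H0007_1``); the
    index holds gene symbols.  All intensities must be strictly positive.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        if df.empty:
            raise ExpressionError("empty expression table")
        parsed = []
        for col in df.columns:
            subject, _, rep = str(col).rpartition("_")
            if not subject or not rep.isdigit():
                raise ExpressionError(
                    f"column {col!r} is not of the form <subject>_<replicate>"
                )
            parsed.append((subject, int(rep)))
        if (df.to_numpy() <= 0).any():
            raise ExpressionError("intensities must be > 0 (normalized scale)")
        self.df = df.astype(float)
        self._columns_by_subject: Dict[str, List[str]] = {}
        for col, (subject, _rep) in zip(df.columns, parsed):
            self._columns_by_subject.setdefault(subject, []).append(col)

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(df)

    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t")

    @property
    def subjects(self) -> List[str]:
        return list(self._columns_by_subject)

    @property
    def genes(self) -> List[str]:
        return list(self.df.index)

    def replicate_count(self, subject: str) -> int:
        return len(self._subject_columns(subject))

    def _subject_columns(self, subject: str) -> List[str]:
        try:
            return self._columns_by_subject[subject]
        except KeyError:
            raise ExpressionError(f"unknown subject {subject!r}") from None

    def intensities(self, gene: str, subject: str) -> np.ndarray:
        """Replicate intensities of one gene for one subject, column order."""
        if gene not in self.df.index:
            raise ExpressionError(f"unknown gene {gene!r}")
        return self.df.loc[gene, self._subject_columns(subject)].to_numpy(dtype=float)


@dataclass
class GeneEnzymeMap:
    """Gene symbol -> list of reaction ids catalyzed by the encoded enzyme."""

    entries: Dict[str, List[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str) -> "GeneEnzymeMap":
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         names=["gene", "reaction_id"], comment="#")
        entries: Dict[str, List[str]] = {}
        for gene, rid in zip(df["gene"], df["reaction_id"]):
            entries.setdefault(str(gene), []).append(str(rid))
        return cls(entries)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for gene, rids in self.entries.items():
                for rid in rids:
                    fh.write(f"{gene}\t{rid}\n")

    def validate_against(self, model: KineticModel) -> None:
        rids = set(model.reaction_ids)
        for gene, mapped in self.entries.items():
            for rid in mapped:
                if rid not in rids:
                    raise ExpressionError(
                        f"gene {gene!r} maps to reaction {rid!r} absent from the model"
                    )

    def reactions_to_genes(self) -> Dict[str, List[str]]:
        inv: Dict[str, List[str]] = {}
        for gene, rids in self.entries.items():
            for rid in rids:
                inv.setdefault(rid, []).append(gene)
        return inv


@dataclass
class VmaxRange:
    """Per-reaction, per-subject interval of maximal rates (mM/h)."""

    reaction_id: str
    condition: str
    per_replicate_vmax: List[float]
    low: float = field(init=False)
    high: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_replicate_vmax:
            raise ExpressionError(f"reaction {self.reaction_id!r}: empty Vmax list")
        self.low = float(min(self.per_replicate_vmax))
        self.high = float(max(self.per_replicate_vmax))
        if self.low <= 0:
            raise ExpressionError(
                f"reaction {self.reaction_id!r}: non-positive Vmax in range"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


def fold_change(expr: ExpressionMatrix, gene: str, case_subject: str,
                control_subject: str):
    """Expression ratio of ``case_subject`` over ``control_subject``.

    Returns ``(ratio, per_replicate)`` where ``ratio`` is the mean of the
    case replicates over the mean of the control replicates and
    ``per_replicate`` divides each case replicate by the control mean.
    """
    case = expr.intensities(gene, case_subject)
    control = expr.intensities(gene, control_subject)
    control_mean = float(control.mean())
    per_replicate = case / control_mean
    return float(case.mean()) / control_mean, per_replicate.tolist()


def vmax_ranges(
    expr: ExpressionMatrix,
    gene_map: GeneEnzymeMap,
    model: KineticModel,
    subject: str,
    control_subject: str,
    proportionality: float = 1.0,
    reference_vmax: Optional[Dict[str, float]] = None,
) -> List[VmaxRange]:
    """Per-reaction Vmax ranges for ``subject`` relative to the control.

    For every Michaelis-Menten reaction with mapped genes, each replicate's
    expression ratio against the control mean scales the reference Vmax;
    several genes mapping to one lumped reaction are combined by geometric
    mean.  ``proportionality`` is the exponent on the mRNA ratio (1 is the
    one-to-one assumption; 0 switches expression scaling off).  Reactions
    without mapped genes keep a degenerate range at the reference value.
    """
    gene_map.validate_against(model)
    by_reaction = gene_map.reactions_to_genes()
    refs = reference_vmax if reference_vmax is not None else model.reference_vmax()
    ranges: List[VmaxRange] = []
    for r in model.reactions:
        if r.rate_law.form not in (IRREVERSIBLE_MM, REVERSIBLE_MM):
            if r.reaction_id in by_reaction:
                raise ExpressionError(
                    f"reaction {r.reaction_id!r} has no Vmax (mass action) but is "
                    f"mapped from genes {by_reaction[r.reaction_id]}"
                )
            continue
        ref = refs[r.reaction_id]
        genes = [g for g in by_reaction.get(r.reaction_id, []) if g in expr.df.index]
        if not genes:
            ranges.append(VmaxRange(r.reaction_id, subject, [ref]))
            continue
        ratio_rows = []
        for gene in genes:
            _, per_rep = fold_change(expr, gene, subject, control_subject)
            ratio_rows.append(per_rep)
        lengths = {len(row) for row in ratio_rows}
        if len(lengths) != 1:
            raise ExpressionError(
                f"reaction {r.reaction_id!r}: genes {genes} have unequal replicate counts"
            )
        combined = np.exp(np.mean(np.log(np.asarray(ratio_rows)), axis=0))
        per_rep_vmax = (ref * combined ** proportionality).tolist()
        ranges.append(VmaxRange(r.reaction_id, subject, per_rep_vmax))
    return ranges


def ranges_to_frame(ranges: Iterable[VmaxRange]) -> pd.DataFrame:
    """Tabulate ranges (reaction, condition, low, high, replicates)."""
    rows = [
        {
            "reaction_id": r.reaction_id,
            "condition": r.condition,
            "low": r.low,
            "high": r.high,
            "per_replicate_vmax": ";".join(f"{v:.10g}" for v in r.per_replicate_vmax),
        }
        for r in ranges
    ]
    return pd.DataFrame(rows)
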