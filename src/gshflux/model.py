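"""Kinetic model representation for the glutathione network.

The central object is :class:`KineticModel`: a list of species (dynamic or
boundary/clamped), a list of reactions with explicit rate laws, and the
stoichiometric matrix N derived from them.  Three rate-law forms cover the
network: irreversible Michaelis-Menten (one saturation term per substrate),
a single-substrate/single-product reversible Michaelis-Menten with an
equilibrium constant, and mass action (including zeroth-order constant
inputs).  Units are fixed at mM for concentrations and hours for time, so
fluxes are mM/h; SBML unit definitions are not converted.

Models are exchanged as SBML Level 3 Version 1 (Level 2 is read too).  The
surrogate glutathione network built by :func:`build_default_gsh_model`
covers the four sub-pathways of hepatic glutathione metabolism: the
methionine cycle, glutathione synthesis, detoxification (peroxidase,
reductase and GST conjugation), and the gamma-glutamyl salvage cycle with
5-oxoprolinase.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import libsbml
import numpy as np

MASS_ACTION = "mass_action"
IRREVERSIBLE_MM = "irreversible_MM"
REVERSIBLE_MM = "reversible_MM"

#: local-parameter id patterns under which a maximal rate is recognised in
#: arbitrary SBML; "{rid}" is replaced by the reaction id.
DEFAULT_VMAX_PATTERNS = ("Vmax", "Vmax_{rid}", "V{rid}", "Vf")


class ModelError(Exception):
    """Base class for model construction and exchange errors."""


class ModelParseError(ModelError):
    """Raised when an SBML document cannot be read; names the element."""


class UnsupportedModelError(ModelError):
    """Raised for structurally valid SBML outside the supported rate-law forms."""


@dataclass
class SpeciesState:
    """A metabolite: id, display name, concentration (mM) and boundary flag.

    Boundary species have clamped concentrations: they appear in rate laws
    but their time derivative is identically zero.  ``moiety_id`` is an
    optional label for a conserved pool the species belongs to (e.g. the
    GSH/GSSG redox couple); conservation itself is detected from the
    stoichiometry, the label is documentation.
    """

    species_id: str
    name: str = ""
    concentration: float = 0.0
    is_boundary: bool = False
    moiety_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ModelError(
                f"species {self.species_id!r}: concentration must be >= 0"
            )


@dataclass
class RateLaw:
    """Kinetic rate law of one of the three supported forms.

    For Michaelis-Menten forms ``vmax`` is the maximal rate in mM/h and
    ``km_substrate``/``km_product`` map species ids to Michaelis constants
    in mM.  The reversible form is restricted to one substrate and one
    product and reads

        v = (Vmax/Kms) * (S - P/Keq) / (1 + S/Kms + P/Kmp)

    so the net rate vanishes exactly when the mass-action ratio P/S equals
    Keq.  Mass action uses ``k`` (h^-1 per concentration order) with rate
    k * prod(substrates); an empty substrate list gives a constant input.
    """

    form: str
    vmax: Optional[float] = None
    km_substrate: Dict[str, float] = field(default_factory=dict)
    km_product: Dict[str, float] = field(default_factory=dict)
    keq: Optional[float] = None
    k: Optional[float] = None
    substrate_refs: List[str] = field(default_factory=list)
    product_refs: List[str] = field(default_factory=list)
    modifier_refs: List[str] = field(default_factory=list)

    def validate(self, reaction_id: str) -> None:
        if self.form not in (MASS_ACTION, IRREVERSIBLE_MM, REVERSIBLE_MM):
            raise ModelError(f"reaction {reaction_id!r}: unknown rate-law form {self.form!r}")
        if self.form == MASS_ACTION:
            if self.k is None or self.k < 0:
                raise ModelError(f"reaction {reaction_id!r}: mass action requires k >= 0")
            return
        if self.vmax is None or self.vmax < 0:
            raise ModelError(f"reaction {reaction_id!r}: Vmax must be >= 0")
        for sid, km in {**self.km_substrate, **self.km_product}.items():
            if km <= 0:
                raise ModelError(f"reaction {reaction_id!r}: Km for {sid!r} must be > 0")
        if self.form == IRREVERSIBLE_MM:
            if not self.substrate_refs:
                raise ModelError(f"reaction {reaction_id!r}: irreversible MM needs a substrate")
            for sid in self.substrate_refs:
                if sid not in self.km_substrate:
                    raise ModelError(f"reaction {reaction_id!r}: missing Km for substrate {sid!r}")
        if self.form == REVERSIBLE_MM:
            if len(self.substrate_refs) != 1 or len(self.product_refs) != 1:
                raise ModelError(
                    f"reaction {reaction_id!r}: reversible MM supports exactly one "
                    "substrate and one product"
                )
            if self.keq is None or self.keq <= 0:
                raise ModelError(f"reaction {reaction_id!r}: reversible MM requires Keq > 0")
            s, p = self.substrate_refs[0], self.product_refs[0]
            if s not in self.km_substrate or p not in self.km_product:
                raise ModelError(f"reaction {reaction_id!r}: missing Km for {s!r} or {p!r}")


@dataclass
class ReactionDef:
    """A reaction: id, name, optional gene symbols, stoichiometry, rate law.

    ``stoichiometry`` maps species id to a signed coefficient (negative for
    consumption).  ``gene_symbols`` lists the genes encoding the enzyme; the
    expression-to-Vmax mapping uses a separate gene->reaction table, so this
    field is informational.
    """

    reaction_id: str
    name: str = ""
    gene_symbols: List[str] = field(default_factory=list)
    stoichiometry: Dict[str, int] = field(default_factory=dict)
    rate_law: RateLaw = field(default_factory=lambda: RateLaw(MASS_ACTION, k=0.0))

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.reaction_id!r}: empty stoichiometry")
        self.rate_law.validate(self.reaction_id)

    @property
    def vmax(self) -> Optional[float]:
        return self.rate_law.vmax


class KineticModel:
    """Species + reactions + stoichiometric matrix of a kinetic network."""

    def __init__(
        self,
        species: Sequence[SpeciesState],
        reactions: Sequence[ReactionDef],
        name: str = "model",
        version: str = "",
        provenance: str = "",
    ) -> None:
        self.species: List[SpeciesState] = list(species)
        self.reactions: List[ReactionDef] = list(reactions)
        self.name = name
        self.version = version
        self.provenance = provenance
        self._species_index = {s.species_id: i for i, s in enumerate(self.species)}
        self._reaction_index = {r.reaction_id: i for i, r in enumerate(self.reactions)}
        self._evaluator: Optional[_RateEvaluator] = None
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if len(self._species_index) != len(self.species):
            raise ModelError("duplicate species ids")
        if len(self._reaction_index) != len(self.reactions):
            raise ModelError("duplicate reaction ids")
        for r in self.reactions:
            r.validate()
            refs = set(r.stoichiometry) | set(r.rate_law.substrate_refs)
            refs |= set(r.rate_law.product_refs) | set(r.rate_law.modifier_refs)
            for sid in refs:
                if sid not in self._species_index:
                    raise ModelError(
                        f"reaction {r.reaction_id!r} references undeclared species {sid!r}"
                    )

    @property
    def species_ids(self) -> List[str]:
        return [s.species_id for s in self.species]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.reaction_id for r in self.reactions]

    @property
    def dynamic_index(self) -> np.ndarray:
        """Indices of non-boundary species, in declaration order."""
        return np.array(
            [i for i, s in enumerate(self.species) if not s.is_boundary], dtype=int
        )

    def species_idx(self, sid: str) -> int:
        try:
            return self._species_index[sid]
        except KeyError:
            raise ModelError(f"unknown species {sid!r}") from None

    def reaction(self, rid: str) -> ReactionDef:
        try:
            return self.reactions[self._reaction_index[rid]]
        except KeyError:
            raise ModelError(f"unknown reaction {rid!r}") from None

    @property
    def stoich_matrix(self) -> np.ndarray:
        """Signed species x reactions matrix (all species, boundary included)."""
        n = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.stoichiometry.items():
                n[self._species_index[sid], j] = coeff
        return n

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.concentration for s in self.species], dtype=float)

    def reference_vmax(self) -> Dict[str, float]:
        """Vmax of every Michaelis-Menten reaction at reference parameters."""
        return {
            r.reaction_id: r.rate_law.vmax
            for r in self.reactions
            if r.rate_law.form in (IRREVERSIBLE_MM, REVERSIBLE_MM)
        }

    def content_hash(self) -> str:
        """Stable hash of the serialized model, for provenance checks."""
        return hashlib.sha256(save_model(self).encode()).hexdigest()[:16]

    # -- evaluation --------------------------------------------------------

    def _get_evaluator(self) -> "_RateEvaluator":
        if self._evaluator is None:
            self._evaluator = _RateEvaluator(self)
        return self._evaluator

    def vmax_vector(self, override: Optional[Dict[str, float]] = None) -> np.ndarray:
        """Per-reaction Vmax vector (NaN for mass-action entries)."""
        v = np.array(
            [
                r.rate_law.vmax if r.rate_law.vmax is not None else np.nan
                for r in self.reactions
            ]
        )
        if override:
            for rid, val in override.items():
                j = self._reaction_index.get(rid)
                if j is None:
                    raise ModelError(f"Vmax override for unknown reaction {rid!r}")
                if self.reactions[j].rate_law.form == MASS_ACTION:
                    raise ModelError(
                        f"reaction {rid!r} is mass action and has no Vmax to override"
                    )
                v[j] = val
        return v


def evaluate_rates(
    model: KineticModel,
    conc: np.ndarray,
    vmax_override: Optional[Dict[str, float]] = None,
) -> np.ndarray:
    """Reaction rates (mM/h) at the given full concentration vector.

    ``conc`` follows the model's species ordering and must be non-negative.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (len(model.species),):
        raise ModelError(
            f"concentration vector has shape {conc.shape}, expected ({len(model.species)},)"
        )
    if np.any(conc < 0):
        bad = model.species_ids[int(np.argmin(conc))]
        raise ModelError(f"negative concentration for species {bad!r}")
    ev = model._get_evaluator()
    return ev.rates(conc, model.vmax_vector(vmax_override))


def ode_rhs(
    model: KineticModel,
    conc: np.ndarray,
    vmax_override: Optional[Dict[str, float]] = None,
) -> np.ndarray:
    """Time derivative N.v with boundary-species rows forced to zero."""
    rates = evaluate_rates(model, conc, vmax_override)
    ev = model._get_evaluator()
    dx = ev.stoich @ rates
    dx[ev.boundary_index] = 0.0
    return dx


class _RateEvaluator:
    """Rate-law evaluation compiled to flat scalar programs.

    The steady-state solver calls the right-hand side tens of thousands of
    times per ensemble; a per-reaction list of (form, indices, constants)
    tuples with plain-float arithmetic is an order of magnitude faster than
    re-walking the dataclasses.
    """

    def __init__(self, model: KineticModel) -> None:
        self.stoich = model.stoich_matrix
        self.boundary_index = np.array(
            [i for i, s in enumerate(model.species) if s.is_boundary], dtype=int
        )
        self.programs = []
        for r in model.reactions:
            law = r.rate_law
            if law.form == MASS_ACTION:
                idx = tuple(model.species_idx(s) for s in law.substrate_refs)
                self.programs.append(("ma", law.k, idx))
            elif law.form == IRREVERSIBLE_MM:
                terms = tuple(
                    (model.species_idx(s), law.km_substrate[s]) for s in law.substrate_refs
                )
                self.programs.append(("imm", terms))
            else:
                s, p = law.substrate_refs[0], law.product_refs[0]
                self.programs.append(
                    (
                        "rmm",
                        model.species_idx(s),
                        law.km_substrate[s],
                        model.species_idx(p),
                        law.km_product[p],
                        law.keq,
                    )
                )

    def rates(self, conc: np.ndarray, vmax: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.programs))
        c = conc
        for j, prog in enumerate(self.programs):
            tag = prog[0]
            if tag == "imm":
                v = vmax[j]
                for i, km in prog[1]:
                    ci = c[i]
                    v *= ci / (km + ci)
                out[j] = v
            elif tag == "ma":
                v = prog[1]
                for i in prog[2]:
                    v *= c[i]
                out[j] = v
            else:
                _, si, kms, pi, kmp, keq = prog
                s, p = c[si], c[pi]
                out[j] = vmax[j] / kms * (s - p / keq) / (1.0 + s / kms + p / kmp)
        return out


# ---------------------------------------------------------------------------
# SBML exchange
# ---------------------------------------------------------------------------


def save_model(model: KineticModel, path: Optional[str] = None) -> str:
    """Serialize to SBML Level 3 Version 1; optionally write to ``path``.

    Empty models (no reactions) are rejected rather than emitting a
    degenerate document.
    """
    if not model.reactions:
        raise ModelError("refusing to serialize a model with no reactions")
    doc = libsbml.SBMLDocument(3, 1)
    sbml = doc.createModel()
    sbml.setId(_sanitize_id(model.name))
    sbml.setName(model.name)
    comp = sbml.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)
    comp.setSpatialDimensions(3)
    for s in model.species:
        sp = sbml.createSpecies()
        sp.setId(s.species_id)
        sp.setName(s.name or s.species_id)
        sp.setCompartment("cell")
        sp.setInitialConcentration(s.concentration)
        sp.setBoundaryCondition(bool(s.is_boundary))
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
    for r in model.reactions:
        rx = sbml.createReaction()
        rx.setId(r.reaction_id)
        rx.setName(r.name or r.reaction_id)
        rx.setReversible(r.rate_law.form == REVERSIBLE_MM)
        rx.setFast(False)
        for sid, coeff in sorted(r.stoichiometry.items()):
            if coeff < 0:
                ref = rx.createReactant()
            else:
                ref = rx.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        for sid in r.rate_law.modifier_refs:
            mod = rx.createModifier()
            mod.setSpecies(sid)
        law = rx.createKineticLaw()
        formula, params = _formula_for(r.rate_law)
        for pid, value in params:
            lp = law.createLocalParameter()
            lp.setId(pid)
            lp.setValue(value)
        ast = libsbml.parseL3Formula(formula)
        if ast is None:  # pragma: no cover - formulas are built internally
            raise ModelError(f"could not build kinetic law for {r.reaction_id!r}")
        law.setMath(ast)
    out = libsbml.writeSBMLToString(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out)
    return out


def _sanitize_id(name: str) -> str:
    sid = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in name)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "m_" + sid
    return sid


def _formula_for(law: RateLaw):
    """Kinetic-law formula string plus local (id, value) parameter pairs."""
    if law.form == MASS_ACTION:
        parts = ["k"] + list(law.substrate_refs)
        return " * ".join(parts), [("k", float(law.k))]
    if law.form == IRREVERSIBLE_MM:
        params = [("Vmax", float(law.vmax))]
        terms = []
        for sid in law.substrate_refs:
            params.append((f"Km_{sid}", float(law.km_substrate[sid])))
            terms.append(f"({sid} / (Km_{sid} + {sid}))")
        return " * ".join(["Vmax"] + terms), params
    s, p = law.substrate_refs[0], law.product_refs[0]
    params = [
        ("Vmax", float(law.vmax)),
        (f"Km_{s}", float(law.km_substrate[s])),
        (f"Km_{p}", float(law.km_product[p])),
        ("Keq", float(law.keq)),
    ]
    formula = (
        f"Vmax / Km_{s} * ({s} - {p} / Keq) / (1 + {s} / Km_{s} + {p} / Km_{p})"
    )
    return formula, params


def load_model(
    document: str,
    vmax_patterns: Sequence[str] = DEFAULT_VMAX_PATTERNS,
) -> KineticModel:
    """Read a kinetic model from SBML content or a file path.

    Supports Level 2 and Level 3 documents whose kinetic laws carry local
    parameters in one of the three supported forms; the maximal-rate
    parameter is located by the configurable ``vmax_patterns`` (``{rid}``
    expands to the reaction id).  Reactions without a kinetic law raise
    :class:`UnsupportedModelError`.
    """
    if document.lstrip().startswith("<"):
        doc = libsbml.readSBMLFromString(document)
    else:
        doc = libsbml.readSBMLFromFile(document)
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelParseError(
                    f"SBML error at line {err.getLine()}: {err.getMessage().strip()}"
                )
    sbml = doc.getModel()
    if sbml is None:
        raise ModelParseError("document contains no <model> element")

    species = []
    declared = set()
    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        conc = sp.getInitialConcentration()
        if math.isnan(conc):
            conc = sp.getInitialAmount()
            if math.isnan(conc):
                conc = 0.0
        species.append(
            SpeciesState(
                species_id=sp.getId(),
                name=sp.getName() or sp.getId(),
                concentration=float(conc),
                is_boundary=bool(sp.getBoundaryCondition() or sp.getConstant()),
            )
        )
        declared.add(sp.getId())

    reactions = []
    for i in range(sbml.getNumReactions()):
        rx = sbml.getReaction(i)
        rid = rx.getId()
        stoich: Dict[str, int] = {}
        substrates, products, modifiers = [], [], []
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            sid = ref.getSpecies()
            if sid not in declared:
                raise ModelParseError(
                    f"reaction {rid!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0) - int(round(ref.getStoichiometry() or 1))
            substrates.append(sid)
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            sid = ref.getSpecies()
            if sid not in declared:
                raise ModelParseError(
                    f"reaction {rid!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0) + int(round(ref.getStoichiometry() or 1))
            products.append(sid)
        for j in range(rx.getNumModifiers()):
            modifiers.append(rx.getModifier(j).getSpecies())
        law = rx.getKineticLaw()
        if law is None:
            raise UnsupportedModelError(f"reaction {rid!r} has no kinetic law")
        params = _local_parameters(law)
        math_symbols = _math_symbols(law.getMath())
        rate_law = _classify_rate_law(rid, params, substrates, products, modifiers,
                                      vmax_patterns, math_symbols)
        reactions.append(
            ReactionDef(
                reaction_id=rid,
                name=rx.getName() or rid,
                stoichiometry=stoich,
                rate_law=rate_law,
            )
        )
    return KineticModel(
        species,
        reactions,
        name=sbml.getName() or sbml.getId() or "model",
        provenance="sbml",
    )


def _local_parameters(law) -> Dict[str, float]:
    params: Dict[str, float] = {}
    for j in range(law.getNumLocalParameters()):
        lp = law.getLocalParameter(j)
        params[lp.getId()] = lp.getValue()
    for j in range(law.getNumParameters()):  # SBML L2 stores them as parameters
        lp = law.getParameter(j)
        params.setdefault(lp.getId(), lp.getValue())
    return params


def _find_vmax(params: Dict[str, float], rid: str, patterns: Sequence[str]):
    for pat in patterns:
        pid = pat.format(rid=rid)
        if pid in params:
            return params[pid]
    return None


def _math_symbols(ast) -> set:
    """Variable names appearing in a kinetic-law MathML tree."""
    if ast is None:
        return set()
    out = set()
    stack = [ast]
    while stack:
        node = stack.pop()
        if node.isName():
            out.add(node.getName())
        for i in range(node.getNumChildren()):
            stack.append(node.getChild(i))
    return out


def _classify_rate_law(rid, params, substrates, products, modifiers, vmax_patterns,
                       math_symbols):
    vmax = _find_vmax(params, rid, vmax_patterns)
    km = {
        pid[len("Km_"):]: val for pid, val in params.items() if pid.startswith("Km_")
    }
    if "Keq" in params:
        if vmax is None or len(substrates) != 1 or len(products) != 1:
            raise UnsupportedModelError(
                f"reaction {rid!r}: reversible form needs Vmax and exactly one "
                "substrate and product"
            )
        s, p = substrates[0], products[0]
        return RateLaw(
            REVERSIBLE_MM,
            vmax=vmax,
            km_substrate={s: km[s]},
            km_product={p: km[p]},
            keq=params["Keq"],
            substrate_refs=[s],
            product_refs=[p],
            modifier_refs=modifiers,
        )
    if vmax is not None:
        return RateLaw(
            IRREVERSIBLE_MM,
            vmax=vmax,
            km_substrate={s: km[s] for s in substrates},
            substrate_refs=list(substrates),
            product_refs=list(products),
            modifier_refs=modifiers,
        )
    if "k" in params:
        # zeroth-order inputs consume a clamped reactant that does not
        # appear in the rate expression; keep only species the math uses
        return RateLaw(
            MASS_ACTION,
            k=params["k"],
            substrate_refs=[s for s in substrates if s in math_symbols],
            product_refs=list(products),
            modifier_refs=modifiers,
        )
    raise UnsupportedModelError(
        f"reaction {rid!r}: kinetic law parameters {sorted(params)} match no "
        "supported form"
    )


# ---------------------------------------------------------------------------
# Surrogate glutathione network
# ---------------------------------------------------------------------------


def build_default_gsh_model() -> KineticModel:
    """Surrogate kinetic model of hepatic glutathione metabolism.

    Topology (boundary species are clamped):

    * methionine cycle: MET(b) -> SAM -> SAH <-> HCY, with remethylation
      HCY -> MET(b) and transsulfuration HCY -> CYS.  The SAM -> SAH
      methyl-transfer step is the DNA methyltransferase reaction ``v11``.
    * glutathione synthesis: CYS + GLU(b) -> GGC (gamma-glutamylcysteine
      synthetase) and GGC + GLY(b) -> GSH (glutathione synthetase).
    * detoxification: 2 GSH -> GSSG (glutathione peroxidase), GSSG -> 2 GSH
      (glutathione reductase), GSSG export, and a GST conjugation drain.
    * gamma-glutamyl cycle: GSH -> OXO + CYSGLY (lumped transpeptidase +
      cyclotransferase), OXO -> GLU(b) via 5-oxoprolinase (``v27``), a slow
      non-enzymatic 5-oxoproline leak, CYSGLY -> CYS dipeptidase salvage,
      and a cysteine export.

    Reference Vmax values were chosen so the network has a unique positive
    steady state; they are surrogate values, not measured constants.  When
    the published reference model is available as SBML it can be used in
    place of this one throughout the pipeline.
    """
    species = [
        SpeciesState("MET", "methionine (extracellular)", 0.05, is_boundary=True),
        SpeciesState("GLU", "glutamate (pool)", 0.3, is_boundary=True),
        SpeciesState("GLY", "glycine (pool)", 0.9, is_boundary=True),
        SpeciesState("SINK", "export sink", 0.0, is_boundary=True),
        SpeciesState("SAM", "S-adenosylmethionine", 0.05),
        SpeciesState("SAH", "S-adenosylhomocysteine", 0.02),
        SpeciesState("HCY", "homocysteine", 0.01),
        SpeciesState("CYS", "cysteine", 0.2),
        SpeciesState("GGC", "gamma-glutamylcysteine", 0.01),
        SpeciesState("GSH", "glutathione (reduced)", 5.0),
        SpeciesState("GSSG", "glutathione disulfide", 0.1),
        SpeciesState("OXO", "5-oxoproline", 0.05),
        SpeciesState("CYSGLY", "cysteinylglycine", 0.02),
    ]

    reactions = [
        ReactionDef(
            "vMAT",
            "methionine adenosyltransferase",
            gene_symbols=["MAT1A"],
            stoichiometry={"MET": -1, "SAM": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=0.4, km_substrate={"MET": 0.04},
                substrate_refs=["MET"], product_refs=["SAM"],
            ),
        ),
        ReactionDef(
            "v11",
            "DNA (cytosine-5-)-methyltransferase",
            gene_symbols=["DNMT1"],
            stoichiometry={"SAM": -1, "SAH": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=1.0, km_substrate={"SAM": 0.05},
                substrate_refs=["SAM"], product_refs=["SAH"],
            ),
        ),
        ReactionDef(
            "vSAHH",
            "S-adenosylhomocysteine hydrolase",
            gene_symbols=["AHCY"],
            stoichiometry={"SAH": -1, "HCY": 1},
            rate_law=RateLaw(
                REVERSIBLE_MM, vmax=5.0,
                km_substrate={"SAH": 0.02}, km_product={"HCY": 0.1}, keq=1.0,
                substrate_refs=["SAH"], product_refs=["HCY"],
            ),
        ),
        ReactionDef(
            "vMS",
            "methionine synthase",
            gene_symbols=["MTR"],
            stoichiometry={"HCY": -1, "MET": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=0.3, km_substrate={"HCY": 0.01},
                substrate_refs=["HCY"], product_refs=["MET"],
            ),
        ),
        ReactionDef(
            "vCBS",
            "transsulfuration (CBS + CTH, lumped)",
            gene_symbols=["CBS", "CTH"],
            stoichiometry={"HCY": -1, "CYS": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=0.6, km_substrate={"HCY": 0.02},
                substrate_refs=["HCY"], product_refs=["CYS"],
            ),
        ),
        ReactionDef(
            "vGCS",
            "gamma-glutamylcysteine synthetase",
            gene_symbols=["GCLC", "GCLM"],
            stoichiometry={"CYS": -1, "GLU": -1, "GGC": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=1.2,
                km_substrate={"CYS": 0.1, "GLU": 1.0},
                substrate_refs=["CYS", "GLU"], product_refs=["GGC"],
            ),
        ),
        ReactionDef(
            "vGS",
            "glutathione synthetase",
            gene_symbols=["GSS"],
            stoichiometry={"GGC": -1, "GLY": -1, "GSH": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=1.5,
                km_substrate={"GGC": 0.05, "GLY": 1.0},
                substrate_refs=["GGC", "GLY"], product_refs=["GSH"],
            ),
        ),
        ReactionDef(
            "vGPX",
            "glutathione peroxidase",
            gene_symbols=["GPX4"],
            stoichiometry={"GSH": -2, "GSSG": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=0.8, km_substrate={"GSH": 2.0},
                substrate_refs=["GSH"], product_refs=["GSSG"],
            ),
        ),
        ReactionDef(
            "vGR",
            "glutathione reductase",
            gene_symbols=["GSR"],
            stoichiometry={"GSSG": -1, "GSH": 2},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=1.0, km_substrate={"GSSG": 0.05},
                substrate_refs=["GSSG"], product_refs=["GSH"],
            ),
        ),
        ReactionDef(
            "vGSSGX",
            "GSSG export",
            stoichiometry={"GSSG": -1, "SINK": 1},
            rate_law=RateLaw(
                MASS_ACTION, k=0.5, substrate_refs=["GSSG"], product_refs=["SINK"],
            ),
        ),
        ReactionDef(
            "vGST",
            "glutathione S-transferase conjugation",
            gene_symbols=["GSTA4", "GSTM1", "GSTM2", "GSTT1"],
            stoichiometry={"GSH": -1, "SINK": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=0.5, km_substrate={"GSH": 5.0},
                substrate_refs=["GSH"], product_refs=["SINK"],
            ),
        ),
        ReactionDef(
            "vGGT",
            "gamma-glutamyl transpeptidase + cyclotransferase (lumped)",
            gene_symbols=["GGT1"],
            stoichiometry={"GSH": -1, "OXO": 1, "CYSGLY": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=0.7, km_substrate={"GSH": 3.0},
                substrate_refs=["GSH"], product_refs=["OXO", "CYSGLY"],
            ),
        ),
        ReactionDef(
            "v27",
            "5-oxoprolinase",
            gene_symbols=["OPLAH"],
            stoichiometry={"OXO": -1, "GLU": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=0.9, km_substrate={"OXO": 0.2},
                substrate_refs=["OXO"], product_refs=["GLU"],
            ),
        ),
        ReactionDef(
            "vOXOX",
            "5-oxoproline leak",
            stoichiometry={"OXO": -1, "SINK": 1},
            rate_law=RateLaw(
                MASS_ACTION, k=0.8, substrate_refs=["OXO"], product_refs=["SINK"],
            ),
        ),
        ReactionDef(
            "vCGase",
            "cysteinylglycine dipeptidase",
            stoichiometry={"CYSGLY": -1, "CYS": 1},
            rate_law=RateLaw(
                IRREVERSIBLE_MM, vmax=2.0, km_substrate={"CYSGLY": 0.05},
                substrate_refs=["CYSGLY"], product_refs=["CYS"],
            ),
        ),
        ReactionDef(
            "vCYSX",
            "cysteine export",
            stoichiometry={"CYS": -1, "SINK": 1},
            rate_law=RateLaw(
                MASS_ACTION, k=0.05, substrate_refs=["CYS"], product_refs=["SINK"],
            ),
        ),
    ]
    return KineticModel(
        species,
        reactions,
        name="glutathione_surrogate",
        version="1",
        provenance="builtin surrogate",
    )


def structurally_equal(a: KineticModel, b: KineticModel, rtol: float = 1e-9) -> bool:
    """Equality on species, reactions, parameters and stoichiometry.

    Display names and gene annotations are excluded: they do not affect
    simulation and are not all preserved through SBML exchange.
    """
    if a.species_ids != b.species_ids or a.reaction_ids != b.reaction_ids:
        return False
    for sa, sb in zip(a.species, b.species):
        if sa.is_boundary != sb.is_boundary:
            return False
        if not math.isclose(sa.concentration, sb.concentration, rel_tol=rtol, abs_tol=1e-12):
            return False
    for ra, rb in zip(a.reactions, b.reactions):
        la, lb = ra.rate_law, rb.rate_law
        if ra.stoichiometry != rb.stoichiometry or la.form != lb.form:
            return False
        if sorted(la.substrate_refs) != sorted(lb.substrate_refs):
            return False
        for attr in ("vmax", "keq", "k"):
            va, vb = getattr(la, attr), getattr(lb, attr)
            if (va is None) != (vb is None):
                return False
            if va is not None and not math.isclose(va, vb, rel_tol=rtol):
                return False
        if la.km_substrate.keys() != lb.km_substrate.keys():
            return False
        for sid in la.km_substrate:
            if not math.isclose(la.km_substrate[sid], lb.km_substrate[sid], rel_tol=rtol):
                return False
        if la.km_product.keys() != lb.km_product.keys():
            return False
        for sid in la.km_product:
            if not math.isclose(la.km_product[sid], lb.km_product[sid], rel_tol=rtol):
                return False
    return True


def load_builtin() -> KineticModel:
    """Load the packaged surrogate glutathione SBML file."""
    from importlib import resources

    text = (
        resources.files("gshflux").joinpath("data/glutathione_surrogate.xml").read_text()
    )
    return load_model(text)
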