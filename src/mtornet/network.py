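"""Reconstruction of the insulin/amino-acid mTOR–AMPK reaction network.

The network is a mass-action state-interconversion model: every protein pool
(IR, IRS, PI3K_PDK1, PI3K_var, Akt, TSC, mTORC1, mTORC2, AMPK, PRAS40,
p70S6K) is a closed set of phosphorylation/activation states, and every
reaction converts one state of a pool into another at rate

    v = k * gate(t) * (sum of catalyst amounts, or 1) * [substrate]

where ``gate`` is a unitless step stimulus (amino acids or insulin) switching
on at t = 0.  Combinatorial phospho-states (Akt, PRAS40, p70-S6K carry two
sites each) use shared rate constants for the "first" and "second" copy of
the same site-specific (de)phosphorylation, which keeps the number of fitted
parameters low while representing every internal state.

Amino-acid inputs are modelled as aa-gated activation reactions.  The
canonical input acts on mTORC1; additional inputs can be attached at any of
twelve candidate sites (``candidate_sites``), each adding exactly one new
rate parameter shared across the site's precursor reactions
(``build_variant``).  The final model — extended p70-S6K module plus extra
inputs on IRS-p, AMPK-pT172 and mTORC2 — has 31 species, 48 reactions and
12 observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SpeciesState",
    "ReactionSpec",
    "ModelSpec",
    "CandidateSite",
    "build_base_model",
    "candidate_sites",
    "build_variant",
    "PARAM_LOWER",
    "PARAM_UPPER",
    "DEFAULT_PARAM_VALUE",
]

PARAM_LOWER = 1e-6
PARAM_UPPER = 1e4
DEFAULT_PARAM_VALUE = 0.1

GATES = ("none", "aa", "insulin")


@dataclass(frozen=True)
class SpeciesState:
    """One molecular state of a protein pool."""

    id: str
    protein: str
    phospho_marks: frozenset = frozenset()
    initial_amount: float = 0.0

    def __post_init__(self):
        if self.initial_amount < 0:
            raise ValueError(f"negative initial amount for {self.id}")
        # phosphorylated/activated/refractory states start empty: cells are
        # starved 16 h before stimulation, so basal network activity is 0.
        if self.phospho_marks and self.initial_amount != 0.0:
            raise ValueError(f"marked state {self.id} must start at 0")


@dataclass(frozen=True)
class ReactionSpec:
    """A mass-action state interconversion within one protein pool."""

    id: str
    substrate: str
    product: str
    rate_param: str
    catalyst_pool: tuple = ()
    stimulus_gate: str = "none"

    def __post_init__(self):
        if self.stimulus_gate not in GATES:
            raise ValueError(f"unknown stimulus gate {self.stimulus_gate!r}")


@dataclass(frozen=True)
class CandidateSite:
    """An activatable state at which an extra aa input may be attached."""

    id: str
    precursors: tuple  # of (substrate, product) pairs


@dataclass
class ModelSpec:
    """Species, reactions, parameters and observables of one network variant."""

    species: list
    reactions: list
    parameters: dict  # param id -> (value, lower, upper)
    observables: dict  # observable id -> list of species ids (summed)
    input_sites: frozenset = frozenset({"mTORC1"})
    s6k_module: str = "extended"

    def __post_init__(self):
        self.validate()

    # -- introspection -------------------------------------------------

    @property
    def species_ids(self):
        return [s.id for s in self.species]

    @property
    def pools(self):
        """Map protein pool name -> list of its species ids."""
        out: dict = {}
        for s in self.species:
            out.setdefault(s.protein, []).append(s.id)
        return out

    @property
    def n_parameters(self):
        return len(self.parameters)

    def initial_amounts(self):
        return {s.id: s.initial_amount for s in self.species}

    def param_values(self):
        return {k: v[0] for k, v in self.parameters.items()}

    def with_params(self, values):
        """Return a copy with updated parameter values (bounds kept)."""
        params = dict(self.parameters)
        for k, v in values.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k!r}")
            _, lo, hi = params[k]
            params[k] = (float(v), lo, hi)
        m = ModelSpec(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=params,
            observables={k: list(v) for k, v in self.observables.items()},
            input_sites=self.input_sites,
            s6k_module=self.s6k_module,
        )
        return m

    def validate(self):
        ids = self.species_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        idset = set(ids)
        prot = {s.id: s.protein for s in self.species}
        rids = set()
        for r in self.reactions:
            if r.id in rids:
                raise ValueError(f"duplicate reaction id {r.id}")
            rids.add(r.id)
            for sp in (r.substrate, r.product):
                if sp not in idset:
                    raise ValueError(f"reaction {r.id}: unknown species {sp!r}")
            if prot[r.substrate] != prot[r.product]:
                raise ValueError(
                    f"reaction {r.id}: substrate and product belong to "
                    f"different pools ({prot[r.substrate]} vs {prot[r.product]})"
                )
            for c in r.catalyst_pool:
                if c not in idset:
                    raise ValueError(f"reaction {r.id}: unknown catalyst {c!r}")
            if r.rate_param not in self.parameters:
                raise ValueError(f"reaction {r.id}: unknown parameter {r.rate_param!r}")
        for obs, splist in self.observables.items():
            if not splist:
                raise ValueError(f"observable {obs} maps to no species")
            for sp in splist:
                if sp not in idset:
                    raise ValueError(f"observable {obs}: unknown species {sp!r}")


# ---------------------------------------------------------------------------
# base model construction
# ---------------------------------------------------------------------------

def _species_table(s6k_module):
    """(id, pool, marks) rows; unmarked states carry the pool's initial mass."""
    rows = [
        ("IR", "IR", ()),
        ("IR_pY1146", "IR", ("pY1146",)),
        ("IR_refractory", "IR", ("refractory",)),
        ("IRS", "IRS", ()),
        ("IRS_p", "IRS", ("p",)),
        ("IRS_pS636", "IRS", ("pS636",)),
        ("PI3K_PDK1", "PI3K_PDK1", ()),
        ("PI3K_PDK1_act", "PI3K_PDK1", ("act",)),
        ("PI3K_var", "PI3K_var", ()),
        ("PI3K_var_act", "PI3K_var", ("act",)),
        ("Akt", "Akt", ()),
        ("Akt_pT308", "Akt", ("pT308",)),
        ("Akt_pS473", "Akt", ("pS473",)),
        ("Akt_pT308_pS473", "Akt", ("pT308", "pS473")),
        ("TSC", "TSC", ()),
        ("TSC_pT1462", "TSC", ("pT1462",)),
        ("TSC_pS1387", "TSC", ("pS1387",)),
        ("mTORC1", "mTORC1", ()),
        ("mTORC1_act", "mTORC1", ("act",)),
        ("mTORC2", "mTORC2", ()),
        ("mTORC2_pS2481", "mTORC2", ("pS2481",)),
        ("AMPK", "AMPK", ()),
        ("AMPK_pT172", "AMPK", ("pT172",)),
        ("PRAS40", "PRAS40", ()),
        ("PRAS40_pT246", "PRAS40", ("pT246",)),
        ("PRAS40_pS183", "PRAS40", ("pS183",)),
        ("PRAS40_pT246_pS183", "PRAS40", ("pT246", "pS183")),
    ]
    if s6k_module == "extended":
        rows += [
            ("p70S6K", "p70S6K", ()),
            ("p70S6K_pT229", "p70S6K", ("pT229",)),
            ("p70S6K_pT389", "p70S6K", ("pT389",)),
            ("p70S6K_pT229_pT389", "p70S6K", ("pT229", "pT389")),
        ]
    else:
        rows += [
            ("p70S6K", "p70S6K", ()),
            ("p70S6K_pT389", "p70S6K", ("pT389",)),
        ]
    return rows


def _base_reactions(s6k_module):
    s6k_active = (
        "p70S6K_pT229_pT389" if s6k_module == "extended" else "p70S6K_pT389"
    )
    akt_t308_pool = ("Akt_pT308", "Akt_pT308_pS473")
    rows = [
        # (id, substrate, product, param, catalysts, gate)
        ("R1", "IR", "IR_pY1146", "k_IR_phos", (), "insulin"),
        ("R2", "IR_pY1146", "IR_refractory", "k_IR_refrac", (), "none"),
        ("R3", "IR_refractory", "IR", "k_IR_recover", (), "none"),
        ("R4", "IRS", "IRS_p", "k_IRS_phos_by_IR", ("IR_pY1146",), "none"),
        ("R6", "IRS_p", "IRS", "k_IRS_dephos", (), "none"),
        # p70-S6K-dependent negative feedback onto IRS (absorbs both the
        # direct S636 phosphorylation and transcriptional suppression)
        ("R7", "IRS_p", "IRS_pS636", "k_IRS_S636_phos", (s6k_active,), "none"),
        ("R8", "IRS_pS636", "IRS", "k_IRS_S636_dephos", (), "none"),
        ("R9", "PI3K_PDK1", "PI3K_PDK1_act", "k_PI3K_PDK1_act", ("IRS_p",), "none"),
        ("R10", "PI3K_PDK1_act", "PI3K_PDK1", "k_PI3K_PDK1_inact", (), "none"),
        # PI3K_var relays the IRS signal to mTORC2, Akt-independently
        ("R11", "PI3K_var", "PI3K_var_act", "k_PI3K_var_act", ("IRS_p",), "none"),
        ("R12", "PI3K_var_act", "PI3K_var", "k_PI3K_var_inact", (), "none"),
        ("R13", "Akt", "Akt_pT308", "k_Akt_T308_phos", ("PI3K_PDK1_act",), "none"),
        ("R14", "Akt_pS473", "Akt_pT308_pS473", "k_Akt_T308_phos", ("PI3K_PDK1_act",), "none"),
        ("R15", "Akt", "Akt_pS473", "k_Akt_S473_phos", ("mTORC2_pS2481",), "none"),
        ("R16", "Akt_pT308", "Akt_pT308_pS473", "k_Akt_S473_phos", ("mTORC2_pS2481",), "none"),
        ("R17", "Akt_pT308", "Akt", "k_Akt_T308_dephos", (), "none"),
        ("R18", "Akt_pT308_pS473", "Akt_pS473", "k_Akt_T308_dephos", (), "none"),
        ("R19", "Akt_pS473", "Akt", "k_Akt_S473_dephos", (), "none"),
        ("R20", "Akt_pT308_pS473", "Akt_pT308", "k_Akt_S473_dephos", (), "none"),
        ("R21", "TSC", "TSC_pT1462", "k_TSC_T1462_phos", akt_t308_pool, "none"),
        ("R22", "TSC_pT1462", "TSC", "k_TSC_T1462_dephos", (), "none"),
        ("R23", "TSC", "TSC_pS1387", "k_TSC_S1387_phos", ("AMPK_pT172",), "none"),
        ("R24", "TSC_pS1387", "TSC", "k_TSC_S1387_dephos", (), "none"),
        # canonical amino-acid input
        ("R25", "mTORC1", "mTORC1_act", "k_aa_mTORC1", (), "aa"),
        # AMPK inhibits mTORC1 by sequestering TSC in the S1387 state, which
        # (with plain TSC) forms the GAP-active pool deactivating mTORC1
        ("R26", "mTORC1_act", "mTORC1", "k_mTORC1_inact", ("TSC", "TSC_pS1387"), "none"),
        ("R27", "mTORC2", "mTORC2_pS2481", "k_mTORC2_act", ("PI3K_var_act",), "none"),
        ("R29", "mTORC2_pS2481", "mTORC2", "k_mTORC2_inact", (), "none"),
        # insulin-responsive arm of the IRS-dependent AMPK feedback
        ("R31", "AMPK", "AMPK_pT172", "k_AMPK_T172_phos", ("IRS_p",), "none"),
        ("R32", "AMPK_pT172", "AMPK", "k_AMPK_T172_dephos", (), "none"),
        ("R33", "PRAS40", "PRAS40_pT246", "k_PRAS40_T246_phos", akt_t308_pool, "none"),
        ("R34", "PRAS40_pS183", "PRAS40_pT246_pS183", "k_PRAS40_T246_phos", akt_t308_pool, "none"),
        ("R35", "PRAS40", "PRAS40_pS183", "k_PRAS40_S183_phos", ("mTORC1_act",), "none"),
        ("R36", "PRAS40_pT246", "PRAS40_pT246_pS183", "k_PRAS40_S183_phos", ("mTORC1_act",), "none"),
        ("R37", "PRAS40_pT246", "PRAS40", "k_PRAS40_T246_dephos", (), "none"),
        ("R38", "PRAS40_pT246_pS183", "PRAS40_pS183", "k_PRAS40_T246_dephos", (), "none"),
        ("R39", "PRAS40_pS183", "PRAS40", "k_PRAS40_S183_dephos", (), "none"),
        ("R40", "PRAS40_pT246_pS183", "PRAS40_pT246", "k_PRAS40_S183_dephos", (), "none"),
    ]
    if s6k_module == "extended":
        rows += [
            ("R41", "p70S6K", "p70S6K_pT229", "k_S6K_T229_phos", ("PI3K_PDK1_act",), "none"),
            ("R42", "p70S6K_pT389", "p70S6K_pT229_pT389", "k_S6K_T229_phos", ("PI3K_PDK1_act",), "none"),
            ("R43", "p70S6K", "p70S6K_pT389", "k_S6K_T389_phos", ("mTORC1_act",), "none"),
            ("R44", "p70S6K_pT229", "p70S6K_pT229_pT389", "k_S6K_T389_phos", ("mTORC1_act",), "none"),
            ("R45", "p70S6K_pT229", "p70S6K", "k_S6K_T229_dephos", (), "none"),
            ("R46", "p70S6K_pT229_pT389", "p70S6K_pT389", "k_S6K_T229_dephos", (), "none"),
            ("R47", "p70S6K_pT389", "p70S6K", "k_S6K_T389_dephos", (), "none"),
            ("R48", "p70S6K_pT229_pT389", "p70S6K_pT229", "k_S6K_T389_dephos", (), "none"),
        ]
    else:
        rows += [
            ("R41", "p70S6K", "p70S6K_pT389", "k_S6K_T389_phos", ("mTORC1_act",), "none"),
            ("R42", "p70S6K_pT389", "p70S6K", "k_S6K_T389_dephos", (), "none"),
        ]
    return rows


def _observables(s6k_module):
    obs = {
        "IR-pY1146": ["IR_pY1146"],
        "Akt-pT308": ["Akt_pT308", "Akt_pT308_pS473"],
        "Akt-pS473": ["Akt_pS473", "Akt_pT308_pS473"],
        "PRAS40-pT246": ["PRAS40_pT246", "PRAS40_pT246_pS183"],
        "PRAS40-pS183": ["PRAS40_pS183", "PRAS40_pT246_pS183"],
        "TSC2-pT1462": ["TSC_pT1462"],
        "TSC2-pS1387": ["TSC_pS1387"],
        "AMPK-pT172": ["AMPK_pT172"],
        "mTOR-pS2448": ["mTORC1_act"],
        "mTOR-pS2481": ["mTORC2_pS2481"],
    }
    if s6k_module == "extended":
        obs["p70S6K-pT389"] = ["p70S6K_pT389", "p70S6K_pT229_pT389"]
        obs["p70S6K-pT229"] = ["p70S6K_pT229", "p70S6K_pT229_pT389"]
    else:
        obs["p70S6K-pT389"] = ["p70S6K_pT389"]
    return obs


def build_base_model(s6k_module="extended", pool_total=1.0):
    """Build the canonical single-aa-input (mTORC1 only) network.

    Parameters
    ----------
    s6k_module : {"extended", "simple"}
        "extended" carries the four combinatorial p70-S6K states (T229 and
        T389); "simple" carries only the T389 state (used during the
        structure-selection scan).
    pool_total : float
        Initial amount placed on the unphosphorylated state of every pool.
    """
    if s6k_module not in ("extended", "simple"):
        raise ValueError(f"unknown s6k_module {s6k_module!r}")
    species = [
        SpeciesState(
            id=sid,
            protein=pool,
            phospho_marks=frozenset(marks),
            initial_amount=pool_total if not marks else 0.0,
        )
        for sid, pool, marks in _species_table(s6k_module)
    ]
    reactions = [
        ReactionSpec(id=rid, substrate=sub, product=prod, rate_param=par,
                     catalyst_pool=tuple(cats), stimulus_gate=gate)
        for rid, sub, prod, par, cats, gate in _base_reactions(s6k_module)
    ]
    params = {
        r.rate_param: (DEFAULT_PARAM_VALUE, PARAM_LOWER, PARAM_UPPER)
        for r in reactions
    }
    return ModelSpec(
        species=species,
        reactions=reactions,
        parameters=params,
        observables=_observables(s6k_module),
        input_sites=frozenset({"mTORC1"}),
        s6k_module=s6k_module,
    )


# ---------------------------------------------------------------------------
# amino-acid input variants
# ---------------------------------------------------------------------------

# Insulin-sensor states (IR pool) and the inhibitory IRS_pS636 state are not
# eligible: an aa "input" is an activating phosphorylation, aa-only protocols
# run with insulin = 0, and mTORC1 already carries the canonical input.
_CANDIDATE_ORDER = [
    "IRS_p",
    "PI3K_PDK1_act",
    "PI3K_var_act",
    "Akt_pT308",
    "Akt_pS473",
    "TSC_pT1462",
    "TSC_pS1387",
    "AMPK_pT172",
    "mTORC2_pS2481",
    "PRAS40_pT246",
    "PRAS40_pS183",
    "p70S6K_pT389",
]

# spec-numbered reaction ids for the inputs of the published best model
_VARIANT_RIDS = {"IRS_p": ["R5"], "mTORC2_pS2481": ["R28"], "AMPK_pT172": ["R30"]}


def candidate_sites(model):
    """The 12 activatable states eligible for an extra amino-acid input."""
    if model.input_sites != frozenset({"mTORC1"}):
        raise ValueError("candidate sites are defined on the base (single-input) model")
    by_id = {s.id: s for s in model.species}
    out = []
    for sid in _CANDIDATE_ORDER:
        if sid not in by_id:
            continue
        target = by_id[sid]
        (site_mark,) = target.phospho_marks  # candidates carry a single mark
        by_marks = {
            s.phospho_marks: s.id
            for s in model.species
            if s.protein == target.protein
        }
        prec = []
        for s in sorted(
            (s for s in model.species if s.protein == target.protein),
            key=lambda s: (len(s.phospho_marks), s.id),
        ):
            if site_mark in s.phospho_marks:
                continue
            prod = by_marks.get(s.phospho_marks | {site_mark})
            if prod is not None:
                prec.append((s.id, prod))
        out.append(CandidateSite(id=sid, precursors=tuple(prec)))
    return out


def build_variant(base, extra_inputs):
    """Attach aa-gated activation reactions at each site in ``extra_inputs``.

    Each site contributes one new rate parameter ``k_aa_<site>`` shared by the
    aa-gated reactions of all its precursor states.
    """
    sites = {c.id: c for c in candidate_sites(base)}
    unknown = set(extra_inputs) - set(sites)
    if unknown:
        raise ValueError(f"unknown candidate site(s): {sorted(unknown)}")
    if not extra_inputs:
        return base

    reactions = list(base.reactions)
    params = dict(base.parameters)
    used = {r.id for r in reactions}
    next_free = 49
    for sid in sorted(extra_inputs, key=_CANDIDATE_ORDER.index):
        par = f"k_aa_{sid}"
        params[par] = (DEFAULT_PARAM_VALUE, PARAM_LOWER, PARAM_UPPER)
        rids = list(_VARIANT_RIDS.get(sid, []))
        for i, (sub, prod) in enumerate(sites[sid].precursors):
            if i < len(rids):
                rid = rids[i]
            else:
                while f"R{next_free}" in used:
                    next_free += 1
                rid = f"R{next_free}"
            used.add(rid)
            reactions.append(
                ReactionSpec(id=rid, substrate=sub, product=prod,
                             rate_param=par, stimulus_gate="aa")
            )
    return ModelSpec(
        species=list(base.species),
        reactions=reactions,
        parameters=params,
        observables={k: list(v) for k, v in base.observables.items()},
        input_sites=base.input_sites | frozenset(extra_inputs),
        s6k_module=base.s6k_module,
    )
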