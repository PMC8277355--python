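"""The nine-variant ODE model family of proximal insulin signalling.

All variants share one mass-action backbone:

* insulin activates the insulin receptor (IR);
* active IR activates the lumped IRS/PI3K node;
* active IRS/PI3K converts PIP2 to PIP3 (rate constant ``Kf3``); PTEN
  catalyses the reverse reaction;
* PIP3 recruits PDPK1 and Akt to the plasma membrane;
* membrane PDPK1 phosphorylates Akt T309 (``Kf6``); active mTORC2
  phosphorylates Akt S474 (``Kf7``);
* mTORC2 is activated both by PIP3 and by active Akt (SIN1 phosphorylation,
  rate constants ``Ki2a``/``Ki2b`` for the pT309-only and doubly
  phosphorylated Akt forms — only T309-phosphorylated Akt carries catalytic
  activity, S474-only Akt is inactive);
* active Akt phosphorylates PRAS40 (``Kf11a``/``Kf11b``), the surrogate for
  mTORC1 activation.

Each variant adds at most one negative-feedback edge onto IRS/PI3K
(multiplicative attenuation ``1/(1 + sum Ki * source)`` of the IRS/PI3K
activation rate) or onto PTEN (multiplicative enhancement
``1 + sum Ki * source`` of PIP3 dephosphorylation):

=======  =========================  ==================
variant  feedback edge              strength parameters
=======  =========================  ==================
1, 2     mTORC1 -> IRS/PI3K         Ki2
3        (none)                     --
4        PDPK1 -> IRS/PI3K          Ki2
5        PDPK1 -> PTEN              Ki2
6        mTORC2 -> IRS/PI3K         Ki2
7        mTORC2 -> PTEN             Ki2
8        Akt -> PTEN                Ki2a, Ki2b
9        Akt -> IRS/PI3K            Ki2a, Ki2b
=======  =========================  ==================

Inhibitors and phospho-site mutants are simulated by *parameter nulling*:
rapamycin (mTORC1 inhibition) sets Ki2 = 0; a pan-Akt inhibitor sets
{Ki2a, Ki2b, Kf11a, Kf11b} = 0; T309A sets Kf6 = 0; S474A sets Kf7 = 0;
wortmannin (PI3K inhibition) sets Kf3 = 0.

Units: each protein moiety total is normalised to 1 (dimensionless
fractions), time is in seconds, and the insulin dose enters linearly in nM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "STATES",
    "PARAM_NAMES",
    "MOIETIES",
    "PERTURBATIONS",
    "FEEDBACK_EDGES",
    "ModelSpecification",
    "ParameterSet",
    "StimulusEvent",
    "StimulusProtocol",
    "build_model",
    "apply_perturbation",
    "default_parameters",
    "default_protocols",
    "influence_graph",
]

#: ODE state names, in integration order.
STATES = (
    "IR_inactive", "IR_active",
    "IRS_inactive", "IRS_active",
    "PIP2", "PIP3",
    "PDPK1_cyt", "PDPK1_mem",
    "Akt_cyt", "Akt_mem", "Akt_mem_pT309", "Akt_mem_pS474", "Akt_mem_pT309_pS474",
    "mTORC2_inactive", "mTORC2_active",
    "PRAS40", "pPRAS40",
    "PTEN",
)

#: Membrane-bound Akt species (the PM-recruitment observable).
MEMBRANE_AKT_STATES = ("Akt_mem", "Akt_mem_pT309", "Akt_mem_pS474", "Akt_mem_pT309_pS474")

#: Conserved moieties: the states of each sum to a constant total (1.0).
MOIETIES: dict[str, tuple[str, ...]] = {
    "IR": ("IR_inactive", "IR_active"),
    "IRS_PI3K": ("IRS_inactive", "IRS_active"),
    "PIP": ("PIP2", "PIP3"),
    "PDPK1": ("PDPK1_cyt", "PDPK1_mem"),
    "Akt": ("Akt_cyt",) + MEMBRANE_AKT_STATES,
    "mTORC2": ("mTORC2_inactive", "mTORC2_active"),
    "PRAS40": ("PRAS40", "pPRAS40"),
    "PTEN": ("PTEN",),
}

#: Full parameter vector order shared by all variants (Ki2 is inert in
#: variants without a single-strength feedback edge).
PARAM_NAMES = (
    "Kf1", "Kb1", "Kf2", "Kb2", "Kf3", "Kb3", "Kf4", "Kb4", "Kf5", "Kb5",
    "Kf6", "Kb6", "Kf7", "Kb7", "Kf8", "Kb8",
    "Ki2a", "Ki2b", "Kf11a", "Kf11b", "Kb11", "Ki2",
)

#: Feedback edge per variant: (source node, target node); sign is always
#: negative.  Variants 8/9 use the Akt-limb strengths Ki2a/Ki2b, the rest Ki2.
FEEDBACK_EDGES: dict[int, tuple[str, str, tuple[str, ...]] | None] = {
    1: ("mTORC1", "IRS_PI3K", ("Ki2",)),
    2: ("mTORC1", "IRS_PI3K", ("Ki2",)),
    3: None,
    4: ("PDPK1", "IRS_PI3K", ("Ki2",)),
    5: ("PDPK1", "PTEN", ("Ki2",)),
    6: ("mTORC2", "IRS_PI3K", ("Ki2",)),
    7: ("mTORC2", "PTEN", ("Ki2",)),
    8: ("Akt", "PTEN", ("Ki2a", "Ki2b")),
    9: ("Akt", "IRS_PI3K", ("Ki2a", "Ki2b")),
}

#: Parameter sets nulled by each named perturbation.
PERTURBATIONS: dict[str, tuple[str, ...]] = {
    "none": (),
    "mtorc1_inhibition": ("Ki2",),
    "akt_inhibition": ("Ki2a", "Ki2b", "Kf11a", "Kf11b"),
    "t309a": ("Kf6",),
    "s474a": ("Kf7",),
    "pi3k_inhibition": ("Kf3",),
}


@dataclass(frozen=True)
class Reaction:
    name: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...]
    rate_law: str
    parameters: tuple[str, ...]


@dataclass(frozen=True)
class ModelSpecification:
    """One reaction-network variant: backbone plus its feedback edge."""

    variant: int
    states: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    feedback: tuple[str, str, tuple[str, ...]] | None   # (source, target, strengths)
    parameter_names: tuple[str, ...]
    moieties: Mapping[str, tuple[str, ...]]

    @property
    def has_feedback(self) -> bool:
        return self.feedback is not None

    def to_json(self, path: str | Path | None = None) -> str:
        """Human-readable reaction listing for inspection/manifests."""
        doc = {
            "variant": self.variant,
            "states": list(self.states),
            "parameters": list(self.parameter_names),
            "feedback_edge": (
                None if self.feedback is None
                else {"source": self.feedback[0], "target": self.feedback[1],
                      "sign": "negative", "strengths": list(self.feedback[2])}
            ),
            "moieties": {k: list(v) for k, v in self.moieties.items()},
            "reactions": [
                {"name": r.name, "substrates": list(r.substrates),
                 "products": list(r.products), "modifiers": list(r.modifiers),
                 "rate_law": r.rate_law, "parameters": list(r.parameters)}
                for r in self.reactions
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _backbone_reactions(variant: int) -> list[Reaction]:
    fb = FEEDBACK_EDGES[variant]
    irs_att = fb is not None and fb[1] == "IRS_PI3K"
    pten_enh = fb is not None and fb[1] == "PTEN"
    att = " / (1 + feedback)" if irs_att else ""
    enh = " * (1 + feedback)" if pten_enh else ""
    rx = [
        Reaction("IR_activation", ("IR_inactive",), ("IR_active",), ("insulin",),
                 "Kf1 * (insulin + L0) * IR_inactive", ("Kf1",)),
        Reaction("IR_deactivation", ("IR_active",), ("IR_inactive",), (),
                 "Kb1 * IR_active", ("Kb1",)),
        Reaction("IRS_PI3K_activation", ("IRS_inactive",), ("IRS_active",), ("IR_active",),
                 f"Kf2 * IR_active * IRS_inactive{att}", ("Kf2",)),
        Reaction("IRS_PI3K_deactivation", ("IRS_active",), ("IRS_inactive",), (),
                 "Kb2 * IRS_active", ("Kb2",)),
        Reaction("PIP3_synthesis", ("PIP2",), ("PIP3",), ("IRS_active",),
                 "Kf3 * IRS_active * PIP2", ("Kf3",)),
        Reaction("PIP3_degradation", ("PIP3",), ("PIP2",), ("PTEN",),
                 f"Kb3 * PTEN * PIP3{enh}", ("Kb3",)),
        Reaction("PDPK1_membrane_binding", ("PDPK1_cyt",), ("PDPK1_mem",), ("PIP3",),
                 "Kf4 * PIP3 * PDPK1_cyt", ("Kf4",)),
        Reaction("PDPK1_membrane_release", ("PDPK1_mem",), ("PDPK1_cyt",), (),
                 "Kb4 * PDPK1_mem", ("Kb4",)),
        Reaction("Akt_membrane_binding", ("Akt_cyt",), ("Akt_mem",), ("PIP3",),
                 "Kf5 * PIP3 * Akt_cyt", ("Kf5",)),
    ] + [
        Reaction(f"{s}_membrane_release", (s,), ("Akt_cyt",), (),
                 f"Kb5 * {s}", ("Kb5",))
        for s in MEMBRANE_AKT_STATES
    ] + [
        Reaction("Akt_T309_phosphorylation", ("Akt_mem",), ("Akt_mem_pT309",), ("PDPK1_mem",),
                 "Kf6 * PDPK1_mem * Akt_mem", ("Kf6",)),
        Reaction("Akt_pS474_T309_phosphorylation", ("Akt_mem_pS474",), ("Akt_mem_pT309_pS474",),
                 ("PDPK1_mem",), "Kf6 * PDPK1_mem * Akt_mem_pS474", ("Kf6",)),
        Reaction("Akt_T309_dephosphorylation", ("Akt_mem_pT309",), ("Akt_mem",), (),
                 "Kb6 * Akt_mem_pT309", ("Kb6",)),
        Reaction("Akt_pTS_T309_dephosphorylation", ("Akt_mem_pT309_pS474",), ("Akt_mem_pS474",), (),
                 "Kb6 * Akt_mem_pT309_pS474", ("Kb6",)),
        Reaction("Akt_S474_phosphorylation", ("Akt_mem",), ("Akt_mem_pS474",), ("mTORC2_active",),
                 "Kf7 * mTORC2_active * Akt_mem", ("Kf7",)),
        Reaction("Akt_pT309_S474_phosphorylation", ("Akt_mem_pT309",), ("Akt_mem_pT309_pS474",),
                 ("mTORC2_active",), "Kf7 * mTORC2_active * Akt_mem_pT309", ("Kf7",)),
        Reaction("Akt_S474_dephosphorylation", ("Akt_mem_pS474",), ("Akt_mem",), (),
                 "Kb7 * Akt_mem_pS474", ("Kb7",)),
        Reaction("Akt_pTS_S474_dephosphorylation", ("Akt_mem_pT309_pS474",), ("Akt_mem_pT309",), (),
                 "Kb7 * Akt_mem_pT309_pS474", ("Kb7",)),
        Reaction("mTORC2_activation_by_PIP3", ("mTORC2_inactive",), ("mTORC2_active",), ("PIP3",),
                 "Kf8 * PIP3 * mTORC2_inactive", ("Kf8",)),
        Reaction("mTORC2_activation_by_Akt", ("mTORC2_inactive",), ("mTORC2_active",),
                 ("Akt_mem_pT309", "Akt_mem_pT309_pS474"),
                 "(Ki2a * Akt_mem_pT309 + Ki2b * Akt_mem_pT309_pS474) * mTORC2_inactive",
                 ("Ki2a", "Ki2b")),
        Reaction("mTORC2_deactivation", ("mTORC2_active",), ("mTORC2_inactive",), (),
                 "Kb8 * mTORC2_active", ("Kb8",)),
        Reaction("PRAS40_phosphorylation", ("PRAS40",), ("pPRAS40",),
                 ("Akt_mem_pT309", "Akt_mem_pT309_pS474"),
                 "(Kf11a * Akt_mem_pT309 + Kf11b * Akt_mem_pT309_pS474) * PRAS40",
                 ("Kf11a", "Kf11b")),
        Reaction("PRAS40_dephosphorylation", ("pPRAS40",), ("PRAS40",), (),
                 "Kb11 * pPRAS40", ("Kb11",)),
    ]
    return rx


def build_model(variant: int) -> ModelSpecification:
    """Return the reaction network for one variant (1-9)."""
    if variant not in FEEDBACK_EDGES:
        raise ValueError(f"unknown model variant {variant!r}; expected 1-9")
    fb = FEEDBACK_EDGES[variant]
    # canonical order: Kf/Kb backbone, Akt limbs, PRAS40, basal ligand, feedback
    names = ["Kf1", "Kb1", "Kf2", "Kb2", "Kf3", "Kb3", "Kf4", "Kb4", "Kf5", "Kb5",
             "Kf6", "Kb6", "Kf7", "Kb7", "Kf8", "Kb8",
             "Ki2a", "Ki2b", "Kf11a", "Kf11b", "Kb11", "L0"]
    if fb is not None and "Ki2" in fb[2]:
        names.append("Ki2")
    return ModelSpecification(
        variant=variant,
        states=STATES,
        reactions=tuple(_backbone_reactions(variant)),
        feedback=fb,
        parameter_names=tuple(names),
        moieties=dict(MOIETIES),
    )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: Hand-chosen default rate constants (s^-1 scale on unit moiety totals);
#: starting point for tests and for bounds-centred sampling.  L0 is the
#: constitutive (basal) ligand equivalent in nM, fixed, not calibrated.
DEFAULT_VALUES: dict[str, float] = {
    "Kf1": 0.05, "Kb1": 0.05,
    "Kf2": 0.2, "Kb2": 0.05,
    "Kf3": 0.02, "Kb3": 0.05,
    "Kf4": 1.0, "Kb4": 0.1,
    "Kf5": 1.0, "Kb5": 0.1,
    "Kf6": 0.2, "Kb6": 0.02,
    "Kf7": 0.1, "Kb7": 0.02,
    "Kf8": 0.2, "Kb8": 0.05,
    "Ki2a": 0.5, "Ki2b": 0.5,
    "Kf11a": 0.1, "Kf11b": 0.1, "Kb11": 0.02,
    "L0": 0.05,
    "Ki2": 5.0,
}

DEFAULT_BOUNDS: tuple[float, float] = (1e-3, 1e3)

#: Parameters held fixed during calibration (none by default; the basal
#: ligand L0 is calibrated within its own narrow bounds).
FIXED_PARAMS: tuple[str, ...] = ()


@dataclass(frozen=True)
class ParameterSet:
    """Named, bounded, non-negative rate constants for one variant."""

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    nulled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
            if name in self.nulled:
                if v != 0.0:
                    raise ValueError(f"nulled parameter {name} must be exactly 0")
            elif name in self.bounds:
                lo, hi = self.bounds[name]
                if not (lo <= v <= hi):
                    raise ValueError(
                        f"parameter {name}={v} outside bounds [{lo}, {hi}]"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        vals = dict(self.values)
        for k, v in updates.items():
            if k not in vals:
                raise KeyError(f"unknown parameter {k!r}")
            vals[k] = float(v)
        return replace(self, values=vals)

    def null(self, names: Iterable[str]) -> "ParameterSet":
        names = tuple(names)
        missing = [n for n in names if n not in self.values]
        if missing:
            raise KeyError(f"parameter(s) {missing} not present in this variant")
        vals = dict(self.values)
        for n in names:
            vals[n] = 0.0
        return replace(self, values=vals, nulled=self.nulled | frozenset(names))

    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.values if n not in FIXED_PARAMS)

    def vector(self) -> np.ndarray:
        """Full-length vector in :data:`PARAM_NAMES` order (+ Kb11, L0).

        Absent parameters (Ki2 in variants without it) are 0.
        """
        return params_to_vector(self.values)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"values": self.values, "bounds": {k: list(v) for k, v in self.bounds.items()},
               "nulled": sorted(self.nulled)}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


#: Order of the packed numeric vector handed to the integrator.
VECTOR_ORDER = ("Kf1", "Kb1", "Kf2", "Kb2", "Kf3", "Kb3", "Kf4", "Kb4", "Kf5", "Kb5",
                "Kf6", "Kb6", "Kf7", "Kb7", "Kf8", "Kb8",
                "Ki2a", "Ki2b", "Kf11a", "Kf11b", "Kb11", "L0", "Ki2")


def params_to_vector(values: Mapping[str, float]) -> np.ndarray:
    return np.array([values.get(n, 0.0) for n in VECTOR_ORDER], dtype=np.float64)


def default_parameters(spec: ModelSpecification,
                       bounds: tuple[float, float] = DEFAULT_BOUNDS) -> ParameterSet:
    values = {n: DEFAULT_VALUES[n] for n in spec.parameter_names}
    bds = {n: bounds for n in spec.parameter_names}
    bds["L0"] = (1e-3, 0.5)
    return ParameterSet(values=values, bounds=bds)


def apply_perturbation(params: ParameterSet, perturbation: str) -> ParameterSet:
    """Null exactly the parameters mandated by the named perturbation."""
    if perturbation not in PERTURBATIONS:
        raise ValueError(
            f"unknown perturbation {perturbation!r}; expected one of {sorted(PERTURBATIONS)}"
        )
    targets = PERTURBATIONS[perturbation]
    if not targets:
        return params
    return params.null(targets)


# ---------------------------------------------------------------------------
# Stimulus protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEvent:
    time: float
    kind: str                          # insulin_dose | parameter_null | parameter_restore
    dose: float = 0.0                  # nM, for insulin_dose
    parameters: tuple[str, ...] = ()   # for parameter_null / parameter_restore

    def __post_init__(self) -> None:
        if self.kind not in ("insulin_dose", "parameter_null", "parameter_restore"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "insulin_dose" and self.dose < 0:
            raise ValueError("insulin dose must be >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered timed insulin steps and parameter-nulling events."""

    events: tuple[StimulusEvent, ...]
    pre_equilibrate: bool = True

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")

    @property
    def event_times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)


def step_protocol(dose: float, *, null: Iterable[str] = (),
                  null_at: float | None = None) -> StimulusProtocol:
    """Insulin step at t=0, with an optional parameter-nulling event.

    ``null_at=None`` applies the nulling together with the stimulus (models
    inhibitor pre-treatment); a positive time models mid-course inhibitor
    addition (for example wortmannin after the trace plateaus).
    """
    events: list[StimulusEvent] = []
    null = tuple(null)
    if null and (null_at is None or null_at <= 0):
        events.append(StimulusEvent(0.0, "parameter_null", parameters=null))
    events.append(StimulusEvent(0.0, "insulin_dose", dose=float(dose)))
    if null and null_at is not None and null_at > 0:
        events.append(StimulusEvent(float(null_at), "parameter_null", parameters=null))
    return StimulusProtocol(events=tuple(events))


def default_protocols(spec: ModelSpecification,
                      washout_time: float = 600.0) -> dict[str, StimulusProtocol]:
    """Protocols for the standard condition names of the synthetic bundle.

    Conditions whose perturbation references a parameter absent from the
    variant (rapamycin on a Ki2-free variant) are omitted.
    """
    protocols = {
        "1nM": step_protocol(1.0),
        "100nM": step_protocol(100.0),
        "1nM+akt_inhibitor": step_protocol(1.0, null=PERTURBATIONS["akt_inhibition"]),
        "1nM+kinase_dead": step_protocol(1.0, null=PERTURBATIONS["akt_inhibition"]),
        "100nM+wortmannin": step_protocol(100.0, null=PERTURBATIONS["pi3k_inhibition"],
                                          null_at=washout_time),
    }
    if "Ki2" in spec.parameter_names:
        protocols["1nM+rapamycin"] = step_protocol(1.0, null=PERTURBATIONS["mtorc1_inhibition"])
    return protocols


# ---------------------------------------------------------------------------
# Network structure
# ---------------------------------------------------------------------------

def influence_graph(spec: ModelSpecification):
    """Directed node-level influence graph (networkx DiGraph).

    Node A -> node B when a species of moiety A appears as substrate or
    modifier of a reaction interconverting species of moiety B.  Used for
    structural checks such as the absence of any feedback path in variant 3.
    """
    import networkx as nx

    state_to_moiety = {s: m for m, states in MOIETIES.items() for s in states}
    g = nx.DiGraph()
    g.add_nodes_from(list(MOIETIES) + ["insulin", "mTORC1"])
    for r in spec.reactions:
        targets = {state_to_moiety[s] for s in r.substrates + r.products}
        sources = {state_to_moiety.get(m, m) for m in r.modifiers}
        for tgt in targets:
            for src in sources:
                if src != tgt:
                    g.add_edge(src, tgt)
    # PRAS40 phosphorylation is the mTORC1-activation surrogate.
    g.add_edge("PRAS40", "mTORC1")
    if spec.feedback is not None:
        src, tgt, _ = spec.feedback
        g.add_edge(src, tgt)
    return g
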