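"""Demographic scenarios: populations, events, priors, and order constraints.

A scenario is a hypothesis about population history: a set of sampled
populations (each with a haploid mitochondrial effective size Ne, a sample
size, and a sampling age in generations before present) plus an ordered,
backward-in-time list of events — divergences (a daughter population's
lineages merge into a parent), instantaneous unidirectional admixture
pulses (each recipient lineage moves to the donor with probability r), and
founder bottlenecks (the daughter population has size Nb for the db
generations following its founding).

All priors are uniform (optionally log-uniform) on the stated range; a
degenerate range [v, v] fixes the parameter.  Inter-parameter order
constraints (t_a > t_b) are enforced by rejection resampling.  Scenarios
serialise to and from plain JSON documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

MAX_REJECTION_TRIES = 100_000


class ScenarioError(ValueError):
    """Raised for invalid scenario structure or unsatisfiable constraints."""


@dataclass(frozen=True)
class Prior:
    """Uniform (or log-uniform) prior on [low, high]; low == high fixes the value."""

    low: float
    high: float
    dist: str = "uniform"

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ScenarioError(f"prior high {self.high} < low {self.low}")
        if self.dist not in ("uniform", "loguniform"):
            raise ScenarioError(f"unknown prior dist {self.dist!r}")
        if self.dist == "loguniform" and self.low <= 0:
            raise ScenarioError("log-uniform prior requires low > 0")

    @property
    def fixed(self) -> bool:
        return self.low == self.high

    def sample(self, rng: np.random.Generator) -> float:
        if self.fixed:
            return self.low
        if self.dist == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    @property
    def midpoint(self) -> float:
        if self.dist == "loguniform":
            return float(np.sqrt(self.low * self.high))
        return 0.5 * (self.low + self.high)

    @staticmethod
    def of(value) -> "Prior":
        """Coerce a number, [low, high] pair, or dict into a Prior."""
        if isinstance(value, Prior):
            return value
        if isinstance(value, dict):
            return Prior(float(value["low"]), float(value["high"]),
                         value.get("dist", "uniform"))
        if isinstance(value, (list, tuple)):
            return Prior(float(value[0]), float(value[1]))
        return Prior(float(value), float(value))

    def to_json(self):
        if self.fixed:
            return self.low
        d = {"low": self.low, "high": self.high}
        if self.dist != "uniform":
            d["dist"] = self.dist
        return d


@dataclass
class PopulationSpec:
    label: str
    ne: Prior  # haploid effective size
    sample_size: int
    sampling_age: int = 0  # generations before present

    def __post_init__(self) -> None:
        self.ne = Prior.of(self.ne)
        if self.ne.low <= 0:
            raise ScenarioError(f"population {self.label}: Ne must be > 0")
        if self.sampling_age < 0:
            raise ScenarioError(f"population {self.label}: sampling_age must be >= 0")


@dataclass
class DemographicEvent:
    """One backward-in-time event.

    divergence: participants = (daughter, parent); at ``time`` the daughter's
    lineages join the parent and the daughter becomes inactive further back.
    admixture: participants = (recipient, donor); at ``time`` each recipient
    lineage moves to the donor with probability ``rate``.
    bottleneck: participants = (population,); the population has size ``nb``
    during the ``duration`` generations ending at ``time``; when ``time`` is
    None it is tied to the population's own divergence time (founder event).
    """

    kind: str
    name: str
    participants: tuple
    time: Prior | None = None
    rate: Prior | None = None  # admixture
    nb: Prior | None = None  # bottleneck founder size
    duration: Prior | None = None  # bottleneck length, generations

    def __post_init__(self) -> None:
        if self.kind not in ("divergence", "admixture", "bottleneck"):
            raise ScenarioError(f"unknown event kind {self.kind!r}")
        self.participants = tuple(self.participants)
        if self.time is not None:
            self.time = Prior.of(self.time)
        if self.kind == "divergence":
            if len(self.participants) != 2:
                raise ScenarioError(f"{self.name}: divergence needs (daughter, parent)")
            if self.time is None:
                raise ScenarioError(f"{self.name}: divergence needs a time prior")
        elif self.kind == "admixture":
            if len(self.participants) != 2:
                raise ScenarioError(f"{self.name}: admixture needs (recipient, donor)")
            if self.time is None or self.rate is None:
                raise ScenarioError(f"{self.name}: admixture needs time and rate priors")
            self.rate = Prior.of(self.rate)
            if self.rate.low < 0 or self.rate.high > 1:
                raise ScenarioError(f"{self.name}: admixture rate prior outside [0, 1]")
        else:  # bottleneck
            if len(self.participants) != 1:
                raise ScenarioError(f"{self.name}: bottleneck names one population")
            if self.nb is None:
                raise ScenarioError(f"{self.name}: bottleneck needs founder size prior")
            self.nb = Prior.of(self.nb)
            if self.nb.low <= 0:
                raise ScenarioError(f"{self.name}: founder size must be > 0")
            self.duration = Prior.of(self.duration if self.duration is not None else (1, 50))
            if self.duration.low < 1:
                raise ScenarioError(f"{self.name}: bottleneck duration must be >= 1")


@dataclass
class DemographicScenario:
    id: str
    populations: list[PopulationSpec]
    events: list[DemographicEvent]
    order_constraints: list[tuple[str, str]] = field(default_factory=list)
    # mutation parameters shared with the simulator: priors for mu (per site
    # per generation) and kappa; fixed alpha, p_inv, pi
    mutation: dict = field(default_factory=dict)

    def population(self, label: str) -> PopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise ScenarioError(f"scenario {self.id}: unknown population {label!r}")

    @property
    def pop_labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def divergence_of(self, label: str) -> DemographicEvent | None:
        """The divergence event in which ``label`` is the daughter, if any."""
        for ev in self.events:
            if ev.kind == "divergence" and ev.participants[0] == label:
                return ev
        return None

    # -- parameter bookkeeping -------------------------------------------------

    def parameter_priors(self) -> dict[str, Prior]:
        """Flat name -> Prior map covering Ne's, event times/rates, mutation."""
        priors: dict[str, Prior] = {}
        for p in self.populations:
            priors[f"Ne_{p.label}"] = p.ne
        for ev in self.events:
            if ev.time is not None:
                priors[f"t_{ev.name}"] = ev.time
            if ev.kind == "admixture":
                priors[f"r_{ev.name}"] = ev.rate
            if ev.kind == "bottleneck":
                priors[f"Nb_{ev.name}"] = ev.nb
                priors[f"db_{ev.name}"] = ev.duration
        for key, default in (("mu", None), ("kappa", None)):
            if key in self.mutation:
                priors[key] = Prior.of(self.mutation[key])
        return priors

    def implicit_constraints(self) -> list[tuple[str, str]]:
        """Nesting constraints: a parent's own divergence is older than the
        daughter's divergence into it."""
        cons = []
        for ev in self.events:
            if ev.kind != "divergence":
                continue
            daughter, parent = ev.participants
            parent_div = self.divergence_of(parent)
            if parent_div is not None:
                cons.append((f"t_{parent_div.name}", f"t_{ev.name}"))
        return cons

    def all_constraints(self) -> list[tuple[str, str]]:
        explicit = [(f"t_{a}" if not a.startswith("t_") else a,
                     f"t_{b}" if not b.startswith("t_") else b)
                    for a, b in self.order_constraints]
        seen = set()
        out = []
        for c in explicit + self.implicit_constraints():
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    # -- serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "populations": [
                {"label": p.label, "ne": p.ne.to_json(), "sample_size": p.sample_size,
                 "sampling_age": p.sampling_age}
                for p in self.populations
            ],
            "events": [_event_to_dict(ev) for ev in self.events],
            "order_constraints": [list(c) for c in self.order_constraints],
            "mutation": {
                k: (Prior.of(v).to_json() if k in ("mu", "kappa") else v)
                for k, v in self.mutation.items()
            },
        }

    @staticmethod
    def from_dict(doc: dict) -> "DemographicScenario":
        pops = [
            PopulationSpec(d["label"], Prior.of(d["ne"]), int(d["sample_size"]),
                           int(d.get("sampling_age", 0)))
            for d in doc["populations"]
        ]
        events = [_event_from_dict(d) for d in doc["events"]]
        return DemographicScenario(
            id=str(doc["id"]),
            populations=pops,
            events=events,
            order_constraints=[tuple(c) for c in doc.get("order_constraints", [])],
            mutation=dict(doc.get("mutation", {})),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @staticmethod
    def from_json(path_or_str) -> "DemographicScenario":
        text = str(path_or_str)
        if text.lstrip().startswith("{"):
            return DemographicScenario.from_dict(json.loads(text))
        with open(path_or_str) as fh:
            return DemographicScenario.from_dict(json.load(fh))


def _event_to_dict(ev: DemographicEvent) -> dict:
    d = {"kind": ev.kind, "name": ev.name, "participants": list(ev.participants)}
    if ev.time is not None:
        d["time"] = ev.time.to_json()
    if ev.rate is not None:
        d["rate"] = ev.rate.to_json()
    if ev.nb is not None:
        d["nb"] = ev.nb.to_json()
    if ev.duration is not None:
        d["duration"] = ev.duration.to_json()
    return d


def _event_from_dict(d: dict) -> DemographicEvent:
    return DemographicEvent(
        kind=d["kind"],
        name=d["name"],
        participants=tuple(d["participants"]),
        time=Prior.of(d["time"]) if "time" in d else None,
        rate=Prior.of(d["rate"]) if "rate" in d else None,
        nb=Prior.of(d["nb"]) if "nb" in d else None,
        duration=Prior.of(d["duration"]) if "duration" in d else None,
    )


@dataclass
class ParameterDraw:
    scenario_id: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def validate_scenario(scenario: DemographicScenario) -> list[str]:
    """Structural validation; returns a list of error strings (empty = valid).

    Checks: all event participants are defined populations; each population
    is the daughter of at most one divergence; the divergence graph
    coalesces to exactly one root with no cycles; admixture rates lie in
    [0, 1] (enforced at construction); bottlenecks attach to populations
    that are founded by a divergence when their time is tied; order
    constraints are satisfiable given the priors.
    """
    errors: list[str] = []
    labels = set(scenario.pop_labels)
    if len(labels) != len(scenario.pop_labels):
        errors.append("duplicate population labels")
    names = [ev.name for ev in scenario.events]
    if len(set(names)) != len(names):
        errors.append("duplicate event names")

    for ev in scenario.events:
        for ref in ev.participants:
            if ref not in labels:
                errors.append(f"event {ev.name}: references undefined population {ref!r}")

    # divergence graph: daughter -> parent
    daughters: dict[str, str] = {}
    for ev in scenario.events:
        if ev.kind != "divergence":
            continue
        daughter, parent = ev.participants
        if daughter in daughters:
            errors.append(f"population {daughter} is daughter in two divergences")
        daughters[daughter] = parent
    roots = labels - set(daughters)
    if len(scenario.populations) > 1:
        if len(roots) != 1:
            errors.append(
                f"divergence graph must coalesce to one root; found roots {sorted(roots)}"
            )
        # cycle check
        for start in daughters:
            seen = {start}
            cur = start
            while cur in daughters:
                cur = daughters[cur]
                if cur in seen:
                    errors.append(f"divergence cycle involving {cur}")
                    break
                seen.add(cur)

    for ev in scenario.events:
        if ev.kind == "bottleneck" and ev.time is None:
            pop = ev.participants[0]
            if pop in labels and scenario.divergence_of(pop) is None:
                errors.append(
                    f"bottleneck {ev.name}: population {pop} has no divergence to tie to"
                )

    priors = scenario.parameter_priors()
    for a, b in scenario.all_constraints():
        for name in (a, b):
            if name not in priors:
                errors.append(f"order constraint references unknown parameter {name}")
        if a in priors and b in priors:
            if priors[a].high <= priors[b].low:
                errors.append(
                    f"constraint {a} > {b} unsatisfiable: "
                    f"max({a})={priors[a].high} <= min({b})={priors[b].low}"
                )
    return errors


def check_valid(scenario: DemographicScenario) -> None:
    errors = validate_scenario(scenario)
    if errors:
        raise ScenarioError(f"scenario {scenario.id}: " + "; ".join(errors))


def sample_parameters(
    scenario: DemographicScenario, rng: np.random.Generator
) -> ParameterDraw:
    """Draw one parameter vector from the priors, honouring order constraints
    by rejection resampling.  Deterministic under a fixed rng state."""
    priors = scenario.parameter_priors()
    constraints = scenario.all_constraints()
    for _ in range(MAX_REJECTION_TRIES):
        values = {name: prior.sample(rng) for name, prior in priors.items()}
        if all(values[a] > values[b] for a, b in constraints):
            return ParameterDraw(scenario.id, values)
    raise ScenarioError(
        f"scenario {scenario.id}: order constraints not satisfied after "
        f"{MAX_REJECTION_TRIES} draws (disjoint priors?)"
    )
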