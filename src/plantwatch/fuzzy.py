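"""Overlap-aware fuzzy inference engine (ELSL).

The engine implements a ratio-based fuzzy scheme — Enhanced Laser Simulator
Logic — designed for linguistic variables whose ranges overlap heavily.  A
linguistic variable is a named range ``[start, end]`` with a ``midst`` point;
membership of a crisp value is the ratio of its distance from the nearer
range endpoint to the distance spanned up to the midst,

    mu(x) = (x - s) / ((x - s) + (m - x))        for s < x < m
    mu(x) = (e - x) / ((e - x) + (x - m))        for m < x < e

which is a triangular profile when ``m`` is the interval midpoint.  When
several variables cover the same crisp value, each active variable's
*half-span* ``min(x - s_i, e_i - x)`` is normalized by the sum of all active
half-spans (the "Delta-D" normalizer), so the active memberships sum to one
exactly.  Two step functions mediate between the regimes: ``f_i`` switches
off variables whose range does not contain x, and ``N_x`` re-introduces the
``|m - x|`` term of the single-variable ratio when at most one variable is
active.  In a region covered by a single variable with midpoint midst the
normalized form reduces exactly to the ratio form above.

Rule firing is min-conjunction over the antecedent memberships; implication
anchors the firing strength into the consequent's output range,

    z_i = start_out + activation * (end_out - start_out),

and defuzzification is the arithmetic mean of the implicated values over the
rules that actually fired.  A crisp decision boundary on the output universe
(default 50, the midpoint of the overlap between the Noise and Defect output
ranges) turns the crisp output into a binary label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "LinguisticVariable",
    "VariableSet",
    "MembershipVector",
    "FuzzyRule",
    "RuleBase",
    "RuleActivation",
    "InferenceResult",
    "ELSLEngine",
    "NoRuleFired",
    "membership_single",
    "active_flags",
    "overlap_indicator",
    "delta_d",
    "membership_all",
    "fire_rules",
    "implicate",
    "defuzzify",
    "classify_output",
    "default_intensity_set",
    "default_area_set",
    "default_output_set",
    "default_rules",
    "default_engine",
    "engine_to_dict",
    "engine_from_dict",
    "load_engine",
    "save_engine",
]


class NoRuleFired(ValueError):
    """Raised when defuzzification is requested with no fired rule."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LinguisticVariable:
    """One named fuzzy range ``[start, end]`` with a ``midst`` peak.

    ``midst`` defaults to the interval midpoint, the convention used
    throughout the default configuration (symmetric profiles).
    """

    name: str
    start: float
    end: float
    midst: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.start) or not np.isfinite(self.end):
            raise ValueError(f"{self.name}: non-finite range")
        if not self.start < self.end:
            raise ValueError(
                f"{self.name}: invalid range start={self.start} end={self.end} "
                "(start must be strictly below end)"
            )
        if self.midst is None:
            object.__setattr__(self, "midst", 0.5 * (self.start + self.end))
        if not (self.start <= self.midst <= self.end):
            raise ValueError(
                f"{self.name}: midst {self.midst} outside [{self.start}, {self.end}]"
            )

    @property
    def width(self) -> float:
        return self.end - self.start

    def half_span(self, x: float) -> float:
        """min(x - start, end - x); non-negative iff x lies in the range."""
        return min(x - self.start, self.end - x)

    def is_active(self, x: float) -> bool:
        return self.half_span(x) >= 0.0


@dataclass(frozen=True)
class VariableSet:
    """Ordered, possibly overlapping linguistic variables for one quantity."""

    name: str
    variables: tuple[LinguisticVariable, ...]
    universe_low: float
    universe_high: float

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError(f"{self.name}: empty variable set")
        ordered = tuple(sorted(self.variables, key=lambda v: (v.start, v.end)))
        object.__setattr__(self, "variables", ordered)
        names = [v.name for v in ordered]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.name}: duplicate variable names {names}")
        for v in ordered:
            if v.start < self.universe_low or v.end > self.universe_high:
                raise ValueError(
                    f"{self.name}/{v.name}: range [{v.start}, {v.end}] outside "
                    f"universe [{self.universe_low}, {self.universe_high}]"
                )

    def __iter__(self) -> Iterator[LinguisticVariable]:
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> LinguisticVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"{self.name}: no variable named {name!r}")


@dataclass(frozen=True)
class MembershipVector:
    """Per-variable membership degrees aligned to a VariableSet's order."""

    set: VariableSet
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.set):
            raise ValueError("membership vector length mismatch")

    def degree(self, variable_name: str) -> float:
        return self.values[self.set.names.index(variable_name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.set.names, self.values))


@dataclass(frozen=True)
class FuzzyRule:
    """IF <one variable per input set> THEN <output variable>."""

    antecedents: Mapping[str, str]
    consequent: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedents", dict(self.antecedents))
        if not self.antecedents:
            raise ValueError("rule with no antecedents")

    def describe(self) -> str:
        cond = " and ".join(f"{k} is {v}" for k, v in self.antecedents.items())
        return f"If {cond} then {self.consequent}"


@dataclass(frozen=True)
class RuleBase:
    rules: tuple[FuzzyRule, ...]
    output_set: VariableSet

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty rule base")
        keys = [tuple(sorted(r.antecedents.items())) for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate antecedent combinations in rule base")
        for r in self.rules:
            self.output_set[r.consequent]  # raises KeyError if absent

    def validate_against(self, input_sets: Mapping[str, VariableSet]) -> None:
        for r in self.rules:
            for set_name, var_name in r.antecedents.items():
                if set_name not in input_sets:
                    raise ValueError(f"rule references unknown input set {set_name!r}")
                input_sets[set_name][var_name]


@dataclass(frozen=True)
class RuleActivation:
    rule: FuzzyRule
    activation: float

    @property
    def fired(self) -> bool:
        return self.activation > 0.0


@dataclass(frozen=True)
class InferenceResult:
    """Full audit record of one inference: memberships through crisp label."""

    inputs: dict[str, float]
    memberships: dict[str, MembershipVector]
    activations: tuple[RuleActivation, ...]
    implicated: tuple[float, ...]  # z_i, aligned with the *fired* rules
    z: float  # NaN when no rule fired
    label: str
    no_rule_fired: bool = False

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "memberships": {k: v.as_dict() for k, v in self.memberships.items()},
            "rules": [
                {
                    "rule": a.rule.describe(),
                    "activation": a.activation,
                    "fired": a.fired,
                }
                for a in self.activations
            ],
            "implicated": list(self.implicated),
            "z": None if np.isnan(self.z) else self.z,
            "label": self.label,
            "no_rule_fired": self.no_rule_fired,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# membership computation


def membership_single(x: float, var: LinguisticVariable) -> float:
    """Membership of ``x`` in one isolated linguistic variable.

    Zero at and outside the range endpoints, one at the midst, and the
    distance-ratio profile in between.
    """
    s, m, e = var.start, var.midst, var.end
    if x <= s or x >= e:
        return 0.0
    if x == m:
        return 1.0
    if x < m:
        return (x - s) / ((x - s) + (m - x))
    return (e - x) / ((e - x) + (x - m))


def active_flags(x: float, variable_set: VariableSet) -> np.ndarray:
    """Binary flag per variable: 1 iff the variable's range contains x.

    The test is ``min(x - s_i, e_i - x) >= 0``, so both endpoints count as
    inside (the zero half-span there makes the membership zero anyway).
    """
    return np.array([1 if v.is_active(x) else 0 for v in variable_set], dtype=int)


def overlap_indicator(x: float, variable_set: VariableSet) -> int:
    """1 in the low-overlap regime (at most one variable active at x), else 0.

    When two or more variables are active, memberships are normalized purely
    by the half-span sum and the ``|m - x|`` term is dropped.
    """
    return 1 if int(active_flags(x, variable_set).sum()) <= 1 else 0


def delta_d(x: float, variable_set: VariableSet) -> float:
    """Sum of half-spans over the variables active at x (the normalizer)."""
    return float(
        sum(v.half_span(x) for v in variable_set if v.is_active(x))
    )


def membership_all(x: float, variable_set: VariableSet) -> MembershipVector:
    """Memberships of x in every variable of the set, overlap-normalized.

    For each active variable ``i``::

        mu_i = half_span_i / (DeltaD + |m_i - x| * N_x)

    where ``DeltaD`` sums the active half-spans and ``N_x`` is 1 only when at
    most one variable is active.  Inactive variables get 0.  With a single
    active variable whose midst is the midpoint this reduces exactly to
    :func:`membership_single`.
    """
    dd = delta_d(x, variable_set)
    nx = overlap_indicator(x, variable_set)
    values = []
    for v in variable_set:
        if not v.is_active(x):
            values.append(0.0)
            continue
        num = v.half_span(x)
        den = dd + abs(v.midst - x) * nx
        values.append(num / den if den > 0.0 else 0.0)
    return MembershipVector(set=variable_set, values=tuple(values))


# ---------------------------------------------------------------------------
# rules, implication, defuzzification


def fire_rules(
    memberships: Mapping[str, MembershipVector], rulebase: RuleBase
) -> list[RuleActivation]:
    """Evaluate every rule; activation is the min over antecedent degrees.

    Rules with zero activation are retained in the list (flagged unfired via
    ``RuleActivation.fired``) so the audit log shows the whole rule base.
    """
    out = []
    for rule in rulebase.rules:
        degs = []
        for set_name, var_name in rule.antecedents.items():
            if set_name not in memberships:
                raise ValueError(
                    f"rule {rule.describe()!r} references input set {set_name!r} "
                    "with no membership vector supplied"
                )
            degs.append(memberships[set_name].degree(var_name))
        out.append(RuleActivation(rule=rule, activation=min(degs)))
    return out


def implicate(activation: float, output_var: LinguisticVariable) -> float:
    """Map a fired rule's activation into its consequent's output range.

    The firing strength is anchored at the consequent range's start:
    ``z_i = start + activation * (end - start)``, so a rule concluding Noise
    (range 0-60) implicates into [0, 60] and one concluding Defect (40-100)
    into [40, 100].  Only fired rules are implicated.
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation {activation} outside [0, 1]")
    return output_var.start + activation * output_var.width


def defuzzify(implicated: Sequence[float]) -> float:
    """Arithmetic mean of the implicated values over the fired rules."""
    if len(implicated) == 0:
        raise NoRuleFired("no rule fired; no crisp output")
    return float(sum(implicated)) / len(implicated)


def classify_output(
    z: float, output_set: VariableSet, boundary: float = 50.0
) -> str:
    """Binary label from the crisp output: first output variable below the
    boundary, second at or above it (ties go to the second, i.e. Defect)."""
    if z < output_set.universe_low or z > output_set.universe_high:
        raise ValueError(
            f"crisp output {z} outside universe "
            f"[{output_set.universe_low}, {output_set.universe_high}]"
        )
    if len(output_set) != 2:
        raise ValueError("binary classification requires exactly two output variables")
    low_label, high_label = output_set.names
    return high_label if z >= boundary else low_label


# ---------------------------------------------------------------------------
# engine


@dataclass(frozen=True)
class ELSLEngine:
    """Complete inference engine: input sets, rule base, decision boundary."""

    input_sets: tuple[VariableSet, ...]
    rulebase: RuleBase
    decision_boundary: float = 50.0

    def __post_init__(self) -> None:
        self.rulebase.validate_against(self.inputs_by_name)

    @property
    def inputs_by_name(self) -> dict[str, VariableSet]:
        return {s.name: s for s in self.input_sets}

    @property
    def output_set(self) -> VariableSet:
        return self.rulebase.output_set

    def memberships(self, crisp: Mapping[str, float]) -> dict[str, MembershipVector]:
        sets = self.inputs_by_name
        missing = set(sets) - set(crisp)
        if missing:
            raise ValueError(f"missing crisp inputs for sets: {sorted(missing)}")
        return {name: membership_all(crisp[name], sets[name]) for name in sets}

    def infer(self, crisp: Mapping[str, float]) -> InferenceResult:
        """Run the full chain: fuzzify, fire, implicate, defuzzify, label.

        When no rule fires the result carries ``z = NaN`` and the label of
        the first output variable (Noise) — the conservative default: no
        evidence, no actuation.
        """
        mvs = self.memberships(crisp)
        activations = tuple(fire_rules(mvs, self.rulebase))
        fired = [a for a in activations if a.fired]
        implicated = tuple(
            implicate(a.activation, self.output_set[a.rule.consequent]) for a in fired
        )
        if not fired:
            return InferenceResult(
                inputs=dict(crisp),
                memberships=mvs,
                activations=activations,
                implicated=(),
                z=float("nan"),
                label=self.output_set.names[0],
                no_rule_fired=True,
            )
        z = defuzzify(implicated)
        label = classify_output(z, self.output_set, self.decision_boundary)
        return InferenceResult(
            inputs=dict(crisp),
            memberships=mvs,
            activations=activations,
            implicated=implicated,
            z=z,
            label=label,
        )


# ---------------------------------------------------------------------------
# defaults: the shipped linguistic ranges and rule base
#
# Intensity is the spot-vs-image intensity difference as a 0-1 ratio; Area is
# the spot's pixel count; the output universe is a 0-100 "spot state" score
# with Noise covering 0-60 and Defect 40-100 (decision boundary 50, the
# midpoint of the overlap).


def default_intensity_set() -> VariableSet:
    return VariableSet(
        name="Intensity",
        variables=(
            LinguisticVariable("Low", 0.0, 0.45),
            LinguisticVariable("Medium", 0.2, 0.8),
            LinguisticVariable("High", 0.55, 1.0),
        ),
        universe_low=0.0,
        universe_high=1.0,
    )


def default_area_set() -> VariableSet:
    return VariableSet(
        name="Area",
        variables=(
            LinguisticVariable("Small", 0.0, 2000.0),
            LinguisticVariable("Medium", 800.0, 5000.0),
            LinguisticVariable("Big", 3200.0, 12000.0),
        ),
        universe_low=0.0,
        universe_high=12000.0,
    )


def default_output_set() -> VariableSet:
    return VariableSet(
        name="SpotState",
        variables=(
            LinguisticVariable("Noise", 0.0, 60.0),
            LinguisticVariable("Defect", 40.0, 100.0),
        ),
        universe_low=0.0,
        universe_high=100.0,
    )


def default_rules(output_set: VariableSet | None = None) -> RuleBase:
    """The six shipped rules mapping (Intensity, Area) onto the spot state."""
    out = output_set or default_output_set()
    mk = lambda i, a, c: FuzzyRule({"Intensity": i, "Area": a}, c)  # noqa: E731
    return RuleBase(
        rules=(
            mk("Low", "Small", "Noise"),
            mk("Low", "Big", "Noise"),
            mk("Medium", "Small", "Noise"),
            mk("Medium", "Medium", "Defect"),
            mk("High", "Medium", "Defect"),
            mk("High", "Big", "Defect"),
        ),
        output_set=out,
    )


def default_engine() -> ELSLEngine:
    return ELSLEngine(
        input_sets=(default_intensity_set(), default_area_set()),
        rulebase=default_rules(),
        decision_boundary=50.0,
    )


# ---------------------------------------------------------------------------
# plain-text configuration (YAML; JSON is a YAML subset)


def _set_to_dict(s: VariableSet) -> dict:
    return {
        "name": s.name,
        "universe": [s.universe_low, s.universe_high],
        "variables": [
            {"name": v.name, "start": v.start, "end": v.end, "midst": v.midst}
            for v in s.variables
        ],
    }


def _set_from_dict(d: Mapping) -> VariableSet:
    lo, hi = d["universe"]
    return VariableSet(
        name=d["name"],
        variables=tuple(
            LinguisticVariable(
                v["name"], float(v["start"]), float(v["end"]),
                float(v["midst"]) if v.get("midst") is not None else None,
            )
            for v in d["variables"]
        ),
        universe_low=float(lo),
        universe_high=float(hi),
    )


def engine_to_dict(engine: ELSLEngine) -> dict:
    return {
        "inputs": [_set_to_dict(s) for s in engine.input_sets],
        "output": _set_to_dict(engine.output_set),
        "rules": [
            {"if": dict(r.antecedents), "then": r.consequent}
            for r in engine.rulebase.rules
        ],
        "decision_boundary": engine.decision_boundary,
    }


def engine_from_dict(d: Mapping) -> ELSLEngine:
    output = _set_from_dict(d["output"])
    rules = RuleBase(
        rules=tuple(
            FuzzyRule({k: v for k, v in r["if"].items()}, r["then"])
            for r in d["rules"]
        ),
        output_set=output,
    )
    return ELSLEngine(
        input_sets=tuple(_set_from_dict(s) for s in d["inputs"]),
        rulebase=rules,
        decision_boundary=float(d.get("decision_boundary", 50.0)),
    )


def load_engine(path) -> ELSLEngine:
    with open(path) as fh:
        return engine_from_dict(yaml.safe_load(fh))


def save_engine(engine: ELSLEngine, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(engine_to_dict(engine), fh, sort_keys=False)
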