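"""Sensor-side computation: pass-filter gates, stream cleaning, actuation.

Three threshold gates mirror the greenhouse controller's decision logic:

* soil moisture — low-pass: a reading passes when it is at or below 20 %
  (a passing reading means "soil is dry, water it");
* CO2 — high-pass: a reading passes at or above 50 ppm ("air is stale,
  ventilate");
* temperature — band-pass: a reading passes inside 12-15 degC (a status
  check only; no actuator is wired to it).

A gate either passes the raw value through or replaces it with zero, and the
pump/fan decisions flip exactly at the printed thresholds.  Missing or
physically impossible samples never actuate anything (fail-safe OFF).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CHANNELS",
    "SensorReading",
    "GateOutput",
    "ActuationDecision",
    "Thresholds",
    "CleanedStream",
    "MonitorResult",
    "moisture_gate",
    "co2_gate",
    "temperature_gate",
    "clean_stream",
    "decide_pump",
    "decide_fan",
    "monitor_stream",
    "read_stream_csv",
    "read_stream_jsonl",
    "write_actuation_log",
]

logger = logging.getLogger(__name__)

CHANNELS = ("moisture", "co2", "temperature", "humidity")

#: physical plausibility bounds per channel (inclusive)
_PHYSICAL_RANGE = {
    "moisture": (0.0, 100.0),
    "humidity": (0.0, 100.0),
    "co2": (0.0, float("inf")),
    "temperature": (-50.0, 100.0),
}


@dataclass(frozen=True)
class SensorReading:
    """One sample from one channel; ``valid=False`` marks a missing sample."""

    channel: str
    timestamp: float
    value: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    def in_physical_range(self) -> bool:
        lo, hi = _PHYSICAL_RANGE[self.channel]
        return self.valid and lo <= self.value <= hi


@dataclass(frozen=True)
class GateOutput:
    channel: str
    passed_value: float
    suppressed: bool
    reason: str | None = None  # "threshold" or "missing" when suppressed


@dataclass(frozen=True)
class Thresholds:
    """Gate thresholds; defaults are the controller's printed values."""

    moisture_max_pct: float = 20.0
    co2_min_ppm: float = 50.0
    temp_low_c: float = 12.0
    temp_high_c: float = 15.0


@dataclass(frozen=True)
class ActuationDecision:
    device: str  # water_pump | exhaust_fan | pesticide_pump
    state: bool  # True = ON
    timestamp: float | None
    trigger: str  # human-readable trigger description

    def to_dict(self) -> dict:
        return {
            "device": self.device,
            "state": "on" if self.state else "off",
            "timestamp": self.timestamp,
            "trigger": self.trigger,
        }


def _gated(reading_or_value, channel: str) -> tuple[float, bool]:
    """Return (value, is_missing) accepting either a raw number or a reading."""
    if isinstance(reading_or_value, SensorReading):
        if reading_or_value.channel != channel:
            raise ValueError(
                f"expected a {channel} reading, got {reading_or_value.channel}"
            )
        return reading_or_value.value, not reading_or_value.valid
    return float(reading_or_value), False


def moisture_gate(x, thresholds: Thresholds = Thresholds()) -> GateOutput:
    """Low-pass gate: pass x when x <= 20 % (inclusive), else 0."""
    value, missing = _gated(x, "moisture")
    if missing:
        return GateOutput("moisture", 0.0, True, "missing")
    if value <= thresholds.moisture_max_pct:
        return GateOutput("moisture", value, False)
    return GateOutput("moisture", 0.0, True, "threshold")


def co2_gate(x, thresholds: Thresholds = Thresholds()) -> GateOutput:
    """High-pass gate: pass x when x >= 50 ppm (inclusive), else 0."""
    value, missing = _gated(x, "co2")
    if missing:
        return GateOutput("co2", 0.0, True, "missing")
    if value >= thresholds.co2_min_ppm:
        return GateOutput("co2", value, False)
    return GateOutput("co2", 0.0, True, "threshold")


def temperature_gate(x, thresholds: Thresholds = Thresholds()) -> GateOutput:
    """Band-pass gate: pass x inside [12, 15] degC (inclusive), else 0."""
    value, missing = _gated(x, "temperature")
    if missing:
        return GateOutput("temperature", 0.0, True, "missing")
    if thresholds.temp_low_c <= value <= thresholds.temp_high_c:
        return GateOutput("temperature", value, False)
    return GateOutput("temperature", 0.0, True, "threshold")


@dataclass(frozen=True)
class CleanedStream:
    readings: tuple[SensorReading, ...]
    n_input: int
    n_dropped: int


def clean_stream(readings: Sequence[SensorReading]) -> CleanedStream:
    """Drop missing samples and physically impossible values.

    Output preserves order; timestamps are a subset of the input's.  An
    empty input yields an empty output with a logged warning.
    """
    readings = list(readings)
    if not readings:
        logger.warning("clean_stream: empty input stream")
        return CleanedStream((), 0, 0)
    kept = tuple(r for r in readings if r.in_physical_range())
    return CleanedStream(kept, len(readings), len(readings) - len(kept))


def decide_pump(gate: GateOutput, timestamp: float | None = None) -> ActuationDecision:
    """Water pump ON iff the moisture gate passed (dry soil regime)."""
    if gate.channel != "moisture":
        raise ValueError("decide_pump expects a moisture gate output")
    on = not gate.suppressed
    trigger = (
        f"moisture={gate.passed_value:g}% passed low-pass gate"
        if on
        else f"moisture gate suppressed ({gate.reason})"
    )
    return ActuationDecision("water_pump", on, timestamp, trigger)


def decide_fan(gate: GateOutput, timestamp: float | None = None) -> ActuationDecision:
    """Exhaust fan ON iff the CO2 gate passed (stale-air regime)."""
    if gate.channel != "co2":
        raise ValueError("decide_fan expects a co2 gate output")
    on = not gate.suppressed
    trigger = (
        f"co2={gate.passed_value:g}ppm passed high-pass gate"
        if on
        else f"co2 gate suppressed ({gate.reason})"
    )
    return ActuationDecision("exhaust_fan", on, timestamp, trigger)


@dataclass
class MonitorResult:
    """One monitoring pass over a stream: cleaning stats, gates, decisions."""

    cleaned: CleanedStream
    gates: list[GateOutput] = field(default_factory=list)
    decisions: list[ActuationDecision] = field(default_factory=list)
    temperature_status: list[dict] = field(default_factory=list)


def monitor_stream(
    readings: Sequence[SensorReading], thresholds: Thresholds = Thresholds()
) -> MonitorResult:
    """Evaluate gates and actuation once per cleaned reading.

    Moisture readings drive the water pump, CO2 readings the exhaust fan;
    temperature readings yield a healthy/unhealthy band status; humidity is
    carried through and logged but drives no decision.
    """
    cleaned = clean_stream(readings)
    result = MonitorResult(cleaned=cleaned)
    for r in cleaned.readings:
        if r.channel == "moisture":
            g = moisture_gate(r, thresholds)
            result.gates.append(g)
            result.decisions.append(decide_pump(g, r.timestamp))
        elif r.channel == "co2":
            g = co2_gate(r, thresholds)
            result.gates.append(g)
            result.decisions.append(decide_fan(g, r.timestamp))
        elif r.channel == "temperature":
            g = temperature_gate(r, thresholds)
            result.gates.append(g)
            result.temperature_status.append(
                {
                    "timestamp": r.timestamp,
                    "value": r.value,
                    "healthy_band": not g.suppressed,
                }
            )
    return result


# ---------------------------------------------------------------------------
# stream and log I/O


def _reading_from_row(channel, timestamp, value) -> SensorReading:
    valid = pd.notna(value)
    return SensorReading(
        channel=str(channel),
        timestamp=float(timestamp),
        value=float(value) if valid else float("nan"),
        valid=bool(valid),
    )


def read_stream_csv(path) -> list[SensorReading]:
    """Read a sensor stream CSV with columns timestamp, channel, value.

    Empty value cells become missing samples (``valid=False``).
    """
    df = pd.read_csv(path)
    required = {"timestamp", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"stream CSV must have columns {sorted(required)}")
    return [
        _reading_from_row(row.channel, row.timestamp, row.value)
        for row in df.itertuples()
    ]


def read_stream_jsonl(path) -> list[SensorReading]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(_reading_from_row(d["channel"], d["timestamp"], d.get("value")))
    return out


def write_actuation_log(decisions: Iterable[ActuationDecision], path) -> None:
    """Write actuation decisions as JSON lines (the IoT-report stand-in)."""
    path = Path(path)
    with path.open("w") as fh:
        for d in decisions:
            fh.write(json.dumps(d.to_dict()) + "\n")
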