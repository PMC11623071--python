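"""Bundled benchmark data: the twenty manually scored detection trials.

Each trial records whether pests were really present on the inspected leaves
(``real``) and whether the detection pipeline called pests (``detected``),
both binary.  Frame-level agreement over these twenty trials is the
package's benchmark detection metric (75 %).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TrialRecord", "BENCHMARK_REAL", "BENCHMARK_DETECTED", "benchmark_trials"]


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    real_pest: int
    detected_pest: int

    def __post_init__(self) -> None:
        if self.real_pest not in (0, 1) or self.detected_pest not in (0, 1):
            raise ValueError("trial entries must be binary")


BENCHMARK_REAL = (0, 1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 0, 1, 1, 1, 1, 1, 1, 0, 1)
BENCHMARK_DETECTED = (1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1)


def benchmark_trials() -> list[TrialRecord]:
    """The bundled twenty-trial benchmark table."""
    return [
        TrialRecord(i + 1, r, d)
        for i, (r, d) in enumerate(zip(BENCHMARK_REAL, BENCHMARK_DETECTED))
    ]
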