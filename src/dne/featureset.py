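"""Named scalar feature collections produced by the per-test extractors.

A feature that cannot be computed (too few movement cycles, constant signal,
degenerate geometry) is stored as NaN — the *undefined marker* — and written to
feature tables as a missing cell, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .skeleton import Test

UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return x is not None and not math.isnan(x)


@dataclass
class FeatureSet:
    """Ordered name -> value map for one recording of one test."""

    test: Test
    values: dict[str, float] = field(default_factory=dict)
    subject_id: str = ""
    label: str = "unknown"
    device: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def names(self) -> list[str]:
        return list(self.values.keys())

    def set(self, name: str, value: float | None) -> None:
        self.values[name] = UNDEFINED if value is None else float(value)

    def set_summary(self, prefix: str, stats, which=("mean", "std", "median")) -> None:
        """Store SummaryStats fields under ``prefix.mean`` etc."""
        for w in which:
            self.set(f"{prefix}.{w}", getattr(stats, w))
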