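"""Fetal biometry container.

A scan's standard biometry consists of up to four measurements, all in
millimetres: biparietal diameter (BPD), head circumference (HC), abdominal
circumference (AC) and femur length (FL).  Trans-cerebellar diameter is not
part of standard biometry in most low-resource settings and is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterator, Optional

MEASUREMENTS = ("bpd", "hc", "ac", "fl")


@dataclass(frozen=True)
class BiometrySet:
    """One scan's fetal biometry, in millimetres.

    At least one measurement must be present; present values must be
    strictly positive and head circumference must exceed biparietal
    diameter whenever both are recorded.
    """

    bpd: Optional[float] = None
    hc: Optional[float] = None
    ac: Optional[float] = None
    fl: Optional[float] = None

    def __post_init__(self) -> None:
        present = [f.name for f in fields(self) if getattr(self, f.name) is not None]
        if not present:
            raise ValueError("BiometrySet requires at least one measurement")
        for name in present:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"measurement {name!r} must be strictly positive, got {value}")
        if self.hc is not None and self.bpd is not None and not self.hc > self.bpd:
            raise ValueError(
                f"head circumference ({self.hc} mm) must exceed "
                f"biparietal diameter ({self.bpd} mm)"
            )

    def present(self) -> tuple[str, ...]:
        """Names of the measurements that are recorded on this scan."""
        return tuple(m for m in MEASUREMENTS if getattr(self, m) is not None)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.present()}

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())

    def scaled(self, multipliers: dict[str, float]) -> "BiometrySet":
        """Return a copy with each present measurement multiplied.

        Measurements without an entry in ``multipliers`` are unchanged.
        """
        values = {m: v * multipliers.get(m, 1.0) for m, v in self.items()}
        return BiometrySet(**values)
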