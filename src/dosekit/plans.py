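"""Treatment-plan beam settings.

A :class:`PlanSpec` carries the beam configuration of one coplanar IMRT
plan: gantry angles, isocenter, prescription dose, patient position and
source-axis distance (SAD).  Gantry angles follow IEC 61217: 0 deg places
the source anterior to a supine patient and angles increase clockwise when
viewed from the foot of the couch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: clinical 7-field cervical arrangement used as the homogeneous reference set
REFERENCE_7_ANGLES = (0.0, 50.0, 100.0, 150.0, 210.0, 260.0, 310.0)

#: standard linac source-axis distance, mm
DEFAULT_SAD_MM = 1000.0

#: prescription for the emulated cervical protocol: 50.4 Gy in 28 fractions
DEFAULT_PRESCRIPTION_GY = 50.4


@dataclass(frozen=True)
class PlanSpec:
    """Beam settings of one coplanar plan.

    Attributes
    ----------
    angles
        Gantry angles in degrees, each in ``[0, 360)``.
    isocenter
        Isocenter position, mm, patient (LPS) coordinates.
    prescription_gy
        PTV prescription dose in Gy; must be positive.
    position
        Patient setup, ``"supine"`` or ``"prone"``.
    sad_mm
        Source-axis distance in mm; must be positive.
    noncoplanar
        Set by readers when any beam has a nonzero couch angle.
    """

    angles: tuple[float, ...]
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY
    position: str = "supine"
    sad_mm: float = DEFAULT_SAD_MM
    noncoplanar: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "angles", tuple(float(a) % 360.0 for a in self.angles)
        )
        object.__setattr__(self, "isocenter", tuple(float(v) for v in self.isocenter))
        if len(self.angles) == 0:
            raise ValueError("plan must have at least one beam")
        if self.prescription_gy <= 0:
            raise ValueError("prescription dose must be positive")
        if self.sad_mm <= 0:
            raise ValueError("SAD must be positive")
        if self.position not in ("supine", "prone"):
            raise ValueError(f"position must be supine|prone, got {self.position!r}")

    @property
    def beam_count(self) -> int:
        return len(self.angles)

    def sorted_angles(self) -> tuple[float, ...]:
        return tuple(sorted(self.angles))

    def to_dict(self) -> dict:
        return {
            "angles": list(self.angles),
            "isocenter": list(self.isocenter),
            "prescription_gy": self.prescription_gy,
            "position": self.position,
            "sad_mm": self.sad_mm,
            "noncoplanar": self.noncoplanar,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlanSpec":
        return cls(
            angles=tuple(d["angles"]),
            isocenter=tuple(d.get("isocenter", (0.0, 0.0, 0.0))),
            prescription_gy=float(d.get("prescription_gy", DEFAULT_PRESCRIPTION_GY)),
            position=d.get("position", "supine"),
            sad_mm=float(d.get("sad_mm", DEFAULT_SAD_MM)),
            noncoplanar=bool(d.get("noncoplanar", False)),
        )
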