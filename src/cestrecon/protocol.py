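"""Acquisition protocol: the saturation pulse and the scanner field.

Defaults reproduce the continuous-wave protocol used throughout this
package: B1 = 1.2 uT for 1,500 ms at 7 T.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GAMMA_H", "SaturationPulse", "ScannerConfig"]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8


@dataclass(frozen=True)
class SaturationPulse:
    """Continuous-wave RF saturation of amplitude ``b1_uT`` (uT) and
    duration ``duration_s`` (s)."""

    b1_uT: float = 1.2
    duration_s: float = 1.5
    shape: str = "cw"

    def __post_init__(self) -> None:
        if self.shape != "cw":
            raise ValueError(f"only continuous-wave saturation is supported, got {self.shape!r}")
        if not (self.b1_uT > 0 and self.duration_s > 0):
            raise ValueError("b1_uT and duration_s must be positive")

    @property
    def omega1_rad_s(self) -> float:
        """RF nutation frequency omega_1 = gamma * B1 in rad/s."""
        return GAMMA_H * self.b1_uT * 1e-6


@dataclass(frozen=True)
class ScannerConfig:
    """Static field configuration; converts chemical-shift ppm to rad/s."""

    b0_T: float = 7.0
    gamma_rad_per_s_per_T: float = GAMMA_H

    def __post_init__(self) -> None:
        if not self.b0_T > 0:
            raise ValueError("b0_T must be positive")
        if not self.ppm_to_rad_s > 0:
            raise ValueError("ppm -> rad/s conversion must be positive")

    @property
    def ppm_to_rad_s(self) -> float:
        """Angular frequency (rad/s) of a 1 ppm shift at this field."""
        return self.gamma_rad_per_s_per_T * self.b0_T * 1e-6
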