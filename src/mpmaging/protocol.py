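"""Acquisition protocol description for the multiparameter-mapping (MPM) FLASH protocol.

The MPM protocol consists of three spoiled multi-echo 3D FLASH acquisitions with
predominant proton-density (PDw), T1 (T1w) and magnetization-transfer (MTw)
weighting, set apart by repetition time, flip angle and (for MTw) an
off-resonance pre-pulse.  Times are stored in milliseconds in configuration
(matching scanner console conventions) and converted to seconds at compute time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = ["MTPulse", "WeightingProtocol", "AcquisitionProtocol", "default_protocol"]

MS = 1e-3  # ms -> s


@dataclass(frozen=True)
class MTPulse:
    """Off-resonance magnetization-transfer pre-pulse descriptor."""

    duration_ms: float = 4.0
    nominal_flip_deg: float = 220.0
    offset_khz: float = 2.0


@dataclass(frozen=True)
class WeightingProtocol:
    """One FLASH acquisition: repetition time, nominal excitation flip, echo train."""

    name: str
    tr_ms: float
    flip_deg: float
    te_ms: tuple[float, ...]
    mt_pulse: MTPulse | None = None

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.flip_deg <= 0:
            raise ValueError(f"{self.name}: TR and flip angle must be positive")
        if len(self.te_ms) < 1 or any(t <= 0 for t in self.te_ms):
            raise ValueError(f"{self.name}: echo times must be positive")
        if any(b <= a for a, b in zip(self.te_ms, self.te_ms[1:])):
            raise ValueError(f"{self.name}: echo times must be strictly increasing")

    @property
    def tr_s(self) -> float:
        return self.tr_ms * MS

    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip_deg)

    @property
    def te_s(self) -> tuple[float, ...]:
        return tuple(t * MS for t in self.te_ms)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """The three-weighting MPM protocol (PDw, T1w, MTw)."""

    pdw: WeightingProtocol
    t1w: WeightingProtocol
    mtw: WeightingProtocol

    def __post_init__(self) -> None:
        if (self.pdw.tr_ms, self.pdw.flip_deg) != (self.mtw.tr_ms, self.mtw.flip_deg):
            raise ValueError("PDw and MTw acquisitions must share TR and flip angle")
        if self.mtw.mt_pulse is None:
            raise ValueError("MTw acquisition requires an MT pre-pulse descriptor")

    @property
    def weightings(self) -> dict[str, WeightingProtocol]:
        return {"pdw": self.pdw, "t1w": self.t1w, "mtw": self.mtw}

    def common_echoes_ms(self) -> tuple[float, ...]:
        """Echo times shared by all three weightings (the common prefix)."""
        n = min(len(w.te_ms) for w in self.weightings.values())
        pd = self.pdw.te_ms[:n]
        for w in (self.t1w, self.mtw):
            if w.te_ms[:n] != pd:
                raise ValueError("weightings do not share a common echo-time prefix")
        return pd

    def to_dict(self) -> dict:
        return asdict(self)


# Six equidistant echoes between 2.2 and 14.7 ms; the PD-weighted acquisition
# adds two further echoes at 17.2 and 19.7 ms used only for the R2* fit.
_COMMON_ECHOES = tuple(round(2.2 + i * 2.5, 1) for i in range(6))
_PDW_ECHOES = _COMMON_ECHOES + (17.2, 19.7)


def default_protocol() -> AcquisitionProtocol:
    """The 3T MPM protocol: PDw/MTw at 23.7 ms / 6 deg, T1w at 18.7 ms / 20 deg."""
    return AcquisitionProtocol(
        pdw=WeightingProtocol("pdw", tr_ms=23.7, flip_deg=6.0, te_ms=_PDW_ECHOES),
        t1w=WeightingProtocol("t1w", tr_ms=18.7, flip_deg=20.0, te_ms=_COMMON_ECHOES),
        mtw=WeightingProtocol(
            "mtw", tr_ms=23.7, flip_deg=6.0, te_ms=_COMMON_ECHOES, mt_pulse=MTPulse()
        ),
    )
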