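"""Shared domain types, physical constants and protocol presets.

Units are fixed package-wide: times in nanoseconds, energies in
kcal/mol, temperatures in kelvin, volumes in cubic angstroms.
Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_VOLUME_A3",
    "GradientSeries",
    "ProtocolConfig",
    "ThermoConstants",
    "protocol_preset",
    "dg_from_kd",
    "PROTOCOL_PRESETS",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98720425864083e-3

#: Volume per molecule at the 1 M standard state, in A^3.
STANDARD_VOLUME_A3 = 1660.5392


@dataclass(frozen=True)
class ThermoConstants:
    """Thermodynamic constants used by analytic free energy terms.

    Attributes
    ----------
    R : float
        Gas constant, kcal/(mol K).
    T : float
        Absolute temperature, K.
    V_std : float
        Standard-state volume per molecule, A^3 (1660.5392 for 1 M).
    """

    R: float = GAS_CONSTANT_KCAL
    T: float = 300.0
    V_std: float = STANDARD_VOLUME_A3

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0 or self.V_std <= 0:
            raise ValueError("R, T and V_std must all be positive")

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.R * self.T


@dataclass(frozen=True)
class GradientSeries:
    """One lambda-window's dV/dlambda time series with uniform sampling.

    Attributes
    ----------
    lambda_value : float
        Coupling parameter of the window, in [0, 1].
    sampling_interval : float
        Spacing between consecutive samples, ns.
    values : np.ndarray
        dV/dlambda samples, kcal/mol.
    start_time : float
        Time of the first sample, ns.
    label : str
        Free-text identifier (window / step / replicate).
    """

    lambda_value: float
    sampling_interval: float
    values: np.ndarray
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not 0.0 <= self.lambda_value <= 1.0:
            raise ValueError(f"lambda_value must lie in [0, 1], got {self.lambda_value}")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Total time spanned by the samples, ns."""
        return len(self) * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        """Sample times in ns (strictly increasing); sample i closes the
        i-th sampling interval, so the first sample sits at
        start_time + sampling_interval."""
        return self.start_time + self.sampling_interval * np.arange(1, len(self) + 1)

    def truncated(self, max_time: float) -> "GradientSeries":
        """Return the prefix of the series whose times are <= ``max_time`` ns."""
        n = int(np.searchsorted(self.times, max_time, side="right"))
        return replace(self, values=self.values[:n])

    def extended(self, new_values: np.ndarray) -> "GradientSeries":
        """Return a copy with ``new_values`` appended."""
        return replace(self, values=np.concatenate([self.values, np.asarray(new_values, float)]))


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of one on-the-fly resource-allocation protocol.

    ``initial_length`` is the first production block per window;
    ``additional_length`` the fixed extension applied whenever the
    convergence test asks for more sampling. Sampling stops early once
    the Jensen-Shannon distance between the two chronological halves of
    the decorrelated gradient series drops to ``js_threshold`` with at
    least ``min_decorrelated`` decorrelated samples, and unconditionally
    at the soft cap (given more than ``min_decorrelated`` samples) or
    the hard cap.
    """

    name: str
    initial_length: float
    additional_length: float
    n_windows: int
    js_threshold: float = 0.1
    min_decorrelated: int = 50
    soft_cap: float = 6.5
    hard_cap: float = 10.5
    n_bins: int = 7

    def __post_init__(self) -> None:
        if not (0 < self.additional_length <= self.initial_length <= self.soft_cap <= self.hard_cap):
            raise ValueError(
                "require 0 < additional_length <= initial_length <= soft_cap <= hard_cap, got "
                f"{self.additional_length}, {self.initial_length}, {self.soft_cap}, {self.hard_cap}"
            )
        if not 0 < self.js_threshold < 1:
            raise ValueError("js_threshold must lie in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.min_decorrelated < 2:
            raise ValueError("min_decorrelated must be at least 2")


PROTOCOL_PRESETS: dict[str, ProtocolConfig] = {
    "A": ProtocolConfig("A", 2.5, 0.5, 9),
    "B": ProtocolConfig("B", 1.5, 0.5, 9),
    "C": ProtocolConfig("C", 1.0, 0.25, 9),
    "D": ProtocolConfig("D", 0.5, 0.25, 9),
    "E": ProtocolConfig("E", 3.5, 0.5, 9),
    "C12": ProtocolConfig("C12", 1.0, 0.25, 12),
}


def protocol_preset(name: str) -> ProtocolConfig:
    """Return the named resource-allocation protocol preset.

    Presets A-E use the 9-window Gauss-Legendre schedule and differ
    only in initial/additional block lengths; C12 is protocol C on the
    12-window schedule. Fields the presets do not vary keep the shared
    defaults (JS threshold 0.1, 50 decorrelated samples, 6.5/10.5 ns
    caps, 7 histogram bins).
    """
    key = name.strip().upper()
    if key not in PROTOCOL_PRESETS:
        valid = ", ".join(sorted(PROTOCOL_PRESETS))
        raise KeyError(f"unknown protocol {name!r}; valid presets: {valid}")
    return PROTOCOL_PRESETS[key]


def dg_from_kd(kd: float, tc: ThermoConstants | None = None) -> float:
    """Standard binding free energy from a dissociation constant.

    Parameters
    ----------
    kd : float
        Dissociation constant in molar units; must be positive.
    tc : ThermoConstants, optional
        Constants to use; defaults to R in kcal/(mol K) at 300 K.

    Returns
    -------
    float
        Delta-G_bind = R*T*ln(Kd), kcal/mol (negative for sub-molar Kd).
    """
    if kd <= 0:
        raise ValueError(f"dissociation constant must be positive, got {kd}")
    tc = tc or ThermoConstants()
    return tc.RT * math.log(kd)
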