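"""Acquisition protocols for b(omega)-tau_R-tau_E encoded measurements.

A measurement ("row") is characterized by the trace ``b`` of its encoding
tensor, the normalized encoding anisotropy ``b_delta`` (-0.5 planar, 0
spherical, 1 linear), the orientation of the encoding symmetry axis
(``theta``, ``phi``; physics convention, polar angle from +z), the centroid
angular frequency ``omega`` of the encoding spectrum, the recovery time
``tau_r`` and the echo time ``tau_e``.  Frequencies are carried internally in
rad/s; files and reports use omega/2pi in Hz.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

#: canonical TSV header (SI units); alternate unit tags handled on read
_TSV_COLUMNS = {
    "b[s/m^2]": ("b", 1.0),
    "b_delta": ("b_delta", 1.0),
    "theta[rad]": ("theta", 1.0),
    "theta[deg]": ("theta", np.pi / 180.0),
    "phi[rad]": ("phi", 1.0),
    "phi[deg]": ("phi", np.pi / 180.0),
    "omega_cent[Hz]": ("omega_hz", 1.0),
    "tau_r[s]": ("tau_r", 1.0),
    "tau_r[ms]": ("tau_r", 1e-3),
    "tau_e[s]": ("tau_e", 1.0),
    "tau_e[ms]": ("tau_e", 1e-3),
}


@dataclass(frozen=True)
class AcquisitionRow:
    """One measurement's encoding parameters (SI units, omega in rad/s)."""

    b: float
    b_delta: float
    theta: float
    phi: float
    omega: float
    tau_r: float
    tau_e: float

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if not -0.5 <= self.b_delta <= 1.0:
            raise ValueError(f"b_delta must be in [-0.5, 1], got {self.b_delta}")
        if self.tau_r <= 0:
            raise ValueError(f"tau_r must be > 0, got {self.tau_r}")
        if self.tau_e < 0:
            raise ValueError(f"tau_e must be >= 0, got {self.tau_e}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")


class Protocol:
    """Ordered collection of acquisition rows, stored as column arrays.

    Parameters
    ----------
    b, b_delta, theta, phi, omega, tau_r, tau_e : array-like, shape (n_rows,)
        Per-row encoding parameters; ``omega`` is the centroid angular
        frequency in rad/s.
    name : str
        Free-text label.
    """

    _FIELDS = ("b", "b_delta", "theta", "phi", "omega", "tau_r", "tau_e")

    def __init__(self, b, b_delta, theta, phi, omega, tau_r, tau_e,
                 name: str = "protocol"):
        arrays = [np.atleast_1d(np.asarray(a, dtype=float))
                  for a in (b, b_delta, theta, phi, omega, tau_r, tau_e)]
        n = len(arrays[0])
        if n < 1:
            raise ValueError("protocol needs at least one row")
        if any(len(a) != n for a in arrays):
            raise ValueError("all protocol columns must have equal length")
        self.b, self.b_delta, self.theta, self.phi, self.omega, \
            self.tau_r, self.tau_e = arrays
        self.name = name
        self._validate()

    def _validate(self) -> None:
        if np.any(self.b < 0):
            raise ValueError("b must be >= 0")
        if np.any((self.b_delta < -0.5) | (self.b_delta > 1.0)):
            raise ValueError("b_delta must be in [-0.5, 1]")
        if np.any(self.tau_r <= 0):
            raise ValueError("tau_r must be > 0")
        if np.any(self.tau_e < 0):
            raise ValueError("tau_e must be >= 0")
        if np.any(self.omega < 0):
            raise ValueError("omega must be >= 0")

    def __len__(self) -> int:
        return len(self.b)

    def __getitem__(self, idx) -> "Protocol":
        """Row subset (used by bootstrap resampling)."""
        return Protocol(*(getattr(self, f)[idx] for f in self._FIELDS),
                        name=self.name)

    def row(self, i: int) -> AcquisitionRow:
        return AcquisitionRow(*(float(getattr(self, f)[i]) for f in self._FIELDS))

    @property
    def omega_hz(self) -> np.ndarray:
        return self.omega / TWO_PI

    @property
    def frequency_window(self) -> tuple[float, float]:
        """(omega_min, omega_max) in rad/s: 10th-90th percentile of rows."""
        lo, hi = np.percentile(self.omega, [10, 90])
        return float(lo), float(hi)

    # ------------------------------------------------------------------ I/O

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "b[s/m^2]": self.b,
            "b_delta": self.b_delta,
            "theta[rad]": self.theta,
            "phi[rad]": self.phi,
            "omega_cent[Hz]": self.omega_hz,
            "tau_r[s]": self.tau_r,
            "tau_e[s]": self.tau_e,
        })

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "protocol") -> "Protocol":
        cols: dict[str, np.ndarray] = {}
        for col in df.columns:
            key = col.strip()
            if key not in _TSV_COLUMNS:
                raise ValueError(f"unknown acquisition column {col!r}")
            target, factor = _TSV_COLUMNS[key]
            cols[target] = np.asarray(df[col], dtype=float) * factor
        missing = {"b", "b_delta", "theta", "phi", "omega_hz", "tau_r",
                   "tau_e"} - cols.keys()
        if missing:
            raise ValueError(f"missing acquisition column(s): {sorted(missing)}")
        return cls(cols["b"], cols["b_delta"], cols["theta"], cols["phi"],
                   cols["omega_hz"] * TWO_PI, cols["tau_r"], cols["tau_e"],
                   name=name)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "Protocol":
        df = pd.read_csv(path, sep="\t")
        return cls.from_dataframe(df, name=name or str(path))

    def __repr__(self) -> str:
        lo, hi = self.frequency_window
        return (f"Protocol({self.name!r}, n_rows={len(self)}, "
                f"b_max={self.b.max():.3g} s/m^2, "
                f"omega/2pi {lo / TWO_PI:.3g}-{hi / TWO_PI:.3g} Hz)")
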