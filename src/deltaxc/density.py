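"""Electron density fields on quadrature grids.

A :class:`DensityField` couples sampled density values to the grid carrying
the integration measure, and records what kind of density it holds:

* ``"full"``    — a valence electron density rho(r), integrating to the
  valence electron count;
* ``"atomic"``  — a superposition of spherical atomic reference profiles,
  one per atom, each carrying its species' valence charge;
* ``"neutral"`` — the difference delta-rho = rho - rho_atm, which integrates
  to zero by construction.

Models may be trained on either the full density or the neutral difference;
the latter is smoother and species-agnostic in its normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid

KINDS = ("full", "neutral", "atomic")


@dataclass
class DensityField:
    grid: Grid
    values: np.ndarray
    kind: str = "full"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != self.grid.npoints:
            raise ValueError("density values do not match grid size")
        if self.kind not in KINDS:
            raise ValueError(f"unknown density kind {self.kind!r}")

    @property
    def nelec(self) -> float:
        """Quadrature integral of the field (electrons)."""
        return self.grid.integrate(self.values)

    def validate(self, expected_electrons: float | None = None,
                 rtol: float = 1e-6, atol: float = 1e-6) -> None:
        """Check the normalization contract of this field's kind."""
        q = self.nelec
        if self.kind == "neutral":
            if abs(q) > atol:
                raise ValueError(f"neutral density integrates to {q:.3e} e, "
                                 f"expected 0 within {atol:g}")
        elif expected_electrons is not None:
            if abs(q - expected_electrons) > rtol * abs(expected_electrons):
                raise ValueError(
                    f"density integrates to {q:.8f} e, expected "
                    f"{expected_electrons:.8f} within rel {rtol:g}")

    def copy(self) -> "DensityField":
        return DensityField(self.grid, self.values.copy(), self.kind)


def delta_density(rho: DensityField, rho_atm: DensityField) -> DensityField:
    """Pointwise difference rho - rho_atm; the neutral training density."""
    if rho.grid is not rho_atm.grid and (
            rho.grid.npoints != rho_atm.grid.npoints
            or not np.array_equal(rho.grid.points, rho_atm.grid.points)):
        raise ValueError("densities live on different grids")
    if rho.kind != "full":
        raise ValueError("first argument must be a full density")
    if rho_atm.kind != "atomic":
        raise ValueError("second argument must be an atomic reference density")
    return DensityField(rho.grid, rho.values - rho_atm.values, kind="neutral")
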