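"""Parametric geometry of the microtubule lattice.

A microtubule is modeled as ``n_pf`` protofilaments arranged on a cylinder.
Within a protofilament, tubulin protomers (alpha or beta monomers) repeat
axially every ``monomer_spacing`` Å (~40-44 Å); successive alpha/beta dimers
repeat every ``dimer_rise = 2 * monomer_spacing``.  Laterally, subunit
``j + 1`` of the start helix is related to subunit ``j`` by an axial rise
``subunit_rise`` and an azimuthal ``subunit_twist``.  For the lattice to
close, ``n_pf`` lateral steps must climb ``n_start`` monomer spacings:

    monomer_spacing = n_pf * subunit_rise / n_start

For the canonical 13-protofilament, 3-start lattice with a 9.61 Å rise this
gives a 41.64 Å protomer repeat and an 83.29 Å dimer rise.

Sign convention: negative twist = left-handed helix, with rotation about +z
taken right-handed when viewed from +z.  The filament axis is z in 3D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "LatticeParams",
    "Spacing",
    "spacing_from_subunit_params",
    "subunit_rise_from_spacing",
    "lattice_positions",
    "layerline_offset_px",
]

#: Default lattice radius (filament axis to protomer center), Å.  Chosen
#: midway inside the 130-330 Å cylindrical annulus conventionally used to
#: mask microtubule density.
DEFAULT_RADIUS_A = 115.0


class Spacing(NamedTuple):
    """Axial repeats implied by a set of subunit helical parameters."""

    monomer: float  #: protomer repeat, Å
    dimer: float    #: dimer repeat = 2 * monomer, Å


def spacing_from_subunit_params(n_pf: int, n_start: int, subunit_rise: float) -> Spacing:
    """Monomer spacing and dimer rise implied by per-subunit helical rise.

    Parameters
    ----------
    n_pf : int
        Protofilament count (>= 8).
    n_start : int
        Monomer helix start number (2, 3 or 4).
    subunit_rise : float
        Axial rise per subunit along the start helix, Å (> 0).

    Returns
    -------
    Spacing
        ``(monomer, dimer)`` in Å, with ``dimer = 2 * monomer`` exactly.
    """
    _check_counts(n_pf, n_start)
    if not subunit_rise > 0:
        raise ValueError(f"subunit_rise must be positive, got {subunit_rise}")
    monomer = n_pf * subunit_rise / n_start
    return Spacing(monomer=monomer, dimer=2.0 * monomer)


def subunit_rise_from_spacing(n_pf: int, n_start: int, monomer_spacing: float) -> float:
    """Inverse of :func:`spacing_from_subunit_params`."""
    _check_counts(n_pf, n_start)
    if not monomer_spacing > 0:
        raise ValueError(f"monomer_spacing must be positive, got {monomer_spacing}")
    return n_start * monomer_spacing / n_pf


def _check_counts(n_pf: int, n_start: int) -> None:
    if n_pf < 8:
        raise ValueError(f"n_pf must be >= 8, got {n_pf}")
    if n_start not in (2, 3, 4):
        raise ValueError(f"n_start must be in {{2, 3, 4}}, got {n_start}")


@dataclass
class LatticeParams:
    """Geometric description of a microtubule lattice.

    ``monomer_spacing`` is the canonical free parameter; ``subunit_rise``
    and ``dimer_rise`` are derived from it through the closure relation
    unless checked against explicitly supplied values.  ``subunit_twist``
    defaults to the exact closure value ``-360 / n_pf`` degrees (no
    protofilament skew); pass the measured value (e.g. -27.67 for the
    axonal lattice) to introduce the natural sub-degree skew.
    """

    monomer_spacing: float = 41.64
    n_pf: int = 13
    n_start: int = 3
    subunit_twist: float | None = None
    radius: float = DEFAULT_RADIUS_A
    seam_present: bool = False

    def __post_init__(self) -> None:
        _check_counts(self.n_pf, self.n_start)
        if not self.monomer_spacing > 0:
            raise ValueError(
                f"monomer_spacing must be positive, got {self.monomer_spacing}"
            )
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.subunit_twist is None:
            self.subunit_twist = -360.0 / self.n_pf

    @classmethod
    def from_subunit(
        cls,
        n_pf: int,
        n_start: int,
        subunit_rise: float,
        subunit_twist: float | None = None,
        **kwargs,
    ) -> "LatticeParams":
        """Build from per-subunit helical parameters (rise in Å, twist in °)."""
        sp = spacing_from_subunit_params(n_pf, n_start, subunit_rise)
        return cls(
            monomer_spacing=sp.monomer,
            n_pf=n_pf,
            n_start=n_start,
            subunit_twist=subunit_twist,
            **kwargs,
        )

    @property
    def subunit_rise(self) -> float:
        """Axial rise per subunit along the start helix, Å."""
        return subunit_rise_from_spacing(self.n_pf, self.n_start, self.monomer_spacing)

    @property
    def dimer_rise(self) -> float:
        """Axial repeat between dimers, Å (exactly twice the monomer spacing)."""
        return 2.0 * self.monomer_spacing

    def to_dict(self) -> dict:
        return {
            "monomer_spacing": self.monomer_spacing,
            "n_pf": self.n_pf,
            "n_start": self.n_start,
            "subunit_twist": self.subunit_twist,
            "radius": self.radius,
            "seam_present": self.seam_present,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatticeParams":
        return cls(**d)


def lattice_positions(params: LatticeParams, length: float) -> np.ndarray:
    """Subunit centers of a lattice of the given axial length.

    The helix axis is z.  The lattice is generated by two operators:
    the lateral subunit step ``(subunit_rise, subunit_twist)`` and the
    axial monomer step ``(monomer_spacing, skew)``, where the skew is the
    small per-monomer azimuthal drift forced by lattice closure,

        skew = (n_pf * subunit_twist + 360) / n_start  degrees,

    zero when ``subunit_twist`` is exactly ``-360 / n_pf`` (the default)
    and ~0.1 degree for the measured twists of real microtubules, whose
    protofilaments consequently spiral slowly (supertwist).  A subunit is
    included iff its axial center lies within ``[0, length)``
    (deterministic edge rule), so the count is
    ``n_pf * floor(length / monomer_spacing)`` up to +/- n_pf depending
    on the protofilament stagger.

    Returns
    -------
    ndarray of shape (N, 3)
        Centers ``(x, y, z)`` in Å, ordered by protofilament then z.
    """
    if not length > 0:
        raise ValueError(f"length must be positive, got {length}")
    sp = params.monomer_spacing
    rise = params.subunit_rise
    twist = params.subunit_twist
    wraps = round(-params.n_pf * twist / 360.0)
    skew = (params.n_pf * twist + 360.0 * wraps) / params.n_start
    out = []
    for p in range(params.n_pf):
        z0 = p * rise
        m0 = int(math.ceil(-z0 / sp))
        n = int(math.ceil((length - z0) / sp)) - m0
        if n <= 0:
            continue
        m = m0 + np.arange(n)
        z = z0 + sp * m
        sel = (z >= 0) & (z < length)
        m, z = m[sel], z[sel]
        phi = np.radians(p * twist + m * skew)
        cols = np.column_stack(
            [params.radius * np.cos(phi), params.radius * np.sin(phi), z]
        )
        out.append(cols)
    if not out:
        return np.empty((0, 3))
    return np.vstack(out)


def layerline_offset_px(monomer_spacing: float, box: int, pixel_size: float) -> float:
    """Expected layer-line offset from the equator, in (sub)pixel rows.

    Inverse of the spacing formula: a repeat of ``monomer_spacing`` Å in an
    image of ``box`` px at ``pixel_size`` Å/px puts the layer line
    ``box * pixel_size / monomer_spacing`` rows from the equator.
    """
    if not monomer_spacing > 0:
        raise ValueError(f"monomer_spacing must be positive, got {monomer_spacing}")
    if not (box > 0 and pixel_size > 0):
        raise ValueError("box and pixel_size must be positive")
    if box % 2:
        raise ValueError(f"box must be even, got {box}")
    return box * pixel_size / monomer_spacing
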