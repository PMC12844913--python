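"""Plot geometry of the maize-soybean strip-width trial.

A periodic unit cell holds one maize strip (two rows) and one soybean strip
(three to eight rows).  The six intercrop treatments M2S3..M2S8 step the cell
width from 2.2 m to 3.7 m in 0.3 m increments by adding soybean rows at fixed
0.3 m row spacing; planted density is held constant, so within-row plant
spacing widens with the strip.  A sole-soybean control (SS) uses uniform 0.5 m
rows and no maize.

Conventions
-----------
The cross-row axis is one-dimensional and periodic with period equal to the
strip width, increasing east -> west, with the origin on the eastern maize row.
Rows are numbered 1..n from east to west.  The cell is split into a maize-strip
width ``Wa`` and soybean-strip width ``Wb`` at the midline of each
maize-soybean gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = [
    "Treatment",
    "LayoutParams",
    "StripGeometry",
    "RowLayout",
    "INTERCROP_NAMES",
    "TREATMENT_NAMES",
    "build_treatment",
    "split_strip",
    "row_positions",
    "plant_spacing",
    "load_layout",
]

#: plants per hectare, identical for sole and intercropped stands
SOY_DENSITY = 150_000.0
MAIZE_DENSITY = 75_000.0

INTERCROP_NAMES = ("M2S3", "M2S4", "M2S5", "M2S6", "M2S7", "M2S8")
TREATMENT_NAMES = INTERCROP_NAMES + ("SS",)


@dataclass(frozen=True)
class Treatment:
    """One experimental treatment (strip configuration and densities)."""

    name: str
    strip_width: float          # m, period of the unit cell
    n_soy_rows: int
    n_maize_rows: int           # 2 for intercrop, 0 for sole soybean
    soy_density: float = SOY_DENSITY     # plants ha-1
    maize_density: float = MAIZE_DENSITY

    @property
    def is_intercrop(self) -> bool:
        return self.n_maize_rows > 0


@dataclass(frozen=True)
class LayoutParams:
    """Within-cell spacings and canopy heights.

    The trial reports total strip widths only; the maize row spacing and the
    maize-soybean gap are defaults inferred from the arithmetic of the width
    series (0.4 + 2*0.6 + (n-1)*0.3 reproduces every printed width), not
    measured facts.  Heights are the virtual experiment's defaults for
    full-grown canopies and are overridden per day by growth curves.
    """

    maize_row_spacing: float = 0.4   # m between the two maize rows
    maize_soy_gap: float = 0.6       # m from maize row to nearest soybean row
    soy_row_spacing: float = 0.3     # m between soybean rows
    ss_row_spacing: float = 0.5      # m, sole-soybean control
    maize_height: float = 2.6        # m, Ha default
    soy_height: float = 0.8          # m, Hb default


@dataclass(frozen=True)
class StripGeometry:
    """Widths, area fractions and canopy heights of one periodic unit cell."""

    Wa: float   # maize-strip width, m
    Wb: float   # soybean-strip width, m
    Ha: float   # maize height, m
    Hb: float   # soybean height, m

    def __post_init__(self) -> None:
        if self.Wa <= 0 or self.Wb <= 0:
            raise ValueError(f"strip widths must be positive, got Wa={self.Wa}, Wb={self.Wb}")
        if self.Hb > self.Ha:
            raise ValueError(
                f"soybean height Hb={self.Hb} exceeds maize height Ha={self.Ha}; "
                "the two-layer model is undefined when the short crop overtops the tall one"
            )
        if self.Hb < 0:
            raise ValueError(f"heights must be non-negative, got Hb={self.Hb}")

    @property
    def fa(self) -> float:
        return self.Wa / (self.Wa + self.Wb)

    @property
    def fb(self) -> float:
        return self.Wb / (self.Wa + self.Wb)

    @property
    def width(self) -> float:
        return self.Wa + self.Wb

    def with_heights(self, Ha: float, Hb: float) -> "StripGeometry":
        return replace(self, Ha=Ha, Hb=Hb)


@dataclass(frozen=True)
class RowLayout:
    """One soybean row inside the periodic cell."""

    row_index: int                       # 1-based, east -> west
    cross_row_position: float            # m from the eastern maize row
    role: str                            # east | middle | west
    distance_to_nearest_maize_row: float  # m, periodic


_WIDTH_BY_ROWS = {n: round(2.2 + 0.3 * (n - 3), 10) for n in range(3, 9)}


def build_treatment(name: str) -> Treatment:
    """Return the named treatment of the strip-width trial.

    ``M2S{n}`` couples two maize rows with ``n`` soybean rows in a
    ``2.2 + 0.3*(n-3)`` m cell; ``SS`` is the sole-soybean control.
    """
    if name == "SS":
        return Treatment(name="SS", strip_width=LayoutParams().ss_row_spacing,
                         n_soy_rows=1, n_maize_rows=0, maize_density=0.0)
    if name not in INTERCROP_NAMES:
        raise ValueError(
            f"unknown treatment {name!r}; valid treatments are {', '.join(TREATMENT_NAMES)}"
        )
    n = int(name[3:])
    return Treatment(name=name, strip_width=_WIDTH_BY_ROWS[n], n_soy_rows=n, n_maize_rows=2)


def split_strip(treatment: Treatment, params: LayoutParams | None = None) -> StripGeometry:
    """Split the unit cell into maize-strip and soybean-strip widths.

    Half of each maize-soybean gap is assigned to each strip (midline
    convention), so ``Wa = maize_row_spacing + gap`` and
    ``Wb = (n_soy_rows - 1) * soy_row_spacing + gap``.

    Raises
    ------
    ValueError
        If the layout spacings do not reconstruct the treatment's strip width.
    """
    params = params or LayoutParams()
    if not treatment.is_intercrop:
        # Sole soybean has no maize strip; the monoculture light model does not
        # use a geometry split, but callers may still want heights.
        return StripGeometry(Wa=params.ss_row_spacing / 2, Wb=params.ss_row_spacing / 2,
                             Ha=params.soy_height, Hb=params.soy_height)
    Wa = params.maize_row_spacing + params.maize_soy_gap
    Wb = (treatment.n_soy_rows - 1) * params.soy_row_spacing + params.maize_soy_gap
    residual = (Wa + Wb) - treatment.strip_width
    if abs(residual) > 1e-9:
        raise ValueError(
            f"layout spacings give Wa+Wb = {Wa + Wb:.4f} m for {treatment.name} "
            f"(strip width {treatment.strip_width} m, residual {residual:+.4f} m)"
        )
    return StripGeometry(Wa=Wa, Wb=Wb, Ha=params.maize_height, Hb=params.soy_height)


def maize_row_positions(treatment: Treatment, params: LayoutParams | None = None) -> list[float]:
    """Cross-row positions of the maize rows within one period (east first)."""
    params = params or LayoutParams()
    if not treatment.is_intercrop:
        return []
    return [0.0, params.maize_row_spacing]


def row_positions(treatment: Treatment, params: LayoutParams | None = None) -> list[RowLayout]:
    """Soybean row positions, east/middle/west roles and maize distances.

    Row 1 is the easternmost soybean row (adjacent to the eastern maize
    strip); row ``n`` the westernmost.  The single-row-from-each-edge
    convention follows the trial's row-wise reporting scheme.
    """
    params = params or LayoutParams()
    if not treatment.is_intercrop:
        raise ValueError("row roles are defined for intercrop treatments only")
    n = treatment.n_soy_rows
    if n < 3:
        raise ValueError(f"need at least 3 soybean rows to define a middle row, got {n}")
    x0 = params.maize_row_spacing + params.maize_soy_gap
    period = treatment.strip_width
    maize_x = maize_row_positions(treatment, params)
    rows = []
    for i in range(1, n + 1):
        x = x0 + (i - 1) * params.soy_row_spacing
        d = min(
            min(abs(x - m), abs(x - m - period), abs(x - m + period)) for m in maize_x
        )
        role = "east" if i == 1 else ("west" if i == n else "middle")
        rows.append(RowLayout(row_index=i, cross_row_position=x, role=role,
                              distance_to_nearest_maize_row=d))
    return rows


def plant_spacing(treatment: Treatment, species: str = "soybean") -> float:
    """Within-row plant spacing (m) that realises the planted density.

    With ``n`` rows of a species in a cell of width ``W`` (m) at density
    ``D`` (plants m-2 of total field area), spacing = n / (D * W).  Sole
    soybean uses its 0.5 m row spacing directly.
    """
    if species not in ("soybean", "maize"):
        raise ValueError(f"species must be 'soybean' or 'maize', got {species!r}")
    if treatment.strip_width <= 0:
        raise ValueError("strip width must be positive")
    if species == "soybean":
        density_m2 = treatment.soy_density / 10_000.0
        if density_m2 <= 0:
            raise ValueError("soybean density must be positive")
        if not treatment.is_intercrop:
            return 1.0 / (density_m2 * LayoutParams().ss_row_spacing)
        return treatment.n_soy_rows / (density_m2 * treatment.strip_width)
    density_m2 = treatment.maize_density / 10_000.0
    if density_m2 <= 0 or treatment.n_maize_rows == 0:
        raise ValueError(f"{treatment.name} has no maize")
    return treatment.n_maize_rows / (density_m2 * treatment.strip_width)


def load_layout(path: str | Path) -> LayoutParams:
    """Read layout overrides from a small YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in LayoutParams.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown layout keys {sorted(unknown)}; known keys: {sorted(known)}")
    return LayoutParams(**raw)
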