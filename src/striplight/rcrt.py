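"""Row-crop radiation transmission (RCRT) model for a two-strip canopy.

The maize canopy is split at soybean height into an upper layer (maize alone)
and a lower layer shared with soybean.  Diffuse radiation moves through the
cell via black-canopy view factors — the classic row-crop result that a gap of
width ``W`` flanked by opaque walls of height ``H`` passes the fraction
``(sqrt(H^2 + W^2) - H) / W`` of isotropic sky radiation — and is absorbed
inside each layer by Beer's law.  The intercepted light is split into nine
pathway fractions F1..F9; maize receives F1+F2+F3+F4+F5+F9 and soybean
F6+F7+F8.  A monoculture canopy reduces to plain Beer's law.

Two variants are exposed:

``literal``
    A verbatim transcription of the published equation set, including its
    internal inconsistencies (mismatched layer subscripts and area weights).
    Out-of-range fractions are clamped and flagged rather than raised.

``consistent``
    The same structure with the minimal corrections that restore symmetry of
    the competition terms and the model's own limits (see docs/methods.md):
    shared-lower-layer terms all use exp(-(ka*LAIiia + kb*LAIb)) with
    k*LAI-proportional absorption shares, lower-layer wall terms use the
    lower-layer view factors, and the below-upper-layer fluxes Fia/Fib carry
    the area fraction of their own strip.  In the homogeneous limit
    (equal heights, equal k, uniform leaf area) this variant reproduces
    1 - exp(-k*LAI) exactly.

Extinction coefficients default to 0.43 (maize), 0.64 (intercropped soybean)
and 0.34 (sole soybean).  ``LAIa``/``LAIb`` are leaf area indices per unit
*total* ground area of the cell; exponents divide by the area fractions where
the radiation traverses strip-local leaf area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .geometry import StripGeometry

__all__ = [
    "K_MAIZE",
    "K_SOY",
    "K_SOY_MONO",
    "CanopyState",
    "ViewFactors",
    "LightPartition",
    "layer_lai",
    "black_view_factor",
    "view_factors",
    "partition",
    "mono_fraction",
]

log = logging.getLogger(__name__)

K_MAIZE = 0.43
K_SOY = 0.64
K_SOY_MONO = 0.34

_EPS = 1e-9


@dataclass(frozen=True)
class CanopyState:
    """Leaf area indices (per unit total ground area) and extinction coefficients."""

    LAIa: float                 # maize LAI
    LAIb: float                 # soybean LAI
    ka: float = K_MAIZE
    kb: float = K_SOY

    def __post_init__(self) -> None:
        if self.LAIa < 0 or self.LAIb < 0:
            raise ValueError(f"LAI must be non-negative, got LAIa={self.LAIa}, LAIb={self.LAIb}")
        if self.ka <= 0 or self.kb <= 0:
            raise ValueError("extinction coefficients must be positive")


@dataclass(frozen=True)
class ViewFactors:
    """Black-canopy view factors beneath the two maize layers, per strip."""

    Fia_black: float    # beneath upper layer, over the maize strip
    Fib_black: float    # beneath upper layer, over the soybean strip
    Fiia_black: float   # beneath lower layer, over the maize strip
    Fiib_black: float   # beneath lower layer, over the soybean strip


@dataclass(frozen=True)
class LightPartition:
    """The nine pathway fractions and species totals of one canopy state."""

    F1: float
    F2: float
    F3: float
    F4: float
    F5: float
    F6: float
    F7: float
    F8: float
    F9: float
    Fia: float   # fraction of incoming light reaching beneath the upper layer, maize strip
    Fib: float   # idem, soybean strip
    variant: str = "consistent"
    clamped: bool = False
    LAIia: float = 0.0
    LAIiia: float = 0.0

    @property
    def Fa(self) -> float:
        """Maize-intercepted fraction."""
        return self.F1 + self.F2 + self.F3 + self.F4 + self.F5 + self.F9

    @property
    def Fb(self) -> float:
        """Soybean-intercepted fraction."""
        return self.F6 + self.F7 + self.F8

    def fractions(self) -> dict[str, float]:
        return {f"F{i}": getattr(self, f"F{i}") for i in range(1, 10)}


def layer_lai(Ha: float, Hb: float, LAIa: float) -> tuple[float, float]:
    """Split maize LAI at soybean height, proportionally to layer depth.

    Returns ``(LAIia, LAIiia)`` — upper- and lower-layer maize LAI; their sum
    is ``LAIa`` exactly.
    """
    if Ha <= 0:
        raise ValueError(f"maize height must be positive, got {Ha}")
    if Hb < 0 or Hb > Ha:
        raise ValueError(
            f"soybean height must lie in [0, Ha]; got Hb={Hb}, Ha={Ha} "
            "(the layered model is undefined when soybean overtops maize)"
        )
    if LAIa < 0:
        raise ValueError(f"LAI must be non-negative, got {LAIa}")
    upper = (Ha - Hb) / Ha * LAIa
    return upper, LAIa - upper


def black_view_factor(H: float, W: float) -> float:
    """Diffuse-sky view factor of a strip of width ``W`` beside opaque walls of height ``H``.

    ``(sqrt(H^2 + W^2) - H) / W`` — the two-dimensional crossed-strings
    result.  Equals 1 for a vanishing wall and decays to 0 as the wall grows.
    """
    if W <= 0:
        raise ValueError(f"strip width must be positive, got {W}")
    if H < 0:
        raise ValueError(f"wall height must be non-negative, got {H}")
    if H == 0:
        return 1.0
    return (math.hypot(H, W) - H) / W


def view_factors(geom: StripGeometry) -> ViewFactors:
    """View factors beneath both maize layers, over both strips."""
    upper = geom.Ha - geom.Hb
    return ViewFactors(
        Fia_black=black_view_factor(upper, geom.Wa),
        Fib_black=black_view_factor(upper, geom.Wb),
        Fiia_black=black_view_factor(geom.Hb, geom.Wa),
        Fiib_black=black_view_factor(geom.Hb, geom.Wb),
    )


def _share(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def partition(geom: StripGeometry, canopy: CanopyState, variant: str = "consistent") -> LightPartition:
    """Partition incoming radiation into the nine pathway fractions.

    Parameters
    ----------
    geom
        Strip widths and canopy heights.
    canopy
        LAI (per total ground area) and extinction coefficients.
    variant
        ``"literal"`` or ``"consistent"`` (see module docstring).

    Raises
    ------
    ValueError
        In the consistent variant, if any fraction falls outside [0, 1]
        (a model violation); the literal variant clamps, logs and sets
        ``clamped`` instead.
    """
    if variant not in ("literal", "consistent"):
        raise ValueError(f"variant must be 'literal' or 'consistent', got {variant!r}")
    fa, fb = geom.fa, geom.fb
    ka, kb = canopy.ka, canopy.kb
    LAIia, LAIiia = layer_lai(geom.Ha, geom.Hb, canopy.LAIa)
    LAIb = canopy.LAIb
    vf = view_factors(geom)
    e = math.exp

    # Upper layer: maize alone.
    F1 = fa * vf.Fia_black * (1 - e(-ka * LAIia / fa))
    F2 = fa * vf.Fia_black * (1 - e(-ka * LAIia))
    F3 = fb * (1 - vf.Fib_black) * (1 - e(-ka * LAIia))

    # Radiation reaching beneath the upper layer over each strip.
    t_up = e(-ka * LAIia)
    Fia = fa * vf.Fia_black * t_up + fa * (1 - vf.Fia_black) * t_up + fa * fb * (1 - vf.Fia_black) * t_up
    lead_b = fa if variant == "literal" else fb
    Fib = lead_b * (vf.Fib_black + fb * (1 - vf.Fib_black) * t_up) + fa * fb * (1 - vf.Fia_black) * t_up

    clamped = False
    if variant == "consistent":
        for name, v in (("Fia", Fia), ("Fib", Fib)):
            if v > 1.0:
                log.warning("renormalising %s = %.4f to 1 (model overshoot)", name, v)
                clamped = True
        Fia, Fib = min(Fia, 1.0), min(Fib, 1.0)

    den = ka * LAIiia + kb * LAIb
    F4 = Fia * vf.Fiia_black * (1 - e(-ka * LAIiia / fa))
    if variant == "literal":
        # Verbatim printed set: upper-layer wall complements, a LAIa/LAIb
        # subscript mix-up in the shared exponent, and a kb-weighted maize
        # numerator in F9.
        shared_a = 1 - e(-(ka * LAIiia + kb * canopy.LAIa))
        shared_b = 1 - e(-den)
        wall_m, wall_s = 1 - vf.Fia_black, 1 - vf.Fib_black
        F5 = Fia * wall_m * shared_b * _share(ka * LAIiia, den)
        F6 = Fia * wall_m * shared_a * _share(kb * LAIb, den)
        F7 = Fia * vf.Fiib_black * (1 - e(-kb * LAIb / fb))
        F8 = Fib * wall_s * shared_a * _share(kb * LAIb, den)
        F9 = Fib * wall_s * shared_a * _share(kb * LAIiia, den)
    else:
        shared = 1 - e(-den)
        wall_m, wall_s = 1 - vf.Fiia_black, 1 - vf.Fiib_black
        F5 = Fia * wall_m * shared * _share(ka * LAIiia, den)
        F6 = Fia * wall_m * shared * _share(kb * LAIb, den)
        F7 = Fib * vf.Fiib_black * (1 - e(-kb * LAIb / fb))
        F8 = Fib * wall_s * shared * _share(kb * LAIb, den)
        F9 = Fib * wall_s * shared * _share(ka * LAIiia, den)

    values = dict(F1=F1, F2=F2, F3=F3, F4=F4, F5=F5, F6=F6, F7=F7, F8=F8, F9=F9,
                  Fia=Fia, Fib=Fib)
    for name, v in values.items():
        if not (-_EPS <= v <= 1 + _EPS):
            if variant == "consistent":
                raise ValueError(f"{name} = {v:.4f} outside [0, 1]: model violated for {geom}, {canopy}")
            log.warning("literal variant: clamping %s = %.4f into [0, 1]", name, v)
            values[name] = min(max(v, 0.0), 1.0)
            clamped = True
        else:
            values[name] = min(max(v, 0.0), 1.0)

    return LightPartition(variant=variant, clamped=clamped, LAIia=LAIia, LAIiia=LAIiia, **values)


def mono_fraction(LAI: float, k: float = K_SOY_MONO) -> float:
    """Beer's-law interception fraction of a homogeneous monoculture canopy."""
    if LAI < 0:
        raise ValueError(f"LAI must be non-negative, got {LAI}")
    if k <= 0:
        raise ValueError(f"extinction coefficient must be positive, got {k}")
    return 1 - math.exp(-k * LAI)
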