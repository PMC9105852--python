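"""Grey-level tone-curve operators applied through lookup tables.

Eight pixel-wise grey-level transfer functions are provided: an identity
(type 0), two thresholded linear stretches and a gamma curve (types I-III),
and their intensity-inverted counterparts (types IV-VII).  Each operator maps
an input grey level ``f`` in ``[0, fmax]`` to an output grey level ``g`` in
the same range; ``fmax`` is 255 for 8-bit data and 4095 for 12-bit data.

The formulas, with ``t`` an integer threshold and ``gamma > 0`` a shape
parameter (threshold branches are strict ``f < t``):

====  =============================================  ==========================
type  g(f)                                           role
====  =============================================  ==========================
0     f                                              identity
I     0 if f < t else f                              dark cutoff
II    0 if f < t else fmax*(f-t)/(fmax-t)            dark cutoff + stretch
III   fmax*(f/fmax)^(1/gamma)                        gamma curve
IV    fmax - f                                       inversion
V     fmax - f if f < t else 0                       inversion + bright cutoff
VI    fmax*(1 - f/t) if f < t else 0                 inverted stretch + cutoff
VII   fmax*((fmax-f)/fmax)^(1/gamma)                 inverted gamma curve
====  =============================================  ==========================

Real-valued outputs are rounded half away from zero and clipped to
``[0, fmax]``.  Because an operator only ever sees ``fmax + 1`` distinct
inputs, it is compiled once into a :class:`LookupTable` and applied to whole
images by fancy indexing, which is both faster than per-pixel evaluation and
exactly equivalent to it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurveType",
    "ToneCurve",
    "LookupTable",
    "GreyImage",
    "ConfigurationError",
    "InputRangeError",
    "evaluate_curve",
    "build_lut",
    "apply_curve",
]


class ConfigurationError(ValueError):
    """A tone-curve parameter is outside the valid range for its type."""


class InputRangeError(ValueError):
    """An input grey level or image is outside ``[0, fmax]``."""


class CurveType(enum.IntEnum):
    """Operator family: 0-III tone curves, IV-VII their inverses."""

    T0 = 0
    T1 = 1
    T2 = 2
    T3 = 3
    T4 = 4
    T5 = 5
    T6 = 6
    T7 = 7


#: types parameterised by the integer threshold t
THRESHOLD_TYPES = frozenset({CurveType.T1, CurveType.T2, CurveType.T5, CurveType.T6})
#: types parameterised by gamma
GAMMA_TYPES = frozenset({CurveType.T3, CurveType.T7})


def _is_valid_fmax(fmax: int) -> bool:
    # fmax must be 2**b - 1 for a positive integer b
    return isinstance(fmax, (int, np.integer)) and fmax >= 1 and (fmax + 1) & fmax == 0


@dataclass(frozen=True)
class ToneCurve:
    """Specification of one grey-level operator.

    Parameters
    ----------
    curve_type
        One of the eight :class:`CurveType` members (or its integer value).
    t
        Integer threshold, required for types I, II, V and VI.  Valid ranges:
        ``0 <= t <= fmax`` for I and V, ``0 <= t <= fmax - 1`` for II (``t ==
        fmax`` would zero the stretch denominator) and ``1 <= t <= fmax`` for
        VI (``t == 0`` would zero the divisor).
    gamma
        Positive shape parameter, required for types III and VII.
    fmax
        Maximum representable grey level; must equal ``2**b - 1``.
    """

    curve_type: CurveType
    t: int | None = None
    gamma: float | None = None
    fmax: int = 255

    def __post_init__(self) -> None:
        object.__setattr__(self, "curve_type", CurveType(self.curve_type))
        ct = self.curve_type
        if not _is_valid_fmax(self.fmax):
            raise ConfigurationError(
                f"fmax must be 2**b - 1 for integer b >= 1, got {self.fmax!r}"
            )
        if ct in THRESHOLD_TYPES:
            if self.t is None:
                raise ConfigurationError(f"type {ct.name} requires a threshold t")
            t = int(self.t)
            object.__setattr__(self, "t", t)
            lo, hi = 0, self.fmax
            if ct is CurveType.T2:
                hi = self.fmax - 1
            elif ct is CurveType.T6:
                lo = 1
            if not lo <= t <= hi:
                raise ConfigurationError(
                    f"type {ct.name} requires {lo} <= t <= {hi}, got t={t}"
                )
            if self.gamma is not None:
                raise ConfigurationError(f"type {ct.name} does not take gamma")
        elif ct in GAMMA_TYPES:
            if self.gamma is None:
                raise ConfigurationError(f"type {ct.name} requires gamma")
            if not self.gamma > 0:
                raise ConfigurationError(
                    f"type {ct.name} requires gamma > 0, got gamma={self.gamma}"
                )
            if self.t is not None:
                raise ConfigurationError(f"type {ct.name} does not take t")
        else:  # T0, T4 are parameter-free
            if self.t is not None or self.gamma is not None:
                raise ConfigurationError(f"type {ct.name} takes no parameter")

    @property
    def parameter(self) -> int | float | None:
        """The operator's free parameter (``t``, ``gamma``, or ``None``)."""
        if self.curve_type in THRESHOLD_TYPES:
            return self.t
        if self.curve_type in GAMMA_TYPES:
            return self.gamma
        return None

    def label(self) -> str:
        """Short method id, e.g. ``"type2(t=20)"`` or ``"type0"``."""
        ct = self.curve_type
        if ct in THRESHOLD_TYPES:
            return f"type{int(ct)}(t={self.t})"
        if ct in GAMMA_TYPES:
            g = self.gamma
            return f"type{int(ct)}(gamma={g:g})"
        return f"type{int(ct)}"


def _transfer(curve: ToneCurve, f: np.ndarray) -> np.ndarray:
    """Real-arithmetic transfer function g(f), before rounding and clipping."""
    fmax = float(curve.fmax)
    ct = curve.curve_type
    if ct is CurveType.T0:
        return f.astype(float)
    if ct is CurveType.T1:
        return np.where(f < curve.t, 0.0, f.astype(float))
    if ct is CurveType.T2:
        t = float(curve.t)
        return np.where(f < curve.t, 0.0, fmax * (f - t) / (fmax - t))
    if ct is CurveType.T3:
        return fmax * (f / fmax) ** (1.0 / curve.gamma)
    if ct is CurveType.T4:
        return fmax - f.astype(float)
    if ct is CurveType.T5:
        return np.where(f < curve.t, fmax - f.astype(float), 0.0)
    if ct is CurveType.T6:
        t = float(curve.t)
        return np.where(f < curve.t, fmax * (1.0 - f / t), 0.0)
    if ct is CurveType.T7:
        return fmax * ((fmax - f) / fmax) ** (1.0 / curve.gamma)
    raise AssertionError(f"unhandled curve type {ct!r}")


def _quantize(g: np.ndarray, fmax: int) -> np.ndarray:
    # round half away from zero (all transfer outputs are >= 0), then clip
    out = np.floor(g + 0.5)
    return np.clip(out, 0, fmax).astype(np.int64)


def evaluate_curve(curve: ToneCurve, f: int) -> int:
    """Evaluate one grey level through the curve's formula.

    Raises :class:`InputRangeError` if ``f`` is outside ``[0, curve.fmax]``.
    """
    if not 0 <= f <= curve.fmax:
        raise InputRangeError(
            f"input grey level {f} outside [0, {curve.fmax}] for {curve.label()}"
        )
    g = _transfer(curve, np.asarray(f))
    return int(_quantize(g, curve.fmax))


@dataclass(frozen=True)
class LookupTable:
    """Precompiled output level for each of the ``fmax + 1`` input levels.

    Calling the table with any integer array returns the transformed array;
    this is exactly equivalent to evaluating the curve formula per pixel.
    """

    entries: np.ndarray
    fmax: int

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.shape != (self.fmax + 1,):
            raise ConfigurationError(
                f"LUT must have fmax+1 = {self.fmax + 1} entries, got {entries.shape}"
            )
        if entries.min() < 0 or entries.max() > self.fmax:
            raise ConfigurationError("LUT entries outside [0, fmax]")
        entries = entries.copy()
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return self.entries.shape[0]

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels)
        if pixels.size and (pixels.min() < 0 or pixels.max() > self.fmax):
            raise InputRangeError("pixel values outside [0, fmax]")
        return self.entries[pixels]


def build_lut(curve: ToneCurve) -> LookupTable:
    """Compile the curve into a :class:`LookupTable` over ``0..fmax``."""
    f = np.arange(curve.fmax + 1)
    return LookupTable(_quantize(_transfer(curve, f), curve.fmax), curve.fmax)


@dataclass(frozen=True)
class GreyImage:
    """A single-channel integer image with its grey-level range.

    ``pixels`` is a 2-D array of non-negative integers, every value within
    ``[0, fmax]``.  Row-major, origin top-left.
    """

    pixels: np.ndarray
    fmax: int = 255

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InputRangeError(f"image must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise InputRangeError(f"image must be integer-valued, got {px.dtype}")
        if not _is_valid_fmax(self.fmax):
            raise ConfigurationError(f"invalid fmax {self.fmax!r}")
        if px.size and (px.min() < 0 or px.max() > self.fmax):
            raise InputRangeError("pixel values outside [0, fmax]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def apply_curve(image: GreyImage, curve: ToneCurve) -> GreyImage:
    """Transform every pixel of ``image`` through ``curve``'s lookup table.

    The input image is left untouched; ``image.fmax`` must match
    ``curve.fmax``.
    """
    if image.fmax != curve.fmax:
        raise InputRangeError(
            f"image fmax {image.fmax} != curve fmax {curve.fmax}"
        )
    lut = build_lut(curve)
    return GreyImage(lut(image.pixels), image.fmax)
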