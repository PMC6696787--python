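"""Phase-scrambled mask generation.

A mask is built from a stimulus image by adding a random deviation field to
its Fourier phase spectrum while leaving the amplitude spectrum untouched.
The deviation field is a single real H x W array shared by all three color
channels, so the scrambling is constant across RGB at every frequency. For
the inverse transform to be real-valued the field must be conjugate
antisymmetric, Delta-phi(-u, -v) = -Delta-phi(u, v) (indices modulo H, W);
the field is built constructively on a half plane and mirrored with
negation, and self-conjugate frequencies (DC and the Nyquist combinations)
are pinned to zero, which also preserves mean luminance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .core import ParameterError, SchemaError

__all__ = ["RasterImage", "PhaseField", "make_phase_field", "phase_scramble"]


@dataclass
class RasterImage:
    """An H x W x 3 real-valued image with its nominal value range."""

    pixels: np.ndarray
    value_range: Tuple[float, float] = (0.0, 1.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ParameterError("pixels must be an H x W x 3 array")
        h, w, _ = self.pixels.shape
        if h < 8 or w < 8:
            raise ParameterError("image dimensions must be at least 8 x 8")
        if not np.isfinite(self.pixels).all():
            raise ParameterError("pixel values must be finite")
        lo, hi = self.value_range
        if not lo < hi:
            raise ParameterError("value_range must be ordered (min < max)")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PhaseField:
    """Conjugate-antisymmetric phase deviations (radians) on an H x W grid."""

    delta: np.ndarray
    symmetry: bool = True

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 2:
            raise ParameterError("delta must be a 2-D array")

    def validate(self, atol: float = 1e-12) -> None:
        """Raise if the conjugate antisymmetry invariant is violated."""
        d = self.delta
        # mirrored[i, j] = d[(-i) % H, (-j) % W]
        mirrored = np.roll(d[::-1, ::-1], shift=(1, 1), axis=(0, 1))
        if not np.allclose(d, -mirrored, atol=atol):
            raise SchemaError("phase field violates conjugate antisymmetry")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.delta.shape


def make_phase_field(
    height: int, width: int, strength: float = 1.0, seed: int = 0
) -> PhaseField:
    """Draw a random conjugate-antisymmetric phase-deviation field.

    Off-axis deviations are uniform on ``[-pi * strength, pi * strength]``
    on one half plane and mirrored with negation onto the other;
    self-conjugate frequencies are set to 0. ``strength`` in [0, 1] scales
    the scrambling from identity (0) to full phase randomization (1).
    """
    if height < 1 or width < 1:
        raise ParameterError("field dimensions must be positive")
    if not 0.0 <= strength <= 1.0:
        raise ParameterError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    i, j = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    mi, mj = (-i) % height, (-j) % width
    primary = (i < mi) | ((i == mi) & (j < mj))
    self_conj = (i == mi) & (j == mj)

    delta = np.zeros((height, width))
    draws = rng.uniform(-np.pi * strength, np.pi * strength, size=(height, width))
    delta[primary] = draws[primary]
    delta[mi[primary], mj[primary]] = -draws[primary]
    delta[self_conj] = 0.0
    return PhaseField(delta=delta)


def phase_scramble(
    image: RasterImage,
    phase_field: PhaseField,
    finalize: str = "clip",
    imag_tol: float = 1e-8,
) -> RasterImage:
    """Scramble an image's phase spectrum while preserving its amplitudes.

    Per channel: forward 2-D DFT, add the shared deviation field to the
    phase, inverse DFT, discard the (numerically tiny) imaginary residue.
    The residue is checked against ``imag_tol`` times the signal norm; a
    larger residue indicates a malformed (non-antisymmetric) field.

    ``finalize`` controls the mapping back into ``image.value_range``:
    ``"clip"`` clips out-of-range pixels, ``"rescale"`` affinely maps the
    observed min/max onto the range, ``"none"`` returns the raw inverse
    transform (useful for spectral checks).
    """
    if finalize not in ("clip", "rescale", "none"):
        raise ParameterError("finalize must be 'clip', 'rescale' or 'none'")
    if phase_field.shape != image.shape:
        raise ParameterError(
            f"phase field shape {phase_field.shape} does not match image {image.shape}"
        )
    rotator = np.exp(1j * phase_field.delta)
    out = np.empty_like(image.pixels)
    for c in range(3):
        spectrum = np.fft.fft2(image.pixels[:, :, c])
        scrambled = np.fft.ifft2(spectrum * rotator)
        norm = np.linalg.norm(scrambled.real)
        residue = np.linalg.norm(scrambled.imag)
        if norm > 0 and residue > imag_tol * norm:
            raise SchemaError(
                "imaginary residue exceeds tolerance: the phase field breaks "
                "conjugate symmetry (rebuild it with make_phase_field)"
            )
        out[:, :, c] = scrambled.real

    lo, hi = image.value_range
    if finalize == "clip":
        out = np.clip(out, lo, hi)
    elif finalize == "rescale":
        omin, omax = out.min(), out.max()
        if omax > omin:
            out = lo + (out - omin) * (hi - lo) / (omax - omin)
        else:
            out = np.full_like(out, (lo + hi) / 2.0)
    return RasterImage(pixels=out, value_range=image.value_range,
                       provenance=f"phase_scrambled:{image.provenance}")
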