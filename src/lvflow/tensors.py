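"""Pointwise decompositions of a 3x3 velocity gradient tensor.

The velocity gradient ``g``, with convention ``g[i, j] = du_i/dx_j`` (units
1/s), admits two complementary splits:

* the classical *double decomposition* into a symmetric strain-rate tensor S
  and a skew-symmetric spin tensor W, ``g = S + W``;
* the *triple decomposition* into irrotational strain (elongation/compression),
  rigid-body rotation, and pure shear, obtained through a real Schur
  factorization ``g = Q T Q^T``: in the Schur frame the quasi-triangular T
  separates into a diagonal (normal, symmetric) part, a skew-symmetric part
  confined to the 2x2 rotation block, and a strictly upper-triangular
  non-normal remainder identified with shear.

The double decomposition cannot distinguish shearing from straining motion: a
simple shear layer contributes to both S and W.  The triple decomposition
isolates shear in its own component, which matters when shear (but not strain)
is the mechanically relevant stimulus, e.g. for shear-induced platelet
activation in blood flow.

This module also provides the von Mises-like scalar shear stress (SSS)
conventionally used in platelet-activation models.  SSS is built from the
symmetric shear-rate tensor alone and therefore conflates shear and strain;
``sss`` and ``triple_decompose`` together quantify that contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import schur

__all__ = [
    "FluidProperties",
    "DoubleDecomposition",
    "SchurForm",
    "TripleDecomposition",
    "double_decompose",
    "schur_standardized",
    "triple_decompose",
    "sss",
    "rotate_to_original_frame",
]

#: Blood density (kg/m^3) and dynamic viscosity (Pa s) used throughout.
BLOOD_DENSITY = 1060.0
BLOOD_VISCOSITY = 0.0027


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Parameters
    ----------
    density : float
        Mass density, kg/m^3.  Default is whole blood.
    dynamic_viscosity : float
        Dynamic viscosity, Pa s.  Default is whole blood.
    """

    density: float = BLOOD_DENSITY
    dynamic_viscosity: float = BLOOD_VISCOSITY

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.dynamic_viscosity > 0):
            raise ValueError("density and dynamic_viscosity must be positive")


@dataclass(frozen=True)
class DoubleDecomposition:
    """Symmetric/skew split ``g = strain_rate + spin``."""

    strain_rate: np.ndarray
    spin: np.ndarray


@dataclass(frozen=True)
class SchurForm:
    """Standardized real Schur factorization ``g = q @ t @ q.T``.

    When the tensor has a complex-conjugate eigenvalue pair
    (``has_complex_pair``), ``t`` is arranged as::

        [[lam, eps,  zeta ],
         [0,   alpha, beta ],
         [0,   gamma, alpha]]

    with the 1x1 real-eigenvalue block leading, the 2x2 block standardized to
    equal diagonal entries, ``|beta| >= |gamma|`` and ``gamma >= 0``.  The
    complex pair is ``alpha +/- i*sqrt(-beta*gamma)``.  With all eigenvalues
    real, ``t`` is upper triangular and ``gamma`` is zero.
    """

    q: np.ndarray
    t: np.ndarray
    has_complex_pair: bool

    @property
    def lam(self) -> float:
        """Real eigenvalue occupying the leading 1x1 block."""
        return float(self.t[0, 0])

    @property
    def alpha(self) -> float:
        return float(self.t[1, 1])

    @property
    def beta(self) -> float:
        return float(self.t[1, 2])

    @property
    def gamma(self) -> float:
        return float(self.t[2, 1])

    @property
    def eps(self) -> float:
        return float(self.t[0, 1])

    @property
    def zeta(self) -> float:
        return float(self.t[0, 2])


@dataclass(frozen=True)
class TripleDecomposition:
    """Strain / rotation / shear split of the Schur form.

    ``el + rr + sh`` reconstructs ``schur.t`` exactly; all three parts live in
    the Schur frame (rotate with :func:`rotate_to_original_frame` to return to
    the lab frame).  ``*_mag`` are Frobenius norms, the magnitude measure used
    for every flow modality.
    """

    schur: SchurForm
    el: np.ndarray
    rr: np.ndarray
    sh: np.ndarray
    el_mag: float
    rr_mag: float
    sh_mag: float


def _as_gradient(g) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape != (3, 3):
        raise ValueError(f"velocity gradient must be 3x3, got shape {g.shape}")
    if not np.all(np.isfinite(g)):
        raise ValueError("velocity gradient contains non-finite entries")
    return g


def double_decompose(g) -> DoubleDecomposition:
    """Split ``g`` into strain-rate S = (g + g^T)/2 and spin W = (g - g^T)/2."""
    g = _as_gradient(g)
    s = (g + g.T) / 2.0
    w = (g - g.T) / 2.0
    return DoubleDecomposition(strain_rate=s, spin=w)


def schur_standardized(g) -> SchurForm:
    """Real Schur factorization with a deterministic block convention.

    The raw factorization is not unique; three normalizations make it so
    (none affects the modality magnitudes): the real-eigenvalue 1x1 block is
    reordered to the leading position, the 2x2 block off-diagonals are swapped
    (by a permutation similarity) so ``|beta| >= |gamma|``, and a column sign
    flip of ``q`` makes ``gamma >= 0``.
    """
    g = _as_gradient(g)
    # Real 1x1 blocks come out of LAPACK with exactly zero imaginary part, so
    # sorting on im == 0 moves the real-eigenvalue block to the front without
    # introducing a tolerance.
    t, q, ndx = schur(g, output="real", sort=lambda re, im: im == 0.0)
    has_pair = ndx == 1 and abs(t[2, 1]) > 0.0
    if not has_pair:
        return SchurForm(q=q, t=_clean_lower(t), has_complex_pair=False)
    if abs(t[1, 2]) < abs(t[2, 1]):
        # Swap rows/cols 1 and 2: exchanges beta<->gamma and eps<->zeta.
        p = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]])
        t = p @ t @ p
        q = q @ p
    if t[2, 1] < 0.0:
        d = np.diag([1.0, 1.0, -1.0])
        t = d @ t @ d
        q = q @ d
    # The LAPACK-standardized 2x2 block has equal diagonal entries up to
    # rounding; enforce exactly so downstream identities hold by construction.
    a = 0.5 * (t[1, 1] + t[2, 2])
    t[1, 1] = t[2, 2] = a
    return SchurForm(q=q, t=_clean_lower(t), has_complex_pair=True)


def _clean_lower(t: np.ndarray) -> np.ndarray:
    """Zero the structurally-zero subdiagonal entries of a quasi-triangular t."""
    t = t.copy()
    t[1, 0] = t[2, 0] = 0.0
    if abs(t[2, 1]) == 0.0:
        t[2, 1] = 0.0
    return t


def triple_decompose(g) -> TripleDecomposition:
    """Decompose ``g`` into irrotational strain, rigid rotation and pure shear.

    In the Schur frame the quasi-triangular form splits as::

        [[lam, eps,  zeta ]    [[lam, 0,  0 ]   [[0, 0,   0  ]   [[0, eps, zeta      ]
         [0,  alpha, beta ]  =  [0, alpha, 0] +  [0, 0, -gamma] +  [0, 0,   beta+gamma]
         [0,  gamma, alpha]]    [0, 0, alpha]]   [0, gamma, 0 ]]   [0, 0,   0         ]]

    i.e. the diagonal (strain), the skew part of the rotation block (rigid
    rotation with rate ``gamma``), and the strictly upper-triangular remainder
    (shear).  With all-real eigenvalues the rotation part is zero and shear is
    the whole strict upper triangle.
    """
    form = schur_standardized(g)
    t = form.t
    el = np.diag(np.diag(t))
    rr = np.zeros((3, 3))
    if form.has_complex_pair:
        gam = t[2, 1]
        rr[1, 2] = -gam
        rr[2, 1] = gam
    sh = t - el - rr
    return TripleDecomposition(
        schur=form,
        el=el,
        rr=rr,
        sh=sh,
        el_mag=float(np.linalg.norm(el)),
        rr_mag=float(np.linalg.norm(rr)),
        sh_mag=float(np.linalg.norm(sh)),
    )


def sss(g) -> float:
    """Von Mises-like scalar shear stress (1/s).

    Built from the symmetric shear-rate tensor ``gdot_ij = g_ij + g_ji`` (the
    viscosity factor is deliberately omitted so units match the triple
    decomposition magnitudes)::

        tau = sqrt( (1/6)[(txx-tyy)^2 + (tyy-tzz)^2 + (txx-tzz)^2]
                    + txy^2 + tyz^2 + txz^2 )

    Note this scalar mixes shear and irrotational strain: it equals the triple
    shear magnitude for a single-plane pure shear but is nonzero for purely
    straining (diagonal trace-free) gradients where the triple shear vanishes.
    """
    g = _as_gradient(g)
    tau = g + g.T
    d = tau[0, 0] - tau[1, 1], tau[1, 1] - tau[2, 2], tau[0, 0] - tau[2, 2]
    return float(
        np.sqrt(
            (d[0] ** 2 + d[1] ** 2 + d[2] ** 2) / 6.0
            + tau[0, 1] ** 2
            + tau[1, 2] ** 2
            + tau[0, 2] ** 2
        )
    )


def rotate_to_original_frame(d: TripleDecomposition):
    """Return (el, rr, sh) conjugated back to the lab frame by ``q``.

    Orthogonal similarity preserves Frobenius norms, symmetry and
    skew-symmetry; the three rotated parts sum to the original gradient.
    """
    q = d.schur.q
    return q @ d.el @ q.T, q @ d.rr @ q.T, q @ d.sh @ q.T
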