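"""Guccione-type transversely isotropic hyperelastic material.

The passive myocardium strain energy is the exponential form

    Psi = c1/2 * (exp(Q) - 1)
    Q   = b_f*E_ff^2 + b_t*(E_tt^2 + E_ss^2 + E_ts^2 + E_st^2)
        + b_s*(E_fs^2 + E_sf^2 + E_tf^2 + E_ft^2)

where E is the Green-Lagrange strain expressed in the local fibre frame
(f = fibre, t = transverse/sheet, s = sheet-normal).  Setting b_t = b_s
reduces the law to transverse isotropy about the fibre axis, which is the
form used throughout this package.  c1 carries units of stress (kPa); the
exponent coefficients are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaterialParams", "exponent_weights", "guccione_energy", "guccione_pk2"]


@dataclass(frozen=True)
class MaterialParams:
    """Converged passive-material constants (c1 in kPa, b_* dimensionless)."""

    c1: float = 2.81
    b_f: float = 12.68
    b_t: float = 11.04
    b_s: float = 11.04

    def __post_init__(self) -> None:
        if not (self.c1 > 0 and self.b_f > 0 and self.b_t > 0 and self.b_s > 0):
            raise ValueError("all material constants must be positive")
        if not np.isclose(self.b_t, self.b_s):
            raise ValueError(
                "transverse isotropy requires b_t == b_s "
                f"(got b_t={self.b_t}, b_s={self.b_s})"
            )


def exponent_weights(params: MaterialParams) -> np.ndarray:
    """3x3 weight matrix W with Q = sum_ij W_ij * E_ij^2 (fibre frame, f=0)."""
    bf, bt, bs = params.b_f, params.b_t, params.b_s
    return np.array(
        [
            [bf, bs, bs],
            [bs, bt, bt],
            [bs, bt, bt],
        ]
    )


def _check_strain(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.shape[-2:] != (3, 3):
        raise ValueError("E must have trailing shape (3, 3)")
    if not np.all(np.isfinite(E)):
        raise ValueError("non-finite strain components")
    return E


def guccione_energy(E_fib: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Strain energy density Psi (kPa) from fibre-frame Green-Lagrange strain.

    Accepts a single 3x3 tensor or any batch of them (leading axes preserved).
    """
    E = _check_strain(E_fib)
    W = exponent_weights(params)
    Q = np.einsum("ij,...ij->...", W, E**2)
    return 0.5 * params.c1 * np.expm1(Q)


def guccione_pk2(E_fib: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Constitutive second Piola-Kirchhoff stress dPsi/dE in the fibre frame.

    S_ij = c1 * exp(Q) * W_ij * E_ij (no sum); symmetric for symmetric E.
    """
    E = _check_strain(E_fib)
    W = exponent_weights(params)
    Q = np.einsum("ij,...ij->...", W, E**2)
    return params.c1 * np.exp(Q)[..., None, None] * W * E
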