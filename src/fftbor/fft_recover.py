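"""Recovery of distance-class probabilities from roots-of-unity evaluations.

The coefficients of the normalized distance polynomial ``Z-hat(x)/Z``
are the Boltzmann probabilities ``p(k) = Z_k / Z`` that a structure lies
at base-pair distance ``k`` from the reference.  Given the vector of
values at the ``m``-th roots of unity, the inverse discrete Fourier
transform

    p(k) = (1/m) * sum_j  values[j] / Z * omega**(-k*j)

returns them exactly (the Vandermonde matrix of the roots of unity has a
closed-form inverse).  Normalizing by ``Z`` before transforming keeps
every input on the unit scale, which is what makes the procedure
numerically stable where interpolation of the raw partition-function
polynomial is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance_poly import ComplexEvaluation, evaluate_on_roots
from .energy import NussinovModel
from .rna_core import RnaSequence, SecondaryStructure, max_distance_bound

__all__ = [
    "NumericalIntegrityError",
    "StructuralProfile",
    "roots_of_unity",
    "inverse_dft",
    "recover_profile",
    "structural_profile",
]

IMAG_TOL = 1e-6
SUM_TOL = 1e-6


class NumericalIntegrityError(ArithmeticError):
    """Raised when recovered coefficients fail their exactness checks.

    A large imaginary residual or a normalized sum far from one signals
    a defect in the dynamic program or the conjugate-symmetry fill, not
    ordinary round-off.
    """


def roots_of_unity(m: int) -> np.ndarray:
    """The ``m``-th complex roots of unity, principal root first."""
    if m < 1:
        raise ValueError("m must be >= 1")
    w = np.exp(2j * np.pi * np.arange(m) / m)
    w[0] = 1.0
    return w


def inverse_dft(values: np.ndarray) -> np.ndarray:
    """Coefficients ``a_k = (1/m) * sum_j values[j] * omega**(-k*j)``.

    Composing with evaluation at the roots of unity is the identity to
    machine precision.
    """
    values = np.asarray(values, dtype=np.complex128)
    return np.fft.fft(values) / len(values)


@dataclass(frozen=True)
class StructuralProfile:
    """The probability vector ``p(0..m-1)`` with provenance metadata.

    ``probabilities`` is kept at full precision; :meth:`rounded` applies
    the output truncation to ``digits`` decimal places.  ``metadata``
    records sequence id, reference structure, model name, theta, RT and
    the largest imaginary residual discarded during recovery.
    """

    probabilities: np.ndarray
    digits: int
    metadata: dict = field(default_factory=dict)

    def rounded(self) -> np.ndarray:
        """Probabilities reported to ``digits`` decimal places."""
        p = np.round(self.probabilities, self.digits)
        return np.where(p == 0.0, 0.0, p)  # normalize -0.0

    def support(self) -> int:
        """Largest ``k`` with truncated ``p(k) > 0``."""
        nz = np.nonzero(self.rounded() > 0)[0]
        return int(nz[-1]) if len(nz) else 0

    def to_tsv(self, stream) -> None:
        """Write ``k <TAB> p(k)`` rows preceded by '#' metadata lines."""
        for key, val in self.metadata.items():
            stream.write(f"# {key}: {val}\n")
        stream.write(f"# digits: {self.digits}\n")
        stream.write("k\tp_k\n")
        p = self.rounded()
        top = self.support()
        for k in range(top + 1):
            stream.write(f"{k}\t{p[k]:.{self.digits}f}\n")


def recover_profile(
    ev: ComplexEvaluation, digits: int = 6, metadata: dict | None = None
) -> StructuralProfile:
    """Normalize by ``Z``, invert the DFT and validate the coefficients.

    Raises :class:`NumericalIntegrityError` if the largest imaginary
    residual exceeds 1e-6 or the coefficient sum strays from 1 by more
    than 1e-6 before truncation.  Negative round-off smaller in
    magnitude than ``10**-digits`` is clamped to zero; the vector is
    renormalized only if the clamped mass exceeds ``10**-digits``.
    """
    if ev.Z <= 0:
        raise NumericalIntegrityError(f"partition function Z={ev.Z} not positive")
    coeffs = inverse_dft(ev.values / ev.Z)
    imag = float(np.max(np.abs(coeffs.imag)))
    if imag > IMAG_TOL:
        raise NumericalIntegrityError(
            f"imaginary residual {imag:.3e} exceeds {IMAG_TOL:.0e}"
        )
    p = coeffs.real.copy()
    total = float(p.sum())
    if abs(total - 1.0) > SUM_TOL:
        raise NumericalIntegrityError(
            f"coefficient sum {total!r} deviates from 1 by more than {SUM_TOL:.0e}"
        )
    eps = 10.0 ** (-digits)
    clamped = p[(p < 0) & (p > -eps)]
    clamped_mass = float(-clamped.sum())
    p[(p < 0) & (p > -eps)] = 0.0
    if clamped_mass > eps:
        p = p / p.sum()
    meta = dict(metadata or {})
    meta["max_imag_residual"] = imag
    return StructuralProfile(probabilities=p, digits=digits, metadata=meta)


def structural_profile(
    seq: RnaSequence,
    Sstar: SecondaryStructure,
    model=None,
    m: int | None = None,
    digits: int = 6,
    validate: bool = True,
    workers: int = 1,
) -> StructuralProfile:
    """End-to-end pipeline: evaluate at roots of unity and recover ``p(k)``."""
    model = model if model is not None else NussinovModel()
    ev = evaluate_on_roots(
        seq, Sstar, model, m=m, validate=validate, workers=workers
    )
    meta = {
        "sequence": seq.id,
        "reference": Sstar.to_dot_bracket(),
        "model": model.name,
        "theta": Sstar.theta,
        "RT": model.RT,
        "Z": ev.Z,
        "distance_bound": max_distance_bound(Sstar),
    }
    return recover_profile(ev, digits=digits, metadata=meta)
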