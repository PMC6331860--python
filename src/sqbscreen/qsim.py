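"""Quantum probability primitives and similarity coefficients.

The retrieval model treats a molecule's weighted fragment vector as a state
in a (complex) Hilbert space whose orthonormal basis is indexed by fragment
identifiers.  The probability that a library compound is relevant to a
reference is the squared length of the projection of the reference's unit
state vector onto the compound's one-dimensional subspace — a Gleason-style
rule ``tr(d S)`` with ``d`` the reference's pure density operator and ``S``
the compound's projector.

Two computational routes are provided.  The production route,
:func:`sqb_probability`, evaluates the algebraically reduced closed form

    ``|<r|c>|^2 / (<r|r> <c|c>)``

on sparse vectors and never materialises a matrix.  The dense route
(:func:`pure_density`, :func:`projector_onto` and
:func:`sqb_probability_dense`) builds the density operator and projector
explicitly; it exists as a brute-force cross-check and for the general
framework operations (distribution densities, subspace probabilities).

The continuous Tanimoto coefficient on count vectors — the field's
benchmark similarity — lives here too (:func:`tanimoto_continuous`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DensityOperator",
    "Projector",
    "FragmentDistribution",
    "subspace_probability",
    "density_from_distribution",
    "pure_density",
    "projector_onto",
    "sqb_probability",
    "sqb_probability_dense",
    "tanimoto_continuous",
]

logger = logging.getLogger(__name__)

_TRACE_TOL = 1e-9


def _as_sparse(vec) -> Mapping[int, complex]:
    """Accept a ComplexVector-like object, a mapping, or a dense sequence."""
    entries = getattr(vec, "entries", None)
    if entries is not None:
        return entries
    if isinstance(vec, Mapping):
        return vec
    return {i: v for i, v in enumerate(vec)}


@dataclass(frozen=True)
class DensityOperator:
    """Hermitian, positive-semidefinite, trace-1 operator.

    Encodes a probability distribution over subspaces; the rank-1 case
    ``phi phi†`` of a unit vector ``phi`` is a pure state.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=complex)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("density operator must be a square matrix")
        if not np.allclose(mat, mat.conj().T, atol=_TRACE_TOL):
            raise ValueError("density operator must be Hermitian")
        tr = np.trace(mat).real
        if abs(tr - 1.0) > 1e-6:
            raise ValueError(f"density operator must have trace 1, got {tr}")
        object.__setattr__(self, "matrix", mat)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def trace(self) -> float:
        return float(np.trace(self.matrix).real)

    def is_psd(self, tol: float = _TRACE_TOL) -> bool:
        """v†Dv >= -tol for all v, checked via the eigenvalue spectrum."""
        eigvals = np.linalg.eigvalsh(self.matrix)
        return bool(eigvals.min() >= -tol)


@dataclass(frozen=True)
class Projector:
    """Hermitian idempotent operator onto a subspace."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=complex)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("projector must be a square matrix")
        if not np.allclose(mat, mat.conj().T, atol=1e-8):
            raise ValueError("projector must be Hermitian")
        if not np.allclose(mat @ mat, mat, atol=1e-8):
            raise ValueError("projector must be idempotent (P @ P == P)")
        object.__setattr__(self, "matrix", mat)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FragmentDistribution:
    """Probability distribution ``pr(f)`` over a fragment sample space."""

    probs: Mapping[int, float]

    def __post_init__(self) -> None:
        probs = {int(k): float(v) for k, v in self.probs.items()}
        if any(p < -_TRACE_TOL for p in probs.values()):
            raise ValueError("probabilities must be non-negative")
        total = sum(probs.values())
        if abs(total - 1.0) > _TRACE_TOL:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        object.__setattr__(self, "probs", probs)

    def support(self) -> set:
        return {f for f, p in self.probs.items() if p > 0}


def subspace_probability(
    dist: FragmentDistribution, subspace_fragments: Iterable[int]
) -> float:
    """Probability of the subspace spanned by the given basis fragments.

    Simply the sum of ``pr(f)`` over the fragments of the subspace; fragments
    outside the distribution's sample space carry zero mass.
    """
    return float(sum(dist.probs.get(f, 0.0) for f in set(subspace_fragments)))


def density_from_distribution(
    dist: FragmentDistribution, basis_order: Sequence[int]
) -> DensityOperator:
    """Mixed-state density ``D = sum_f pr(f) |f><f|`` in the given basis.

    In the fragment basis this is diagonal with ``pr(f)`` on the diagonal.
    ``basis_order`` must enumerate the full sample space.
    """
    missing = dist.support() - set(basis_order)
    if missing:
        raise ValueError(f"basis order misses fragments with mass: {sorted(missing)}")
    diag = np.array([dist.probs.get(f, 0.0) for f in basis_order], dtype=float)
    return DensityOperator(np.diag(diag).astype(complex))


def _dense_vector(vec, basis_order: Sequence[int]) -> np.ndarray:
    entries = _as_sparse(vec)
    missing = {f for f, v in entries.items() if v != 0} - set(basis_order)
    if missing:
        raise ValueError(f"basis order misses fragments: {sorted(missing)}")
    return np.array([complex(entries.get(f, 0.0)) for f in basis_order])


def pure_density(phi, basis_order: Sequence[int]) -> DensityOperator:
    """Pure-state density ``phi phi†`` of the unit-normalised vector."""
    v = _dense_vector(phi, basis_order)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot build a pure density from a zero vector")
    v = v / norm
    return DensityOperator(np.outer(v, v.conj()))


def projector_onto(phi, basis_order: Sequence[int]) -> Projector:
    """Projector onto the one-dimensional subspace spanned by ``phi``."""
    v = _dense_vector(phi, basis_order)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot project onto a zero vector")
    v = v / norm
    return Projector(np.outer(v, v.conj()))


def sqb_probability(reference, compound) -> float:
    """Projection probability of the reference state onto the compound subspace.

    Closed form ``|<r|c>|^2 / (<r|r><c|c>)`` over the union fragment support,
    with the conjugate taken on the reference side (the modulus makes the
    choice immaterial).  Equals ``tr(d S)`` for the reference's pure density
    ``d`` and the compound's subspace projector ``S``; lies in ``[0, 1]`` by
    Cauchy–Schwarz.  A zero-norm argument yields similarity 0 (logged).
    """
    r = _as_sparse(reference)
    c = _as_sparse(compound)
    rr = sum(abs(v) ** 2 for v in r.values())
    cc = sum(abs(v) ** 2 for v in c.values())
    if rr == 0 or cc == 0:
        logger.warning(
            "zero-norm vector in projection probability; returning similarity 0"
        )
        return 0.0
    small, large = (r, c) if len(r) <= len(c) else (c, r)
    inner = sum(
        complex(r.get(f, 0.0)).conjugate() * complex(c.get(f, 0.0)) for f in small
    )
    return float(abs(inner) ** 2 / (rr * cc))


def sqb_probability_dense(reference, compound, basis_order: Sequence[int]) -> float:
    """Brute-force route: materialise ``d`` and ``S`` and take ``tr(d S)``."""
    d = pure_density(reference, basis_order)
    s = projector_onto(compound, basis_order)
    return float(np.trace(d.matrix @ s.matrix).real)


def tanimoto_continuous(w_k, w_l) -> float:
    """Continuous (count-valued) Tanimoto coefficient of two sparse vectors.

    ``sum(w_k w_l) / (sum(w_k^2) + sum(w_l^2) - sum(w_k w_l))`` — the
    generalisation of ``|A∩B| / |A∪B|`` to non-binary fingerprints, with
    which it coincides on 0/1 vectors.  Identical non-zero vectors score 1,
    disjoint supports score 0, and two zero vectors score 0 by convention
    (logged).
    """
    a = _as_sparse(w_k)
    b = _as_sparse(w_l)
    aa = sum(float(v) ** 2 for v in a.values())
    bb = sum(float(v) ** 2 for v in b.values())
    if aa == 0 and bb == 0:
        logger.warning("both vectors empty in Tanimoto; returning similarity 0")
        return 0.0
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    ab = sum(float(small[f]) * float(large.get(f, 0.0)) for f in small)
    return float(ab / (aa + bb - ab))
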