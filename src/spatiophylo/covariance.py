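"""Named covariance structures over a fixed taxon order.

A :class:`CovarianceStructure` wraps a dense symmetric positive
semi-definite matrix ``C`` over ``taxa`` together with its standardized
form (scaled so that the mean diagonal element is 1) and, on request,
the precision matrix ``Q = C^{-1}``.  Random effects in the mixed model
are parameterized as ``u ~ N(0, sigma^2 * C_standardized)``, so
standardizing every structure to unit mean variance makes the effect
SDs directly comparable across phylogenetic, spatial and group-block
structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, NumericalError

log = logging.getLogger(__name__)

#: relative PSD tolerance: smallest eigenvalue may be >= -PSD_TOL * max diag
PSD_TOL = 1e-8

#: starting diagonal jitter (relative to mean diagonal) and escalation cap
JITTER_START = 1e-8
JITTER_MAX = 1e-4


@dataclass
class CovarianceStructure:
    """A named PSD covariance matrix over an ordered set of taxa."""

    name: str
    kind: str  # "phylogenetic" | "spatial" | "group" | "rw2"
    taxa: list[str]
    matrix: np.ndarray
    standardized: bool = False
    precision: np.ndarray | None = None
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"covariance matrix must be square, got {C.shape}")
        if C.shape[0] != len(self.taxa):
            raise AlignmentError(
                f"{len(self.taxa)} taxa but matrix of shape {C.shape}"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon identifiers in covariance structure")
        if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
            raise ValueError(f"covariance matrix {self.name!r} is not symmetric")
        self.matrix = (C + C.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.taxa)

    def check_psd(self) -> float:
        """Return the smallest eigenvalue; raise if materially negative."""
        w = np.linalg.eigvalsh(self.matrix)
        floor = -PSD_TOL * max(self.matrix.diagonal().max(), 1.0)
        if w[0] < floor:
            raise NumericalError(
                f"structure {self.name!r} is not PSD: min eigenvalue {w[0]:.3e}"
            )
        return float(w[0])

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values, vectors) of the matrix."""
        if self._eig is None:
            w, U = np.linalg.eigh(self.matrix)
            self._eig = (np.clip(w, 0.0, None), U)
        return self._eig

    def standardize_and_invert(self, invert: bool = True) -> "CovarianceStructure":
        """Scale C by its mean diagonal and (optionally) invert to a precision.

        Scaling makes the average marginal variance 1 so that structures of
        different kinds compete on the same SD scale.  Inversion uses a
        Cholesky factorization with an escalating diagonal jitter
        (relative 1e-8 up to 1e-4); failure beyond the cap raises
        :class:`NumericalError` with the condition number.
        """
        mean_diag = float(self.matrix.diagonal().mean())
        if mean_diag <= 0:
            raise NumericalError(f"structure {self.name!r} has nonpositive mean diagonal")
        C = self.matrix / mean_diag
        Q = None
        if invert:
            # the jitter actually used becomes part of the structure, so the
            # precision is an exact inverse of the stored matrix
            Q, jitter = _jittered_inverse(C, self.name)
            if jitter > 0:
                C = C + jitter * np.eye(self.n)
        return replace(self, matrix=C, standardized=True, precision=Q, _eig=None)

    def subset(self, taxa: list[str]) -> "CovarianceStructure":
        """Restrict the structure to ``taxa`` (in the given order)."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise AlignmentError(
                f"taxa absent from structure {self.name!r}: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        idx = np.array([index[t] for t in taxa])
        return replace(
            self,
            taxa=list(taxa),
            matrix=self.matrix[np.ix_(idx, idx)],
            precision=None,
            _eig=None,
        )

    def to_csv(self, path) -> None:
        """Write the dense matrix with a taxon header row (debugging aid)."""
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa).to_csv(path)


def _jittered_inverse(C: np.ndarray, name: str) -> tuple[np.ndarray, float]:
    """Invert via Cholesky with escalating diagonal jitter.

    Returns (Q, jitter) where Q is verified to invert C + jitter*I to
    1e-7 in the max norm; jitter escalates x10 from 1e-8 to 1e-4.
    """
    n = C.shape[0]
    mean_diag = float(C.diagonal().mean())
    jitter = JITTER_START
    while jitter <= JITTER_MAX:
        Cj = C + jitter * mean_diag * np.eye(n)
        try:
            L = np.linalg.cholesky(Cj)
        except np.linalg.LinAlgError:
            log.info("inversion of %r: escalating jitter to %g", name, jitter * 10)
            jitter *= 10
            continue
        Linv = np.linalg.inv(L)
        Q = Linv.T @ Linv
        err = float(np.abs(Q @ Cj - np.eye(n)).max())
        if err < 1e-7:
            return Q, jitter * mean_diag
        log.info("inversion of %r imprecise (%.2e); escalating jitter", name, err)
        jitter *= 10
    cond = float(np.linalg.cond(C))
    raise NumericalError(
        f"structure {name!r} singular after jitter {JITTER_MAX:g}"
        f" (condition number {cond:.3e})"
    )


def standardize_and_invert(c: CovarianceStructure) -> CovarianceStructure:
    """Functional alias for :meth:`CovarianceStructure.standardize_and_invert`."""
    return c.standardize_and_invert()
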