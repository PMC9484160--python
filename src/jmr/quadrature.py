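"""Gauss-Hermite quadrature adapted to standard-normal expectations."""

from __future__ import annotations

import numpy as np

__all__ = ["gh_rule"]


def gh_rule(Q: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights such that ``sum(w * h(z)) ~= E[h(Z)], Z ~ N(0,1)``.

    The physicists' Gauss-Hermite rule targets ``int e^{-x^2} h(x) dx``;
    the change of variable ``z = sqrt(2) x`` turns it into an expectation
    against the standard normal density, with weights ``w / sqrt(pi)``.
    Exact for polynomials ``h`` up to degree ``2Q - 1``.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    x, w = np.polynomial.hermite.hermgauss(Q)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)
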