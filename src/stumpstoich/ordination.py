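"""Redundancy analysis with a single continuous constraint (ergosterol).

RDA partitions the variance of a multivariate response matrix Y into the part
explained by a linear predictor and a residual part, and eigen-decomposes
each.  Here Y holds the column-standardized natural logs of the 12 element
concentrations and the single constraint x is the standardized log ergosterol
concentration, so there is exactly one constrained axis:

    Ŷ = x (xᵀx)⁻¹ xᵀ Y                 (rank-1 fitted part)
    λ₁ = ‖Ŷ‖² / (n − 1)                 (constrained eigenvalue)
    residual axes = principal components of Y − Ŷ

Axis-1 loadings are reported as Pearson correlations of each element's
(standardized log) column with the axis-1 site scores, hence bounded in
[−1, 1].  Axis significance uses a permutation test of the pseudo-F statistic

    F = (constrained SS / 1) / (residual SS / (n − 2)),

permuting the constraint vector; p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ELEMENTS, StumpSample
from .errors import InsufficientDataError, LogDomainError


@dataclass(frozen=True)
class RDAResult:
    """Eigen-structure and permutation significance of a single-constraint RDA."""

    eigenvalues: np.ndarray        # constrained first, then unconstrained
    variance_fractions: np.ndarray
    axis1_loadings: dict[str, float]
    site_scores: np.ndarray        # (n, 1 + n_unconstrained) axis coordinates
    perm_p: float
    n_permutations: int
    seed: int
    pseudo_f: float

    @property
    def constrained_fraction(self) -> float:
        return float(self.variance_fractions[0])


def _standardize_log(matrix: np.ndarray) -> np.ndarray:
    logged = np.log(matrix)
    centred = logged - logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)  # constant column → zeros, not NaN
    return centred / sd


def _fitted_ss(x: np.ndarray, y: np.ndarray) -> float:
    coef = (x @ y) / (x @ x)
    return float((x @ x) * (coef @ coef))


def rda_single_constraint(samples: Sequence[StumpSample],
                          n_permutations: int = 999,
                          seed: int = 0,
                          elements: Sequence[str] = ELEMENTS) -> RDAResult:
    """Run the single-constraint RDA on log-transformed, standardized data.

    Requires at least 4 samples and strictly positive concentrations and
    ergosterol values (both are log-transformed).
    """
    samples = list(samples)
    n = len(samples)
    if n < 4:
        raise InsufficientDataError(f"rda: need at least 4 samples, got {n}")
    for s in samples:
        if s.ergosterol_ug_g <= 0:
            raise LogDomainError(
                f"rda: stump {s.stump_id}: non-positive ergosterol")
        for el in elements:
            if s.profile[el] <= 0:
                raise LogDomainError(
                    f"rda: stump {s.stump_id}: non-positive {el} concentration")

    raw = np.array([[s.profile[el] for el in elements] for s in samples])
    y = _standardize_log(raw)
    erg = np.array([s.ergosterol_ug_g for s in samples])
    x = _standardize_log(erg[:, None])[:, 0]

    p = y.shape[1]
    coef = (x @ y) / (x @ x)              # 1×p regression coefficients
    fitted = np.outer(x, coef)
    residual = y - fitted

    lam_constrained = float(np.sum(fitted ** 2)) / (n - 1)
    # Unconstrained axes: principal components of the residual matrix.
    cov_res = residual.T @ residual / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov_res)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    eigenvalues = np.concatenate([[lam_constrained], eigval])
    total = float(eigenvalues.sum())
    fractions = eigenvalues / total if total > 0 else eigenvalues * 0.0

    # Constrained axis-1 site scores: the rank-1 fitted part collapses to x
    # scaled by the coefficient norm (SVD of Ŷ = x·coefᵀ).
    axis1_scores = x * float(np.linalg.norm(coef))
    unconstrained_scores = residual @ eigvec
    site_scores = np.column_stack([axis1_scores, unconstrained_scores])

    loadings = {}
    for j, el in enumerate(elements):
        col = y[:, j]
        if axis1_scores.std() == 0 or col.std() == 0:
            loadings[el] = 0.0
        else:
            loadings[el] = float(np.corrcoef(col, axis1_scores)[0, 1])

    ss_total = float(np.sum(y ** 2))
    ss_constrained = float(np.sum(fitted ** 2))
    ss_residual = ss_total - ss_constrained
    if ss_residual <= 0:
        pseudo_f = np.inf
    else:
        pseudo_f = (ss_constrained / 1.0) / (ss_residual / (n - 2))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        xp = rng.permutation(x)
        ssc = _fitted_ss(xp, y)
        ssr = ss_total - ssc
        f_perm = np.inf if ssr <= 0 else (ssc / 1.0) / (ssr / (n - 2))
        if f_perm >= pseudo_f:
            hits += 1
    perm_p = (1 + hits) / (n_permutations + 1)

    return RDAResult(eigenvalues=eigenvalues,
                     variance_fractions=fractions,
                     axis1_loadings=loadings,
                     site_scores=site_scores,
                     perm_p=perm_p,
                     n_permutations=n_permutations,
                     seed=seed,
                     pseudo_f=float(pseudo_f))


def rda_to_dict(result: RDAResult) -> dict:
    """JSON-serializable summary (eigenvalues, fractions, loadings, perm_p)."""
    return {
        "eigenvalues": [float(v) for v in result.eigenvalues],
        "variance_fractions": [float(v) for v in result.variance_fractions],
        "axis1_loadings": result.axis1_loadings,
        "pseudo_f": result.pseudo_f,
        "perm_p": result.perm_p,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
    }
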