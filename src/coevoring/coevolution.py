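"""Residue coevolution scoring via sparse inverse covariance estimation.

The score of a column pair (i, j) is the sum of absolute values of the
20 x 20 block linking the two columns in the estimated inverse covariance
(precision) matrix of amino-acid indicator variables — the PSICOV coupling
score.  Raw scores are corrected with the average product correction (APC)
to remove entropic and phylogenetic background, standardised to z-scores
over eligible pairs, and thresholded in sigma units.

Counts use 20 amino-acid states only; rows contributing a gap at a column
are excluded from that column's (and pair's) counts.  Redundancy weighting
and a uniform pseudocount regularise the frequencies before the covariance
is formed.  A light shrinkage of the covariance toward its diagonal
(as in PSICOV's own preprocessing) conditions the graphical-lasso solve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from coevoring.errors import ConvergenceError, CoevoringError, ParameterError
from coevoring.msa import GAP_STATE, Msa, N_STATES, SequenceWeights, sequence_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyModel:
    """Weighted single- and pair-column amino-acid frequencies.

    ``f1`` has shape (L, 20); ``f2`` has shape (L, L, 20, 20) with
    ``f2[i, i]`` the diagonal block ``diag(f1[i])``.  ``lam`` is the
    pseudocount mass mixed with the uniform distribution via
    ``lam' = lam / (lam + n_eff)``.
    """

    f1: np.ndarray
    f2: np.ndarray
    lam: float
    n_eff: float


@dataclass(frozen=True)
class Coupling:
    """A scored column pair in 1-based reference residue numbering (i < j)."""

    i: int
    j: int
    score_raw: float
    score_apc: float
    z: float
    score_norm: float = float("nan")
    inter_domain: bool = False


@dataclass(frozen=True)
class CoevolutionResult:
    """Raw, APC-corrected and standardised score matrices with couplings."""

    raw: np.ndarray
    apc: np.ndarray
    z: np.ndarray
    sigma_cut: float
    min_separation: int
    couplings: list[Coupling]
    fraction_above: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.raw.shape[0]


# ---------------------------------------------------------------------------
# Frequencies and covariance


def pair_frequencies(
    msa: Msa, weights: SequenceWeights | None = None, lam: float = 1.0
) -> FrequencyModel:
    """Weighted, pseudocounted column and column-pair frequencies.

    Rows gapped at a column are excluded from that column's counts; rows
    gapped at either member of a pair are excluded from the pair's counts.
    Frequencies are mixed with the uniform distribution:
    ``f = (1 - lam') f_obs + lam' / 20`` (or ``/400`` for pairs), with
    ``lam' = lam / (lam + n_eff)``.
    """
    if msa.L < 2:
        raise ParameterError("need at least 2 columns")
    if lam < 0:
        raise ParameterError("pseudocount lambda must be >= 0")
    enc = msa.encoded()
    L = msa.L
    w = weights.weights if weights is not None else np.ones(msa.N)
    n_eff = float(w.sum())
    lam_p = lam / (lam + n_eff)

    nongap = enc != GAP_STATE
    f1_obs = np.zeros((L, N_STATES))
    for c in range(L):
        mask = nongap[:, c]
        total = float(w[mask].sum())
        if total == 0:
            raise CoevoringError(f"column {c + 1} has no non-gap rows")
        f1_obs[c] = np.bincount(enc[mask, c], weights=w[mask], minlength=N_STATES) / total
    f1 = (1.0 - lam_p) * f1_obs + lam_p / N_STATES

    f2 = np.zeros((L, L, N_STATES, N_STATES))
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
        for j in range(i + 1, L):
            mask = nongap[:, i] & nongap[:, j]
            total = float(w[mask].sum())
            if total == 0:
                logger.warning("column pair (%d, %d) has no joint coverage", i + 1, j + 1)
                f2_obs = np.outer(f1_obs[i], f1_obs[j])
            else:
                code = enc[mask, i].astype(np.int64) * N_STATES + enc[mask, j]
                f2_obs = (
                    np.bincount(code, weights=w[mask], minlength=N_STATES * N_STATES).reshape(
                        N_STATES, N_STATES
                    )
                    / total
                )
            block = (1.0 - lam_p) * f2_obs + lam_p / (N_STATES * N_STATES)
            f2[i, j] = block
            f2[j, i] = block.T
    return FrequencyModel(f1=f1, f2=f2, lam=lam, n_eff=n_eff)


def build_covariance(fm: FrequencyModel) -> np.ndarray:
    """20L x 20L covariance ``C[(i,a),(j,b)] = f2_ij(a,b) - f1_i(a) f1_j(b)``."""
    L = fm.f1.shape[0]
    d = L * N_STATES
    flat = fm.f1.reshape(d)
    cov = fm.f2.transpose(0, 2, 1, 3).reshape(d, d) - np.outer(flat, flat)
    return (cov + cov.T) / 2.0


def shrink_covariance(cov: np.ndarray, shrink: float = 0.1) -> np.ndarray:
    """Shrink the covariance toward its diagonal: ``(1-s) C + s diag(C)``."""
    if not 0.0 <= shrink < 1.0:
        raise ParameterError("shrink must be in [0, 1)")
    if shrink == 0.0:
        return cov
    return (1.0 - shrink) * cov + shrink * np.diag(np.diag(cov))


def sparse_precision(
    cov: np.ndarray,
    rho: float,
    tol: float = 1e-2,
    max_iter: int = 30,
    ridge_scale: float = 1e-4,
    raise_on_nonconvergence: bool = False,
) -> np.ndarray:
    """L1-penalised inverse covariance (graphical lasso) estimate.

    At ``rho = 0`` on a well-conditioned matrix this is the direct inverse.
    If the input is not positive definite, a ridge of
    ``ridge_scale * mean(diag)`` is added (escalating tenfold until a
    Cholesky factorisation succeeds).  Non-convergence raises
    :class:`ConvergenceError` with iteration diagnostics when
    ``raise_on_nonconvergence`` is set, and logs a warning otherwise.
    """
    if rho < 0:
        raise ParameterError("penalty rho must be >= 0")
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ParameterError("covariance must be square")
    work = (cov + cov.T) / 2.0
    eps = ridge_scale * float(np.mean(np.diag(work)))
    if eps <= 0:
        eps = ridge_scale
    if rho > 0.0:
        # the penalised solver needs a safely conditioned input; a ridge of
        # this size is far below the penalty scale and does not move scores
        eps *= 10.0
        work = work + eps * np.eye(work.shape[0])
    for _ in range(40):
        try:
            np.linalg.cholesky(work)
            break
        except np.linalg.LinAlgError:
            work = work + eps * np.eye(work.shape[0])
            eps *= 10.0
    else:
        raise ConvergenceError("covariance could not be made positive definite")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        last_exc: Exception | None = None
        precision = None
        for _attempt in range(6):
            try:
                _, precision, n_iter = graphical_lasso(
                    work,
                    alpha=rho,
                    mode="cd",
                    tol=tol,
                    enet_tol=1e-5,
                    max_iter=max_iter,
                    return_n_iter=True,
                )
                break
            except FloatingPointError as exc:
                # near-singular input: strengthen the diagonal and retry
                last_exc = exc
                work = work + eps * np.eye(work.shape[0])
                eps *= 10.0
        if precision is None:
            raise ConvergenceError(f"graphical lasso diverged: {last_exc}") from last_exc
    if not np.all(np.isfinite(precision)):
        raise ConvergenceError("graphical lasso produced non-finite entries", n_iter=max_iter)
    converged_warnings = [c for c in caught if issubclass(c.category, ConvergenceWarning)]
    if converged_warnings:
        msg = f"graphical lasso did not reach tol={tol} within {max_iter} iterations"
        if raise_on_nonconvergence:
            raise ConvergenceError(msg, n_iter=max_iter)
        logger.warning(msg)
    return (precision + precision.T) / 2.0


# ---------------------------------------------------------------------------
# Scores


def psicov_score_matrix(precision: np.ndarray, L: int) -> np.ndarray:
    """Raw coupling scores: sum of |entries| of each 20 x 20 block; zero diagonal."""
    d = L * N_STATES
    if precision.shape != (d, d):
        raise ParameterError(
            f"precision has shape {precision.shape}, expected ({d}, {d}) for L={L}"
        )
    blocks = np.abs(precision).reshape(L, N_STATES, L, N_STATES)
    raw = blocks.sum(axis=(1, 3))
    raw = (raw + raw.T) / 2.0
    np.fill_diagonal(raw, 0.0)
    return raw


def apc_correct(raw: np.ndarray) -> np.ndarray:
    """Average product correction: ``APC_ij = raw_ij - mean_i mean_j / mean_all``.

    Row means are over off-diagonal entries; ``mean_all`` is over all i < j
    pairs.  A zero overall mean returns the input unchanged with a warning.
    """
    L = raw.shape[0]
    if L < 3:
        raise ParameterError("APC needs at least 3 columns")
    if not np.allclose(raw, raw.T):
        raise ParameterError("raw score matrix must be symmetric")
    row_means = raw.sum(axis=1) / (L - 1)
    iu = np.triu_indices(L, 1)
    mean_all = float(raw[iu].mean())
    if mean_all == 0.0:
        logger.warning("APC skipped: overall mean score is zero")
        return raw.copy()
    apc = raw - np.outer(row_means, row_means) / mean_all
    np.fill_diagonal(apc, 0.0)
    return apc


def normalize_and_threshold(
    apc: np.ndarray,
    sigma_cut: float = 3.0,
    min_separation: int = 5,
    raw: np.ndarray | None = None,
    colmap: np.ndarray | None = None,
    domain_boundary: int | None = None,
    min_eligible: int = 10,
) -> tuple[np.ndarray, list[Coupling], float]:
    """Standardise APC scores over eligible pairs and extract top couplings.

    Eligible pairs satisfy ``|i - j| >= min_separation`` (column indices).
    Returns the z matrix, couplings with ``z > sigma_cut`` sorted by
    descending z, and the fraction of eligible pairs above the cut.
    ``score_norm`` on each coupling is the min–max normalisation of the APC
    score over eligible pairs.  ``colmap`` translates column indices to the
    reported 1-based residue numbers.
    """
    L = apc.shape[0]
    iu = np.triu_indices(L, 1)
    sep_ok = (iu[1] - iu[0]) >= min_separation
    ei, ej = iu[0][sep_ok], iu[1][sep_ok]
    if ei.size < max(min_eligible, 2):
        raise ParameterError(f"only {ei.size} eligible pairs (need >= {min_eligible})")
    vals = apc[ei, ej]
    mean, sd = float(vals.mean()), float(vals.std())
    if sd == 0.0:
        raise CoevoringError("degenerate score distribution (zero spread)")
    z = (apc - mean) / sd
    np.fill_diagonal(z, 0.0)
    span = float(vals.max() - vals.min())
    zvals = (vals - mean) / sd
    above = zvals > sigma_cut
    fraction = float(above.mean())
    order = np.argsort(-zvals[above], kind="stable")

    def resnum(col: int) -> int:
        if colmap is None:
            return col + 1
        return int(colmap[col])

    couplings = []
    for k in np.flatnonzero(above)[order]:
        ci, cj = int(ei[k]), int(ej[k])
        inter = (
            domain_boundary is not None and (ci < domain_boundary) != (cj < domain_boundary)
        )
        couplings.append(
            Coupling(
                i=resnum(ci),
                j=resnum(cj),
                score_raw=float(raw[ci, cj]) if raw is not None else float("nan"),
                score_apc=float(apc[ci, cj]),
                z=float(zvals[k]),
                score_norm=float((vals[k] - vals.min()) / span) if span > 0 else 0.0,
                inter_domain=bool(inter),
            )
        )
    return z, couplings, fraction


def column_shuffle_null(msa: Msa, seed: int) -> Msa:
    """Randomisation control: permute residues independently within each column.

    Every column keeps its composition but inter-column covariance is
    destroyed; rescoring the shuffled alignment yields the null score
    distribution (symmetric, signal lost).  Deterministic per seed.
    """
    if msa.N < 2:
        raise ParameterError("need at least 2 rows to shuffle")
    rng = np.random.default_rng(seed)
    chars = np.array([list(r) for r in msa.rows])
    for c in range(msa.L):
        chars[:, c] = chars[rng.permutation(msa.N), c]
    rows = ["".join(row) for row in chars]
    return replace(msa, rows=rows)


# ---------------------------------------------------------------------------
# Driver


def compute_coevolution(
    msa: Msa,
    weights: SequenceWeights | None = None,
    lam: float = 1.0,
    theta: float = 0.62,
    rho: float = 0.005,
    shrink: float = 0.1,
    sigma_cut: float = 3.0,
    min_separation: int = 5,
    tol: float = 1e-2,
    max_iter: int = 30,
    seed: int | None = None,
) -> CoevolutionResult:
    """Full scoring chain: weights -> frequencies -> covariance -> precision
    -> raw/APC/z matrices and thresholded couplings.

    The reported ``fraction_above`` always includes the 2.5-sigma and
    3.0-sigma fractions alongside the requested cut, for comparison of the
    tail mass across alignments.
    """
    if weights is None:
        weights = sequence_weights(msa, theta=theta)
    fm = pair_frequencies(msa, weights, lam=lam)
    cov = shrink_covariance(build_covariance(fm), shrink=shrink)
    precision = sparse_precision(cov, rho=rho, tol=tol, max_iter=max_iter)
    raw = psicov_score_matrix(precision, msa.L)
    apc = apc_correct(raw)
    z, couplings, fraction = normalize_and_threshold(
        apc,
        sigma_cut=sigma_cut,
        min_separation=min_separation,
        raw=raw,
        colmap=msa.colmap,
        domain_boundary=msa.domain_boundary,
    )
    fractions = {f"{sigma_cut:g}": fraction}
    for extra in (2.5, 3.0):
        key = f"{extra:g}"
        if key not in fractions:
            _, _, frac = normalize_and_threshold(
                apc, sigma_cut=extra, min_separation=min_separation
            )
            fractions[key] = frac
    return CoevolutionResult(
        raw=raw,
        apc=apc,
        z=z,
        sigma_cut=sigma_cut,
        min_separation=min_separation,
        couplings=couplings,
        fraction_above=fractions,
        meta={
            "rho": rho,
            "lambda": lam,
            "theta": theta,
            "shrink": shrink,
            "seed": seed,
            "n_eff": fm.n_eff,
            "N": msa.N,
            "L": msa.L,
        },
    )


def write_scores_tsv(result: CoevolutionResult, path: str | Path, colmap=None) -> None:
    """Write all eligible pairs as TSV (i, j, raw, apc, z; 1-based numbering)."""
    L = result.L
    with open(path, "w") as fh:
        fh.write("i\tj\traw\tapc\tz\n")
        for ci in range(L):
            for cj in range(ci + result.min_separation, L):
                i = int(colmap[ci]) if colmap is not None else ci + 1
                j = int(colmap[cj]) if colmap is not None else cj + 1
                fh.write(
                    f"{i}\t{j}\t{result.raw[ci, cj]:.6g}\t"
                    f"{result.apc[ci, cj]:.6g}\t{result.z[ci, cj]:.6g}\n"
                )


def write_score_matrix(result: CoevolutionResult, path: str | Path, which: str = "apc") -> None:
    """Write one score matrix (raw/apc/z) as a whitespace-delimited square grid."""
    mat = {"raw": result.raw, "apc": result.apc, "z": result.z}[which]
    np.savetxt(path, mat, fmt="%.6g")
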