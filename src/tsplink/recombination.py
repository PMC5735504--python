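"""Pairwise recombination-frequency (rf) estimation.

The rf matrix is the pipeline's central object: markers are vertices of a
complete graph whose edge weights are pairwise rf estimates, and every
downstream stage (spanning-tree clustering, path splitting, merging,
ordering) operates on it.

Three estimators are provided, matching the mapping designs supported:

* :func:`rf_homozygous` -- recombinant inbred lines by selfing / doubled
  haploids, where each individual is a two-state (A/B) mosaic and rf is a
  mismatch fraction.
* :func:`rf_backcross` -- backcross to the A parent, calls in {A, H};
  again a direct mismatch fraction.
* :func:`rf_f2_em` -- F2 intercross, calls in {A, H, B}; the double
  heterozygote is ambiguous, so rf is fitted by expectation-maximisation
  on the 3x3 joint genotype table under the standard two-locus model.

Missing-data handling for the direct estimators: when one of the two
calls is missing, the comparison could resolve either way, so the pair's
rf is placed at the midpoint of its attainable range.  With c mutually
scored individuals, d mismatches among them and u individuals with at
least one missing call, the attainable range is [d/(c+u), (d+u)/(c+u)]
and the midpoint is (d + u/2)/(c + u).  This keeps missing calls from
either attracting or repelling marker pairs.

Estimates above a cutoff (default 0.4) are inflated to exactly 0.5 by
:func:`apply_cutoff`: large rf values separate linkage groups but their
precise magnitude is noise, and inflating them stops the path solvers
from spending effort optimising non-informative edges.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, UndefinedRfError, ValidationError
from .genotypes import CALL_A, CALL_B, CALL_H, MISSING, GenotypeMatrix


@dataclass
class RFMatrix:
    """Symmetric pairwise rf matrix with per-entry informative-pair counts."""

    marker_names: list[str]
    rf: np.ndarray  # float64, shape (m, m), entries in [0, 0.5]
    support: np.ndarray  # number of mutually scored individuals per pair

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=np.float64)
        self.support = np.asarray(self.support)
        self.validate()

    def validate(self) -> None:
        m = len(self.marker_names)
        if self.rf.shape != (m, m):
            raise ValidationError(f"rf matrix shape {self.rf.shape} for {m} markers")
        if self.support.shape != (m, m):
            raise ValidationError("support matrix shape mismatch")
        if not np.allclose(self.rf, self.rf.T, atol=1e-9):
            raise ValidationError("rf matrix is not symmetric")
        if np.any(np.diag(self.rf) != 0.0):
            raise ValidationError("rf diagonal must be zero")
        if self.rf.min() < 0.0 or self.rf.max() > 0.5 + 1e-12:
            raise ValidationError("rf entries must lie in [0, 0.5]")
        if self.support.min() < 0:
            raise ValidationError("negative support count")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)


def _mismatch_rf(
    g: GenotypeMatrix, code_a: int, code_b: int, legal: set[int]
) -> RFMatrix:
    """Shared midpoint-adjusted mismatch estimator for two-state designs."""
    if g.n_individuals < 1:
        raise UndefinedRfError("no individuals: rf undefined for every pair")
    present = set(np.unique(g.calls).tolist())
    if not present <= legal:
        raise ValidationError(
            f"calls {sorted(present - legal)} not legal for this design; "
            "filter/recode heterozygous calls first"
        )
    a = (g.calls == code_a).astype(np.float64)
    b = (g.calls == code_b).astype(np.float64)
    obs = a + b  # 1 where scored
    n = g.n_individuals
    c = obs @ obs.T  # mutually scored count
    d = a @ b.T + b @ a.T  # mismatches among mutually scored
    u = n - c  # at least one call missing
    # midpoint of the attainable range [d/(c+u), (d+u)/(c+u)]; c + u == n
    rf = (d + 0.5 * u) / n
    np.fill_diagonal(rf, 0.0)
    rf = np.minimum(rf, 0.5)
    rf = 0.5 * (rf + rf.T)  # exact symmetry against float noise
    return RFMatrix(list(g.marker_names), rf, c.astype(np.int64))


def rf_homozygous(g: GenotypeMatrix) -> RFMatrix:
    """rf for homozygous designs (RIL by selfing, doubled haploid).

    Calls must be in {A, B, missing}; heterozygous calls must have been
    recoded by the filter stage.  No inverse mapping-function correction
    is applied: the RIL inflation R = 2r/(1+2r) is monotone in r, and the
    clustering and ordering stages only need a monotone distance.
    """
    return _mismatch_rf(g, CALL_A, CALL_B, {CALL_A, CALL_B, MISSING})


def rf_backcross(g: GenotypeMatrix) -> RFMatrix:
    """rf for a backcross to the A parent; calls in {A, H, missing}."""
    return _mismatch_rf(g, CALL_A, CALL_H, {CALL_A, CALL_H, MISSING})


# ordered haplotype-pair enumeration for the F2 two-locus model:
# each individual carries two independent gametes; a gamete is
# non-recombinant with probability 1-r.  For each joint genotype class
# (i, j) = (# B alleles at locus 1, # B alleles at locus 2) we count the
# haplotype-pair configurations with 0, 1 and 2 recombinant gametes.
_F2_CLASS_TERMS = np.zeros((3, 3, 3))  # [i, j, n_recombinant_gametes] -> #configs
for _h1 in ((0, 0), (0, 1), (1, 0), (1, 1)):
    for _h2 in ((0, 0), (0, 1), (1, 0), (1, 1)):
        _i, _j = _h1[0] + _h2[0], _h1[1] + _h2[1]
        _k = int(_h1[0] != _h1[1]) + int(_h2[0] != _h2[1])
        _F2_CLASS_TERMS[_i, _j, _k] += 1


def f2_class_probabilities(r: np.ndarray) -> np.ndarray:
    """Joint genotype-class probabilities P(i, j | r) for the F2 model.

    ``r`` may be scalar or an array; the result has shape (3, 3) + r.shape.
    """
    r = np.asarray(r, dtype=np.float64)
    w0 = (1.0 - r) / 2.0
    w1 = r / 2.0
    pad = (3, 3) + (1,) * r.ndim
    t0 = _F2_CLASS_TERMS[:, :, 0].reshape(pad)
    t1 = _F2_CLASS_TERMS[:, :, 1].reshape(pad)
    t2 = _F2_CLASS_TERMS[:, :, 2].reshape(pad)
    return t0 * w0 * w0 + t1 * w0 * w1 + t2 * w1 * w1


def rf_f2_em(
    g: GenotypeMatrix, max_iter: int = 100, tol: float = 1e-6
) -> RFMatrix:
    """Maximum-likelihood rf for an F2 intercross, fitted by EM.

    For every marker pair the 3x3 joint genotype table is tallied over
    mutually scored individuals.  The E step computes the expected number
    of recombinant gametes per individual given the current rf (only the
    double-heterozygote class is genuinely ambiguous); the M step divides
    by twice the individual count.  Initialised at rf = 0.25; iterated to
    ``tol`` or ``max_iter``.  All pairs are updated simultaneously with
    vectorised arithmetic.
    """
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    legal = {CALL_A, CALL_H, CALL_B, MISSING}
    present = set(np.unique(g.calls).tolist())
    if not present <= legal:
        raise ValidationError(f"illegal F2 calls {sorted(present - legal)}")

    m = g.n_markers
    # genotype class = number of B alleles: A -> 0, H -> 1, B -> 2
    cls = {0: (g.calls == CALL_A), 1: (g.calls == CALL_H), 2: (g.calls == CALL_B)}
    ind = {k: v.astype(np.float64) for k, v in cls.items()}
    counts = np.empty((3, 3, m, m))
    for i in range(3):
        for j in range(3):
            counts[i, j] = ind[i] @ ind[j].T
    total = counts.sum(axis=(0, 1))  # mutually scored individuals per pair
    off_diag = ~np.eye(m, dtype=bool)
    if np.any(total[off_diag] == 0):
        bad = np.argwhere((total == 0) & off_diag)[0]
        raise UndefinedRfError(
            f"no mutually scored individuals for markers "
            f"{g.marker_names[bad[0]]!r} and {g.marker_names[bad[1]]!r}"
        )

    iu = np.triu_indices(m, k=1)
    n_pairs = total[iu]
    c = counts[:, :, iu[0], iu[1]]  # (3, 3, P)
    terms = _F2_CLASS_TERMS  # (3, 3, 3)

    r = np.full(len(iu[0]), 0.25)
    for _ in range(max_iter):
        w0 = (1.0 - r) / 2.0
        w1 = r / 2.0
        p = (
            terms[:, :, 0, None] * w0 * w0
            + terms[:, :, 1, None] * w0 * w1
            + terms[:, :, 2, None] * w1 * w1
        )
        e_rec = terms[:, :, 1, None] * w0 * w1 + 2.0 * terms[:, :, 2, None] * w1 * w1
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(p > 0, e_rec / np.maximum(p, 1e-300), 0.0)
        r_new = (c * ratio).sum(axis=(0, 1)) / (2.0 * n_pairs)
        r_new = np.clip(r_new, 1e-9, 0.5)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new

    rf = np.zeros((m, m))
    rf[iu] = r
    rf = rf + rf.T
    return RFMatrix(list(g.marker_names), rf, total.astype(np.int64))


def f2_pair_loglik(table: np.ndarray, r: float) -> float:
    """Log-likelihood of a 3x3 joint genotype count table at recombination r.

    Exposed for cross-checking the EM estimate against direct
    maximisation.
    """
    p = f2_class_probabilities(np.asarray(r))
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    t = np.asarray(table, dtype=float)
    return float(np.sum(np.where(t > 0, t * logp, 0.0)))


def apply_cutoff(r: RFMatrix, cutoff: float = 0.4) -> RFMatrix:
    """Inflate every off-diagonal rf strictly above ``cutoff`` to 0.5.

    Idempotent and monotone; entries at or below the cutoff are untouched.
    """
    if not 0.0 < cutoff <= 0.5:
        raise ParameterError(f"cutoff must be in (0, 0.5], got {cutoff}")
    rf = r.rf.copy()
    mask = rf > cutoff
    np.fill_diagonal(mask, False)
    rf[mask] = 0.5
    return RFMatrix(list(r.marker_names), rf, r.support.copy())


def write_rf_matrix(r: RFMatrix, path) -> None:
    """Write a square rf CSV with marker names as header row and column."""
    df = pd.DataFrame(r.rf, index=r.marker_names, columns=r.marker_names)
    df.to_csv(path, float_format="%.10g")


def read_rf_matrix(path) -> RFMatrix:
    """Read a square rf CSV (e.g. exported from R/qtl for other designs).

    Rejects non-square files, entries outside [0, 0.5], and asymmetry
    beyond 1e-9.  Support counts are not recoverable from such a file and
    are set to zero.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    names = [c.strip() for c in rows[0][1:]]
    if len(rows) - 1 != len(names):
        raise FormatError(
            f"{path}: {len(rows) - 1} rows for {len(names)} columns (not square)"
        )
    m = len(names)
    rf = np.empty((m, m))
    for i, row in enumerate(rows[1:]):
        if len(row) != m + 1:
            raise FormatError(f"{path}: row {i + 2} has {len(row)} fields")
        rf[i] = [float(v) for v in row[1:]]
    if rf.min() < 0.0 or rf.max() > 0.5:
        raise ValidationError(f"{path}: rf entries outside [0, 0.5]")
    if np.max(np.abs(rf - rf.T)) > 1e-9:
        raise ValidationError(f"{path}: rf matrix is asymmetric")
    rf = 0.5 * (rf + rf.T)
    np.fill_diagonal(rf, 0.0)
    return RFMatrix(names, rf, np.zeros((m, m), dtype=np.int64))
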