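"""Genotype matrices: reading, writing and marker pre-filtering.

A mapping population is stored as a markers x individuals call matrix.
Calls are coded internally as small integers:

====  =====  =========================================
code  value  meaning
====  =====  =========================================
A        0   homozygous for the first parental allele
B        1   homozygous for the second parental allele
H        2   heterozygous
-       -1   missing call
====  =====  =========================================

Before recombination frequencies are estimated, markers are filtered:
exact duplicates are dropped, markers with excessive heterozygous calls
are dropped in homozygous designs (recombinant inbred lines), and of any
pair of markers more similar than a user-chosen threshold only the first
is kept.  Every removal is recorded in a :class:`FilterReport`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import CodingError, FormatError, ParameterError, ValidationError

CALL_A: int = 0
CALL_B: int = 1
CALL_H: int = 2
MISSING: int = -1

#: default mapping from file tokens to internal call codes
DEFAULT_CODING: dict[str, int] = {
    "A": CALL_A,
    "B": CALL_B,
    "H": CALL_H,
    "-": MISSING,
    "NA": MISSING,
}

_CODE_TO_TOKEN = {CALL_A: "A", CALL_B: "B", CALL_H: "H", MISSING: "-"}

CROSS_TYPES = ("riself", "f2", "bc", "unknown")

#: designs scored as (nearly) fully homozygous
HOMOZYGOUS_DESIGNS = ("riself",)


@dataclass
class GenotypeMatrix:
    """Markers x individuals call matrix with names and cross-type tag."""

    marker_names: list[str]
    individual_ids: list[str]
    calls: np.ndarray  # int8, shape (m, n)
    cross_type: str = "unknown"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("duplicate marker names")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("duplicate individual ids")
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D matrix")
        m, n = self.calls.shape
        if m != len(self.marker_names):
            raise ValidationError(
                f"{len(self.marker_names)} marker names for {m} call rows"
            )
        if n != len(self.individual_ids):
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {n} call columns"
            )
        legal = {CALL_A, CALL_B, CALL_H, MISSING}
        present = set(np.unique(self.calls).tolist())
        if not present <= legal:
            raise ValidationError(f"illegal call codes {sorted(present - legal)}")
        if self.cross_type not in CROSS_TYPES:
            raise ValidationError(f"unknown cross type {self.cross_type!r}")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the marker rows in ``keep`` (index array)."""
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            marker_names=[self.marker_names[i] for i in keep],
            individual_ids=list(self.individual_ids),
            calls=self.calls[keep].copy(),
            cross_type=self.cross_type,
        )


@dataclass
class FilterReport:
    """Audit trail of :func:`filter_markers`."""

    removed_duplicates: list[tuple[str, str]] = field(default_factory=list)
    removed_heterozygous: list[str] = field(default_factory=list)
    removed_similarity: list[tuple[str, str, float]] = field(default_factory=list)
    n_markers_in: int = 0
    n_markers_out: int = 0

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_duplicates)
            + len(self.removed_heterozygous)
            + len(self.removed_similarity)
        )


def read_genotypes(
    path, coding: dict[str, int] | None = None, cross_type: str = "unknown"
) -> GenotypeMatrix:
    """Read a genotype CSV: header row of individual ids, one row per marker.

    The first column holds marker names.  Tokens not present in ``coding``
    raise :class:`~tsplink.errors.CodingError` naming the offending cell;
    nothing is silently treated as missing.
    """
    coding = DEFAULT_CODING if coding is None else coding
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    individual_ids = [c.strip() for c in header[1:]]
    width = len(header)
    marker_names: list[str] = []
    calls = np.empty((len(rows) - 1, width - 1), dtype=np.int8)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: line {r} has {len(row)} fields, expected {width}"
            )
        marker_names.append(row[0].strip())
        for c, token in enumerate(row[1:]):
            token = token.strip()
            try:
                calls[r - 2, c] = coding[token]
            except KeyError:
                raise CodingError(
                    f"{path}: unknown genotype token {token!r} at marker "
                    f"{row[0].strip()!r} (line {r}), individual "
                    f"{individual_ids[c]!r} (column {c + 2})"
                ) from None
    return GenotypeMatrix(marker_names, individual_ids, calls, cross_type)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write a genotype CSV in the dialect accepted by :func:`read_genotypes`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker", *g.individual_ids])
        for name, row in zip(g.marker_names, g.calls):
            writer.writerow([name, *(_CODE_TO_TOKEN[int(v)] for v in row)])


def similarity_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise fraction of agreeing calls among mutually non-missing individuals.

    Pairs with no mutually scored individual get similarity 0.
    """
    obs = (calls != MISSING).astype(np.float64)
    both = obs @ obs.T
    agree = np.zeros_like(both)
    for code in (CALL_A, CALL_B, CALL_H):
        ind = (calls == code).astype(np.float64)
        agree += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(both > 0, agree / np.maximum(both, 1.0), 0.0)
    return sim


def filter_markers(
    g: GenotypeMatrix,
    similarity_threshold: float = 1.0,
    max_het_fraction: float = 0.10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the pre-filters, in order: heterozygous, duplicate, similarity.

    * In homozygous designs (``riself``) a marker whose fraction of H calls
      among its non-missing calls exceeds ``max_het_fraction`` is removed;
      H calls on surviving markers are recoded to missing, because residual
      heterozygosity carries no information in a two-state rf estimate.
    * A marker whose call vector is identical to an earlier marker
      (missing matching missing) is removed as a duplicate.
    * Of any pair with similarity above ``similarity_threshold``, the later
      marker in file order is removed.  The default threshold of 1.0 means
      only exact duplicates go; the threshold is deliberately user-chosen.

    Returns the filtered matrix and a :class:`FilterReport`; the surviving
    markers keep their input order, and the first member of any
    duplicate/similar pair is always the one kept.
    """
    if not 0.0 <= similarity_threshold <= 1.0:
        raise ParameterError(
            f"similarity_threshold must be in [0, 1], got {similarity_threshold}"
        )
    if not 0.0 <= max_het_fraction <= 1.0:
        raise ParameterError(
            f"max_het_fraction must be in [0, 1], got {max_het_fraction}"
        )

    report = FilterReport(n_markers_in=g.n_markers)
    calls = g.calls.copy()
    names = list(g.marker_names)
    keep = np.ones(len(names), dtype=bool)

    # stage 1: heterozygous markers (homozygous designs only)
    if g.cross_type in HOMOZYGOUS_DESIGNS:
        non_missing = (calls != MISSING).sum(axis=1)
        het = (calls == CALL_H).sum(axis=1)
        with np.errstate(invalid="ignore"):
            het_frac = np.where(non_missing > 0, het / np.maximum(non_missing, 1), 0.0)
        for i in np.nonzero(het_frac > max_het_fraction)[0]:
            keep[i] = False
            report.removed_heterozygous.append(names[i])
        calls[(calls == CALL_H)] = MISSING  # surviving H calls are uninformative

    # stage 2: exact duplicates (missing == missing)
    surviving = [i for i in range(len(names)) if keep[i]]
    seen: dict[bytes, int] = {}
    for i in surviving:
        key = calls[i].tobytes()
        if key in seen:
            keep[i] = False
            report.removed_duplicates.append((names[seen[key]], names[i]))
        else:
            seen[key] = i

    # stage 3: similarity above threshold (later marker removed)
    surviving = [i for i in range(len(names)) if keep[i]]
    if surviving and similarity_threshold < 1.0:
        sim = similarity_matrix(calls[surviving])
        kept_local: list[int] = []
        for a, i in enumerate(surviving):
            hit = None
            for b in kept_local:
                if sim[b, a] > similarity_threshold:
                    hit = b
                    break
            if hit is None:
                kept_local.append(a)
            else:
                keep[i] = False
                report.removed_similarity.append(
                    (names[surviving[hit]], names[i], float(sim[hit, a]))
                )

    idx = np.nonzero(keep)[0]
    out = GenotypeMatrix(
        marker_names=[names[i] for i in idx],
        individual_ids=list(g.individual_ids),
        calls=calls[idx],
        cross_type=g.cross_type,
    )
    report.n_markers_out = out.n_markers
    assert report.n_markers_out == report.n_markers_in - report.n_removed
    return out, report
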