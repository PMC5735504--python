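"""Mapping-population simulator with known truth.

Generates the study designs the pipeline targets -- recombinant inbred
lines by selfing (riself), F2 intercross (f2) and backcross (bc) -- as a
no-interference Markov chain along each chromosome: adjacent-marker
recombination probabilities come from the inverse Haldane map of the cM
spacing, and genotypes propagate marker to marker with the appropriate
per-design transition.

* riself: each line is a mosaic of two homozygous states; the observed
  switch probability between adjacent markers is the RIL-inflated
  R = 2r / (1 + 2r).
* bc: one informative meiosis; states AA/AB switch with probability r.
* f2: two independent meioses; the genotype is the sum of two gamete
  chains, giving A/H/B calls.

After the clean genotypes are drawn, each call is flipped to a uniformly
chosen different legal genotype with probability eta (genotyping error)
and then blanked with probability gamma (missing data).  Everything is
deterministic given the seed.  Crossover interference and residual
heterozygosity in RILs are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genotypes import CALL_A, CALL_B, CALL_H, MISSING, GenotypeMatrix


@dataclass
class Chromosome:
    name: str
    length_cm: float
    marker_names: list[str]
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions_cm = np.asarray(self.positions_cm, dtype=np.float64)
        if np.any(np.diff(self.positions_cm) < 0):
            raise ParameterError("marker positions must be sorted")
        if self.positions_cm.size and (
            self.positions_cm[0] < 0 or self.positions_cm[-1] > self.length_cm
        ):
            raise ParameterError("marker positions outside chromosome")


@dataclass
class TrueMap:
    chromosomes: list[Chromosome]

    @property
    def n_markers(self) -> int:
        return sum(len(c.marker_names) for c in self.chromosomes)

    def marker_chromosome(self) -> dict[str, str]:
        return {m: c.name for c in self.chromosomes for m in c.marker_names}

    def marker_position(self) -> dict[str, float]:
        return {
            m: float(p)
            for c in self.chromosomes
            for m, p in zip(c.marker_names, c.positions_cm)
        }


@dataclass
class SimParams:
    """Study-design knobs: population size, marker layout, noise rates."""

    n: int = 300
    m: int = 1000
    k: int = 5
    lengths: list[float] | None = None
    cross_type: str = "riself"
    eta: float = 0.0  # genotyping error rate
    gamma: float = 0.0  # missing-data rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lengths is None:
            self.lengths = [100.0] * self.k
        if len(self.lengths) != self.k:
            raise ParameterError("lengths must have one entry per chromosome")
        if self.n < 2:
            raise ParameterError("need at least 2 individuals")
        if self.m < self.k:
            raise ParameterError("need at least one marker per chromosome")
        if not (0.0 <= self.eta < 1.0 and 0.0 <= self.gamma < 1.0):
            raise ParameterError("eta and gamma must be in [0, 1)")
        if self.cross_type not in ("riself", "f2", "bc"):
            raise ParameterError(f"unsupported cross type {self.cross_type!r}")


def make_true_map(p: SimParams) -> TrueMap:
    """Evenly spaced markers, split as evenly as possible across chromosomes."""
    base, extra = divmod(p.m, p.k)
    chroms: list[Chromosome] = []
    for c in range(p.k):
        count = base + (1 if c < extra else 0)
        length = float(p.lengths[c])
        positions = np.linspace(0.0, length, count) if count > 1 else np.array([0.0])
        names = [f"C{c + 1:02d}M{i + 1:04d}" for i in range(count)]
        chroms.append(Chromosome(f"chr{c + 1:02d}", length, names, positions))
    return TrueMap(chroms)


def haldane_inverse(d_cm: np.ndarray) -> np.ndarray:
    """Recombination probability for a cM interval under the Haldane map."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=np.float64) / 50.0))


def ril_self_inflation(r: np.ndarray) -> np.ndarray:
    """Observed recombinant fraction in selfed RILs: R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=np.float64)
    return 2.0 * r / (1.0 + 2.0 * r)


def _gamete_chain(rng: np.random.Generator, n: int, r: np.ndarray) -> np.ndarray:
    """n independent two-state chains over len(r)+1 markers, switch prob r."""
    n_mark = len(r) + 1
    start = rng.integers(0, 2, size=(n, 1))
    switches = rng.random((n, len(r))) < r[None, :]
    flips = np.concatenate((start, switches.astype(np.int64)), axis=1)
    return np.cumsum(flips, axis=1) % 2


def simulate_population(tm: TrueMap, p: SimParams) -> GenotypeMatrix:
    """Draw a genotype matrix for the given true map and design."""
    rng = np.random.default_rng(p.seed)
    columns: list[np.ndarray] = []
    for chrom in tm.chromosomes:
        r = haldane_inverse(np.diff(chrom.positions_cm))
        if p.cross_type == "riself":
            states = _gamete_chain(rng, p.n, ril_self_inflation(r))
            calls = np.where(states == 0, CALL_A, CALL_B)
        elif p.cross_type == "bc":
            states = _gamete_chain(rng, p.n, r)
            calls = np.where(states == 0, CALL_A, CALL_H)
        else:  # f2: two independent meioses
            g1 = _gamete_chain(rng, p.n, r)
            g2 = _gamete_chain(rng, p.n, r)
            dosage = g1 + g2
            calls = np.where(dosage == 0, CALL_A, np.where(dosage == 1, CALL_H, CALL_B))
        columns.append(calls.T.astype(np.int8))  # markers x individuals
    calls = np.vstack(columns)

    legal = {"riself": [CALL_A, CALL_B], "bc": [CALL_A, CALL_H],
             "f2": [CALL_A, CALL_H, CALL_B]}[p.cross_type]
    if p.eta > 0:
        err = rng.random(calls.shape) < p.eta
        # flip to a uniformly chosen *different* legal genotype
        offset = rng.integers(1, len(legal), size=calls.shape)
        lut = np.array(legal)
        inv = np.full(max(legal) + 1, -1)
        for idx, code in enumerate(legal):
            inv[code] = idx
        new_codes = lut[(inv[calls] + offset) % len(legal)]
        calls = np.where(err, new_codes, calls).astype(np.int8)
    if p.gamma > 0:
        miss = rng.random(calls.shape) < p.gamma
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    names = [m for c in tm.chromosomes for m in c.marker_names]
    individuals = [f"ind{i + 1:05d}" for i in range(p.n)]
    return GenotypeMatrix(names, individuals, calls, cross_type=p.cross_type)


def shuffle_markers(
    g: GenotypeMatrix, seed: int = 0
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Randomise marker row order (pipeline input should not leak the truth).

    Returns the shuffled matrix and the permutation used, so evaluation
    can still recover each marker's true identity by name.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(g.n_markers)
    return g.subset(perm), perm


def write_truth(tm: TrueMap, path) -> None:
    """Truth table CSV: marker, chromosome, position_cM."""
    rows = [
        {"marker": m, "chromosome": c.name, "position_cM": float(pos)}
        for c in tm.chromosomes
        for m, pos in zip(c.marker_names, c.positions_cm)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth(path) -> TrueMap:
    df = pd.read_csv(path)
    chroms = []
    for name, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values("position_cM")
        positions = sub["position_cM"].to_numpy(dtype=float)
        length = float(positions[-1]) if len(positions) else 0.0
        chroms.append(
            Chromosome(str(name), length, [str(m) for m in sub["marker"]], positions)
        )
    return TrueMap(chroms)
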