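"""Pan-genome analysis: protein families, core/accessory/unique partition,
rarefaction curves and the Heaps'-law open/closed call.

Proteins are clustered into orthologous families by greedy centroid
clustering at a global-alignment identity threshold (default 0.5, the
usearch-style setting). The family-by-genome presence matrix is then
partitioned into core (all genomes), unique (exactly one) and accessory
(the rest), rarefied over random genome orderings (default 500), and the
pan curve pan(N) ~ kappa * N^gamma is fitted in log-log space. A
pan-genome is called open when the bootstrap confidence interval for
gamma stays above a small positive threshold: every added genome keeps
contributing new families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .errors import ValidationError
from .records import ProteinRecord


@njit(cache=True)
def _nw_align(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """Global alignment, match +1 / mismatch 0 / gap -1 (linear).

    Returns (matches, alignment_length) from the deterministic traceback
    that prefers diagonal over up over left at score ties.
    """
    la, lb = a.shape[0], b.shape[0]
    H = np.empty((la + 1, lb + 1), np.int32)
    for j in range(lb + 1):
        H[0, j] = -j
    for i in range(1, la + 1):
        H[i, 0] = -i
        for j in range(1, lb + 1):
            best = H[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            up = H[i - 1, j] - 1
            if up > best:
                best = up
            left = H[i, j - 1] - 1
            if left > best:
                best = left
            H[i, j] = best
    i, j = la, lb
    matches = 0
    alen = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0):
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        alen += 1
    return matches, alen


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (gaps count
    toward the length)."""
    if not a or not b:
        raise ValidationError("sequences must be non-empty")
    matches, alen = _nw_align(_encode(a), _encode(b))
    return matches / alen


@dataclass
class PangenomeMatrix:
    """Family-by-genome presence matrix plus family membership lists."""

    families: list[str]
    genomes: list[str]
    presence: np.ndarray  # bool, shape (n_families, n_genomes)
    family_members: dict[str, list[tuple[str, str]]]  # family -> [(genome, protein)]

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.presence.astype(int), index=self.families, columns=self.genomes)


def cluster_proteins(records: Sequence[ProteinRecord], threshold: float = 0.5) -> PangenomeMatrix:
    """Greedy centroid clustering of proteins into families.

    Records are processed longest-first (ties by genome|protein id). A
    record joins the FIRST existing family whose centroid (the founding
    sequence) aligns at identity >= threshold; otherwise it founds a new
    family. Deterministic under input shuffling.
    """
    if not records:
        raise ValidationError("cluster_proteins needs at least one record")
    keys = [f"{r.genome_id}|{r.protein_id}" for r in records]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (genome_id, protein_id)")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i].sequence), keys[i]))

    centroids: list[np.ndarray] = []
    members: list[list[ProteinRecord]] = []
    for i in order:
        rec = records[i]
        enc = _encode(rec.sequence)
        placed = False
        for fam_idx, cent in enumerate(centroids):
            matches, alen = _nw_align(enc, cent)
            if matches / alen >= threshold:
                members[fam_idx].append(rec)
                placed = True
                break
        if not placed:
            centroids.append(enc)
            members.append([rec])

    genomes = sorted({r.genome_id for r in records})
    gidx = {g: k for k, g in enumerate(genomes)}
    width = max(4, len(str(len(members))))
    families = [f"F{k + 1:0{width}d}" for k in range(len(members))]
    presence = np.zeros((len(members), len(genomes)), dtype=bool)
    family_members: dict[str, list[tuple[str, str]]] = {}
    for k, recs in enumerate(members):
        family_members[families[k]] = sorted((r.genome_id, r.protein_id) for r in recs)
        for r in recs:
            presence[k, gidx[r.genome_id]] = True
    return PangenomeMatrix(
        families=families, genomes=genomes, presence=presence, family_members=family_members
    )


def matrix_from_planted(records: Sequence[ProteinRecord]) -> PangenomeMatrix:
    """Presence matrix straight from planted family labels (synthetic
    data), skipping alignment-based clustering."""
    fams = sorted({r.planted_family for r in records if r.planted_family is not None})
    if not fams:
        raise ValidationError("records carry no planted_family labels")
    genomes = sorted({r.genome_id for r in records})
    fidx = {f: i for i, f in enumerate(fams)}
    gidx = {g: i for i, g in enumerate(genomes)}
    presence = np.zeros((len(fams), len(genomes)), dtype=bool)
    family_members: dict[str, list[tuple[str, str]]] = {f: [] for f in fams}
    for r in records:
        presence[fidx[r.planted_family], gidx[r.genome_id]] = True
        family_members[r.planted_family].append((r.genome_id, r.protein_id))
    return PangenomeMatrix(
        families=list(fams),
        genomes=genomes,
        presence=presence,
        family_members={f: sorted(v) for f, v in family_members.items()},
    )


@dataclass
class PartitionResult:
    """Core/accessory/unique split of the family set."""

    core: list[str]
    accessory: list[str]
    unique: list[str]
    per_genome_unique: dict[str, int]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "core": len(self.core),
            "accessory": len(self.accessory),
            "unique": len(self.unique),
        }


def partition(m: PangenomeMatrix) -> PartitionResult:
    """Core = families in all genomes; unique = in exactly one (credited
    to that genome); accessory = everything else."""
    if m.n_genomes < 2:
        raise ValidationError("pan-genome partition needs >= 2 genomes")
    counts = m.presence.sum(axis=1)
    core, accessory, unique = [], [], []
    per_genome_unique = {g: 0 for g in m.genomes}
    for k, fam in enumerate(m.families):
        if counts[k] == m.n_genomes:
            core.append(fam)
        elif counts[k] == 1:
            unique.append(fam)
            per_genome_unique[m.genomes[int(np.argmax(m.presence[k]))]] += 1
        else:
            accessory.append(fam)
    return PartitionResult(
        core=core, accessory=accessory, unique=unique, per_genome_unique=per_genome_unique
    )


@dataclass
class RarefactionResult:
    """Pan/core rarefaction curves over random genome orderings.

    ``pan_curves``/``core_curves`` hold one row per permutation; the
    median/quartile summaries are per prefix size N = 1..n_genomes.
    """

    sizes: np.ndarray
    pan_curves: np.ndarray  # (iterations, n_genomes)
    core_curves: np.ndarray
    iterations: int
    seed: int
    pan_median: np.ndarray = field(init=False)
    core_median: np.ndarray = field(init=False)
    pan_quartiles: tuple[np.ndarray, np.ndarray] = field(init=False)
    core_quartiles: tuple[np.ndarray, np.ndarray] = field(init=False)

    def __post_init__(self):
        self.pan_median = np.median(self.pan_curves, axis=0)
        self.core_median = np.median(self.core_curves, axis=0)
        self.pan_quartiles = (
            np.percentile(self.pan_curves, 25, axis=0),
            np.percentile(self.pan_curves, 75, axis=0),
        )
        self.core_quartiles = (
            np.percentile(self.core_curves, 25, axis=0),
            np.percentile(self.core_curves, 75, axis=0),
        )


def rarefaction(m: PangenomeMatrix, iterations: int = 500, seed: int = 0) -> RarefactionResult:
    """Pan/core family counts over prefixes of random genome orderings.

    pan(N) = families seen in the first N genomes of a permutation
    (non-decreasing); core(N) = families present in all N of them
    (non-increasing). Reproducible for a given seed.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if m.n_genomes < 2:
        raise ValidationError("rarefaction needs >= 2 genomes")
    rng = np.random.default_rng(seed)
    pan = np.empty((iterations, m.n_genomes), dtype=np.int64)
    core = np.empty((iterations, m.n_genomes), dtype=np.int64)
    for it in range(iterations):
        perm = rng.permutation(m.n_genomes)
        ordered = m.presence[:, perm]
        pan[it] = np.logical_or.accumulate(ordered, axis=1).sum(axis=0)
        core[it] = np.logical_and.accumulate(ordered, axis=1).sum(axis=0)
    return RarefactionResult(
        sizes=np.arange(1, m.n_genomes + 1),
        pan_curves=pan,
        core_curves=core,
        iterations=iterations,
        seed=seed,
    )


@dataclass
class HeapsFit:
    """Heaps'-law fit pan(N) = kappa * N^gamma with an open/closed call."""

    kappa: float
    gamma: float
    gamma_ci: tuple[float, float]
    open: bool
    open_threshold: float


def _fit_loglog(curve: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    if (curve <= 0).any():
        raise ValidationError("pan curve values must be > 0 for a log-log fit")
    gamma, log_kappa = np.polyfit(np.log(sizes), np.log(curve), 1)
    return float(np.exp(log_kappa)), float(gamma)


def fit_heaps(
    pan: RarefactionResult | np.ndarray | Sequence[float],
    open_threshold: float = 0.02,
    ci: tuple[float, float] = (2.5, 97.5),
) -> HeapsFit:
    """Least-squares fit of log pan(N) = log kappa + gamma log N.

    Given a RarefactionResult, the point estimate comes from the median
    curve and the gamma confidence interval from refitting every stored
    permutation curve (a bootstrap over genome orderings). Given a bare
    curve, the interval degenerates to the point estimate. Open iff the
    CI lower bound exceeds ``open_threshold``.
    """
    if isinstance(pan, RarefactionResult):
        sizes = pan.sizes.astype(float)
        if len(sizes) < 3:
            raise ValidationError("need >= 3 prefix sizes to fit Heaps' law")
        kappa, gamma = _fit_loglog(pan.pan_median, sizes)
        gammas = np.array([_fit_loglog(c, sizes)[1] for c in pan.pan_curves])
        lo, hi = np.percentile(gammas, ci)
        gamma_ci = (float(lo), float(hi))
    else:
        curve = np.asarray(pan, dtype=float)
        if curve.ndim != 1 or len(curve) < 3:
            raise ValidationError("need a 1-D pan curve of length >= 3")
        sizes = np.arange(1, len(curve) + 1, dtype=float)
        kappa, gamma = _fit_loglog(curve, sizes)
        gamma_ci = (gamma, gamma)
    return HeapsFit(
        kappa=kappa,
        gamma=gamma,
        gamma_ci=gamma_ci,
        open=gamma_ci[0] > open_threshold,
        open_threshold=open_threshold,
    )


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Proteins from FASTA with ``>genome|protein`` headers."""
    from .io_formats import read_fasta

    seqs = read_fasta(path)
    records = []
    for name, seq in seqs.records:
        if "|" not in name:
            raise ValidationError(f"protein header {name!r} lacks 'genome|protein' form")
        genome, protein = name.split("|", 1)
        records.append(ProteinRecord(genome_id=genome, protein_id=protein, sequence=seq))
    return records


def write_protein_fasta(records: Sequence[ProteinRecord], path) -> None:
    from .io_formats import SequenceSet, write_fasta

    write_fasta(
        SequenceSet(records=[(f"{r.genome_id}|{r.protein_id}", r.sequence) for r in records]),
        path,
    )
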