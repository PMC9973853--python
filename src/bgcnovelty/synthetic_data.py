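"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the shape of a real genome-mining study without
any downloads: a reference landscape of gene cluster families (GCFs) in
domain-feature space, strain repertoires that mix family members with
planted novel clusters at a controlled novelty fraction, contig-break
fragmentation of clusters, and multi-genome protein sets with planted
core/accessory/unique family structure.

Two deliberate modelling choices shape the landscape. First, novelty is
defined geometrically — a planted novel cluster is rejection-sampled
until it lies at least ``novel_min_separation`` from every centroid —
so planted novelty lives on the same scale as the calibrated novelty
threshold tau. Second, the landscape includes a handful of small,
common families (short conserved domain combinations that many strains
carry, the synthetic analogue of ubiquitous terpene/siderophore-like
clusters), and every simulated cluster draws part of its content from
the same common domain pool. Planted novel clusters are drawn from the
large end of the size spectrum, mirroring the large assembly-line loci
in which uncharted chemistry concentrates; they are therefore also the
clusters that contig breaks damage most. Together these give
fragmentation its observed signature: pieces of a broken large cluster
resemble the small common families far more than the intact cluster
resembles anything, so measured novelty drops on fragmented input.

All generators are pure functions of (config, seed): one RNG stream per
call, no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .features import DomainVocabulary, featurize
from .io_formats import write_fixture_genbank  # re-exported fixture writer  # noqa: F401
from .records import PRODUCT_CLASSES, BgcRecord, ProteinRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Configurations (defaults are the study conditions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeConfig:
    """Reference GCF landscape.

    Regular families have 18-30 domains, a quarter drawn from a small
    pool of common domains; centroids are rejection-sampled to keep a
    minimum pairwise feature distance so the planted partition is
    unambiguous. Small common families (3 disjoint common-pool domains
    each, repeated ``small_family_multiplicity`` times, zero
    within-family jitter) model ubiquitous short conserved clusters.
    """

    n_gcfs: int = 20
    vocab_size: int = 200
    domains_per_centroid: tuple[int, int] = (18, 30)
    include_small_common_families: bool = True
    n_small_families: int = 4
    small_family_size: int = 3
    small_family_multiplicity: int = 2
    common_pool_size: int = 12
    common_domain_fraction: float = 0.25
    members_per_gcf: int = 8
    within_gcf_jitter: int = 1
    min_intercentroid_distance: float = 5.5
    seed: int = 0

    def __post_init__(self):
        if self.domains_per_centroid[1] > self.vocab_size:
            raise ValidationError("domains_per_centroid max exceeds vocab_size")
        if self.n_small_families * self.small_family_size > self.common_pool_size:
            raise ValidationError("common pool too small for disjoint small families")
        if min(self.n_gcfs, self.vocab_size, self.members_per_gcf) < 1:
            raise ValidationError("counts must be >= 1")


@dataclass(frozen=True)
class StrainSimConfig:
    """Strain repertoires at a controlled novelty fraction.

    Each strain carries between 10 and 20 clusters; a fraction
    ``novelty_fraction`` of them are planted novel (geometrically
    separated from every centroid), the rest are jittered copies of
    landscape centroids with small common families sampled at
    ``small_family_weight`` times the rate of regular ones.
    """

    n_strains: int = 20
    bgcs_per_strain: tuple[int, int] = (10, 20)
    novelty_fraction: float | tuple[float, float] | Sequence[float] = 0.5
    novel_min_separation: float = 3.0
    novel_domains_per_bgc: tuple[int, int] = (32, 56)
    small_family_weight: float = 3.0
    seed: int = 0


@dataclass(frozen=True)
class FragmentationConfig:
    """Contig-break model: per cluster, Poisson(breaks_per_bgc) cuts
    partition the ordered domain list; every resulting fragment is
    flagged incomplete. The default rate 1.5 emulates the published
    contrast between heavily fragmented and near-complete assemblies."""

    breaks_per_bgc: float = 1.5
    min_fragment_domains: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.breaks_per_bgc < 0:
            raise ValidationError("breaks_per_bgc must be >= 0")


@dataclass(frozen=True)
class PangenomeSimConfig:
    """Multi-genome protein sets with planted family structure.

    Core families appear in every genome, accessory families in a
    presence_prob share of genomes (forced into [2, n_genomes-1]),
    and each genome gets exactly ``unique_per_genome`` private families.
    Orthologs are the ancestral sequence with i.i.d. substitutions at
    ``within_family_mutation_rate`` per site.
    """

    n_genomes: int = 8
    core_families: int = 50
    accessory_families: int = 30
    presence_prob: float = 0.5
    unique_per_genome: int = 12
    protein_length: int = 200
    within_family_mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.presence_prob <= 1) or not (0 <= self.within_family_mutation_rate <= 1):
            raise ValidationError("probabilities must be in [0, 1]")
        if self.accessory_families > 0 and self.n_genomes < 3:
            raise ValidationError(
                "accessory families (present in some but not all genomes, and in "
                "more than one) need at least 3 genomes"
            )


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """Planted GCF landscape: centroid domain lists, reference member
    records (planted_gcf labels) and the shared vocabulary."""

    config: LandscapeConfig
    centroid_domains: list[tuple[str, ...]]
    small_family_indices: list[int]
    records: list[BgcRecord]
    vocabulary: DomainVocabulary

    @property
    def n_families(self) -> int:
        return len(self.centroid_domains)

    def save(self, path) -> None:
        import dataclasses
        import json
        from pathlib import Path

        payload = {
            "config": dataclasses.asdict(self.config),
            "centroid_domains": [list(c) for c in self.centroid_domains],
            "small_family_indices": self.small_family_indices,
            "vocabulary": list(self.vocabulary.domains),
            "records": [
                {
                    "strain_id": r.strain_id,
                    "bgc_id": r.bgc_id,
                    "contig_id": r.contig_id,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "product_class": r.product_class,
                    "complete": r.complete,
                    "domains": list(r.domains),
                    "planted_gcf": r.planted_gcf,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "Landscape":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        raw_cfg = dict(payload["config"])
        for key in ("domains_per_centroid",):
            raw_cfg[key] = tuple(raw_cfg[key])
        return cls(
            config=LandscapeConfig(**raw_cfg),
            centroid_domains=[tuple(c) for c in payload["centroid_domains"]],
            small_family_indices=list(payload["small_family_indices"]),
            records=[BgcRecord(**{**r, "domains": tuple(r["domains"])}) for r in payload["records"]],
            vocabulary=DomainVocabulary(domains=tuple(payload["vocabulary"])),
        )


def _vocab_labels(n: int) -> list[str]:
    return [f"D{i:04d}" for i in range(n)]


def _capped_vector(domains: Sequence[str], vocab: DomainVocabulary) -> np.ndarray:
    return featurize(tuple(domains), vocab, "capped").values


def _substitute(domains: tuple[str, ...], k: int, labels: list[str], rng) -> tuple[str, ...]:
    out = list(domains)
    for _ in range(k):
        pos = int(rng.integers(len(out)))
        choices = [d for d in labels if d != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return tuple(out)


def _random_bgc_domains(
    size: int, labels: list[str], common_pool: list[str], common_fraction: float, rng
) -> tuple[str, ...]:
    n_common = int(round(common_fraction * size)) if common_pool else 0
    common = [common_pool[i] for i in rng.integers(len(common_pool), size=n_common)] if n_common else []
    rest = [labels[i] for i in rng.integers(len(labels), size=size - n_common)]
    domains = common + rest
    rng.shuffle(domains)
    return tuple(domains)


def simulate_landscape(cfg: LandscapeConfig = LandscapeConfig()) -> Landscape:
    """Draw GCF centroids and their jittered member records.

    Regular centroids are rejection-sampled until every pair of regular
    centroids is at least ``min_intercentroid_distance`` apart in capped
    feature space. Small common families use disjoint common-pool
    domain triples and their members carry no jitter (they model highly
    conserved ubiquitous clusters).
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _vocab_labels(cfg.vocab_size)
    vocab = DomainVocabulary(domains=tuple(labels))
    common_pool = labels[: cfg.common_pool_size] if cfg.include_small_common_families else []
    specific = labels[cfg.common_pool_size :] if cfg.include_small_common_families else labels

    centroids: list[tuple[str, ...]] = []
    vectors: list[np.ndarray] = []
    lo, hi = cfg.domains_per_centroid
    for _ in range(cfg.n_gcfs):
        for attempt in range(10_000):
            size = int(rng.integers(lo, hi + 1))
            cand = _random_bgc_domains(size, specific, common_pool, cfg.common_domain_fraction, rng)
            v = _capped_vector(cand, vocab)
            if all(
                np.linalg.norm(v - u) >= cfg.min_intercentroid_distance for u in vectors
            ):
                break
        else:
            raise ValidationError(
                "could not place a centroid at the required separation; "
                "increase vocab_size or lower min_intercentroid_distance"
            )
        centroids.append(cand)
        vectors.append(v)

    small_indices: list[int] = []
    if cfg.include_small_common_families:
        pool = list(common_pool)
        for s in range(cfg.n_small_families):
            take = pool[s * cfg.small_family_size : (s + 1) * cfg.small_family_size]
            take = tuple(take) * cfg.small_family_multiplicity
            small_indices.append(len(centroids))
            centroids.append(take)
            vectors.append(_capped_vector(take, vocab))

    records: list[BgcRecord] = []
    classes = list(PRODUCT_CLASSES)
    for k, cent in enumerate(centroids):
        gcf_label = f"PG{k:03d}"
        jitter = 0 if k in small_indices else cfg.within_gcf_jitter
        for m in range(cfg.members_per_gcf):
            domains = _substitute(cent, jitter, labels, rng) if jitter else tuple(cent)
            start = m * 60_000 + int(rng.integers(0, 20_000))
            records.append(
                BgcRecord(
                    strain_id="REFSET",
                    bgc_id=f"REF_{gcf_label}_M{m:02d}",
                    contig_id=f"refctg{k:03d}",
                    start_bp=start,
                    end_bp=start + 1000 * max(len(domains), 1),
                    product_class=classes[int(rng.integers(len(classes)))],
                    complete=True,
                    domains=domains,
                    planted_gcf=gcf_label,
                )
            )
    return Landscape(
        config=cfg,
        centroid_domains=centroids,
        small_family_indices=small_indices,
        records=records,
        vocabulary=vocab,
    )


# ---------------------------------------------------------------------------
# Strain repertoires
# ---------------------------------------------------------------------------


def _novelty_per_strain(cfg: StrainSimConfig) -> list[float]:
    f = cfg.novelty_fraction
    if isinstance(f, (int, float)):
        values = [float(f)] * cfg.n_strains
    elif isinstance(f, tuple) and len(f) == 2 and all(isinstance(x, (int, float)) for x in f):
        lo, hi = float(f[0]), float(f[1])
        values = list(np.linspace(lo, hi, cfg.n_strains))
    else:
        values = [float(x) for x in f]
        if len(values) != cfg.n_strains:
            raise ValidationError("per-strain novelty_fraction length != n_strains")
    if any(not (0 <= x <= 1) for x in values):
        raise ValidationError("novelty_fraction values must lie in [0, 1]")
    return values


def simulate_strains(
    landscape: Landscape, cfg: StrainSimConfig = StrainSimConfig()
) -> list[list[BgcRecord]]:
    """Strain repertoires with planted_novel flags.

    Each strain draws floor((1-f) * n) member clusters — jittered copies
    of landscape centroids, small common families oversampled by
    ``small_family_weight`` — and the remainder novel clusters,
    rejection-sampled until at least ``novel_min_separation`` from every
    centroid in capped feature space.
    """
    rng = np.random.default_rng(cfg.seed)
    lcfg = landscape.config
    labels = list(landscape.vocabulary.domains)
    common_pool = labels[: lcfg.common_pool_size] if lcfg.include_small_common_families else []
    specific = labels[lcfg.common_pool_size :] if lcfg.include_small_common_families else labels
    centroid_vectors = np.vstack(
        [_capped_vector(c, landscape.vocabulary) for c in landscape.centroid_domains]
    )
    weights = np.ones(landscape.n_families)
    for i in landscape.small_family_indices:
        weights[i] = cfg.small_family_weight
    weights = weights / weights.sum()
    fractions = _novelty_per_strain(cfg)
    classes = list(PRODUCT_CLASSES)

    strains: list[list[BgcRecord]] = []
    for s in range(cfg.n_strains):
        f = fractions[s]
        n = int(rng.integers(cfg.bgcs_per_strain[0], cfg.bgcs_per_strain[1] + 1))
        n_member = int(np.floor((1 - f) * n))
        strain_id = f"S{s:03d}"
        records: list[BgcRecord] = []
        for b in range(n):
            novel = b >= n_member
            if not novel:
                k = int(rng.choice(landscape.n_families, p=weights))
                domains = _substitute(
                    landscape.centroid_domains[k], lcfg.within_gcf_jitter, labels, rng
                )
                planted_gcf = f"PG{k:03d}"
            else:
                for attempt in range(10_000):
                    size = int(
                        rng.integers(cfg.novel_domains_per_bgc[0], cfg.novel_domains_per_bgc[1] + 1)
                    )
                    domains = _random_bgc_domains(
                        size, specific, common_pool, lcfg.common_domain_fraction, rng
                    )
                    v = _capped_vector(domains, landscape.vocabulary)
                    d = np.linalg.norm(centroid_vectors - v, axis=1).min()
                    if d >= cfg.novel_min_separation:
                        break
                else:
                    raise ValidationError(
                        "rejection sampling for a novel cluster exceeded 10^4 tries; "
                        "increase vocab_size or lower novel_min_separation"
                    )
                planted_gcf = None
            # non-overlapping region coordinates within a strain's contigs
            start = (b % 4) * 100_000 + int(rng.integers(0, 30_000))
            records.append(
                BgcRecord(
                    strain_id=strain_id,
                    bgc_id=f"{strain_id}_B{b:03d}",
                    contig_id=f"{strain_id}_ctg{b // 4:03d}",
                    start_bp=start,
                    end_bp=start + 1000 * max(len(domains), 1),
                    product_class=classes[int(rng.integers(len(classes)))],
                    complete=True,
                    domains=domains,
                    planted_novel=novel,
                    planted_gcf=planted_gcf,
                )
            )
        strains.append(records)
    return strains


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------


def fragment_records(
    records: Sequence[BgcRecord],
    cfg: FragmentationConfig = FragmentationConfig(),
    rng: np.random.Generator | None = None,
) -> list[BgcRecord]:
    """Break clusters at random inter-domain positions.

    Per record, k ~ Poisson(breaks_per_bgc) distinct cut points split
    the ordered domain list into k+1 fragments, each flagged incomplete
    (a contig break truncates the cluster). k is capped so that every
    fragment keeps at least ``min_fragment_domains`` domains. k = 0
    leaves the record untouched, completeness flag included. The total
    domain multiset is conserved.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out: list[BgcRecord] = []
    for r in records:
        L = len(r.domains)
        k = int(rng.poisson(cfg.breaks_per_bgc))
        lo, hi = cfg.min_fragment_domains, L - cfg.min_fragment_domains
        candidates = list(range(lo, hi + 1))
        if k == 0 or not candidates:
            out.append(r)
            continue
        cuts = sorted(rng.choice(candidates, size=min(k, len(candidates)), replace=False).tolist())
        # enforce the minimum fragment size between consecutive cuts
        kept: list[int] = []
        for c in cuts:
            if not kept or c - kept[-1] >= cfg.min_fragment_domains:
                kept.append(int(c))
        if not kept:
            out.append(r)
            continue
        bounds = [0] + kept + [L]
        span = r.end_bp - r.start_bp
        for fi in range(len(bounds) - 1):
            a, b = bounds[fi], bounds[fi + 1]
            fstart = r.start_bp + span * a // L
            fend = r.start_bp + span * b // L
            out.append(
                r.with_fields(
                    bgc_id=f"{r.bgc_id}.f{fi:02d}",
                    start_bp=fstart,
                    end_bp=max(fend, fstart + 1),
                    complete=False,
                    domains=r.domains[a:b],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pan-genome proteins
# ---------------------------------------------------------------------------


def _random_protein(length: int, rng) -> str:
    return "".join(_AA[i] for i in rng.integers(len(_AA), size=length))


def _mutate(seq: str, rate: float, rng) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = _AA.replace(chars[i], "")
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def simulate_pangenome(cfg: PangenomeSimConfig = PangenomeSimConfig()) -> list[ProteinRecord]:
    """Protein records with planted core/accessory/unique family labels.

    One random ancestral sequence per family; core families appear in
    every genome, accessory families in a random subset (at least 2 and
    at most n_genomes - 1 genomes, so they are genuinely accessory),
    and each genome receives exactly ``unique_per_genome`` private
    families. Every ortholog copy is independently mutated.
    """
    rng = np.random.default_rng(cfg.seed)
    genomes = [f"G{g:03d}" for g in range(cfg.n_genomes)]
    records: list[ProteinRecord] = []
    counters = {g: 0 for g in genomes}

    def emit(genome: str, family: str, ancestor: str) -> None:
        counters[genome] += 1
        records.append(
            ProteinRecord(
                genome_id=genome,
                protein_id=f"p{counters[genome]:05d}",
                sequence=_mutate(ancestor, cfg.within_family_mutation_rate, rng),
                planted_family=family,
            )
        )

    for c in range(cfg.core_families):
        anc = _random_protein(cfg.protein_length, rng)
        for g in genomes:
            emit(g, f"core{c:04d}", anc)
    for a in range(cfg.accessory_families):
        anc = _random_protein(cfg.protein_length, rng)
        while True:
            mask = rng.random(cfg.n_genomes) < cfg.presence_prob
            if 2 <= mask.sum() <= cfg.n_genomes - 1:
                break
        for g, present in zip(genomes, mask):
            if present:
                emit(g, f"acc{a:04d}", anc)
    for g in genomes:
        for u in range(cfg.unique_per_genome):
            anc = _random_protein(cfg.protein_length, rng)
            emit(g, f"uniq_{g}_{u:04d}", anc)
    return records
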