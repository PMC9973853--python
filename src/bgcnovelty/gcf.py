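"""Gene cluster family (GCF) reference models and nearest-family distance.

A GCF reference is a set of centroid vectors in domain-feature space,
built by deterministic greedy clustering of a BGC collection. The
distance d of a query cluster is its Euclidean distance to the nearest
centroid — the d that enters the biosynthetic novelty index. A cluster
is called "novel" when d exceeds the novelty threshold tau: the literal
tau = 900 applies only to distances on the external BiG-FAM scale;
locally built references live on a different scale, so tau is calibrated
as a percentile of the reference's own member-to-centroid distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .features import DEFAULT_CAP, DomainVocabulary, FeatureVector, feature_matrix
from .records import BgcRecord

#: Novelty threshold on the external BiG-FAM distance scale.
BIGFAM_TAU = 900.0

#: Default greedy-clustering radius for locally built references, in
#: capped-count feature units. Chosen to exceed the within-family
#: scatter of the synthetic landscape (at most ~2.8 for one domain
#: substitution per member) while staying well below inter-family
#: separations.
DEFAULT_BUILD_THRESHOLD = 3.0


@dataclass
class GcfModel:
    """One family: centroid vector, member count and a radius statistic.

    member_radius_p95 is the 95th percentile (nearest-rank) of the
    members' distances to the refined centroid.
    """

    gcf_id: str
    centroid: np.ndarray
    n_members: int
    member_radius_p95: float
    member_distances: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    #: leave-one-out member distances (see build_reference); used for
    #: tau calibration when present, since plain member distances
    #: underestimate the distance of a held-out family member.
    loo_distances: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class GcfReference:
    """A built reference: models, the vocabulary and the thresholds."""

    models: list[GcfModel]
    vocabulary: DomainVocabulary
    build_threshold: float
    novelty_tau: float
    scaling: str = "capped"
    cap: int = DEFAULT_CAP
    #: bgc_id -> gcf_id membership assigned during the build pass.
    assignment: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        ids = [m.gcf_id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate gcf_id in reference")
        if self.novelty_tau <= 0:
            raise ValidationError("novelty_tau must be > 0")

    @property
    def centroid_matrix(self) -> np.ndarray:
        return np.vstack([m.centroid for m in self.models])

    def save(self, path: str | Path) -> None:
        payload = {
            "build_threshold": self.build_threshold,
            "novelty_tau": self.novelty_tau,
            "scaling": self.scaling,
            "cap": self.cap,
            "vocabulary": list(self.vocabulary.domains),
            "models": [
                {
                    "gcf_id": m.gcf_id,
                    "centroid": m.centroid.tolist(),
                    "n_members": m.n_members,
                    "member_radius_p95": m.member_radius_p95,
                }
                for m in self.models
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GcfReference":
        payload = json.loads(Path(path).read_text())
        return cls(
            models=[
                GcfModel(
                    gcf_id=m["gcf_id"],
                    centroid=np.asarray(m["centroid"], dtype=float),
                    n_members=int(m["n_members"]),
                    member_radius_p95=float(m["member_radius_p95"]),
                )
                for m in payload["models"]
            ],
            vocabulary=DomainVocabulary(domains=tuple(payload["vocabulary"])),
            build_threshold=float(payload["build_threshold"]),
            novelty_tau=float(payload["novelty_tau"]),
            scaling=payload.get("scaling", "capped"),
            cap=int(payload.get("cap", DEFAULT_CAP)),
        )


def _nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    return float(np.percentile(values, percentile, method="inverted_cdf"))


def build_reference(
    records: Sequence[BgcRecord],
    build_threshold: float,
    vocabulary: DomainVocabulary | None = None,
    scaling: str = "capped",
    cap: int = DEFAULT_CAP,
    novelty_tau: float | None = None,
    tau_percentile: float = 95.0,
) -> GcfReference:
    """Greedy centroid clustering of a BGC collection into GCF models.

    Records are processed in a deterministic order (descending domain
    count, then lexicographic bgc_id). Each record joins the nearest
    existing seed centroid if its distance is <= build_threshold,
    otherwise it founds a new family seeded at its own vector. After the
    pass each centroid is recomputed as its member mean and the member
    radius statistics are refreshed. The input order therefore never
    affects the result.

    The returned reference carries the record -> gcf_id membership in
    ``ref.assignment``. novelty_tau defaults to :func:`calibrate_tau`
    at ``tau_percentile`` unless given explicitly.
    """
    if build_threshold < 0:
        raise ValidationError("build_threshold must be >= 0")
    records = [r for r in records]
    if not any(r.domains for r in records):
        raise ValidationError("need at least one record with non-empty domains")
    from .features import build_vocabulary

    vocab = vocabulary or build_vocabulary(records)
    order = sorted(range(len(records)), key=lambda i: (-len(records[i].domains), records[i].bgc_id))
    X = feature_matrix([records[i] for i in order], vocab, scaling, cap)

    seeds: list[np.ndarray] = []
    members: list[list[int]] = []  # indices into `order`
    for pos in range(len(order)):
        x = X[pos]
        if seeds:
            d = np.linalg.norm(np.vstack(seeds) - x, axis=1)
            best = int(np.argmin(d))  # first minimum = lowest gcf index = lowest id
            if d[best] <= build_threshold:
                members[best].append(pos)
                continue
        seeds.append(x)
        members.append([pos])

    width = max(4, len(str(len(seeds))))
    models: list[GcfModel] = []
    assignment: dict[str, str] = {}
    for k, idxs in enumerate(members):
        gcf_id = f"GCF{k + 1:0{width}d}"
        mat = X[idxs]
        centroid = mat.mean(axis=0)
        dists = np.linalg.norm(mat - centroid, axis=1)
        n_mem = len(idxs)
        models.append(
            GcfModel(
                gcf_id=gcf_id,
                centroid=centroid,
                n_members=n_mem,
                member_radius_p95=_nearest_rank_percentile(dists, 95.0),
                member_distances=dists,
                loo_distances=dists * (n_mem / (n_mem - 1)) if n_mem > 1 else dists,
            )
        )
        for pos in idxs:
            assignment[records[order[pos]].bgc_id] = gcf_id

    ref = GcfReference(
        models=models,
        vocabulary=vocab,
        build_threshold=build_threshold,
        novelty_tau=1.0,  # placeholder, set below
        scaling=scaling,
        cap=cap,
        assignment=assignment,
    )
    ref.novelty_tau = novelty_tau if novelty_tau is not None else calibrate_tau(ref, tau_percentile)
    if ref.novelty_tau <= 0:
        # degenerate all-identical-members landscape: any positive distance is novel
        ref.novelty_tau = np.finfo(float).tiny
    return ref


def nearest_gcf(x: FeatureVector | np.ndarray, ref: GcfReference) -> tuple[str, float]:
    """Nearest centroid id and Euclidean distance; ties break to the
    lexicographically smallest gcf_id."""
    if not ref.models:
        raise ValidationError("empty reference: no GCF models")
    v = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    d = np.linalg.norm(ref.centroid_matrix - v, axis=1)
    best = d.min()
    candidates = [ref.models[i].gcf_id for i in np.flatnonzero(d == best)]
    return min(candidates), float(best)


def calibrate_tau(ref: GcfReference, percentile: float = 95.0) -> float:
    """Novelty threshold for a locally built reference: the given
    percentile (nearest-rank) of all member-to-centroid distances across
    models. Models built by :func:`build_reference` carry leave-one-out
    distances, which are preferred: a member's distance to a mean
    centroid that includes the member itself underestimates the distance
    of a fresh cluster from the same family (with centroid_{-i} =
    (n c - x_i)/(n - 1) the held-out distance is exactly
    ||x_i - c|| * n/(n - 1)), and calibrating on the corrected values
    keeps the false-novel rate of held-out family members near the
    chosen percentile. Requires at least one model with >= 2 members
    (singleton models have radius 0 by construction and carry no scale
    information on their own).
    """
    if all(m.n_members < 2 for m in ref.models):
        raise ValidationError(
            "all models are singletons; pass an explicit novelty_tau instead of calibrating"
        )
    pools = []
    for m in ref.models:
        if m.loo_distances is not None:
            pools.append(np.asarray(m.loo_distances, dtype=float))
        elif m.member_distances is not None:
            pools.append(np.asarray(m.member_distances, dtype=float))
        else:
            pools.append(np.zeros(m.n_members))
    return _nearest_rank_percentile(np.concatenate(pools), percentile)


def classify_bgc(d: float, tau: float) -> str:
    """"novel" iff d > tau (strict), else "member"."""
    if d < 0 or tau < 0:
        raise ValidationError("d and tau must be >= 0")
    return "novel" if d > tau else "member"
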