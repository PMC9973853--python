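"""Domain-composition feature vectors for BGCs.

A cluster's domain content is counted over a fixed vocabulary to give the
vector on which nearest-family distances are computed. Domains absent
from the vocabulary are not dropped: they accumulate in one reserved
"unknown" bin at the end of the vector, so unrecognized content raises a
cluster's distance to every reference family instead of vanishing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .records import BgcRecord

#: Reserved label for the unknown-domain bin (always the last position).
UNKNOWN_BIN = "__unknown__"

SCALINGS = ("raw_count", "unit_l2", "capped")
DEFAULT_CAP = 5


@dataclass(frozen=True)
class DomainVocabulary:
    """Ordered, de-duplicated domain identifiers plus one unknown bin.

    ``domains`` holds the named domains; feature vectors have length
    ``size = len(domains) + 1``, the extra slot being the unknown bin.
    """

    domains: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.domains)) != len(self.domains):
            raise ValidationError("vocabulary contains duplicate domains")
        if UNKNOWN_BIN in self.domains:
            raise ValidationError(f"{UNKNOWN_BIN!r} is reserved")
        object.__setattr__(self, "_index", {d: i for i, d in enumerate(self.domains)})

    @property
    def index(self) -> dict[str, int]:
        return self._index  # type: ignore[attr-defined]

    @property
    def size(self) -> int:
        return len(self.domains) + 1

    @property
    def unknown_index(self) -> int:
        return len(self.domains)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.domains) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DomainVocabulary":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(domains=tuple(lines))


@dataclass(frozen=True)
class FeatureVector:
    """A non-negative vector over a vocabulary (last slot = unknown bin)."""

    values: np.ndarray
    scaling: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if (self.values < 0).any():
            raise ValidationError("feature values must be non-negative")
        if self.scaling not in SCALINGS:
            raise ValidationError(f"unknown scaling {self.scaling!r}")


def build_vocabulary(records: Sequence[BgcRecord]) -> DomainVocabulary:
    """Sorted union of all domain identifiers across records.

    Deterministic: the result is invariant under any permutation of the
    input. Raises if no record carries any domain (un-annotated input
    cannot be featurized; use synthetic or domain-annotated records).
    """
    domains = sorted({d for r in records for d in r.domains})
    if not domains:
        raise ValidationError(
            "no record carries domain annotations; provide annotated or synthetic input"
        )
    return DomainVocabulary(domains=tuple(domains))


def featurize(
    record_or_domains: BgcRecord | Iterable[str],
    vocabulary: DomainVocabulary,
    scaling: str = "capped",
    cap: int = DEFAULT_CAP,
) -> FeatureVector:
    """Count a record's domains over the vocabulary and scale.

    raw_count: plain multiplicities. capped: multiplicities clipped at
    ``cap`` (default 5), so one giant multi-module cluster cannot
    dominate distances. unit_l2: raw counts divided by their Euclidean
    norm (all-zero vectors stay zero). Domains outside the vocabulary
    are counted in the reserved unknown bin.
    """
    domains = (
        record_or_domains.domains
        if isinstance(record_or_domains, BgcRecord)
        else tuple(record_or_domains)
    )
    v = np.zeros(vocabulary.size, dtype=float)
    idx = vocabulary.index
    unk = vocabulary.unknown_index
    for dom, count in Counter(domains).items():
        v[idx.get(dom, unk)] += count
    if scaling == "capped":
        v = np.minimum(v, cap)
    elif scaling == "unit_l2":
        norm = np.linalg.norm(v)
        if norm > 0:
            v = v / norm
    elif scaling != "raw_count":
        raise ValidationError(f"unknown scaling {scaling!r}")
    return FeatureVector(values=v, scaling=scaling)


def feature_matrix(
    records: Sequence[BgcRecord],
    vocabulary: DomainVocabulary,
    scaling: str = "capped",
    cap: int = DEFAULT_CAP,
) -> np.ndarray:
    """Stack featurized records into an (n_records, vocabulary.size) array."""
    return np.vstack([featurize(r, vocabulary, scaling, cap).values for r in records])


def write_vectors_tsv(
    records: Sequence[BgcRecord],
    vocabulary: DomainVocabulary,
    path: str | Path,
    scaling: str = "capped",
    cap: int = DEFAULT_CAP,
) -> None:
    """Export featurized records as a bgc_id x domain TSV (last column
    is the reserved unknown bin); rows sorted by bgc_id."""
    header = "bgc_id\t" + "\t".join(vocabulary.domains) + f"\t{UNKNOWN_BIN}"
    lines = [header]
    for r in sorted(records, key=lambda r: r.bgc_id):
        v = featurize(r, vocabulary, scaling, cap).values
        lines.append(r.bgc_id + "\t" + "\t".join(f"{x:g}" for x in v))
    Path(path).write_text("\n".join(lines) + "\n")
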