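"""Core record types shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: The seven product-class bins used for class tallies. Any antiSMASH
#: product string that maps to none of the first six falls into "other".
PRODUCT_CLASSES = ("NRPS", "PKS", "hybrid", "terpene", "RiPP", "saccharide", "other")


@dataclass(frozen=True)
class BgcRecord:
    """One detected biosynthetic gene cluster.

    Coordinates are 0-based half-open internally (GenBank's 1-based
    inclusive convention is converted on parse). ``complete`` is the
    negation of the antiSMASH ``contig_edge`` flag: a cluster truncated
    by a contig boundary is incomplete. ``domains`` is the ordered list
    of biosynthetic domain identifiers found inside the region; repeats
    are allowed and order is genomic order (used by the network module's
    adjacency index).

    ``planted_novel`` / ``planted_gcf`` carry synthetic ground truth and
    are ``None`` for records parsed from real annotation output.
    """

    strain_id: str
    bgc_id: str
    contig_id: str
    start_bp: int
    end_bp: int
    product_class: str
    complete: bool
    domains: tuple[str, ...] = field(default_factory=tuple)
    planted_novel: bool | None = None
    planted_gcf: str | None = None

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"{self.bgc_id}: start_bp ({self.start_bp}) must be < end_bp ({self.end_bp})"
            )
        if self.product_class not in PRODUCT_CLASSES:
            raise ValueError(
                f"{self.bgc_id}: unknown product_class {self.product_class!r}; "
                f"expected one of {PRODUCT_CLASSES}"
            )
        object.__setattr__(self, "domains", tuple(self.domains))

    def with_fields(self, **kwargs) -> "BgcRecord":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its genome of origin (pan-genome input)."""

    genome_id: str
    protein_id: str
    sequence: str
    planted_family: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.genome_id}|{self.protein_id}: empty sequence")

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.protein_id)
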