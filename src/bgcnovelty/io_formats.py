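"""Readers, writers and assembly statistics for every external format.

FASTA and GenBank go through Biopython; tabular formats through pandas.
Everything written here is plain text and deterministically ordered so
that identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .records import BgcRecord

if TYPE_CHECKING:  # pragma: no cover
    from .network import BgcNetwork

# IUPAC nucleotide codes accepted by compute_assembly_stats.
_IUPAC_NT = set("ACGTNRYSWKMBDHV")

# antiSMASH product string -> 7-class scheme. The published figures bin
# clusters into NRPS, PKS, hybrid (PKS/NRPS), terpene, RiPP, saccharide
# and "other"; this table covers the common antiSMASH v6 product labels
# and anything unlisted falls back to "other". A region whose product
# list contains both a PKS-type and an NRPS-type label is a hybrid.
PRODUCT_CLASS_MAP: dict[str, str] = {
    "nrps": "NRPS",
    "nrps-like": "NRPS",
    "thioamide-nrp": "NRPS",
    "t1pks": "PKS",
    "t2pks": "PKS",
    "t3pks": "PKS",
    "transat-pks": "PKS",
    "transat-pks-like": "PKS",
    "pks-like": "PKS",
    "hgle-ks": "PKS",
    "terpene": "terpene",
    "lanthipeptide-class-i": "RiPP",
    "lanthipeptide-class-ii": "RiPP",
    "lanthipeptide-class-iii": "RiPP",
    "lanthipeptide-class-iv": "RiPP",
    "lanthipeptide-class-v": "RiPP",
    "lassopeptide": "RiPP",
    "ripp-like": "RiPP",
    "thiopeptide": "RiPP",
    "linaridin": "RiPP",
    "cyanobactin": "RiPP",
    "bacteriocin": "RiPP",
    "ranthipeptide": "RiPP",
    "lap": "RiPP",
    "sactipeptide": "RiPP",
    "microviridin": "RiPP",
    "proteusin": "RiPP",
    "saccharide": "saccharide",
    "oligosaccharide": "saccharide",
    "amglyccycl": "saccharide",
    "other": "other",
}

# Representative product string per class, used by the fixture writer so
# that write -> parse round-trips the class exactly.
CLASS_REPRESENTATIVE_PRODUCTS: dict[str, tuple[str, ...]] = {
    "NRPS": ("NRPS",),
    "PKS": ("T1PKS",),
    "hybrid": ("T1PKS", "NRPS"),
    "terpene": ("terpene",),
    "RiPP": ("RiPP-like",),
    "saccharide": ("saccharide",),
    "other": ("other",),
}


def map_product_class(products: Iterable[str]) -> str:
    """Map an antiSMASH region's product list onto the 7-class scheme."""
    classes = {PRODUCT_CLASS_MAP.get(p.strip().lower(), "other") for p in products}
    if "PKS" in classes and "NRPS" in classes:
        return "hybrid"
    for c in ("NRPS", "PKS", "terpene", "RiPP", "saccharide"):
        if c in classes:
            return c
    return "other"


@dataclass
class SequenceSet:
    """An ordered set of named sequences (assembly contigs or proteins)."""

    records: list[tuple[str, str]]
    source_path: str = ""

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise FormatError(f"duplicate sequence id {dup!r}")
        for i, s in self.records:
            if not s:
                raise FormatError(f"empty sequence for id {i!r}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AssemblyStats:
    """Basic assembly statistics (contig count, size, G+C mol%, N50)."""

    n_contigs: int
    total_length_bp: int
    gc_mol_percent: float
    n50_bp: int


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a SequenceSet (sequences upper-cased)."""
    path = Path(path)
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return SequenceSet(records=records, source_path=str(path))


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in seqs.records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def compute_assembly_stats(seqs: SequenceSet) -> AssemblyStats:
    """Contig count, total size, G+C mol% (to 0.1, excluding N/ambiguity
    codes) and N50 (length at which the descending-length cumulative sum
    first reaches half the assembly size)."""
    if len(seqs) == 0:
        raise ValidationError("cannot compute assembly statistics on an empty set")
    at = gc = 0
    lengths = []
    for name, seq in seqs.records:
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise ValidationError(f"contig {name!r}: non-IUPAC characters {sorted(bad)}")
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        lengths.append(len(seq))
    total = int(sum(lengths))
    if at + gc == 0:
        raise ValidationError("no unambiguous A/C/G/T bases; G+C undefined")
    lengths.sort(reverse=True)
    cum = np.cumsum(lengths)
    n50 = int(lengths[int(np.searchsorted(cum, total / 2))])
    return AssemblyStats(
        n_contigs=len(lengths),
        total_length_bp=total,
        gc_mol_percent=round(100.0 * gc / (at + gc), 1),
        n50_bp=n50,
    )


# ---------------------------------------------------------------------------
# antiSMASH region parsing
# ---------------------------------------------------------------------------

_DOMAIN_FEATURE_TYPES = ("aSDomain", "PFAM_domain")


def _domain_name(feature: SeqFeature) -> str | None:
    for key in ("aSDomain", "domain", "description", "label"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return None


def parse_antismash_regions(path: str | Path, strain_id: str) -> list[BgcRecord]:
    """Parse antiSMASH ``region`` output into BgcRecords.

    Accepts either a (multi-record) GenBank file, each record being one
    contig of the strain, or the equivalent JSON region export (see
    :func:`write_regions_json` for the schema). ``region`` features must
    carry ``product`` and ``contig_edge`` qualifiers; domains are taken
    from ``aSDomain``/``PFAM_domain`` features inside the region, in
    genomic order. External 1-based inclusive coordinates become 0-based
    half-open. A file with no region features yields an empty list.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _parse_regions_json(path, strain_id)

    records: list[BgcRecord] = []
    for contig in SeqIO.parse(str(path), "genbank"):
        regions = [f for f in contig.features if f.type == "region"]
        domain_feats = [f for f in contig.features if f.type in _DOMAIN_FEATURE_TYPES]
        for idx, feat in enumerate(regions, start=1):
            try:
                start, end = int(feat.location.start), int(feat.location.end)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: malformed coordinates in region feature at {feat.location}"
                ) from exc
            products = feat.qualifiers.get("product", [])
            contig_edge = str(feat.qualifiers.get("contig_edge", ["False"])[0]).lower() == "true"
            name_q = feat.qualifiers.get("name")
            bgc_id = str(name_q[0]) if name_q else f"{strain_id}_{contig.id}_r{idx:03d}"
            inner = sorted(
                (f for f in domain_feats if start <= int(f.location.start) < end),
                key=lambda f: int(f.location.start),
            )
            domains = tuple(n for n in (_domain_name(f) for f in inner) if n is not None)
            records.append(
                BgcRecord(
                    strain_id=strain_id,
                    bgc_id=bgc_id,
                    contig_id=contig.id,
                    start_bp=start,
                    end_bp=end,
                    product_class=map_product_class(products),
                    complete=not contig_edge,
                    domains=domains,
                )
            )
    return records


def _parse_regions_json(path: Path, strain_id: str) -> list[BgcRecord]:
    data = json.loads(Path(path).read_text())
    records: list[BgcRecord] = []
    for contig in data.get("records", []):
        cid = contig["name"]
        for idx, region in enumerate(contig.get("regions", []), start=1):
            start, end = int(region["start"]), int(region["end"])
            records.append(
                BgcRecord(
                    strain_id=strain_id,
                    bgc_id=region.get("name", f"{strain_id}_{cid}_r{idx:03d}"),
                    contig_id=cid,
                    start_bp=start,
                    end_bp=end,
                    product_class=map_product_class(region.get("products", [])),
                    complete=not bool(region.get("contig_edge", False)),
                    domains=tuple(region.get("domains", [])),
                    planted_novel=region.get("planted_novel"),
                    planted_gcf=region.get("planted_gcf"),
                )
            )
    return records


def write_regions_json(records: list[BgcRecord], path: str | Path) -> None:
    """Write BgcRecords as the JSON region export consumed by
    :func:`parse_antismash_regions` (0-based half-open coordinates)."""
    by_contig: dict[str, list[BgcRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)

    def region_dict(r: BgcRecord) -> dict:
        d = {
            "name": r.bgc_id,
            "start": r.start_bp,
            "end": r.end_bp,
            "products": list(CLASS_REPRESENTATIVE_PRODUCTS[r.product_class]),
            "contig_edge": not r.complete,
            "domains": list(r.domains),
        }
        if r.planted_novel is not None:
            d["planted_novel"] = r.planted_novel
        if r.planted_gcf is not None:
            d["planted_gcf"] = r.planted_gcf
        return d

    payload = {
        "records": [
            {
                "name": cid,
                "regions": [region_dict(r) for r in sorted(regs, key=lambda r: (r.start_bp, r.bgc_id))],
            }
            for cid, regs in sorted(by_contig.items())
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_fixture_genbank(records: list[BgcRecord], path: str | Path) -> None:
    """Write a minimal antiSMASH-style GenBank file that
    :func:`parse_antismash_regions` inverts exactly.

    One GenBank record per contig; each cluster becomes a ``region``
    feature (``product``, ``contig_edge``, ``name`` qualifiers) and each
    domain an ``aSDomain`` feature placed at consecutive positions inside
    the region. The nucleotide sequence is an N-run placeholder.
    """
    by_contig: dict[str, list[BgcRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)

    gb_records = []
    for cid in sorted(by_contig) if by_contig else []:
        regs = sorted(by_contig[cid], key=lambda r: r.start_bp)
        for prev, cur in zip(regs, regs[1:]):
            if cur.start_bp < prev.end_bp:
                raise ValidationError(
                    f"regions {prev.bgc_id} and {cur.bgc_id} overlap on contig {cid}; "
                    "domain features are associated with regions by position"
                )
        length = max(r.end_bp for r in regs) + 100
        features = []
        for r in regs:
            features.append(
                SeqFeature(
                    SimpleLocation(r.start_bp, r.end_bp),
                    type="region",
                    qualifiers={
                        "name": [r.bgc_id],
                        "product": list(CLASS_REPRESENTATIVE_PRODUCTS[r.product_class]),
                        "contig_edge": ["True" if not r.complete else "False"],
                    },
                )
            )
            span = max(r.end_bp - r.start_bp, 1)
            step = max(span // max(len(r.domains), 1), 1)
            for j, dom in enumerate(r.domains):
                dstart = r.start_bp + min(j * step, span - 1)
                dend = min(dstart + max(step, 2), r.end_bp)
                features.append(
                    SeqFeature(
                        SimpleLocation(dstart, max(dend, dstart + 1)),
                        type="aSDomain",
                        qualifiers={"aSDomain": [dom]},
                    )
                )
        rec = SeqRecord(
            Seq("N" * length),
            id=cid,
            name=cid[:16],
            description="synthetic antiSMASH-style fixture",
            annotations={"molecule_type": "DNA"},
        )
        rec.features = features
        gb_records.append(rec)
    if not gb_records:
        # a syntactically valid GenBank file with a single region-free contig
        rec = SeqRecord(
            Seq("N" * 100),
            id="EMPTY",
            name="EMPTY",
            description="synthetic fixture, no regions",
            annotations={"molecule_type": "DNA"},
        )
        gb_records.append(rec)
    SeqIO.write(gb_records, str(path), "genbank")


# ---------------------------------------------------------------------------
# External distance tables (BiG-FAM-style exports)
# ---------------------------------------------------------------------------


@dataclass
class ExternalDistanceTable:
    """Per-BGC nearest-family distances computed by an external platform.

    Each row is (strain_id, bgc_id, d, reference_tag); d is on the
    external platform's own scale (the literal novelty threshold 900
    applies to this scale).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"strain_id", "bgc_id", "d"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"distance table missing columns: {sorted(missing)}")
        if "reference_tag" not in self.frame.columns:
            self.frame["reference_tag"] = ""
        self.frame["d"] = self.frame["d"].astype(float)
        if (self.frame["d"] < 0).any():
            bad = self.frame.loc[self.frame["d"] < 0].iloc[0]
            raise ValidationError(f"negative distance for ({bad.strain_id}, {bad.bgc_id})")
        if self.frame.duplicated(subset=["strain_id", "bgc_id"]).any():
            bad = self.frame[self.frame.duplicated(subset=["strain_id", "bgc_id"])].iloc[0]
            raise ValidationError(f"duplicate (strain, bgc) pair ({bad.strain_id}, {bad.bgc_id})")

    def distances_for(self, strain_id: str) -> list[float]:
        return self.frame.loc[self.frame["strain_id"] == strain_id, "d"].tolist()

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.frame["strain_id"].unique())


def read_distance_table(path: str | Path) -> ExternalDistanceTable:
    """Read a TSV (strain_id, bgc_id, d[, reference_tag]) distance table."""
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty distance table") from exc
    return ExternalDistanceTable(frame=frame)


def write_distance_table(table: ExternalDistanceTable, path: str | Path) -> None:
    cols = ["strain_id", "bgc_id", "d", "reference_tag"]
    out = table.frame[cols].sort_values(["strain_id", "bgc_id"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network edge / node lists
# ---------------------------------------------------------------------------


def write_network_edgelist(
    net: "BgcNetwork", edge_path: str | Path, node_path: str | Path | None = None
) -> None:
    """Serialize a BGC network as two TSVs: edges (node_a, node_b,
    raw_distance) and node attributes (bgc_id, strain, class,
    component_id, singleton). Rows are lexicographically ordered."""
    edge_path = Path(edge_path)
    if node_path is None:
        node_path = edge_path.with_suffix(".nodes.tsv")
    edges = sorted((min(a, b), max(a, b), d) for a, b, d in net.edges)
    with Path(edge_path).open("w") as fh:
        fh.write("node_a\tnode_b\traw_distance\n")
        for a, b, d in edges:
            fh.write(f"{a}\t{b}\t{d:.6f}\n")
    singles = set(net.singletons)
    with Path(node_path).open("w") as fh:
        fh.write("bgc_id\tstrain\tclass\tcomponent_id\tsingleton\n")
        for r in sorted(net.nodes, key=lambda r: r.bgc_id):
            fh.write(
                f"{r.bgc_id}\t{r.strain_id}\t{r.product_class}\t"
                f"{net.components[r.bgc_id]}\t{str(r.bgc_id in singles).lower()}\n"
            )


def read_network_edgelist(edge_path: str | Path) -> list[tuple[str, str, float]]:
    """Read back an edge TSV written by :func:`write_network_edgelist`."""
    frame = pd.read_csv(edge_path, sep="\t")
    return [
        (str(a), str(b), float(d))
        for a, b, d in frame[["node_a", "node_b", "raw_distance"]].itertuples(index=False)
    ]
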