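"""Data model and I/O for polyketide biosynthetic gene clusters (BGCs).

A modular type I cis-AT polyketide synthase is encoded by one or more genes,
each carrying an ordered series of modules; every module holds catalytic
domains (AT, KS, ACP, KR, DH, ER, TE).  Tailoring enzymes elsewhere in the
cluster modify the released core structure.  This module defines the in-memory
containers for that hierarchy plus readers for a declarative BGC JSON schema,
antiSMASH-annotated GenBank regions, and a genomic windowing helper.

Coordinates are 0-based half-open everywhere; the GenBank reader converts
Biopython's locations at the boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in protein strings (standard 20 plus ambiguous X)
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}

#: core PKS catalytic domain labels
PKS_DOMAINS = ("AT", "KS", "ACP", "KR", "DH", "ER", "TE")
#: per-module reductive domains, at most one each
_UNIQUE_PER_MODULE = ("AT", "KR", "DH", "ER")


class BGCError(ValueError):
    """Raised on schema or invariant violations in BGC inputs."""


@dataclass
class Domain:
    """A catalytic domain or tailoring enzyme.

    ``kind`` is a core PKS label (AT, KS, ...) or a tailoring-enzyme family
    tag understood by the modification database.  ``coords`` locate the
    domain within its protein (0-based half-open); tailoring enzymes that are
    whole proteins may use the full span.
    """

    kind: str
    sequence: str
    active: bool = True
    coords: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise BGCError(f"domain {self.kind}: empty sequence")
        bad = set(self.sequence.upper()) - PROTEIN_ALPHABET
        if bad:
            raise BGCError(
                f"domain {self.kind}: non-amino-acid characters {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()
        if self.coords == (0, 0):
            self.coords = (0, len(self.sequence))
        start, end = self.coords
        if not start < end:
            raise BGCError(f"domain {self.kind}: coords {self.coords} not start<end")


@dataclass
class Module:
    """One extension unit of the assembly line: an ordered list of domains."""

    domains: list[Domain]
    index: int = 0

    def __post_init__(self) -> None:
        for kind in _UNIQUE_PER_MODULE:
            if sum(1 for d in self.domains if d.kind == kind) > 1:
                raise BGCError(f"module {self.index}: more than one {kind} domain")

    def get(self, kind: str) -> Domain | None:
        for d in self.domains:
            if d.kind == kind:
                return d
        return None

    @property
    def is_extension(self) -> bool:
        """An extension module loads a substrate, hence contains an AT."""
        return self.get("AT") is not None


@dataclass
class Gene:
    """One PKS open reading frame: protein plus its ordered modules."""

    id: str
    protein: str
    modules: list[Module] = field(default_factory=list)
    genomic_rank: int = 0
    strand: str = "+"
    location: tuple[int, int] | None = None  # genomic span, 0-based half-open

    def __post_init__(self) -> None:
        self.protein = self.protein.upper()
        if self.strand not in ("+", "-"):
            raise BGCError(f"gene {self.id}: strand must be '+' or '-'")
        for m in self.modules:
            for d in m.domains:
                if d.coords[1] > len(self.protein):
                    raise BGCError(
                        f"gene {self.id}: domain {d.kind} coords {d.coords} "
                        f"exceed protein length {len(self.protein)}"
                    )


@dataclass
class BGC:
    """A biosynthetic gene cluster: genes sorted by genomic rank."""

    genes: list[Gene]
    tailoring_enzymes: list[Domain] = field(default_factory=list)
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise BGCError("a BGC requires at least one gene")
        ranks = [g.genomic_rank for g in self.genes]
        if len(set(ranks)) != len(ranks):
            raise BGCError(f"duplicate genomic_rank among genes: {sorted(ranks)}")
        self.genes = sorted(self.genes, key=lambda g: g.genomic_rank)

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def modules_in_order(self, gene_order: Sequence[str] | None = None) -> list[Module]:
        """All modules following ``gene_order`` (default: genomic order)."""
        order = gene_order if gene_order is not None else self.gene_ids
        out: list[Module] = []
        for gid in order:
            out.extend(self.gene(gid).modules)
        return out


# ---------------------------------------------------------------------------
# JSON schema
# ---------------------------------------------------------------------------

def _domain_to_dict(d: Domain) -> dict:
    return {
        "kind": d.kind,
        "sequence": d.sequence,
        "active": d.active,
        "start": d.coords[0],
        "end": d.coords[1],
    }


def serialize_bgc(bgc: BGC) -> dict:
    """BGC → plain dict matching the declarative JSON schema."""
    return {
        "genes": [
            {
                "id": g.id,
                "genomic_rank": g.genomic_rank,
                "strand": g.strand,
                "protein": g.protein,
                "modules": [
                    {"domains": [_domain_to_dict(d) for d in m.domains]}
                    for m in g.modules
                ],
            }
            for g in bgc.genes
        ],
        "tailoring_enzymes": [
            {"kind": t.kind, "sequence": t.sequence} for t in bgc.tailoring_enzymes
        ],
        "source": bgc.source,
    }


def _domain_from_dict(obj: dict, where: str) -> Domain:
    try:
        kind = obj["kind"]
        seq = obj["sequence"]
    except KeyError as exc:
        raise BGCError(f"{where}: missing required field {exc}") from exc
    coords = (obj.get("start", 0), obj.get("end", len(seq)))
    return Domain(kind=kind, sequence=seq, active=obj.get("active", True), coords=coords)


def bgc_from_dict(obj: dict) -> BGC:
    if "genes" not in obj:
        raise BGCError("BGC JSON: missing required field 'genes'")
    genes = []
    for i, g in enumerate(obj["genes"]):
        where = f"genes[{i}]"
        for req in ("id", "protein"):
            if req not in g:
                raise BGCError(f"{where}: missing required field '{req}'")
        modules = [
            Module(
                domains=[
                    _domain_from_dict(d, f"{where}.modules[{j}]")
                    for d in m.get("domains", [])
                ],
                index=j,
            )
            for j, m in enumerate(g.get("modules", []))
        ]
        genes.append(
            Gene(
                id=g["id"],
                protein=g["protein"],
                modules=modules,
                genomic_rank=g.get("genomic_rank", i),
                strand=g.get("strand", "+"),
                location=tuple(g["location"]) if "location" in g else None,
            )
        )
    tailoring = [
        _domain_from_dict(t, f"tailoring_enzymes[{i}]")
        for i, t in enumerate(obj.get("tailoring_enzymes", []))
    ]
    return BGC(genes=genes, tailoring_enzymes=tailoring, source=obj.get("source", {}))


def parse_bgc_json(path: str | Path) -> BGC:
    """Read a declarative BGC JSON file (see schema in the repo docs)."""
    with open(path) as fh:
        obj = json.load(fh)
    bgc = bgc_from_dict(obj)
    bgc.source.setdefault("path", str(path))
    return bgc


def write_bgc_json(bgc: BGC, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(serialize_bgc(bgc), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# GenBank reader (antiSMASH-style annotated regions)
# ---------------------------------------------------------------------------

#: feature qualifiers consulted for per-CDS domain annotations; each entry is
#: "KIND:start-end[:inactive]" with protein coordinates, modules separated by
#: the "module" boundary marker, e.g. aSDomain-style flattened qualifiers.
DOMAIN_QUALIFIER = "pks_domains"

_KNOWN_TAGS = set(PKS_DOMAINS)


def _parse_domain_qualifier(spec: str, protein: str, gene_id: str) -> list[Module]:
    """Parse ``M|AT:10-20,KR:30-40|M|...`` style module/domain strings."""
    modules: list[Module] = []
    for mi, chunk in enumerate(x for x in spec.split("|") if x and x != "M"):
        domains = []
        for token in chunk.split(","):
            token = token.strip()
            if not token:
                continue
            parts = token.split(":")
            kind = parts[0]
            if kind not in _KNOWN_TAGS:
                warnings.warn(
                    f"gene {gene_id}: unknown domain tag {kind!r} kept as opaque"
                )
            start, end = (int(x) for x in parts[1].split("-"))
            active = not (len(parts) > 2 and parts[2] == "inactive")
            domains.append(
                Domain(kind=kind, sequence=protein[start:end], active=active,
                       coords=(start, end))
            )
        modules.append(Module(domains=domains, index=mi))
    return modules


def parse_genbank_region(path: str | Path) -> BGC:
    """Read an annotated GenBank region into a BGC.

    CDS features must carry a ``translation`` and may carry a
    ``pks_domains`` qualifier describing modules and domain coordinates
    (protein-level, 0-based half-open).  Minus-strand genes use the annotated
    translation as-is; nothing is re-translated.
    """
    record = SeqIO.read(str(path), "genbank")
    genes: list[Gene] = []
    tailoring: list[Domain] = []
    rank = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        gene_id = (quals.get("locus_tag") or quals.get("gene") or [f"cds{rank}"])[0]
        if "translation" not in quals:
            raise BGCError(f"CDS {gene_id}: missing translation")
        protein = quals["translation"][0]
        strand = "-" if feat.location.strand == -1 else "+"
        modules: list[Module] = []
        if DOMAIN_QUALIFIER in quals:
            modules = _parse_domain_qualifier(
                quals[DOMAIN_QUALIFIER][0], protein, gene_id
            )
        if "tailoring" in quals:
            for tag in quals["tailoring"][0].split(","):
                tailoring.append(Domain(kind=tag.strip(), sequence=protein))
            continue
        genes.append(
            Gene(
                id=gene_id,
                protein=protein,
                modules=modules,
                genomic_rank=rank,
                strand=strand,
                location=(int(feat.location.start), int(feat.location.end)),
            )
        )
        rank += 1
    if not genes:
        raise BGCError(f"{path}: no PKS genes found in feature table")
    return BGC(genes=genes, tailoring_enzymes=tailoring,
               source={"path": str(path), "format": "genbank"})


# ---------------------------------------------------------------------------
# Genomic windowing
# ---------------------------------------------------------------------------

def window_bgc(
    anchor_positions: Iterable[int],
    features: BGC | Sequence[Gene],
    flank: int = 10_000,
) -> BGC:
    """Restrict to genes within ``flank`` bp of the anchor enzymes.

    The window is [min(anchors) − flank, max(anchors) + flank]; a gene is kept
    when its genomic span overlaps the window.  A 10 kb default flank follows
    the convention of defining a polyketide BGC as the region within 10,000 bp
    up- and downstream of cluster-specific enzymes.
    """
    anchors = sorted(anchor_positions)
    if not anchors:
        raise BGCError("window_bgc: no anchor positions supplied")
    if flank < 0:
        raise BGCError("window_bgc: flank must be >= 0")
    if isinstance(features, BGC):
        genes, tailoring, source = features.genes, features.tailoring_enzymes, features.source
    else:
        genes, tailoring, source = list(features), [], {}
    lo, hi = anchors[0] - flank, anchors[-1] + flank
    kept = []
    for g in genes:
        if g.location is None:
            raise BGCError(f"gene {g.id}: no genomic location; cannot window")
        start, end = g.location
        if start <= hi and end >= lo:  # overlap with [lo, hi]
            kept.append(g)
    if not kept:
        raise BGCError(f"no gene overlaps window [{lo}, {hi}]")
    return BGC(genes=kept, tailoring_enzymes=tailoring,
               source={**source, "window": [lo, hi]})
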