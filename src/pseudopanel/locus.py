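"""Paralog locus model: coordinates, HGVS-style variant descriptions, index variants.

The model describes a functional gene ("gene B", tenascin-X-like, 44 exons) whose
3' exons 32-44 are >97% identical to a nearby pseudogene ("pseudogene A").  The
~30-kb unit between them carries a marker gene ("marker gene C", CYP21A2-like)
whose presence distinguishes gene conversion (unit retained) from non-allelic
homologous recombination (unit deleted, fusion gene).  Seven diagnostic index
variants (a-g) mark pseudogene-derived sequence inside the functional gene.

Coordinates follow the HGVS cDNA convention: 1-based, inclusive, with signed
intronic offsets (``c.12204+39`` is 39 bases into the intron downstream of
cDNA position 12204).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "CdnaCoordinate",
    "VariantDescription",
    "Exon",
    "ExonMap",
    "IndexVariant",
    "ParalogLocus",
    "parse_cdna_coordinate",
    "format_cdna_coordinate",
    "parse_variant",
    "format_variant",
    "span_length",
    "default_exon_map",
    "default_index_variants",
]


class CoordinateParseError(ValueError):
    """Raised for malformed cDNA coordinate or HGVS text."""


class CoordinateRangeError(ValueError):
    """Raised when a coordinate falls outside the modeled locus."""


@dataclass(frozen=True, order=True)
class CdnaCoordinate:
    """A cDNA position with an optional signed intronic offset.

    ``intron_offset == 0`` means the coordinate is exonic; ``+k`` lies k bases
    into the intron downstream of ``position``; ``-k`` lies k bases upstream.
    """

    position: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateParseError(f"cDNA position must be >= 1, got {self.position}")


_COORD_RE = re.compile(r"^(\d+)(?:([+-])(\d+))?$")


def parse_cdna_coordinate(text: str) -> CdnaCoordinate:
    """Parse ``"12204+39"``, ``"12628-52"`` or ``"100"`` into a CdnaCoordinate.

    Whitespace anywhere in the string is tolerated (printed HGVS often reads
    ``c.12204 + 39dup``).
    """
    compact = re.sub(r"\s+", "", text)
    m = _COORD_RE.match(compact)
    if not m:
        raise CoordinateParseError(f"malformed cDNA coordinate: {text!r}")
    pos = int(m.group(1))
    off = 0
    if m.group(2):
        off = int(m.group(3))
        if m.group(2) == "-":
            off = -off
    return CdnaCoordinate(pos, off)


def format_cdna_coordinate(c: CdnaCoordinate) -> str:
    if c.intron_offset == 0:
        return str(c.position)
    sign = "+" if c.intron_offset > 0 else "-"
    return f"{c.position}{sign}{abs(c.intron_offset)}"


@dataclass(frozen=True)
class VariantDescription:
    """A cDNA-level variant: substitution, deletion, duplication or delins.

    ``label`` preserves the original HGVS text verbatim; protein-level
    annotations (``p.(...)``) are opaque strings carried in ``protein`` and are
    never computed from sequence.
    """

    kind: str  # substitution | deletion | duplication | delins
    start: CdnaCoordinate
    end: CdnaCoordinate
    ref_base: str = ""
    alt_base: str = ""
    label: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"substitution", "deletion", "duplication", "delins"}:
            raise CoordinateParseError(f"unsupported variant kind: {self.kind!r}")
        if self.kind == "substitution" and self.ref_base == self.alt_base:
            raise CoordinateParseError(f"substitution with ref == alt in {self.label!r}")


_SUB_RE = re.compile(r"^c\.(\d+(?:[+-]\d+)?)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+(?:[+-]\d+)?)(?:_(\d+(?:[+-]\d+)?))?del$")
_DUP_RE = re.compile(r"^c\.(\d+(?:[+-]\d+)?)(?:_(\d+(?:[+-]\d+)?))?dup$")
_DELINS_RE = re.compile(r"^c\.(\d+(?:[+-]\d+)?)(?:_(\d+(?:[+-]\d+)?))?delins([ACGT]+)$")


def parse_variant(hgvs_text: str) -> VariantDescription:
    """Parse a ``c.``-prefixed HGVS string of a supported kind.

    Supported: substitutions (``c.12174C>G``), deletions
    (``c.11435_11524+30del``), duplications (``c.9271dup``) and delins.  An
    appended protein annotation after a comma (``c.9271dup,p.(Gln3091Profs*31)``)
    is stored verbatim.  Inversions and other kinds raise.
    """
    compact = re.sub(r"\s+", "", hgvs_text)
    protein = ""
    if "," in compact:
        compact, protein = compact.split(",", 1)
    if not compact.startswith("c."):
        raise CoordinateParseError(f"expected 'c.' prefix in {hgvs_text!r}")

    m = _SUB_RE.match(compact)
    if m:
        c = parse_cdna_coordinate(m.group(1))
        return VariantDescription("substitution", c, c, m.group(2), m.group(3),
                                  label=hgvs_text.strip(), protein=protein)
    for kind, rx in (("deletion", _DEL_RE), ("duplication", _DUP_RE)):
        m = rx.match(compact)
        if m:
            start = parse_cdna_coordinate(m.group(1))
            end = parse_cdna_coordinate(m.group(2)) if m.group(2) else start
            return VariantDescription(kind, start, end, label=hgvs_text.strip(),
                                      protein=protein)
    m = _DELINS_RE.match(compact)
    if m:
        start = parse_cdna_coordinate(m.group(1))
        end = parse_cdna_coordinate(m.group(2)) if m.group(2) else start
        return VariantDescription("delins", start, end, alt_base=m.group(3),
                                  label=hgvs_text.strip(), protein=protein)
    raise CoordinateParseError(
        f"unsupported or malformed HGVS description: {hgvs_text!r} "
        "(supported kinds: substitution, deletion, duplication, delins)")


def format_variant(v: VariantDescription) -> str:
    """Canonical HGVS text for a VariantDescription (round-trips with parse)."""
    s = format_cdna_coordinate(v.start)
    e = format_cdna_coordinate(v.end)
    if v.kind == "substitution":
        return f"c.{s}{v.ref_base}>{v.alt_base}"
    rng = s if v.start == v.end else f"{s}_{e}"
    if v.kind == "deletion":
        return f"c.{rng}del"
    if v.kind == "duplication":
        return f"c.{rng}dup"
    return f"c.{rng}delins{v.alt_base}"


@dataclass(frozen=True)
class Exon:
    exon_id: int
    c_start: int
    c_end: int
    g_start: int
    g_end: int


class ExonMap:
    """Ordered, non-overlapping exons on the forward strand.

    Per-exon cDNA length equals genomic length; introns have positive length.
    """

    def __init__(self, exons: list[Exon]):
        if not exons:
            raise ValueError("empty exon map")
        prev = None
        for ex in exons:
            if ex.c_end - ex.c_start != ex.g_end - ex.g_start:
                raise ValueError(f"exon {ex.exon_id}: cDNA and genomic lengths differ")
            if ex.c_start > ex.c_end:
                raise ValueError(f"exon {ex.exon_id}: inverted coordinates")
            if prev is not None:
                if ex.c_start != prev.c_end + 1:
                    raise ValueError(f"exon {ex.exon_id}: cDNA not contiguous with previous")
                if ex.g_start <= prev.g_end + 1:
                    raise ValueError(f"exon {ex.exon_id}: intron has non-positive length")
            prev = ex
        self.exons = list(exons)

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self):
        return iter(self.exons)

    def exon(self, exon_id: int) -> Exon:
        for ex in self.exons:
            if ex.exon_id == exon_id:
                return ex
        raise KeyError(f"no exon {exon_id}")

    def exon_of_c(self, position: int) -> Exon:
        for ex in self.exons:
            if ex.c_start <= position <= ex.c_end:
                return ex
        raise CoordinateRangeError(f"cDNA position {position} outside transcript "
                                   f"(1..{self.exons[-1].c_end})")

    def c_to_genomic(self, coord: CdnaCoordinate) -> int:
        """Map a cDNA coordinate (with intronic offset) to a genomic position."""
        ex = self.exon_of_c(coord.position)
        g = ex.g_start + (coord.position - ex.c_start)
        if coord.intron_offset > 0 and coord.position != ex.c_end:
            raise CoordinateRangeError(
                f"+offset on {coord.position}, which is not the last base of exon {ex.exon_id}")
        if coord.intron_offset < 0 and coord.position != ex.c_start:
            raise CoordinateRangeError(
                f"-offset on {coord.position}, which is not the first base of exon {ex.exon_id}")
        g += coord.intron_offset
        if coord.intron_offset != 0:
            idx = self.exons.index(ex)
            if coord.intron_offset > 0:
                if idx + 1 >= len(self.exons) or g >= self.exons[idx + 1].g_start:
                    raise CoordinateRangeError(f"offset {coord.intron_offset} runs past intron")
            else:
                if idx == 0 or g <= self.exons[idx - 1].g_end:
                    raise CoordinateRangeError(f"offset {coord.intron_offset} runs past intron")
        return g

    def g_to_c(self, g: int) -> CdnaCoordinate:
        """Inverse of c_to_genomic for positions within the gene span.

        Intronic positions report the nearest exon edge with the appropriate
        signed offset (downstream edge for the first half of the intron).
        """
        for i, ex in enumerate(self.exons):
            if ex.g_start <= g <= ex.g_end:
                return CdnaCoordinate(ex.c_start + (g - ex.g_start))
            if g < ex.g_start:
                if i == 0:
                    break
                prev = self.exons[i - 1]
                d_prev = g - prev.g_end
                d_next = ex.g_start - g
                if d_prev <= d_next:
                    return CdnaCoordinate(prev.c_end, d_prev)
                return CdnaCoordinate(ex.c_start, -d_next)
        raise CoordinateRangeError(f"genomic position {g} outside the gene span")

    def to_dicts(self) -> list[dict]:
        return [vars(ex).copy() for ex in self.exons]


def span_length(v: VariantDescription, exon_map: ExonMap) -> int:
    """Genomic length in bp of a deletion/duplication span: g(end) - g(start) + 1."""
    if v.kind not in {"deletion", "duplication"}:
        raise ValueError(f"span_length applies to deletions/duplications, not {v.kind}")
    g0 = exon_map.c_to_genomic(v.start)
    g1 = exon_map.c_to_genomic(v.end)
    if g1 < g0:
        raise CoordinateRangeError(f"variant span inverted: {v.label!r}")
    return g1 - g0 + 1


# Default desk-scale exon geometry.  44 exons; lengths chosen so that the
# paper-visible anchor coordinates land where they do on the real transcript:
# exon 35 spans c.11435-11524 (90 nt, so the a-index deletion including 30
# intronic bases is exactly 120 bp), exon 40 ends at c.12204 and contains
# c.12150/c.12174, exon 44 starts at c.12628, and the unique-region variant
# positions c.1650 (exon 3), c.6948 (exon 20), c.8585 (exon 25), c.9271
# (exon 27) and c.10274 (exon 30) fall in their annotated exons.
DEFAULT_EXON_LENGTHS: tuple[int, ...] = (
    100, 350, 1300,
    *([300] * 16),          # exons 4-19
    500,                    # exon 20
    *([350] * 4),           # exons 21-24
    400, 200, 300, 300, 300, 400,   # exons 25-30
    300,                    # exon 31
    300, 250, 234, 90, 150, 150, 150, 150, 80, 140, 140, 143, 273,  # exons 32-44
)

DEFAULT_INTRON_LENGTH = 60
HOMOLOGY_FIRST_EXON = 32  # pseudogene A is homologous to exons 32-44 of gene B


def default_exon_map(gene_start: int = 201,
                     exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS,
                     intron_length: int = DEFAULT_INTRON_LENGTH) -> ExonMap:
    exons = []
    c = 1
    g = gene_start
    for i, ln in enumerate(exon_lengths, start=1):
        exons.append(Exon(i, c, c + ln - 1, g, g + ln - 1))
        c += ln
        g += ln + intron_length
    return ExonMap(exons)


@dataclass(frozen=True)
class IndexVariant:
    """One of the seven diagnostic markers (a-g) of pseudogene-derived sequence.

    Index ``g`` is the marker-gene-C copy loss and carries no cDNA-level
    description.  Only ``a`` (the 120-bp deletion) and ``c`` (the exon-40
    missense substitution) are pathogenic.
    """

    index_id: str
    description: VariantDescription | None
    pathogenic: bool


# Fig.-style index table: labels are the field-standard HGVS strings.
_INDEX_TABLE = (
    ("a", "c.11435_11524+30del", True),
    ("b", "c.12150C>G,p.(Arg4050=)", False),
    ("c", "c.12174C>G,p.(Cys4058Trp)", True),
    ("d", "c.12204+39dup", False),
    ("e", "c.12204+43T>G", False),
    ("f", "c.12628-52A>G", False),
    ("g", None, False),  # marker gene C (CYP21A2-like) deletion
)


def default_index_variants() -> list[IndexVariant]:
    out = []
    for idx, label, path in _INDEX_TABLE:
        desc = parse_variant(label) if label else None
        out.append(IndexVariant(idx, desc, path))
    return out


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def to_bed_fields(self, name: str) -> tuple[int, int, str]:
        # BED is 0-based half-open; the conversion lives here, at the boundary.
        return (self.start - 1, self.end, name)


@dataclass
class ParalogLocus:
    """The full synthetic locus: gene B, the intervening unit with marker gene
    C, and pseudogene A, on one forward-strand sequence.

    ``b_to_a`` maps each genomic position of gene B's homologous region
    (exons 32-44) to the corresponding locus position inside pseudogene A, or
    to ``None`` where the pseudogene carries its constitutive 120-bp deletion.
    """

    sequence: str
    exon_map: ExonMap
    gene_b_span: Interval
    homology_span: Interval           # gene B exons 32-44, genomic
    intervening_unit_span: Interval
    marker_gene_c_span: Interval
    pseudogene_a_span: Interval
    index_variants: list[IndexVariant]
    homology_identity: float
    b_to_a: dict[int, int | None] = field(repr=False, default_factory=dict)
    psv_positions: list[int] = field(repr=False, default_factory=list)

    def c_to_g(self, coord: CdnaCoordinate) -> int:
        return self.exon_map.c_to_genomic(coord)

    def base_at(self, g: int) -> str:
        return self.sequence[g - 1]

    def a_position(self, g: int) -> int | None:
        """Pseudogene-A locus position homologous to gene-B position ``g``."""
        try:
            return self.b_to_a[g]
        except KeyError:
            raise CoordinateRangeError(f"{g} is outside gene B's homologous region")

    def index_variant(self, index_id: str) -> IndexVariant:
        for iv in self.index_variants:
            if iv.index_id == index_id:
                return iv
        raise KeyError(index_id)

    # --- serialization -------------------------------------------------
    def to_fasta(self, name: str = "locus") -> str:
        lines = [f">{name}"]
        for i in range(0, len(self.sequence), 70):
            lines.append(self.sequence[i:i + 70])
        return "\n".join(lines) + "\n"

    def sidecar_json(self) -> str:
        payload = {
            "gene_b_span": [self.gene_b_span.start, self.gene_b_span.end],
            "homology_span": [self.homology_span.start, self.homology_span.end],
            "intervening_unit_span": [self.intervening_unit_span.start,
                                      self.intervening_unit_span.end],
            "marker_gene_c_span": [self.marker_gene_c_span.start,
                                   self.marker_gene_c_span.end],
            "pseudogene_a_span": [self.pseudogene_a_span.start,
                                  self.pseudogene_a_span.end],
            "homology_identity": self.homology_identity,
            "exon_map": self.exon_map.to_dicts(),
            "index_variants": [
                {"index_id": iv.index_id,
                 "label": iv.description.label if iv.description else "marker gene C deletion",
                 "pathogenic": iv.pathogenic}
                for iv in self.index_variants
            ],
        }
        return json.dumps(payload, indent=2)

    def index_bed(self) -> str:
        """Index-variant sites as BED (0-based half-open)."""
        rows = []
        for iv in self.index_variants:
            if iv.description is None:
                s, e, n = self.marker_gene_c_span.to_bed_fields(f"index_{iv.index_id}")
            else:
                g0 = self.c_to_g(iv.description.start)
                g1 = self.c_to_g(iv.description.end)
                s, e, n = Interval(g0, g1).to_bed_fields(f"index_{iv.index_id}")
            rows.append(f"locus\t{s}\t{e}\t{n}")
        return "\n".join(rows) + "\n"
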