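"""Hotspot calling with explicit no-call logic, and the exon-35 deletion
zygosity rule.

The hotspot file fixes a set of sites at which the caller must emit a result
(``called`` / ``absent``) or an explicit ``no_call`` when coverage is below
``min_depth``.  Two *paired coverage sentinels* — one inside exon 35 of the
gene, one inside the pseudogene's exon-35-homologous segment — encode the
120-bp-deletion zygosity rule: deletion-junction reads abandon the gene and
pile up on the pseudogene segment, so

* gene site called and pseudogene site called   -> heterozygous deletion,
* gene site no-call and pseudogene site called  -> homozygous deletion,
* gene site called and pseudogene site no-call  -> no deletion,
* both no-call                                  -> indeterminate.

Substitution and small-indel hotspots (index variants b-f) are genotyped by
allele fraction with declared het/hom bands (defaults 0.15 / 0.85 — these
bands are this tool's own operating points, configurable per run).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .align import AlignmentRecord, MaskedReference
from .locus import CdnaCoordinate, ParalogLocus, VariantDescription, format_variant

__all__ = [
    "HotspotDefinition",
    "HotspotCall",
    "HotspotCalls",
    "Pileup",
    "default_hotspots",
    "call_hotspots",
    "infer_ex35_deletion_zygosity",
    "genotype_index_variants",
    "scan_region_variants",
    "calls_to_vcf",
]

DEFAULT_MIN_DEPTH = 20
DEFAULT_MIN_ALT_FRAC = 0.15
DEFAULT_HOM_FRAC = 0.85


class HotspotDefinitionError(ValueError):
    pass


@dataclass(frozen=True)
class HotspotDefinition:
    """A site the caller must always report on.

    ``kind``: ``coverage`` (sentinel; called iff covered), ``substitution``
    (ref>alt), or ``insertion`` (1-2 bp duplication/insertion after
    ``position``).
    """

    hotspot_id: str
    target: str                     # gene_b_site | pseudogene_a_site
    position: int                   # 1-based locus position
    kind: str = "substitution"
    ref: str = ""
    alt: str = ""


@dataclass(frozen=True)
class HotspotCall:
    hotspot_id: str
    status: str                     # called | absent | no_call
    depth: int
    alt_fraction: float


class HotspotCalls(dict):
    """hotspot_id -> HotspotCall."""


def default_hotspots(locus: ParalogLocus) -> list[HotspotDefinition]:
    """The packaged hotspot file: paired exon-35 sentinels plus index sites
    b-f, with ref/alt read off the locus index table."""
    em = locus.exon_map
    e35 = em.exon(35)
    b_sentinel = em.c_to_genomic(CdnaCoordinate(11480))     # mid exon 35
    a_sentinel = locus.a_position(e35.g_end + 31)           # first base past the junction
    defs = [
        HotspotDefinition("ex35_gene", "gene_b_site", b_sentinel, kind="coverage"),
        HotspotDefinition("ex35_pseudogene", "pseudogene_a_site", a_sentinel,
                          kind="coverage"),
    ]
    for iv in locus.index_variants:
        if iv.index_id in ("a", "g") or iv.description is None:
            continue
        v = iv.description
        pos = em.c_to_genomic(v.start)
        if v.kind == "substitution":
            defs.append(HotspotDefinition(f"index_{iv.index_id}", "gene_b_site",
                                          pos, "substitution", v.ref_base or
                                          locus.base_at(pos), v.alt_base))
        elif v.kind == "duplication":
            defs.append(HotspotDefinition(f"index_{iv.index_id}", "gene_b_site",
                                          pos, "insertion",
                                          locus.base_at(pos), locus.base_at(pos)))
    return defs


class Pileup:
    """Depth, mismatch and indel-event summaries of an alignment set."""

    def __init__(self, alignments: list[AlignmentRecord], ref: MaskedReference):
        diff = np.zeros(len(ref.sequence) + 1, dtype=np.int64)
        mismatches: dict[int, Counter] = defaultdict(Counter)
        insertions: dict[int, Counter] = defaultdict(Counter)
        deletions: dict[tuple[int, int], int] = defaultdict(int)
        for rec in alignments:
            if not rec.mapped:
                continue
            for ref_start, _rs, length in rec.blocks:
                diff[ref_start - 1] += 1
                diff[ref_start - 1 + length] -= 1
            for p, b in zip(rec.mismatch_positions, rec.mismatch_bases):
                mismatches[p][b] += 1
            if rec.insertion is not None:
                insertions[rec.insertion[0]][rec.insertion[1]] += 1
            if rec.deletion is not None:
                deletions[(rec.deletion[0], rec.deletion[1])] += 1
        self.depth = np.cumsum(diff[:-1])
        self.mismatches = mismatches
        self.insertions = insertions
        self.deletions = deletions
        self.ref = ref

    def depth_at(self, pos: int) -> int:
        return int(self.depth[pos - 1])

    def alt_count(self, pos: int, alt: str) -> int:
        return self.mismatches.get(pos, Counter())[alt]

    def insertion_count(self, pos: int, tolerance: int = 3) -> int:
        """Insertion events recorded within ``tolerance`` of ``pos`` (indel
        placement inside repeats is ambiguous by one or two bases)."""
        return sum(c for p, cnt in self.insertions.items()
                   if abs(p - pos) <= tolerance for c in cnt.values())

    def deletion_count(self, pos: int, tolerance: int = 3) -> int:
        return sum(c for (p, _l), c in self.deletions.items()
                   if abs(p - pos) <= tolerance)


def call_hotspots(alignments_or_pileup, hotspots: list[HotspotDefinition],
                  ref: MaskedReference | None = None,
                  min_depth: int = DEFAULT_MIN_DEPTH,
                  min_alt_frac: float = DEFAULT_MIN_ALT_FRAC) -> HotspotCalls:
    """Per-site pileup genotyping with explicit no-call on low depth."""
    if min_depth <= 0 or min_alt_frac <= 0:
        raise ValueError("thresholds must be positive")
    if isinstance(alignments_or_pileup, Pileup):
        pile = alignments_or_pileup
    else:
        if ref is None:
            raise ValueError("ref required when passing raw alignments")
        pile = Pileup(alignments_or_pileup, ref)
    if any(h.position < 1 or h.position > len(pile.ref.sequence) for h in hotspots):
        raise HotspotDefinitionError("hotspot outside the reference")

    calls = HotspotCalls()
    for h in hotspots:
        depth = pile.depth_at(h.position)
        if depth < min_depth:
            calls[h.hotspot_id] = HotspotCall(h.hotspot_id, "no_call", depth, 0.0)
            continue
        if h.kind == "coverage":
            calls[h.hotspot_id] = HotspotCall(h.hotspot_id, "called", depth, 1.0)
            continue
        if h.kind == "substitution":
            alt = pile.alt_count(h.position, h.alt)
        else:
            alt = pile.insertion_count(h.position)
        frac = alt / depth
        status = "called" if frac >= min_alt_frac else "absent"
        calls[h.hotspot_id] = HotspotCall(h.hotspot_id, status, depth, frac)
    return calls


def infer_ex35_deletion_zygosity(calls: HotspotCalls) -> str:
    """Apply the paired-sentinel rule for the 120-bp deletion.

    Returns one of ``none``, ``heterozygous``, ``homozygous``,
    ``indeterminate``.
    """
    try:
        b = calls["ex35_gene"]
        a = calls["ex35_pseudogene"]
    except KeyError as exc:
        raise HotspotDefinitionError(
            f"paired exon-35 sentinel {exc} missing from the call set") from exc
    b_cov = b.status != "no_call"
    a_cov = a.status == "called"
    if b_cov and a_cov:
        return "heterozygous"
    if not b_cov and a_cov:
        return "homozygous"
    if b_cov and not a_cov:
        return "none"
    return "indeterminate"


def genotype_index_variants(calls: HotspotCalls,
                            hom_frac: float = DEFAULT_HOM_FRAC,
                            min_alt_frac: float = DEFAULT_MIN_ALT_FRAC) -> dict[str, str]:
    """Zygosity of index variants b-f from allele fractions.

    A no-call site is reported ``absent`` (no positive evidence).
    """
    out = {}
    for idx in "bcdef":
        call = calls.get(f"index_{idx}")
        if call is None or call.status == "no_call" or call.alt_fraction < min_alt_frac:
            out[idx] = "absent"
        elif call.alt_fraction >= hom_frac:
            out[idx] = "hom"
        else:
            out[idx] = "het"
    return out


def _zygosity_from_frac(frac: float, hom_frac: float, min_alt_frac: float) -> str:
    if frac >= hom_frac:
        return "hom"
    if frac >= min_alt_frac:
        return "het"
    return "absent"


def scan_region_variants(pile: Pileup, locus: ParalogLocus,
                         region: "Interval | None" = None,
                         min_depth: int = DEFAULT_MIN_DEPTH,
                         min_alt_frac: float = DEFAULT_MIN_ALT_FRAC,
                         hom_frac: float = DEFAULT_HOM_FRAC,
                         ) -> list[tuple[VariantDescription, str]]:
    """Simple pileup scan for novel variants along the gene's unique region
    (exons 1-31 by default): substitutions plus 1-2 bp deletions and
    duplications, labelled in cDNA coordinates via the exon map."""
    from .locus import Interval
    if region is None:
        region = Interval(locus.gene_b_span.start,
                          locus.exon_map.exon(31).g_end + 30)
    em = locus.exon_map
    found: list[tuple[VariantDescription, str]] = []

    for pos, counter in sorted(pile.mismatches.items()):
        if not region.contains(pos):
            continue
        depth = pile.depth_at(pos)
        if depth < min_depth:
            continue
        base, count = counter.most_common(1)[0]
        frac = count / depth
        if frac < min_alt_frac:
            continue
        c = em.g_to_c(pos)
        ref = locus.base_at(pos)
        v = VariantDescription("substitution", c, c, ref, base,
                               label=f"c.{_fmt(c)}{ref}>{base}")
        found.append((v, _zygosity_from_frac(frac, hom_frac, min_alt_frac)))

    for (pos, length), count in sorted(pile.deletions.items()):
        if not region.contains(pos):
            continue
        # deletion-carrying reads do not cover the deleted bases; measure
        # depth at the last reference base before the event
        depth = pile.depth_at(pos - 1)
        if depth < min_depth or count / depth < min_alt_frac:
            continue
        c0 = em.g_to_c(pos)
        c1 = em.g_to_c(pos + length - 1)
        rng = _fmt(c0) if length == 1 else f"{_fmt(c0)}_{_fmt(c1)}"
        v = VariantDescription("deletion", c0, c1, label=f"c.{rng}del")
        found.append((v, _zygosity_from_frac(count / depth, hom_frac, min_alt_frac)))

    for pos, cnt in sorted(pile.insertions.items()):
        if not region.contains(pos):
            continue
        depth = pile.depth_at(pos)
        if depth < min_depth:
            continue
        total = sum(cnt.values())
        if total / depth < min_alt_frac:
            continue
        seq, _ = cnt.most_common(1)[0]
        # an insertion equal to the adjacent reference bases is a duplication;
        # indel placement inside a repeat may put the event on either side
        ln = len(seq)
        if locus.sequence[pos - ln:pos] == seq:
            dup_start, dup_end = pos - ln + 1, pos
        elif locus.sequence[pos:pos + ln] == seq:
            dup_start, dup_end = pos + 1, pos + ln
        else:
            dup_start = None
        if dup_start is not None:
            c0 = em.g_to_c(dup_start)
            c1 = em.g_to_c(dup_end)
            rng = _fmt(c1) if ln == 1 else f"{_fmt(c0)}_{_fmt(c1)}"
            v = VariantDescription("duplication", c0, c1, label=f"c.{rng}dup")
        else:
            c0 = em.g_to_c(pos)
            v = VariantDescription("delins", c0, c0, alt_base=seq,
                                   label=f"c.{_fmt(c0)}delins{seq}")
        found.append((v, _zygosity_from_frac(total / depth, hom_frac, min_alt_frac)))
    return found


def _fmt(c: CdnaCoordinate) -> str:
    from .locus import format_cdna_coordinate
    return format_cdna_coordinate(c)


def calls_to_vcf(calls: HotspotCalls, hotspots: list[HotspotDefinition],
                 ref_name: str = "locus") -> str:
    """Minimal VCF export: one record per hotspot; FILTER carries no_call."""
    by_id = {h.hotspot_id: h for h in hotspots}
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=no_call,Description="Insufficient coverage to genotype">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for hid, call in sorted(calls.items()):
        h = by_id[hid]
        ref = h.ref or "N"
        alt = h.alt or "."
        filt = "no_call" if call.status == "no_call" else "PASS"
        info = f"DP={call.depth};AF={call.alt_fraction:.4f}"
        lines.append(f"{ref_name}\t{h.position}\t{hid}\t{ref}\t{alt}\t.\t{filt}\t{info}")
    return "\n".join(lines) + "\n"
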