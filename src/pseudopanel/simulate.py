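"""Synthetic locus, allele, sample and amplicon-read generation.

The simulator emits a desk-scale paralog locus (gene B + intervening unit with
marker gene C + pseudogene A on one forward strand), recombinant and
conversion haplotypes with ground-truth labels, long-PCR and allele-specific
PCR templates, and error-bearing single-end amplicon reads.

Desk-scale geometry: the real ~30-kb intervening unit is represented by a
3-kb unit and introns default to 60 bp, so an end-to-end screen runs in
seconds without changing any calling logic.  All lengths are configurable.
All randomness flows through explicit integer seeds; identical seeds
reproduce byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .locus import (
    DEFAULT_EXON_LENGTHS,
    DEFAULT_INTRON_LENGTH,
    ExonMap,
    IndexVariant,
    Interval,
    ParalogLocus,
    VariantDescription,
    default_exon_map,
    default_index_variants,
    parse_variant,
)

__all__ = [
    "LocusConfig",
    "AlleleSpec",
    "Haplotype",
    "DiploidSample",
    "Amplicon",
    "PanelDesign",
    "Read",
    "build_locus",
    "make_allele",
    "make_sample",
    "long_pcr_amplify",
    "phasing_amplify",
    "simulate_reads",
    "default_genomic_panel",
    "default_modified_panel",
    "detect_indices",
    "reads_to_fastq",
]

ALLELE_CLASSES = ("normal", "fusion_type1", "fusion_type2",
                  "conversion_type1", "conversion_type2", "point_variant")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SpecError(ValueError):
    """Invalid allele specification for the given locus."""


class ConfigError(ValueError):
    """Locus configuration that cannot be realized."""


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusConfig:
    """Geometry and divergence settings for the synthetic paralog locus.

    ``identity`` is the target sequence identity of pseudogene A to gene B's
    exon 32-44 region, counting substitutions only (the constitutive 120-bp
    deletion and the 1-bp duplication are structural, not counted as
    divergent sites).
    """

    exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS
    intron_length: int = DEFAULT_INTRON_LENGTH
    gene_start: int = 201
    spacer: int = 200
    unit_length: int = 3000          # desk-scale stand-in for the 30-kb unit
    marker_offset: int = 1000        # marker gene C start within the unit
    marker_length: int = 800
    tail: int = 200
    identity: float = 0.97
    include_index_variants: bool = True
    psv_min_spacing: int = 20

    def __post_init__(self) -> None:
        if self.intron_length < 60:
            raise ConfigError("intron_length must be >= 60 (primer geometry)")
        if not 0.5 <= self.identity <= 1.0:
            raise ConfigError("identity must be in [0.5, 1.0]")
        if self.marker_offset + self.marker_length > self.unit_length:
            raise ConfigError("marker gene C does not fit inside the unit")


def _geometry(exon_map: ExonMap) -> dict[str, Interval]:
    """Primer-site and landmark intervals shared by the locus builder and the
    default panels (all in gene-B genomic coordinates)."""
    g = exon_map.c_to_genomic
    from .locus import CdnaCoordinate as C
    e35 = exon_map.exon(35)
    e36 = exon_map.exon(36)
    e40 = exon_map.exon(40)
    e43 = exon_map.exon(43)
    e44 = exon_map.exon(44)
    e2 = exon_map.exon(2)
    e3 = exon_map.exon(3)
    geo: dict[str, Interval] = {
        "longpcr_fwd": Interval(g(C(10400)), g(C(10400)) + 19),       # exon 31, gene-B specific
        "longpcr_rev": Interval(g(C(12700)), g(C(12700)) + 19),       # exon 44, common to B and A
        "phasing_fwd": Interval(g(C(11460)), g(C(11460)) + 19),       # inside the 120-bp deletion
        "amp_ex35_f": Interval(e35.g_start - 25, e35.g_start - 6),
        "amp_ex35_r": Interval(e35.g_end + 36, e35.g_end + 55),
        "amp_ex36_f": Interval(e36.g_start - 20, e36.g_start - 1),
        "amp_ex36_r": Interval(e36.g_start + 110, e36.g_start + 129),
        "amp_ex40_f": Interval(e40.g_start - 20, e40.g_start - 1),
        "amp_ex40_r": Interval(e40.g_end + 46, e40.g_end + 65),
        "amp_int43_f": Interval(e43.g_end - 19, e43.g_end),
        "amp_int43_r": Interval(e44.g_start + 41, e44.g_start + 60),
        "amp_ex2_f": Interval(e2.g_start - 25, e2.g_start - 6),
        "amp_ex2_r": Interval(e2.g_start + 130, e2.g_start + 149),
        "amp_ex3_f": Interval(e3.g_start - 25, e3.g_start - 6),
        "amp_ex3_r": Interval(e3.g_start + 130, e3.g_start + 149),
    }
    for label, exon_id in (("r1", 5), ("r2", 8), ("r3", 12), ("r4", 16), ("r5", 22)):
        ex = exon_map.exon(exon_id)
        geo[f"amp_{label}_f"] = Interval(ex.g_start - 25, ex.g_start - 6)
        geo[f"amp_{label}_r"] = Interval(ex.g_start + 130, ex.g_start + 149)
    for label, cpos in (("pv3", 1650), ("pv20", 6948), ("pv25", 8585),
                        ("pv27", 9271), ("pv30", 10274)):
        gp = g(C(cpos))
        geo[f"amp_{label}_f"] = Interval(gp - 80, gp - 61)
        geo[f"amp_{label}_r"] = Interval(gp + 61, gp + 80)
    return geo


def _index_edit_positions(locus_or_map, exon_map: ExonMap) -> dict[str, object]:
    """Genomic realizations of index variants a-f on gene B coordinates."""
    g = exon_map.c_to_genomic
    idx = {iv.index_id: iv for iv in default_index_variants()}
    a = idx["a"].description
    out = {
        "a_del": Interval(g(a.start), g(a.end)),                 # 120-bp deletion
        "b_sub": (g(idx["b"].description.start), "G"),
        "c_sub": (g(idx["c"].description.start), "G"),
        "d_dup": g(idx["d"].description.start),                  # duplicated base
        "e_sub": (g(idx["e"].description.start), "G"),
        "f_sub": (g(idx["f"].description.start), "G"),
    }
    return out


def build_locus(config: LocusConfig | None = None, seed: int = 0) -> ParalogLocus:
    """Generate the paralog locus.

    Pseudogene A is derived from gene B's exon 32-44 genomic region by
    applying the constitutive index-variant edits (the 120-bp deletion, four
    substitutions, one 1-bp duplication) plus randomly placed paralogous
    sequence variants (PSVs) to reach the configured identity.  PSVs avoid
    primer sites and index positions so that panel amplification and index
    signatures stay well defined; they keep a minimum spacing so no single
    read window exceeds the aligner's mismatch budget systematically.
    """
    config = config or LocusConfig()
    rng = np.random.default_rng(seed)
    exon_map = default_exon_map(config.gene_start, config.exon_lengths,
                                config.intron_length)
    last = exon_map.exons[-1]
    gene_b_span = Interval(config.gene_start, last.g_end)
    hom_first = exon_map.exon(32)
    homology_span = Interval(hom_first.g_start, last.g_end)

    unit_start = gene_b_span.end + config.spacer + 1
    unit_span = Interval(unit_start, unit_start + config.unit_length - 1)
    marker_span = Interval(unit_start + config.marker_offset,
                           unit_start + config.marker_offset + config.marker_length - 1)
    a_start = unit_span.end + config.spacer + 1

    # random sequence for everything up to the start of pseudogene A
    pre_len = a_start - 1
    seq = rng.choice(_BASES, size=pre_len).astype(np.uint8)

    # force reference bases at index-variant sites so the field-standard HGVS
    # labels (e.g. c.12174C>G) are literally true on this locus
    edits = _index_edit_positions(None, exon_map)
    for key, ref in (("b_sub", "C"), ("c_sub", "C"), ("e_sub", "T"), ("f_sub", "A")):
        pos = edits[key][0]
        seq[pos - 1] = ord(ref)
    # reference bases at the recurrent unique-region variant sites, so their
    # field-standard HGVS labels (c.8585G>A etc.) hold on this locus too
    from .locus import CdnaCoordinate as _C
    for cpos, ref in ((10274, "C"), (8585, "G"), (12174, "C")):
        seq[exon_map.c_to_genomic(_C(cpos)) - 1] = ord(ref)

    # ------------------------------------------------------------------
    # choose PSV positions within the homologous region
    # ------------------------------------------------------------------
    hom_len = len(homology_span)
    n_divergent = int(round((1.0 - config.identity) * hom_len))
    n_index_subs = 4 if config.include_index_variants else 0
    if config.include_index_variants and n_divergent < n_index_subs and config.identity < 1.0:
        raise ConfigError(
            f"identity {config.identity} leaves room for {n_divergent} divergent "
            f"sites but {n_index_subs} index substitutions are required")
    n_psv = max(0, n_divergent - n_index_subs)

    excluded: set[int] = set()
    geo = _geometry(exon_map)
    for iv in geo.values():
        excluded.update(range(iv.start, iv.end + 1))
    # Keep the hotspot-bearing amplicon windows free of extra random PSVs:
    # there the clustered index variants themselves are the local divergence,
    # and piling further differences into a 150-bp read window would push
    # recombinant-tract reads past any reasonable mismatch budget.
    for f_key, r_key in (("amp_ex35_f", "amp_ex35_r"), ("amp_ex36_f", "amp_ex36_r"),
                         ("amp_ex40_f", "amp_ex40_r"), ("amp_int43_f", "amp_int43_r")):
        excluded.update(range(geo[f_key].start, geo[r_key].end + 1))
    for key in ("b_sub", "c_sub", "e_sub", "f_sub"):
        p = edits[key][0]
        excluded.update(range(p - 3, p + 4))
    excluded.update(range(edits["d_dup"] - 3, edits["d_dup"] + 4))
    a_del = edits["a_del"]
    excluded.update(range(a_del.start - 3, a_del.start + 1))
    excluded.update(range(a_del.end, a_del.end + 4))

    psv_positions: list[int] = []
    if n_psv > 0:
        spacing = config.psv_min_spacing
        chosen: list[int] = []
        attempts = 0
        max_attempts = 400 * n_psv
        while len(chosen) < n_psv and attempts < max_attempts:
            attempts += 1
            p = int(rng.integers(homology_span.start, homology_span.end + 1))
            if p in excluded:
                continue
            if any(abs(p - q) < spacing for q in chosen):
                continue
            chosen.append(p)
        if len(chosen) < n_psv:
            raise ConfigError(
                f"could not place {n_psv} divergent sites at identity "
                f"{config.identity} in a {hom_len}-bp homologous region")
        psv_positions = sorted(chosen)

    # ------------------------------------------------------------------
    # emit pseudogene A and the B->A coordinate map
    # ------------------------------------------------------------------
    psv_alt: dict[int, int] = {}
    for p in psv_positions:
        ref = seq[p - 1]
        alts = [b for b in _BASES if b != ref]
        psv_alt[p] = int(alts[int(rng.integers(0, 3))])

    sub_edits: dict[int, int] = dict(psv_alt)
    if config.include_index_variants:
        for key in ("b_sub", "c_sub", "e_sub", "f_sub"):
            pos, alt = edits[key]
            sub_edits[pos] = ord(alt)

    a_chars: list[int] = []
    b_to_a: dict[int, int | None] = {}
    for p in range(homology_span.start, homology_span.end + 1):
        if config.include_index_variants and a_del.contains(p):
            b_to_a[p] = None
            continue
        base = sub_edits.get(p, int(seq[p - 1]))
        a_chars.append(base)
        b_to_a[p] = a_start + len(a_chars) - 1
        if config.include_index_variants and p == edits["d_dup"]:
            a_chars.append(base)  # 1-bp duplication

    a_arr = np.array(a_chars, dtype=np.uint8)
    tail = rng.choice(_BASES, size=config.tail).astype(np.uint8)
    full = np.concatenate([seq, a_arr, tail])
    a_span = Interval(a_start, a_start + len(a_arr) - 1)

    achieved = 1.0 - (len(psv_positions) + n_index_subs) / hom_len if hom_len else 1.0

    return ParalogLocus(
        sequence=full.tobytes().decode("ascii"),
        exon_map=exon_map,
        gene_b_span=gene_b_span,
        homology_span=homology_span,
        intervening_unit_span=unit_span,
        marker_gene_c_span=marker_span,
        pseudogene_a_span=a_span,
        index_variants=default_index_variants() if config.include_index_variants else [],
        homology_identity=achieved,
        b_to_a=b_to_a,
        psv_positions=psv_positions,
    )


# ---------------------------------------------------------------------------
# Alleles and samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleSpec:
    allele_class: str
    extra_variants: tuple[VariantDescription, ...] = ()
    conversion_tract: Interval | None = None

    def __post_init__(self) -> None:
        if self.allele_class not in ALLELE_CLASSES:
            raise SpecError(f"unknown allele class {self.allele_class!r}")
        if self.allele_class == "point_variant" and not self.extra_variants:
            raise SpecError("point_variant allele requires >= 1 extra variant")

    @classmethod
    def from_hgvs(cls, allele_class: str, *hgvs: str) -> "AlleleSpec":
        return cls(allele_class, tuple(parse_variant(h) for h in hgvs))


@dataclass
class Haplotype:
    sequence: str
    truth_class: str
    carried_indices: frozenset[str]
    carried_variants: tuple[str, ...] = ()


@dataclass
class DiploidSample:
    sample_id: str
    haplotype_1: Haplotype
    haplotype_2: Haplotype
    seed: int = 0

    @property
    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return (self.haplotype_1, self.haplotype_2)

    def truth_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.haplotype_1.truth_class, self.haplotype_2.truth_class)))


def _default_tract(locus: ParalogLocus, allele_class: str) -> Interval:
    em = locus.exon_map
    e35 = em.exon(35)
    e40 = em.exon(40)
    e44 = em.exon(44)
    if allele_class == "conversion_type1":
        # covers only the 120-bp deletion (index a) plus tight flanks
        return Interval(e35.g_start - 20, e35.g_end + 35)
    return Interval(e40.g_start - 30, e44.g_start + 10)  # indices b-f


_BREAKPOINT_OFFSETS = {"fusion_type1": 35, "fusion_type2": 40}


def _breakpoint(locus: ParalogLocus, allele_class: str) -> int:
    em = locus.exon_map
    if allele_class == "fusion_type1":
        return em.exon(35).g_start - 40      # mid intron 34: tract includes index a
    return em.exon(40).g_start - 30          # mid intron 39: downstream of index a


def _apply_genomic_edits(seq: str, edits: list[tuple]) -> str:
    """Apply ('sub', pos, alt) / ('del', start, end) / ('dup', start, end) /
    ('delins', start, end, alt) edits, 1-based, applied right-to-left."""
    s = seq
    for edit in sorted(edits, key=lambda e: e[1], reverse=True):
        kind = edit[0]
        if kind == "sub":
            _, pos, alt = edit
            s = s[:pos - 1] + alt + s[pos:]
        elif kind == "del":
            _, g0, g1 = edit
            s = s[:g0 - 1] + s[g1:]
        elif kind == "dup":
            _, g0, g1 = edit
            s = s[:g1] + s[g0 - 1:g1] + s[g1:]
        else:
            _, g0, g1, alt = edit
            s = s[:g0 - 1] + alt + s[g1:]
    return s


def variant_to_edit(v: VariantDescription, exon_map: ExonMap) -> tuple:
    g0 = exon_map.c_to_genomic(v.start)
    g1 = exon_map.c_to_genomic(v.end)
    if v.kind == "substitution":
        return ("sub", g0, v.alt_base)
    if v.kind == "deletion":
        return ("del", g0, g1)
    if v.kind == "duplication":
        return ("dup", g0, g1)
    return ("delins", g0, g1, v.alt_base)


def _indices_in_tract(locus: ParalogLocus, tract: Interval) -> frozenset[str]:
    edits = _index_edit_positions(None, locus.exon_map)
    carried = set()
    a_del: Interval = edits["a_del"]
    if tract.start <= a_del.start and tract.end >= a_del.end:
        carried.add("a")
    for idx, key in (("b", "b_sub"), ("c", "c_sub"), ("e", "e_sub"), ("f", "f_sub")):
        if tract.contains(edits[key][0]):
            carried.add(idx)
    if tract.contains(edits["d_dup"]):
        carried.add("d")
    return frozenset(carried)


def make_allele(locus: ParalogLocus, spec: AlleleSpec) -> Haplotype:
    """Realize one haplotype.

    Fusion haplotypes splice pseudogene A's sequence onto gene B at an
    intronic breakpoint and drop the intervening unit, marker gene C and the
    free pseudogene copy (index g).  Conversion haplotypes splice the
    pseudogene counterpart of a bounded tract into gene B and retain the rest
    of the locus.  Both are exact splices of A-derived sequence, so carried
    index variants are recoverable by literal string search.
    """
    cls = spec.allele_class
    S = locus.sequence
    em = locus.exon_map
    carried: frozenset[str] = frozenset()

    if cls == "normal" or cls == "point_variant":
        seq = S
    elif cls.startswith("fusion"):
        bp = _breakpoint(locus, cls)
        a_pos = locus.a_position(bp)
        if a_pos is None:
            raise SpecError("fusion breakpoint falls in the pseudogene's deleted segment")
        seq = S[:bp - 1] + S[a_pos - 1:locus.pseudogene_a_span.end] + S[locus.pseudogene_a_span.end:]
        carried = _indices_in_tract(locus, Interval(bp, locus.homology_span.end)) | {"g"}
    else:  # conversion
        tract = spec.conversion_tract or _default_tract(locus, cls)
        if not (locus.homology_span.start <= tract.start <= tract.end <= locus.homology_span.end):
            raise SpecError("conversion tract must lie inside the homologous region")
        carried = _indices_in_tract(locus, tract)
        defining = "a" if cls == "conversion_type1" else "c"
        if defining not in carried:
            raise SpecError(f"tract override excludes class-defining index {defining!r}")
        a0 = locus.a_position(tract.start)
        a1 = locus.a_position(tract.end)
        if a0 is None or a1 is None:
            raise SpecError("conversion tract endpoints fall in the deleted segment")
        seq = S[:tract.start - 1] + S[a0 - 1:a1] + S[tract.end:]

    if spec.extra_variants:
        if cls.startswith("fusion") or cls.startswith("conversion"):
            limit = (_breakpoint(locus, cls) if cls.startswith("fusion")
                     else (spec.conversion_tract or _default_tract(locus, cls)).start)
            for v in spec.extra_variants:
                if em.c_to_genomic(v.end) >= limit:
                    raise SpecError(
                        f"extra variant {v.label!r} falls inside the pseudogene-derived tract")
        edits = [variant_to_edit(v, em) for v in spec.extra_variants]
        seq = _apply_genomic_edits(seq, edits)

    return Haplotype(
        sequence=seq,
        truth_class=cls,
        carried_indices=carried,
        carried_variants=tuple(v.label for v in spec.extra_variants),
    )


def make_sample(locus: ParalogLocus, spec1: AlleleSpec, spec2: AlleleSpec,
                sample_id: str = "sample", seed: int = 0) -> DiploidSample:
    return DiploidSample(sample_id, make_allele(locus, spec1),
                         make_allele(locus, spec2), seed=seed)


# ---------------------------------------------------------------------------
# Index recovery by string search (independent of make_allele bookkeeping)
# ---------------------------------------------------------------------------

def _seq_at(locus: ParalogLocus, start: int, end: int) -> str:
    return locus.sequence[start - 1:end]


def detect_indices(locus: ParalogLocus, haplotype_sequence: str) -> frozenset[str]:
    """Recover carried index variants from a haplotype by exact string search.

    The search is restricted to the functional-gene portion (up to the first
    occurrence of the common exon-44 primer site) so that the free pseudogene
    copy of a normal or conversion haplotype does not shadow the result.
    """
    geo = _geometry(locus.exon_map)
    rev = _seq_at(locus, geo["longpcr_rev"].start, geo["longpcr_rev"].end)
    cut = haplotype_sequence.find(rev)
    gene_part = haplotype_sequence[:cut + len(rev) + 400] if cut >= 0 else haplotype_sequence

    edits = _index_edit_positions(None, locus.exon_map)
    carried = set()
    # a: the normal exon-35 window is absent from the functional gene
    a_del = edits["a_del"]
    ref_win = _seq_at(locus, a_del.start - 10, a_del.start + 20)
    if ref_win not in gene_part:
        carried.add("a")
    # b-f: search for the pseudogene's local sequence context (which carries
    # the index allele plus any nearby constitutive differences)
    for idx, key in (("b", "b_sub"), ("c", "c_sub"), ("e", "e_sub"), ("f", "f_sub"),
                     ("d", "d_dup")):
        pos = edits[key][0] if isinstance(edits[key], tuple) else edits[key]
        a_pos = locus.b_to_a[pos]
        alt_win = _seq_at(locus, a_pos - 12, a_pos + 12)
        if alt_win in gene_part:
            carried.add(idx)
    marker_sig = _seq_at(locus, locus.marker_gene_c_span.start + 200,
                         locus.marker_gene_c_span.start + 260)
    if marker_sig not in haplotype_sequence:
        carried.add("g")
    return frozenset(carried)


# ---------------------------------------------------------------------------
# PCR template generation
# ---------------------------------------------------------------------------

def long_pcr_primers(locus: ParalogLocus) -> tuple[str, str]:
    geo = _geometry(locus.exon_map)
    fwd = _seq_at(locus, geo["longpcr_fwd"].start, geo["longpcr_fwd"].end)
    rev = _seq_at(locus, geo["longpcr_rev"].start, geo["longpcr_rev"].end)
    return fwd, rev


def phasing_primer(locus: ParalogLocus) -> str:
    geo = _geometry(locus.exon_map)
    return _seq_at(locus, geo["phasing_fwd"].start, geo["phasing_fwd"].end)


def long_pcr_amplify(sample: DiploidSample, locus: ParalogLocus,
                     forward_primer: str | None = None,
                     reverse_primer: str | None = None) -> list[tuple[str, str]]:
    """Long-range enrichment of the functional gene's 3' region.

    The forward primer is gene-B specific (exon 31); the reverse primer sits
    in a sequence common to gene B and pseudogene A, so recombinant (fusion)
    alleles are amplified while free pseudogene copies are not.  Returns
    (template_name, template_sequence) pairs, one per amplifiable haplotype.
    """
    fwd_d, rev_d = long_pcr_primers(locus)
    fwd = forward_primer or fwd_d
    rev = reverse_primer or rev_d
    out = []
    for i, hap in enumerate(sample.haplotypes, start=1):
        f = hap.sequence.find(fwd)
        if f < 0:
            continue
        r = hap.sequence.find(rev, f)
        if r < 0:
            continue
        out.append((f"{sample.sample_id}_hap{i}", hap.sequence[f:r + len(rev)]))
    if not out:
        warnings.warn(f"long PCR yielded no template for {sample.sample_id} "
                      "(forward primer site absent from both haplotypes)")
    return out


def phasing_amplify(sample: DiploidSample, locus: ParalogLocus,
                    allele_specific_primer: str | None = None) -> list[tuple[str, str]]:
    """Allele-specific amplification anchored in the normal exon-35 sequence.

    Only haplotypes that retain the sequence removed by the 120-bp deletion
    (index a) are amplified; the returned templates stand for the long-range
    allele-specific products used to phase variants onto the normal-exon-35
    allele (anchored downstream at the common exon-44 site, so the free
    pseudogene copy is never part of the product; the gene's unique 5'
    region is included, covering upstream point variants).  Returns an empty
    list (with a warning) when both haplotypes carry the deletion.
    """
    primer = allele_specific_primer or phasing_primer(locus)
    _, rev = long_pcr_primers(locus)
    out = []
    for i, hap in enumerate(sample.haplotypes, start=1):
        p = hap.sequence.find(primer)
        if p < 0:
            continue
        r = hap.sequence.find(rev, p)
        end = r + len(rev) if r >= 0 else p + len(primer)
        out.append((f"{sample.sample_id}_hap{i}", hap.sequence[:end]))
    if not out:
        warnings.warn(f"phasing PCR yielded no template for {sample.sample_id} "
                      "(both haplotypes carry the exon-35 deletion)")
    return out


# ---------------------------------------------------------------------------
# Amplicon panels and read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Amplicon:
    name: str
    interval: Interval        # reference (gene B) span of the insert incl. primers
    fwd_seq: str
    rev_seq: str
    target: str = ""          # optional CNV target this amplicon informs


@dataclass(frozen=True)
class PanelDesign:
    name: str
    mode: str                 # genomic | long_pcr
    amplicons: tuple[Amplicon, ...]

    def amplicon(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    def to_bed(self) -> str:
        rows = []
        for a in self.amplicons:
            s, e, n = a.interval.to_bed_fields(a.name)
            rows.append(f"locus\t{s}\t{e}\t{n}")
        return "\n".join(rows) + "\n"


def _amp(locus: ParalogLocus, geo: dict, name: str, key_f: str, key_r: str,
         target: str = "") -> Amplicon:
    f_iv, r_iv = geo[key_f], geo[key_r]
    return Amplicon(name, Interval(f_iv.start, r_iv.end),
                    _seq_at(locus, f_iv.start, f_iv.end),
                    _seq_at(locus, r_iv.start, r_iv.end), target)


def default_genomic_panel(locus: ParalogLocus) -> PanelDesign:
    """Panel for the standard (whole-genome template) run: unique-region
    exons, CNV reference amplicons, point-variant sites, marker gene C, and
    the homologous-region amplicons (which the standard mask silences)."""
    geo = _geometry(locus.exon_map)
    amps = [
        _amp(locus, geo, "ex2", "amp_ex2_f", "amp_ex2_r", target="exon2"),
        _amp(locus, geo, "ex3", "amp_ex3_f", "amp_ex3_r", target="exon3"),
    ]
    for label in ("r1", "r2", "r3", "r4", "r5"):
        amps.append(_amp(locus, geo, label, f"amp_{label}_f", f"amp_{label}_r",
                         target="reference"))
    for label in ("pv3", "pv20", "pv25", "pv27", "pv30"):
        amps.append(_amp(locus, geo, label, f"amp_{label}_f", f"amp_{label}_r"))
    m = locus.marker_gene_c_span
    amps.append(Amplicon("markerC", Interval(m.start + 100, m.start + 260),
                         _seq_at(locus, m.start + 100, m.start + 119),
                         _seq_at(locus, m.start + 241, m.start + 260),
                         target="marker_c"))
    amps.append(_amp(locus, geo, "ex35", "amp_ex35_f", "amp_ex35_r", target="exon35"))
    amps.append(_amp(locus, geo, "ex40", "amp_ex40_f", "amp_ex40_r"))
    return PanelDesign("genomic_default", "genomic", tuple(amps))


def default_modified_panel(locus: ParalogLocus) -> PanelDesign:
    """Panel applied to long-PCR templates (functional-gene 3' region only)."""
    geo = _geometry(locus.exon_map)
    amps = (
        _amp(locus, geo, "ex35", "amp_ex35_f", "amp_ex35_r", target="exon35"),
        _amp(locus, geo, "ex36", "amp_ex36_f", "amp_ex36_r", target="reference"),
        _amp(locus, geo, "ex40", "amp_ex40_f", "amp_ex40_r"),
        _amp(locus, geo, "int43", "amp_int43_f", "amp_int43_r"),
    )
    return PanelDesign("modified_default", "long_pcr", amps)


@dataclass(frozen=True)
class Read:
    name: str
    sequence: str


_MAX_PRODUCT = 800


def _find_products(template: str, amp: Amplicon) -> list[str]:
    """All amplification products of one amplicon on one template (a primer
    pair may prime more than once when the template carries both the gene and
    the free pseudogene copy)."""
    products = []
    f = template.find(amp.fwd_seq)
    while f >= 0:
        r = template.find(amp.rev_seq, f + len(amp.fwd_seq))
        if 0 <= r and r + len(amp.rev_seq) - f <= _MAX_PRODUCT:
            products.append(template[f:r + len(amp.rev_seq)])
        f = template.find(amp.fwd_seq, f + 1)
    return products


def simulate_reads(templates: list[tuple[str, str]], panel: PanelDesign,
                   mean_depth: float, error_rate: float, seed: int,
                   read_length: int = 150) -> list[Read]:
    """Single-end amplicon reads with independent substitution errors.

    Per amplicon the total read count is Poisson(mean_depth), split evenly
    across the provided templates (Poisson(mean_depth / n_templates) per
    template product).  Read names encode template and amplicon of origin for
    debugging; truth never rides in the sequence itself.  Amplicons with no
    priming site on any template are dropped with a warning.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0 <= error_rate < 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")
    rng = np.random.default_rng(seed)
    n_templates = max(1, len(templates))
    lam = mean_depth / n_templates
    reads: list[Read] = []
    for amp in panel.amplicons:
        hit_any = False
        for tname, tseq in templates:
            for pi, product in enumerate(_find_products(tseq, amp)):
                hit_any = True
                frag = product[:read_length]
                frag_arr = np.frombuffer(frag.encode(), dtype=np.uint8)
                n = int(rng.poisson(lam))
                for j in range(n):
                    arr = frag_arr.copy()
                    if error_rate > 0:
                        n_err = rng.binomial(len(arr), error_rate)
                        if n_err:
                            pos = rng.choice(len(arr), size=n_err, replace=False)
                            shift = rng.integers(1, 4, size=n_err)
                            lut = {65: 0, 67: 1, 71: 2, 84: 3}
                            for p_, s_ in zip(pos, shift):
                                arr[p_] = _BASES[(lut[int(arr[p_])] + int(s_)) % 4]
                    reads.append(Read(f"{tname}|{amp.name}|p{pi}|{j}",
                                      arr.tobytes().decode("ascii")))
        if not hit_any and templates:
            warnings.warn(f"amplicon {amp.name} has no priming site on any template")
    return reads


def reads_to_fastq(reads: list[Read]) -> str:
    lines = []
    for r in reads:
        lines.append(f"@{r.name}")
        lines.append(r.sequence)
        lines.append("+")
        lines.append("I" * len(r.sequence))
    return "\n".join(lines) + "\n"
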