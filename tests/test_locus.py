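"""Coordinate arithmetic, HGVS parsing and the index-variant table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudopanel.locus import (CdnaCoordinate, CoordinateParseError,
                               CoordinateRangeError, Exon, ExonMap,
                               default_exon_map, default_index_variants,
                               format_cdna_coordinate, format_variant,
                               parse_cdna_coordinate, parse_variant,
                               span_length)


@pytest.mark.parametrize("text,pos,off", [
    ("12204+39", 12204, 39),
    ("12628-52", 12628, -52),
    ("100", 100, 0),
    (" 12204 + 39 ", 12204, 39),   # whitespace as printed in figure legends
])
def test_parse_cdna_coordinate(text, pos, off):
    c = parse_cdna_coordinate(text)
    assert (c.position, c.intron_offset) == (pos, off)


@pytest.mark.parametrize("bad", ["", "abc", "12+", "-5", "12++3"])
def test_parse_cdna_coordinate_rejects_malformed(bad):
    with pytest.raises(CoordinateParseError):
        parse_cdna_coordinate(bad)


@pytest.mark.parametrize("text,kind,start,end,ref,alt", [
    ("c.12174C>G", "substitution", (12174, 0), (12174, 0), "C", "G"),
    ("c.11435_11524+30del", "deletion", (11435, 0), (11524, 30), "", ""),
    ("c.9271dup", "duplication", (9271, 0), (9271, 0), "", ""),
    ("c.12204 + 39dup", "duplication", (12204, 39), (12204, 39), "", ""),
    ("c.12628-52A>G", "substitution", (12628, -52), (12628, -52), "A", "G"),
])
def test_parse_variant(text, kind, start, end, ref, alt):
    v = parse_variant(text)
    assert v.kind == kind
    assert (v.start.position, v.start.intron_offset) == start
    assert (v.end.position, v.end.intron_offset) == end
    assert (v.ref_base, v.alt_base) == (ref, alt)
    assert v.label == text.strip()


def test_parse_variant_keeps_protein_annotation_opaque():
    v = parse_variant("c.9271dup,p.(Gln3091Profs*31)")
    assert v.kind == "duplication"
    assert v.protein == "p.(Gln3091Profs*31)"


def test_parse_variant_rejects_unsupported_kind():
    with pytest.raises(CoordinateParseError, match="unsupported"):
        parse_variant("c.100_200inv")
    with pytest.raises(CoordinateParseError):
        parse_variant("g.100A>G")


coords = st.builds(CdnaCoordinate, st.integers(1, 20000),
                   st.integers(-80, 80))


@settings(max_examples=200, derandomize=True)
@given(coords)
def test_coordinate_round_trip(c):
    assert parse_cdna_coordinate(format_cdna_coordinate(c)) == c


@settings(max_examples=100, derandomize=True)
@given(st.sampled_from(["substitution", "deletion", "duplication"]),
       st.integers(1, 12000), st.integers(0, 40),
       st.sampled_from("ACGT"), st.sampled_from("ACGT"))
def test_variant_round_trip(kind, pos, span, ref, alt):
    if kind == "substitution":
        if ref == alt:
            alt = "ACGT"[("ACGT".index(alt) + 1) % 4]
        text = f"c.{pos}{ref}>{alt}"
    elif span == 0:
        text = f"c.{pos}{'del' if kind == 'deletion' else 'dup'}"
    else:
        text = f"c.{pos}_{pos + span}{'del' if kind == 'deletion' else 'dup'}"
    v = parse_variant(text)
    assert format_variant(v) == text
    assert parse_variant(format_variant(v)) == v


# ---------------------------------------------------------------------------
# cDNA -> genomic mapping
# ---------------------------------------------------------------------------

def _random_exon_map(rng) -> ExonMap:
    exons, c, g = [], 1, int(rng.integers(1, 500))
    for i in range(1, int(rng.integers(2, 9))):
        ln = int(rng.integers(30, 400))
        exons.append(Exon(i, c, c + ln - 1, g, g + ln - 1))
        c += ln
        g += ln + int(rng.integers(20, 300))
    return ExonMap(exons)


def _walk_oracle(em: ExonMap, c_pos: int) -> int:
    """Brute-force enumeration: walk every exonic base in order."""
    n = 0
    for ex in em:
        for g in range(ex.g_start, ex.g_end + 1):
            n += 1
            if n == c_pos:
                return g
    raise AssertionError("position beyond transcript")


def test_c_to_genomic_identity_and_offsets():
    em = ExonMap([Exon(1, 1, 90, 1001, 1090), Exon(2, 91, 180, 1201, 1290)])
    assert em.c_to_genomic(CdnaCoordinate(1)) == 1001
    assert em.c_to_genomic(CdnaCoordinate(90, 30)) == 1120
    assert em.c_to_genomic(CdnaCoordinate(91, -20)) == 1181
    with pytest.raises(CoordinateRangeError):
        em.c_to_genomic(CdnaCoordinate(500))
    with pytest.raises(CoordinateRangeError):
        em.c_to_genomic(CdnaCoordinate(90, 200))  # runs past the intron


def test_c_to_genomic_matches_exhaustive_walk():
    rng = np.random.default_rng(7)
    for _ in range(10):
        em = _random_exon_map(rng)
        total = em.exons[-1].c_end
        probes = rng.integers(1, total + 1, size=25)
        for c_pos in probes:
            assert em.c_to_genomic(CdnaCoordinate(int(c_pos))) == _walk_oracle(em, int(c_pos))


def test_c_to_genomic_strictly_increasing():
    em = default_exon_map()
    g = [em.c_to_genomic(CdnaCoordinate(p)) for p in range(1, em.exons[-1].c_end + 1, 97)]
    assert all(b > a for a, b in zip(g, g[1:]))


def test_g_to_c_inverts_exonic_positions():
    em = default_exon_map()
    rng = np.random.default_rng(3)
    for c_pos in rng.integers(1, em.exons[-1].c_end + 1, size=50):
        g = em.c_to_genomic(CdnaCoordinate(int(c_pos)))
        assert em.g_to_c(g) == CdnaCoordinate(int(c_pos))


# ---------------------------------------------------------------------------
# span lengths
# ---------------------------------------------------------------------------

def test_span_length_of_the_index_deletion_is_120():
    em = default_exon_map()
    assert span_length(parse_variant("c.11435_11524+30del"), em) == 120


def test_span_length_trivial_and_oracle():
    em = default_exon_map()
    assert span_length(parse_variant("c.1_2del"), em) == 2
    rng = np.random.default_rng(11)
    for _ in range(20):
        ex = em.exons[int(rng.integers(0, len(em.exons)))]
        a = int(rng.integers(ex.c_start, ex.c_end + 1))
        b = int(rng.integers(a, ex.c_end + 1))
        v = parse_variant(f"c.{a}_{b}del" if a != b else f"c.{a}del")
        expected = len(range(em.c_to_genomic(CdnaCoordinate(a)),
                             em.c_to_genomic(CdnaCoordinate(b)) + 1))
        assert span_length(v, em) == expected


def test_span_length_rejects_substitutions():
    em = default_exon_map()
    with pytest.raises(ValueError):
        span_length(parse_variant("c.12174C>G"), em)


# ---------------------------------------------------------------------------
# index table
# ---------------------------------------------------------------------------

def test_default_index_table_has_exactly_seven_entries():
    table = default_index_variants()
    assert [iv.index_id for iv in table] == list("abcdefg")
    labels = {iv.index_id: iv.description.label if iv.description else None
              for iv in table}
    assert labels["a"] == "c.11435_11524+30del"
    assert labels["b"].startswith("c.12150C>G")
    assert labels["c"].startswith("c.12174C>G")
    assert labels["d"] == "c.12204+39dup"
    assert labels["e"] == "c.12204+43T>G"
    assert labels["f"] == "c.12628-52A>G"
    assert labels["g"] is None
    assert {iv.index_id for iv in table if iv.pathogenic} == {"a", "c"}


def test_locus_serialization(locus, tmp_path):
    fasta = locus.to_fasta()
    assert fasta.startswith(">locus")
    assert sum(len(l) for l in fasta.splitlines()[1:]) == len(locus.sequence)
    import json
    payload = json.loads(locus.sidecar_json())
    assert len(payload["exon_map"]) == 44
    bed = locus.index_bed()
    # BED is 0-based half-open: the a-index row spans exactly 120 bases
    row_a = next(l for l in bed.splitlines() if l.endswith("index_a"))
    _, s, e, _ = row_a.split("\t")
    assert int(e) - int(s) == 120
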