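"""Locus/allele/read simulator: divergence targets, splice correctness,
string-search recoverability, PCR behavior and read statistics."""

import numpy as np
import pytest

from pseudopanel.locus import Interval, parse_variant
from pseudopanel.simulate import (ALLELE_CLASSES, AlleleSpec, ConfigError,
                                  LocusConfig, SpecError, build_locus,
                                  default_genomic_panel, default_modified_panel,
                                  detect_indices, long_pcr_amplify, make_allele,
                                  make_sample, phasing_amplify, phasing_primer,
                                  reads_to_fastq, simulate_reads)


def _divergent_site_count(locus) -> int:
    """Mismatches between gene B's homologous region and pseudogene A over
    aligned (non-deleted) columns — the independent divergence oracle."""
    n = 0
    for p in range(locus.homology_span.start, locus.homology_span.end + 1):
        a = locus.b_to_a[p]
        if a is None:
            continue
        if locus.sequence[p - 1] != locus.sequence[a - 1]:
            n += 1
    return n


def test_build_locus_divergence_matches_identity_target():
    # ~10-kb homologous region at 97% identity -> ~300 divergent sites
    cfg = LocusConfig(intron_length=646)
    locus = build_locus(cfg, seed=5)
    hom_len = len(locus.homology_span)
    assert 9500 <= hom_len <= 10500
    n = _divergent_site_count(locus)
    assert 280 <= n <= 320
    assert abs(locus.homology_identity - 0.97) <= 0.005


def test_build_locus_identity_one_without_indices_is_exact_copy():
    cfg = LocusConfig(identity=1.0, include_index_variants=False)
    locus = build_locus(cfg, seed=2)
    hom = locus.sequence[locus.homology_span.start - 1:locus.homology_span.end]
    a = locus.sequence[locus.pseudogene_a_span.start - 1:locus.pseudogene_a_span.end]
    assert hom == a


def test_build_locus_rejects_impossible_identity():
    with pytest.raises(ConfigError):
        build_locus(LocusConfig(identity=0.5), seed=0)


def test_default_locus_index_labels(locus):
    assert [iv.index_id for iv in locus.index_variants] == list("abcdefg")
    # the forced reference bases make the HGVS labels literally true
    em = locus.exon_map
    for idx, ref in (("b", "C"), ("c", "C"), ("e", "T"), ("f", "A")):
        v = locus.index_variant(idx).description
        assert locus.base_at(em.c_to_genomic(v.start)) == ref


EXPECTED_INDICES = {
    "normal": set(),
    "conversion_type1": {"a"},
    "conversion_type2": {"b", "c", "d", "e", "f"},
    "fusion_type1": set("abcdefg"),
    "fusion_type2": set("bcdefg"),
}


@pytest.mark.parametrize("cls,expected", sorted(EXPECTED_INDICES.items()))
def test_make_allele_carried_indices(locus, cls, expected):
    hap = make_allele(locus, AlleleSpec(cls))
    assert hap.carried_indices == frozenset(expected)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_carried_indices_recoverable_by_string_search(seed):
    """make_allele bookkeeping must agree with exact string search on the
    emitted sequence, for every class."""
    locus = build_locus(seed=seed)
    for cls in EXPECTED_INDICES:
        hap = make_allele(locus, AlleleSpec(cls))
        assert detect_indices(locus, hap.sequence) == hap.carried_indices, cls


def test_marker_c_presence_iff_not_fusion(locus):
    marker = locus.sequence[locus.marker_gene_c_span.start - 1 + 300:
                            locus.marker_gene_c_span.start - 1 + 360]
    for cls in EXPECTED_INDICES:
        hap = make_allele(locus, AlleleSpec(cls))
        assert (marker in hap.sequence) == (not cls.startswith("fusion"))


def test_normal_allele_is_reference(locus):
    assert make_allele(locus, AlleleSpec("normal")).sequence == locus.sequence


def test_fusion_type1_lacks_normal_exon35_window(locus):
    hap = make_allele(locus, AlleleSpec("fusion_type1"))
    e35 = locus.exon_map.exon(35)
    window = locus.sequence[e35.g_start - 1:e35.g_end]
    assert window not in hap.sequence
    assert len(hap.sequence) < len(locus.sequence) - 2000  # unit + free copy gone


def test_point_variant_spec_requires_variants():
    with pytest.raises(SpecError):
        AlleleSpec("point_variant")
    with pytest.raises(SpecError):
        AlleleSpec("nonsense_class")


def test_extra_variant_rejected_inside_tract(locus):
    v = parse_variant("c.12174C>G")  # inside any pseudogene-derived tract
    with pytest.raises(SpecError):
        make_allele(locus, AlleleSpec("fusion_type1", (v,)))


def test_tract_override_must_keep_defining_index(locus):
    e40 = locus.exon_map.exon(40)
    tract = Interval(e40.g_start - 30, e40.g_end + 50)  # excludes index a
    with pytest.raises(SpecError):
        make_allele(locus, AlleleSpec("conversion_type1", conversion_tract=tract))
    # but it is a fine type 2 tract
    hap = make_allele(locus, AlleleSpec("conversion_type2", conversion_tract=tract))
    assert "c" in hap.carried_indices and "f" not in hap.carried_indices


# ---------------------------------------------------------------------------
# PCR template generation
# ---------------------------------------------------------------------------

def test_long_pcr_amplifies_both_alleles(locus):
    s = make_sample(locus, AlleleSpec("conversion_type1"), AlleleSpec("conversion_type1"))
    assert len(long_pcr_amplify(s, locus)) == 2
    s = make_sample(locus, AlleleSpec("normal"), AlleleSpec("fusion_type1"))
    assert len(long_pcr_amplify(s, locus)) == 2  # fusion alleles are amplified


def test_long_pcr_never_amplifies_free_pseudogene(locus):
    s = make_sample(locus, AlleleSpec("normal"), AlleleSpec("normal"))
    for _, template in long_pcr_amplify(s, locus):
        # template ends at the functional gene's common exon-44 site, well
        # before the free pseudogene copy
        assert len(template) < len(locus.homology_span) + 3000


def test_long_pcr_primer_dropout(locus):
    s = make_sample(locus, AlleleSpec("normal"), AlleleSpec("normal"))
    mutated = s.haplotype_2.sequence
    from pseudopanel.simulate import long_pcr_primers
    fwd, _ = long_pcr_primers(locus)
    pos = mutated.find(fwd)
    mutated = mutated[:pos + 5] + ("A" if mutated[pos + 5] != "A" else "C") + mutated[pos + 6:]
    s.haplotype_2.sequence = mutated
    assert len(long_pcr_amplify(s, locus)) == 1


def test_phasing_amplify_selects_normal_exon35_alleles(locus):
    s = make_sample(locus, AlleleSpec("conversion_type1"), AlleleSpec("fusion_type2"))
    templates = phasing_amplify(s, locus)
    assert [name for name, _ in templates] == ["sample_hap2"]
    # the amplified (type 2 fusion) allele carries index c
    c_pos = locus.exon_map.c_to_genomic(locus.index_variant("c").description.start)
    a_pos = locus.b_to_a[c_pos]
    c_window = locus.sequence[a_pos - 12:a_pos + 12]
    assert c_window in templates[0][1]


def test_phasing_amplify_empty_for_homozygous_deletion(locus):
    s = make_sample(locus, AlleleSpec("conversion_type1"), AlleleSpec("conversion_type1"))
    with pytest.warns(UserWarning):
        assert phasing_amplify(s, locus) == []


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def test_error_free_reads_are_template_substrings(locus):
    s = make_sample(locus, AlleleSpec("normal"), AlleleSpec("normal"))
    template = [("hap1", s.haplotype_1.sequence)]
    reads = simulate_reads(template, default_genomic_panel(locus), 50, 0.0, 9)
    assert reads
    for r in reads:
        assert r.sequence in s.haplotype_1.sequence


def test_read_counts_follow_poisson_totals(locus):
    s = make_sample(locus, AlleleSpec("normal"), AlleleSpec("normal"))
    panel = default_genomic_panel(locus)
    templates = [("hap1", s.haplotype_1.sequence), ("hap2", s.haplotype_2.sequence)]
    reads = simulate_reads(templates, panel, 200, 0.0, 21)
    # unique-region amplicons prime once per haplotype; the two 3' amplicons
    # also prime the free pseudogene copy where their sites are conserved
    n_products = 0
    from pseudopanel.simulate import _find_products
    for amp in panel.amplicons:
        for _, t in templates:
            n_products += len(_find_products(t, amp))
    expected = 100.0 * n_products
    assert abs(len(reads) - expected) <= 3 * np.sqrt(expected)


def test_heterozygous_allele_fraction_near_half(locus):
    v = parse_variant("c.8585G>A")
    s = make_sample(locus, AlleleSpec("point_variant", (v,)), AlleleSpec("normal"))
    templates = [("hap1", s.haplotype_1.sequence), ("hap2", s.haplotype_2.sequence)]
    reads = simulate_reads(templates, default_genomic_panel(locus), 500, 0.0, 33)
    g = locus.exon_map.c_to_genomic(v.start)
    ref_ctx = locus.sequence[g - 6:g + 5]
    alt_ctx = ref_ctx[:5] + "A" + ref_ctx[6:]
    n_alt = sum(alt_ctx in r.sequence for r in reads)
    n_tot = sum((alt_ctx in r.sequence) or (ref_ctx in r.sequence) for r in reads)
    p = n_alt / n_tot
    assert abs(p - 0.5) <= 3 * np.sqrt(0.25 / n_tot)


def test_reads_deterministic_per_seed(locus):
    s = make_sample(locus, AlleleSpec("conversion_type1"), AlleleSpec("normal"))
    templates = long_pcr_amplify(s, locus)
    panel = default_modified_panel(locus)
    r1 = simulate_reads(templates, panel, 100, 0.01, 77)
    r2 = simulate_reads(templates, panel, 100, 0.01, 77)
    assert reads_to_fastq(r1) == reads_to_fastq(r2)
    r3 = simulate_reads(templates, panel, 100, 0.01, 78)
    assert reads_to_fastq(r1) != reads_to_fastq(r3)


def test_simulate_reads_validates_parameters(locus):
    panel = default_modified_panel(locus)
    with pytest.raises(ValueError):
        simulate_reads([], panel, 0, 0.0, 1)
    with pytest.raises(ValueError):
        simulate_reads([], panel, 10, 0.5, 1)


def test_panel_bed_round_trip(locus):
    panel = default_genomic_panel(locus)
    lines = panel.to_bed().strip().splitlines()
    assert len(lines) == len(panel.amplicons)
    for line, amp in zip(lines, panel.amplicons):
        chrom, s, e, name = line.split("\t")
        assert name == amp.name
        assert int(e) - int(s) == len(amp.interval)
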