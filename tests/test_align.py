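"""Masking semantics and the seeded aligner, checked against a brute-force
Hamming-scan oracle."""

import numpy as np
import pytest

from pseudopanel.align import (ReferenceIndex, align_reads, alignments_to_sam,
                               brute_force_best, build_masked_reference,
                               depth_profile, pseudogene_unmask_window)
from pseudopanel.simulate import (AlleleSpec, LocusConfig, build_locus,
                                  default_genomic_panel, default_modified_panel,
                                  long_pcr_amplify, make_sample, simulate_reads,
                                  Read)


def test_standard_mask_covers_homolog_and_pseudogene(locus):
    ref = build_masked_reference(locus, "standard")
    n_count = ref.sequence.count("N")
    expected = len(locus.homology_span) + len(locus.pseudogene_a_span)
    assert n_count == expected
    assert len(ref.sequence) == len(locus.sequence)


def test_modified_mask_leaves_exon35_homolog_open(locus):
    ref = build_masked_reference(locus, "modified")
    win = pseudogene_unmask_window(locus)
    segment = ref.sequence[win.start - 1:win.end]
    assert "N" not in segment
    a = locus.pseudogene_a_span
    outside = ref.sequence[a.start - 1:win.start - 1] + ref.sequence[win.end:a.end]
    assert set(outside) == {"N"}


def test_unmasked_mode_is_identity(locus):
    ref = build_masked_reference(locus, "unmasked")
    assert ref.sequence == locus.sequence
    with pytest.raises(ValueError):
        build_masked_reference(locus, "bogus")


def test_error_free_read_maps_at_origin(locus):
    ref = build_masked_reference(locus, "unmasked")
    start = 5000
    read = Read("r", locus.sequence[start:start + 150])
    (rec,) = align_reads([read], ref)
    assert rec.mapped and rec.position == start + 1 and rec.n_mismatch == 0


def test_junction_reads_map_to_pseudogene_window(locus):
    """Reads spanning the 120-bp deletion junction align inside the
    pseudogene's unmasked exon-35-homologous segment."""
    ref = build_masked_reference(locus, "modified")
    win = pseudogene_unmask_window(locus)
    sample = make_sample(locus, AlleleSpec("conversion_type1"),
                         AlleleSpec("conversion_type1"))
    templates = long_pcr_amplify(sample, locus)
    reads = simulate_reads(templates, default_modified_panel(locus), 100, 0.0, 3)
    junction = [r for r in reads if "ex35" in r.name]
    assert junction
    recs = align_reads(junction, ref)
    in_window = [r for r in recs
                 if r.mapped and win.start <= r.position <= win.end]
    assert len(in_window) >= 0.9 * len(junction)


def test_standard_mask_silences_homologous_region(locus):
    """No read of a sample whose variants all lie in exons 32-44 maps into
    that region under the standard mask."""
    ref = build_masked_reference(locus, "standard")
    idx = ReferenceIndex(ref)
    for cls in ("conversion_type1", "conversion_type2", "fusion_type1"):
        sample = make_sample(locus, AlleleSpec(cls), AlleleSpec(cls))
        templates = [("h1", sample.haplotype_1.sequence),
                     ("h2", sample.haplotype_2.sequence)]
        reads = simulate_reads(templates, default_genomic_panel(locus), 50, 0.0, 5)
        recs = align_reads(reads, idx)
        for rec in recs:
            if rec.mapped:
                end = rec.blocks[-1][0] + rec.blocks[-1][2] - 1
                assert not (rec.position <= locus.homology_span.end
                            and end >= locus.homology_span.start)


def test_ambiguous_placement_is_unmapped():
    cfg = LocusConfig(identity=1.0, include_index_variants=False)
    locus = build_locus(cfg, seed=4)
    ref = build_masked_reference(locus, "unmasked")
    # with a perfect-copy pseudogene, any homolog-region read has two
    # equal-best placements
    start = locus.homology_span.start + 500
    read = Read("r", locus.sequence[start - 1:start + 149])
    (rec,) = align_reads([read], ref)
    assert not rec.mapped and rec.reason == "ambiguous"


def test_aligner_matches_brute_force_oracle():
    """On a <=20-kb locus, seeded alignment equals the exhaustive Hamming
    scan wherever the oracle's best placement is unique and within budget."""
    cfg = LocusConfig(unit_length=1000, spacer=100, tail=100, marker_offset=100)
    locus = build_locus(cfg, seed=6)
    assert len(locus.sequence) <= 20_000
    ref = build_masked_reference(locus, "unmasked")
    idx = ReferenceIndex(ref)
    rng = np.random.default_rng(8)
    L = 150
    reads = []
    for i in range(500):
        s = int(rng.integers(0, len(locus.sequence) - L))
        arr = np.frombuffer(locus.sequence[s:s + L].encode(), np.uint8).copy()
        n_mut = int(rng.integers(0, 9))
        pos = rng.choice(L, size=n_mut, replace=False)
        for p in pos:
            arr[p] = ord("ACGT"[int(rng.integers(0, 4))])
        reads.append(Read(f"r{i}", arr.tobytes().decode()))
    recs = align_reads(reads, idx)
    budget = int(0.05 * L)
    checked = 0
    for read, rec in zip(reads, recs):
        pos, mm, unique = brute_force_best(read.sequence, ref)
        if not unique:
            continue
        checked += 1
        if mm <= budget:
            assert rec.mapped and rec.position == pos, read.name
            assert rec.n_mismatch == mm
        elif rec.mapped:
            # only the indel rescue may beat the ungapped oracle
            assert len(rec.blocks) == 2
    assert checked >= 400


def test_alignment_deterministic(locus):
    ref = build_masked_reference(locus, "modified")
    sample = make_sample(locus, AlleleSpec("conversion_type2"), AlleleSpec("normal"))
    reads = simulate_reads(long_pcr_amplify(sample, locus),
                           default_modified_panel(locus), 100, 0.01, 13)
    a1 = align_reads(reads, ref)
    a2 = align_reads(reads, ref)
    assert [(r.position, r.cigar(), r.n_mismatch) for r in a1] == \
           [(r.position, r.cigar(), r.n_mismatch) for r in a2]


def test_depth_profile_conservation(locus):
    ref = build_masked_reference(locus, "unmasked")
    cov, _ = depth_profile([], ref)
    assert cov.sum() == 0
    read = Read("r", locus.sequence[1000:1150])
    recs = align_reads([read], ref)
    cov, _ = depth_profile(recs, ref)
    assert cov.sum() == 150
    assert (cov[1000:1150] == 1).all()


def test_depth_profile_poisson_per_amplicon(locus):
    ref = build_masked_reference(locus, "unmasked")
    idx = ReferenceIndex(ref)
    sample = make_sample(locus, AlleleSpec("normal"), AlleleSpec("normal"))
    panel = default_genomic_panel(locus)
    reads = simulate_reads([("h1", sample.haplotype_1.sequence),
                            ("h2", sample.haplotype_2.sequence)],
                           panel, 200, 0.0, 17)
    recs = align_reads(reads, idx)
    _, means = depth_profile(recs, ref, panel)
    for name in ("r1", "r2", "r3", "ex2", "markerC"):
        assert abs(means[name] - 200) <= 3 * np.sqrt(200), name


def test_sam_output_parses_with_pysam(tmp_path, locus):
    pysam = pytest.importorskip("pysam")
    ref = build_masked_reference(locus, "unmasked")
    reads = [Read("ok", locus.sequence[3000:3150]), Read("junk", "ACGT" * 37 + "AC")]
    recs = align_reads(reads, ref)
    sam_path = tmp_path / "out.sam"
    sam_path.write_text(alignments_to_sam(recs, ref, reads))
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        rows = list(fh)
    assert len(rows) == 2
    assert rows[0].reference_start == 3000 and not rows[0].is_unmapped
    assert rows[1].is_unmapped
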