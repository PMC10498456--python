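"""End-to-end screening: simulate -> mask -> align -> call -> CNV -> classify.

A :class:`ScreenContext` caches everything reusable across samples (the
locus, panels, masked references with their k-mer indexes, the hotspot file
and a pool of wild-type control runs for copy-number normalization), so a
batch of screens costs one context build plus per-sample work.

The screen runs both analysis modes: the *standard* run aligns genomic-
template reads against the standard mask (unique-region small variants and
amplicon copy number); the *modified* run aligns long-PCR-template reads
against the modified mask (exon-35 deletion zygosity and index-variant
hotspots).  Ambiguous classifications trigger an allele-specific phasing
amplification automatically when enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .align import (MaskedReference, ReferenceIndex, align_reads,
                    build_masked_reference, depth_profile,
                    pseudogene_unmask_window)
from .classify import (AllelePairCall, CnvLossEvidence, EvidenceBundle,
                       PointVariantEvidence, classify_alleles, is_biallelic_null)
from .cnv import LOG2_BANDS, _copies_from_log2, estimate_copy_number
from .hotspots import (Pileup, call_hotspots, default_hotspots,
                       genotype_index_variants, infer_ex35_deletion_zygosity,
                       scan_region_variants)
from .locus import Interval, ParalogLocus, VariantDescription, parse_variant
from .simulate import (AlleleSpec, DiploidSample, LocusConfig, PanelDesign,
                       build_locus, default_genomic_panel, default_modified_panel,
                       long_pcr_amplify, make_sample, phasing_amplify,
                       simulate_reads, variant_to_edit)

__all__ = [
    "Thresholds",
    "RunConfig",
    "ScreenContext",
    "ScreenReport",
    "run_screen",
    "run_mode_comparison",
    "load_patient_scenarios",
]


@dataclass(frozen=True)
class Thresholds:
    min_depth: int = 20
    min_alt_frac: float = 0.15
    hom_frac: float = 0.85
    seed_k: int = 15
    max_mismatch_frac: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    spec1: AlleleSpec
    spec2: AlleleSpec
    sample_id: str = "sample"
    mean_depth: float = 200.0
    error_rate: float = 0.005
    mode: str = "both"                  # standard | modified | both
    with_phasing: bool = True
    seed: int = 0
    thresholds: Thresholds = Thresholds()
    annotations: dict[str, str] = field(default_factory=dict)
    expected: tuple[str, str] | None = None   # expected class pair, for validation runs


class ScreenContext:
    """Locus, panels, masked references and a control pool, built once."""

    def __init__(self, locus: ParalogLocus | None = None,
                 locus_config: LocusConfig | None = None,
                 locus_seed: int = 0,
                 thresholds: Thresholds = Thresholds(),
                 control_depth: float = 200.0,
                 control_seed: int = 990_000,
                 n_controls: int = 3):
        self.locus = locus or build_locus(locus_config, seed=locus_seed)
        self.thresholds = thresholds
        self.genomic_panel = default_genomic_panel(self.locus)
        self.modified_panel = default_modified_panel(self.locus)
        self.standard_ref = build_masked_reference(self.locus, "standard")
        self.modified_ref = build_masked_reference(self.locus, "modified")
        self.standard_index = ReferenceIndex(self.standard_ref, thresholds.seed_k)
        self.modified_index = ReferenceIndex(self.modified_ref, thresholds.seed_k)
        self.hotspots = default_hotspots(self.locus)
        self.cnv_targets = {"marker_c": ["markerC"], "exon2": ["ex2"], "exon3": ["ex3"]}
        self._build_controls(control_depth, control_seed, n_controls)

    # -- helpers ---------------------------------------------------------
    def _genomic_amp_depths(self, pile_cov: np.ndarray) -> dict[str, float]:
        """Mean coverage per unmasked genomic amplicon insert."""
        out = {}
        for amp in self.genomic_panel.amplicons:
            iv = amp.interval
            if self.standard_ref.n_count(iv.start - 1, iv.end):
                continue  # amplicon silenced by the mask; useless for CNV
            out[amp.name] = float(pile_cov[iv.start - 1:iv.end].mean())
        return out

    def _modified_ratio(self, cov: np.ndarray) -> float:
        """Exon-35 coverage relative to the exon-36 reference amplicon."""
        e35 = self.locus.exon_map.exon(35)
        ref_amp = self.modified_panel.amplicon("ex36")
        num = float(cov[e35.g_start - 1:e35.g_end].mean())
        den = float(cov[ref_amp.interval.start - 1:ref_amp.interval.end].mean())
        return num / den if den > 0 else 0.0

    def _build_controls(self, depth: float, seed: int, n: int) -> None:
        self.control_genomic: list[dict[str, float]] = []
        self.control_mod_ratio: list[float] = []
        wild = AlleleSpec("normal")
        for i in range(n):
            sample = make_sample(self.locus, wild, wild, f"control{i}", seed + i)
            g_reads = simulate_reads(
                [(f"control{i}_hap1", sample.haplotype_1.sequence),
                 (f"control{i}_hap2", sample.haplotype_2.sequence)],
                self.genomic_panel, depth, 0.0, seed + i)
            g_aln = align_reads(g_reads, self.standard_index,
                                max_mismatch_frac=self.thresholds.max_mismatch_frac)
            cov, _ = depth_profile(g_aln, self.standard_ref)
            self.control_genomic.append(self._genomic_amp_depths(cov))
            templates = long_pcr_amplify(sample, self.locus)
            m_reads = simulate_reads(templates, self.modified_panel, depth, 0.0,
                                     seed + 100 + i)
            m_aln = align_reads(m_reads, self.modified_index,
                                max_mismatch_frac=self.thresholds.max_mismatch_frac)
            m_cov, _ = depth_profile(m_aln, self.modified_ref)
            self.control_mod_ratio.append(self._modified_ratio(m_cov))


@dataclass
class ScreenReport:
    sample_id: str
    ex35_del_zygosity: str
    index_zygosity: dict[str, str]
    hotspot_calls: dict
    copy_calls: dict
    ex35_copies: int | None
    point_variants: list
    call: AllelePairCall
    biallelic_null: bool | None
    biallelic_summary: str
    truth_pair: tuple[str, str] | None = None
    expected_pair: tuple[str, str] | None = None
    matches_expected: bool | None = None

    def summary_text(self) -> str:
        lines = [f"sample {self.sample_id}",
                 f"  exon-35 deletion zygosity: {self.ex35_del_zygosity}",
                 f"  index zygosity: {self.index_zygosity}",
                 f"  exon-35 copies: {self.ex35_copies}",
                 f"  copy calls: " + ", ".join(
                     f"{t}={c.copies}" for t, c in sorted(self.copy_calls.items())),
                 f"  point variants: " + (", ".join(
                     f"{v.label}({z})" for v, z in self.point_variants) or "none")]
        if self.call.conflicts:
            lines.append("  CONFLICT: " + "; ".join(self.call.conflicts))
        elif self.call.ambiguous:
            lines.append(f"  ambiguous call, candidates: {self.call.candidate_set}")
        else:
            lines.append(f"  call: {self.call.allele_1} / {self.call.allele_2}")
        lines.append(f"  biallelic null: {self.biallelic_summary}")
        for r in self.call.rationale:
            lines.append(f"    - {r}")
        return "\n".join(lines)


def _point_variant_evidence(found, annotations) -> tuple[PointVariantEvidence, ...]:
    out = []
    for v, zyg in found:
        protein = annotations.get(v.label, "")
        out.append(PointVariantEvidence(v.label, "hom" if zyg == "hom" else "het",
                                        protein))
    return tuple(out)


def _merge_cnv_losses(copy_calls) -> tuple[CnvLossEvidence, ...]:
    """Merge equal-copy exon losses into one event (contiguous multi-exon
    deletions present as a run of equally-reduced targets)."""
    losses: dict[int, list[str]] = {}
    for target, call in copy_calls.items():
        if target == "marker_c" or call.copies is None or call.copies >= 2:
            continue
        losses.setdefault(call.copies, []).append(target)
    return tuple(CnvLossEvidence("+".join(sorted(names)), copies)
                 for copies, names in sorted(losses.items()))


def _variant_alt_window(locus: ParalogLocus, v: VariantDescription, flank: int = 12) -> str:
    """The haplotype sequence context produced by a variant (for exact-search
    phasing of Sanger-confirmable variants)."""
    S = locus.sequence
    edit = variant_to_edit(v, locus.exon_map)
    if edit[0] == "sub":
        _, g, alt = edit
        return S[g - 1 - flank:g - 1] + alt + S[g:g + flank]
    if edit[0] == "del":
        _, g0, g1 = edit
        return S[g0 - 1 - flank:g0 - 1] + S[g1:g1 + flank]
    if edit[0] == "dup":
        _, g0, g1 = edit
        return S[g0 - 1 - flank:g1] + S[g0 - 1:g1] + S[g1:g1 + flank]
    _, g0, g1, alt = edit
    return S[g0 - 1 - flank:g0 - 1] + alt + S[g1:g1 + flank]


def _index_c_window(locus: ParalogLocus) -> str:
    v = locus.index_variant("c").description
    return _variant_alt_window(locus, v)


def _derive_phasing(ctx: ScreenContext, sample: DiploidSample,
                    evidence: EvidenceBundle) -> dict[str, str]:
    """Phase discriminating variants with the allele-specific product that
    amplifies only the normal-exon-35 haplotype(s)."""
    templates = phasing_amplify(sample, ctx.locus)
    if not templates:
        return {}
    joined = [t for _, t in templates]

    def side(window: str) -> str:
        return ("on_normal_ex35_allele" if any(window in t for t in joined)
                else "on_deleted_ex35_allele")

    phasing: dict[str, str] = {}
    if evidence.index_zygosity.get("c") == "het":
        phasing["index_c"] = side(_index_c_window(ctx.locus))
    for pv in evidence.point_variants:
        if pv.zygosity != "het":
            continue
        try:
            v = parse_variant(pv.label)
        except ValueError:
            continue
        phasing[pv.label] = side(_variant_alt_window(ctx.locus, v))
    return phasing


def run_screen(ctx: ScreenContext, config: RunConfig) -> ScreenReport:
    """Run the full screen for one (simulated) diploid sample."""
    th = config.thresholds
    locus = ctx.locus
    sample = make_sample(locus, config.spec1, config.spec2,
                         config.sample_id, config.seed)

    point_variants: tuple[PointVariantEvidence, ...] = ()
    found_pvs: list = []
    cnv_losses: tuple[CnvLossEvidence, ...] = ()
    copy_calls = {}
    marker_copies = None
    if config.mode in ("standard", "both"):
        g_reads = simulate_reads(
            [(f"{config.sample_id}_hap1", sample.haplotype_1.sequence),
             (f"{config.sample_id}_hap2", sample.haplotype_2.sequence)],
            ctx.genomic_panel, config.mean_depth, config.error_rate, config.seed)
        g_aln = align_reads(g_reads, ctx.standard_index,
                            max_mismatch_frac=th.max_mismatch_frac)
        g_pile = Pileup(g_aln, ctx.standard_ref)
        found_pvs = scan_region_variants(g_pile, locus,
                                         min_depth=th.min_depth,
                                         min_alt_frac=th.min_alt_frac,
                                         hom_frac=th.hom_frac)
        point_variants = _point_variant_evidence(found_pvs, config.annotations)
        amp_depths = ctx._genomic_amp_depths(g_pile.depth)
        copy_calls = estimate_copy_number(amp_depths, ctx.control_genomic,
                                          ctx.cnv_targets)
        marker_copies = copy_calls["marker_c"].copies
        cnv_losses = _merge_cnv_losses(copy_calls)

    zygosity = "indeterminate"
    index_zyg = {k: "absent" for k in "bcdef"}
    calls = {}
    ex35_copies = None
    if config.mode in ("modified", "both"):
        templates = long_pcr_amplify(sample, locus)
        m_reads = simulate_reads(templates, ctx.modified_panel,
                                 config.mean_depth, config.error_rate,
                                 config.seed + 1)
        m_aln = align_reads(m_reads, ctx.modified_index,
                            max_mismatch_frac=th.max_mismatch_frac)
        m_pile = Pileup(m_aln, ctx.modified_ref)
        calls = call_hotspots(m_pile, ctx.hotspots,
                              min_depth=th.min_depth, min_alt_frac=th.min_alt_frac)
        zygosity = infer_ex35_deletion_zygosity(calls)
        index_zyg = genotype_index_variants(calls, th.hom_frac, th.min_alt_frac)
        ratio = ctx._modified_ratio(m_pile.depth)
        ctrl = float(np.median(ctx.control_mod_ratio))
        ex35_copies = _copies_from_log2(math.log2((ratio + 0.01) / (ctrl + 0.01)))

    evidence = EvidenceBundle(
        ex35_del_zygosity=zygosity,
        index_zygosity=index_zyg,
        ex35_copies=ex35_copies,
        marker_c_copies=marker_copies,
        point_variants=point_variants,
        cnv_losses=cnv_losses,
    )
    call = classify_alleles(evidence)
    if call.ambiguous and config.with_phasing:
        phasing = _derive_phasing(ctx, sample, evidence)
        if phasing:
            call = classify_alleles(replace(evidence, phasing=phasing))

    try:
        null, summary = is_biallelic_null(call)
    except ValueError as exc:
        null, summary = None, str(exc)

    truth = sample.truth_pair()
    expected = tuple(sorted(config.expected)) if config.expected else None
    matches = None
    if expected is not None:
        matches = call.class_pair() == expected
    return ScreenReport(
        sample_id=config.sample_id,
        ex35_del_zygosity=zygosity,
        index_zygosity=index_zyg,
        hotspot_calls=dict(calls),
        copy_calls=dict(copy_calls),
        ex35_copies=ex35_copies,
        point_variants=found_pvs,
        call=call,
        biallelic_null=null,
        biallelic_summary=summary,
        truth_pair=truth,
        expected_pair=expected,
        matches_expected=matches,
    )


def run_mode_comparison(ctx: ScreenContext, config: RunConfig):
    """Which variants each analysis mode can see for one sample.

    Returns rows (variant, detected_by_standard, detected_by_modified):
    variants in the gene's exon 32-44 homologous region require the modified
    mode (the standard mask silences them), while unique-region point
    variants require the standard (whole-genome template) run.
    """
    import pandas as pd
    std = run_screen(ctx, replace(config, mode="standard", with_phasing=False))
    mod = run_screen(ctx, replace(config, mode="modified", with_phasing=False))

    rows = []
    std_labels = {v.label for v, _ in std.point_variants}
    mod_del = mod.ex35_del_zygosity in ("heterozygous", "homozygous")
    sample = make_sample(ctx.locus, config.spec1, config.spec2,
                         config.sample_id, config.seed)
    truth_indices = sample.haplotype_1.carried_indices | sample.haplotype_2.carried_indices
    truth_pvs = set(sample.haplotype_1.carried_variants) | set(sample.haplotype_2.carried_variants)
    if "a" in truth_indices:
        rows.append(("index_a (120-bp deletion)", False, mod_del))
    for idx in "bcdef":
        if idx in truth_indices:
            rows.append((f"index_{idx}",
                         False,  # masked region: the standard run cannot call it
                         mod.index_zygosity.get(idx, "absent") != "absent"))
    for label in sorted(truth_pvs):
        rows.append((label, label in std_labels, False))
    return pd.DataFrame(rows, columns=["variant", "standard_mode", "modified_mode"])


def load_patient_scenarios() -> dict[str, RunConfig]:
    """The packaged per-family screening scenarios as ready-to-run configs."""
    path = resources.files("pseudopanel").joinpath("data", "scenarios.yaml")
    payload = yaml.safe_load(path.read_text())
    out: dict[str, RunConfig] = {}
    for pid, entry in payload["patients"].items():
        specs = []
        for allele in entry["alleles"]:
            variants = tuple(parse_variant(h) for h in allele.get("variants", []))
            specs.append(AlleleSpec(allele["class"], variants))
        out[pid] = RunConfig(
            spec1=specs[0], spec2=specs[1], sample_id=pid,
            annotations=dict(entry.get("annotations", {})),
            expected=tuple(entry["expected"]),
        )
    return out
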