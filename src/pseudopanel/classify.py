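"""Fuse molecular evidence into a per-allele classification.

The six recognized allele classes are ``normal``, ``fusion_type1``,
``fusion_type2``, ``conversion_type1``, ``conversion_type2`` and
``point_variant`` (plus ``cnv_deletion`` for multi-exon copy losses outside
the homologous region).  Type 1 classes carry the 120-bp exon-35 deletion
(index a); type 2 classes begin downstream of it and are keyed on the
exon-40 missense index c (indices b, d, e, f are supporting evidence only).
Fusions have lost the intervening unit, so each fusion allele removes one
marker-gene-C copy; conversions retain it.

Some evidence combinations are genuinely ambiguous — a heterozygous deletion
with a heterozygous index c and single-copy marker-C loss is either
``fusion_type1 + X`` (deletion and c in cis) or
``conversion_type1 + fusion_type2`` (in trans).  Ambiguity is an explicit
output state resolved by phasing evidence (allele-specific PCR or trio
genotyping through the same interface), never silently collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "EvidenceBundle",
    "AllelePairCall",
    "classify_alleles",
    "apply_phasing",
    "is_biallelic_null",
    "allele_class_of",
    "is_truncating",
]

ZYGOSITIES = ("none", "heterozygous", "homozygous", "indeterminate")
INDEX_ZYGOSITIES = ("absent", "het", "hom")

_NULL_CLASSES = {"fusion_type1", "fusion_type2", "conversion_type1",
                 "conversion_type2", "cnv_deletion"}


@dataclass(frozen=True)
class PointVariantEvidence:
    label: str
    zygosity: str                  # het | hom
    protein: str = ""


@dataclass(frozen=True)
class CnvLossEvidence:
    """A copy loss outside the homologous region (e.g. 'exons 2-3')."""
    label: str
    copies: int                    # 0 (homozygous loss) or 1


@dataclass(frozen=True)
class EvidenceBundle:
    ex35_del_zygosity: str                       # none/heterozygous/homozygous/indeterminate
    index_zygosity: dict[str, str]               # b-f -> absent/het/hom
    ex35_copies: int | None = None
    marker_c_copies: int | None = None
    point_variants: tuple[PointVariantEvidence, ...] = ()
    cnv_losses: tuple[CnvLossEvidence, ...] = ()
    # variant key ('index_c' or a point-variant label) -> on_normal_ex35_allele
    # / on_deleted_ex35_allele
    phasing: dict[str, str] | None = None


@dataclass(frozen=True)
class AllelePairCall:
    """Unordered pair of allele labels with an explicit ambiguity state.

    ``candidate_set`` holds every pair consistent with the evidence when
    ``ambiguous``; ``conflicts`` lists clashing evidence fields (a non-empty
    list means no call was possible).  ``rationale`` records the applied
    rules in order.
    """

    allele_1: str | None
    allele_2: str | None
    ambiguous: bool = False
    candidate_set: tuple[tuple[str, str], ...] = ()
    rationale: tuple[str, ...] = ()
    conflicts: tuple[str, ...] = ()

    @property
    def pair(self) -> tuple[str, str] | None:
        if self.allele_1 is None or self.allele_2 is None:
            return None
        return tuple(sorted((self.allele_1, self.allele_2)))

    def class_pair(self) -> tuple[str, str] | None:
        if self.pair is None:
            return None
        return tuple(sorted(allele_class_of(a) for a in self.pair))


def allele_class_of(label: str) -> str:
    """Strip a parenthesised variant annotation: point_variant(c.1A>G) -> point_variant."""
    return label.split("(", 1)[0]


def is_truncating(pv: PointVariantEvidence) -> bool:
    """Syntactic truncation judgement: nonsense/frameshift (protein text with
    '*' or 'fs') or out-of-frame small indels.  Missense is not null."""
    text = pv.protein or pv.label
    return "*" in text or "fs" in text.lower() or text.endswith("del") or text.endswith("dup")


def _pv_label(pv: PointVariantEvidence) -> str:
    if pv.protein:
        return f"point_variant({pv.label},{pv.protein})"
    return f"point_variant({pv.label})"


def _other_allele(e: EvidenceBundle, rationale: list[str]) -> str:
    """The partner allele X of a recombinant call: a heterozygous point
    variant when present, otherwise a heterozygous CNV loss, else normal."""
    het_pvs = [p for p in e.point_variants if p.zygosity == "het"]
    if het_pvs:
        rationale.append(f"heterozygous point variant {het_pvs[0].label} fills the second allele")
        return _pv_label(het_pvs[0])
    het_cnv = [c for c in e.cnv_losses if c.copies == 1]
    if het_cnv:
        rationale.append(f"heterozygous copy loss {het_cnv[0].label} fills the second allele")
        return f"cnv_deletion({het_cnv[0].label})"
    rationale.append("no second pathogenic finding; second allele normal")
    return "normal"


def _conflict(e: EvidenceBundle, msgs: list[str], rationale: list[str]) -> AllelePairCall:
    return AllelePairCall(None, None, rationale=tuple(rationale), conflicts=tuple(msgs))


def classify_alleles(e: EvidenceBundle) -> AllelePairCall:
    """Exhaustive decision table over the discretized evidence space.

    Every combination reaches a resolved pair, an explicit ambiguous
    candidate set, or a conflict report.
    """
    rationale: list[str] = []
    conflicts: list[str] = []
    zyg = e.ex35_del_zygosity
    if zyg not in ZYGOSITIES:
        raise ValueError(f"unknown zygosity {zyg!r}")
    c_zyg = e.index_zygosity.get("c", "absent")
    marker = e.marker_c_copies

    # internal-consistency checks: zygosity vs exon-35 copy number
    if e.ex35_copies is not None:
        expected = {"homozygous": 0, "heterozygous": 1, "none": 2}.get(zyg)
        if expected is not None and e.ex35_copies != expected:
            conflicts.append(
                f"ex35_del_zygosity={zyg} but ex35_copies={e.ex35_copies}")
    if conflicts:
        return _conflict(e, conflicts, rationale)

    if zyg == "indeterminate":
        return _conflict(e, ["exon-35 deletion zygosity indeterminate "
                             "(both sentinel sites no-call)"], rationale)

    if zyg == "homozygous":
        rationale.append("homozygous 120-bp deletion: both alleles type 1")
        if marker is None or marker == 2:
            rationale.append("marker gene C intact: conversions on both alleles")
            pair = ("conversion_type1", "conversion_type1")
        elif marker == 1:
            rationale.append("one marker-C copy lost: one fusion, one conversion")
            pair = ("conversion_type1", "fusion_type1")
        elif marker == 0:
            rationale.append("both marker-C copies lost: fusions on both alleles")
            pair = ("fusion_type1", "fusion_type1")
        else:
            return _conflict(e, [f"marker_c_copies={marker} with homozygous deletion"],
                             rationale)
        return AllelePairCall(*pair, rationale=tuple(rationale))

    if zyg == "heterozygous":
        rationale.append("heterozygous 120-bp deletion: one type 1 allele")
        if c_zyg == "absent":
            if marker in (None, 2):
                rationale.append("index c absent and marker C intact: "
                                 "deleted allele is a type 1 conversion")
                x = _other_allele(e, rationale)
                return AllelePairCall("conversion_type1", x, rationale=tuple(rationale))
            return _conflict(e, [f"marker_c_copies={marker} (fusion) but index c absent"],
                             rationale)
        if c_zyg == "het":
            if marker == 1:
                cands = _het_del_het_c_candidates(e, rationale)
                rationale.append("het deletion + het index c + one marker-C loss: "
                                 "cis (fusion type 1) and trans "
                                 "(conversion type 1 + fusion type 2) both fit")
                call = AllelePairCall(None, None, ambiguous=True,
                                      candidate_set=cands, rationale=tuple(rationale))
                if e.phasing:
                    call = apply_phasing(call, e)
                return call
            if marker in (None, 2):
                rationale.append("het deletion + het index c with marker C intact: "
                                 "type 1 and type 2 conversions in trans")
                return AllelePairCall("conversion_type1", "conversion_type2",
                                      rationale=tuple(rationale))
            return _conflict(e, [f"marker_c_copies={marker} incompatible with "
                                 "heterozygous index c"], rationale)
        # c hom
        if marker == 1:
            rationale.append("het deletion + homozygous index c + one marker-C loss: "
                             "fusion type 1 in trans with conversion type 2")
            return AllelePairCall("fusion_type1", "conversion_type2",
                                  rationale=tuple(rationale))
        if marker == 0:
            rationale.append("het deletion + homozygous index c + two marker-C losses: "
                             "fusion type 1 and fusion type 2")
            return AllelePairCall("fusion_type1", "fusion_type2",
                                  rationale=tuple(rationale))
        rationale.append("het deletion + homozygous index c with marker C intact: "
                         "extended-tract type 1 conversion in trans with type 2")
        return AllelePairCall("conversion_type1", "conversion_type2",
                              rationale=tuple(rationale))

    # zyg == none
    if c_zyg == "hom":
        rationale.append("homozygous index c without the deletion: type 2 on both alleles")
        if marker in (None, 2):
            pair = ("conversion_type2", "conversion_type2")
        elif marker == 1:
            pair = ("fusion_type2", "conversion_type2")
        elif marker == 0:
            pair = ("fusion_type2", "fusion_type2")
        else:
            return _conflict(e, [f"marker_c_copies={marker} with homozygous index c"],
                             rationale)
        return AllelePairCall(*pair, rationale=tuple(rationale))
    if c_zyg == "het":
        if marker == 1:
            rationale.append("het index c + one marker-C loss: fusion type 2")
            x = _other_allele(e, rationale)
            return AllelePairCall("fusion_type2", x, rationale=tuple(rationale))
        if marker in (None, 2):
            rationale.append("het index c with marker C intact: conversion type 2")
            x = _other_allele(e, rationale)
            return AllelePairCall("conversion_type2", x, rationale=tuple(rationale))
        return _conflict(e, [f"marker_c_copies={marker} with heterozygous index c"],
                         rationale)
    # no pseudogene-derived evidence at all
    if marker not in (None, 2):
        return _conflict(e, [f"marker-gene-C copies={marker} without any index evidence"],
                         rationale)
    alleles: list[str] = []
    for c in e.cnv_losses:
        n = 2 - c.copies
        rationale.append(f"copy loss {c.label} ({c.copies} copies remaining)")
        alleles.extend([f"cnv_deletion({c.label})"] * n)
    for p in e.point_variants:
        n = 2 if p.zygosity == "hom" else 1
        rationale.append(f"point variant {p.label} ({p.zygosity})")
        alleles.extend([_pv_label(p)] * n)
    if len(alleles) > 2:
        return _conflict(e, [f"more than two pathogenic alleles implied: {alleles}"],
                         rationale)
    while len(alleles) < 2:
        alleles.append("normal")
    if alleles == ["normal", "normal"]:
        rationale.append("no pathogenic finding on either allele")
    return AllelePairCall(alleles[0], alleles[1], rationale=tuple(rationale))


def _het_del_het_c_candidates(e: EvidenceBundle, rationale: list[str]
                              ) -> tuple[tuple[str, str], ...]:
    x = _other_allele(e, list(rationale))  # do not pollute shared rationale
    return ((tuple(sorted(("fusion_type1", x)))),
            (tuple(sorted(("conversion_type1", "fusion_type2")))))


def apply_phasing(call: AllelePairCall, evidence: EvidenceBundle) -> AllelePairCall:
    """Reduce an ambiguous candidate set with phasing evidence.

    Phasing localizes a discriminating variant to the allele retaining the
    normal exon-35 sequence or to the deleted-exon-35 allele.  Trio evidence
    enters through the same map.  A candidate pair is kept only if it is
    consistent with every phased variant; phasing that contradicts all
    candidates yields a conflict report.
    """
    if not call.ambiguous:
        return call
    phasing = evidence.phasing or {}
    if not phasing:
        return call
    rationale = list(call.rationale)
    kept = []
    for pair in call.candidate_set:
        if _pair_consistent(pair, phasing):
            kept.append(pair)
    for key, side in phasing.items():
        rationale.append(f"phasing: {key} on the "
                         f"{'normal' if side == 'on_normal_ex35_allele' else 'deleted'}"
                         "-exon-35 allele")
    if not kept:
        return AllelePairCall(None, None, rationale=tuple(rationale),
                              conflicts=("phasing evidence contradicts every candidate pair",))
    if len(kept) == 1:
        return AllelePairCall(*kept[0], rationale=tuple(rationale))
    return AllelePairCall(None, None, ambiguous=True, candidate_set=tuple(kept),
                          rationale=tuple(rationale))


def _pair_consistent(pair: tuple[str, str], phasing: dict[str, str]) -> bool:
    classes = tuple(allele_class_of(a) for a in pair)
    for key, side in phasing.items():
        if key == "index_c":
            # which allele of the pair carries index c?
            carriers_del = {"fusion_type1"}            # deleted-ex35 allele with c
            carriers_norm = {"fusion_type2", "conversion_type2"}
            if side == "on_normal_ex35_allele":
                if not any(c in carriers_norm for c in classes):
                    return False
            else:
                if not any(c in carriers_del for c in classes):
                    return False
        else:
            # a phased point variant must sit on a point_variant allele of the
            # pair when phased to the normal-ex35 side
            has_pv = any(allele_class_of(a) == "point_variant" and key in a for a in pair)
            if side == "on_normal_ex35_allele" and not has_pv:
                return False
            if side == "on_deleted_ex35_allele" and has_pv:
                return False
    return True


def is_biallelic_null(call: AllelePairCall) -> tuple[bool, str]:
    """True iff both alleles abolish the gene product.

    Fusions, conversions, multi-exon copy losses and truncating point
    variants count; a normal allele or a missense variant of unknown
    significance does not.  Refuses (raises) on ambiguous or conflicted calls.
    """
    if call.conflicts:
        raise ValueError("cannot judge biallelic status: evidence conflicts "
                         + "; ".join(call.conflicts))
    if call.ambiguous or call.pair is None:
        raise ValueError("cannot judge biallelic status of an ambiguous call; "
                         "resolve with phasing first")
    verdicts = []
    for allele in call.pair:
        cls = allele_class_of(allele)
        if cls in _NULL_CLASSES:
            verdicts.append(True)
        elif cls == "point_variant":
            label = allele[len("point_variant("):-1]
            verdicts.append(is_truncating(PointVariantEvidence(label, "het")))
        else:
            verdicts.append(False)
    both = all(verdicts)
    if both:
        text = f"biallelic null: {call.pair[0]} / {call.pair[1]}"
    elif any(verdicts):
        text = f"carrier: one null allele ({call.pair})"
    else:
        text = "no null allele detected"
    return both, text
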