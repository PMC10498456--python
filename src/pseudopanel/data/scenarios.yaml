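# Nine simulated screening scenarios matching the cohort's per-family
# genotypes.  These are simulations consistent with the cohort table's
# determinations, not patient data.  Protein annotations are the published
# descriptions attached to the detected cDNA variants at reporting time.
patients:
  P1:
    alleles:
      - {class: point_variant, variants: ["c.101-30_1000del"]}
      - {class: point_variant, variants: ["c.101-30_1000del"]}
    expected: [cnv_deletion, cnv_deletion]
  P2:
    alleles:
      - {class: conversion_type1}
      - {class: conversion_type1}
    expected: [conversion_type1, conversion_type1]
  P3:
    alleles:
      - {class: point_variant, variants: ["c.1650_1651del"]}
      - {class: point_variant, variants: ["c.1650_1651del"]}
    expected: [point_variant, point_variant]
    annotations:
      "c.1650_1651del": "p.(Glu552Argfs*41)"
  P4:
    alleles:
      - {class: point_variant, variants: ["c.10274C>G"]}
      - {class: fusion_type1}
    expected: [fusion_type1, point_variant]
    annotations:
      "c.10274C>G": "p.(Ser3425*)"
  P5:
    alleles:
      - {class: point_variant, variants: ["c.6948del"]}
      - {class: fusion_type1}
    expected: [fusion_type1, point_variant]
    annotations:
      "c.6948del": "p.(Asp2317Thrfs*53)"
  P6:
    alleles:
      - {class: conversion_type2}
      - {class: conversion_type2}
    expected: [conversion_type2, conversion_type2]
  P7:
    alleles:
      - {class: conversion_type1}
      - {class: fusion_type2}
    expected: [conversion_type1, fusion_type2]
  P8:
    alleles:
      - {class: point_variant, variants: ["c.8585G>A"]}
      - {class: conversion_type1}
    expected: [conversion_type1, point_variant]
    annotations:
      "c.8585G>A": "p.(Trp2862*)"
  P9:
    alleles:
      - {class: point_variant, variants: ["c.9271dup"]}
      - {class: fusion_type1}
    expected: [fusion_type1, point_variant]
    annotations:
      "c.9271dup": "p.(Gln3091Profs*31)"
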