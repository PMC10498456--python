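"""Exon-level copy number from amplicon coverage, and MLPA probe-ratio
interpretation.

The amplicon caller is a standard median-normalized log2-ratio estimator:
each sample's per-amplicon depths are divided by the sample median (library
size), ratios are taken against the median of the normalized control depths,
and the per-target median log2 ratio is mapped to integer copies.  Default
bands place log2(1/2) = -1 comfortably inside the one-copy band:

    <= -2.0            0 copies
    (-2.0, -0.42]      1 copy
    (-0.42,  0.32)     2 copies
    >=  0.32           3+ copies

MLPA probe ratios follow common diagnostic practice: ~0 for zero copies,
~0.5 for one, ~1.0 for two, >=1.3 for gains; bands are configurable per kit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CopyCall",
    "CopyCallTable",
    "estimate_copy_number",
    "classify_mlpa",
    "read_mlpa_ratios",
    "mlpa_copy_table",
    "simulate_target_depths",
]

LOG2_BANDS = (-2.0, -0.42, 0.32)
MLPA_BANDS = (0.25, 0.75, 1.3)
_EPS = 0.01


@dataclass(frozen=True)
class CopyCall:
    target: str
    copies: int | None        # None when uncallable
    log2_ratio: float
    source: str               # amplicon_cnv | mlpa


class CopyCallTable(dict):
    """target -> CopyCall."""

    def copies(self, target: str) -> int | None:
        return self[target].copies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.target, c.copies, c.log2_ratio, c.source) for c in self.values()],
            columns=["target", "copies", "log2_ratio", "source"])


def _copies_from_log2(r: float) -> int:
    if r <= LOG2_BANDS[0]:
        return 0
    if r <= LOG2_BANDS[1]:
        return 1
    if r < LOG2_BANDS[2]:
        return 2
    return 3


def estimate_copy_number(sample_depths: dict[str, float],
                         control_depths: list[dict[str, float]],
                         targets: dict[str, list[str]]) -> CopyCallTable:
    """Call integer copies per target from per-amplicon mean depths.

    ``targets`` maps a target name to the amplicons that inform it.  Requires
    at least three controls.  A target whose control median depth is zero is
    flagged uncallable (copies None) rather than guessed.
    """
    if len(control_depths) < 3:
        raise ValueError("need >= 3 control samples")
    for t, amps in targets.items():
        if not amps:
            raise ValueError(f"target {t!r} has no amplicons")

    def normalize(d: dict[str, float]) -> dict[str, float]:
        # library-size factor from amplicons that worked at all, so a dead
        # amplicon does not skew the median on small panels
        positive = [v for v in d.values() if v > 0]
        if not positive:
            raise ValueError("all amplicon depths are zero; cannot normalize")
        med = float(np.median(positive))
        return {k: v / med for k, v in d.items()}

    s_norm = normalize(sample_depths)
    c_norms = [normalize(c) for c in control_depths]

    table = CopyCallTable()
    for target, amps in targets.items():
        ratios = []
        uncallable = False
        for amp in amps:
            ctrl = float(np.median([c.get(amp, 0.0) for c in c_norms]))
            if ctrl <= 0:
                uncallable = True
                continue
            ratios.append(math.log2((s_norm.get(amp, 0.0) + _EPS) / (ctrl + _EPS)))
        if not ratios:
            table[target] = CopyCall(target, None, float("nan"), "amplicon_cnv")
            continue
        r = float(np.median(ratios))
        copies = _copies_from_log2(r)
        if uncallable and not ratios:
            copies = None
        table[target] = CopyCall(target, copies, r, "amplicon_cnv")
    return table


def classify_mlpa(ratio: float, bands: tuple[float, float, float] = MLPA_BANDS) -> int:
    """Map an MLPA probe ratio to integer copies (monotone in the ratio)."""
    if ratio < 0:
        raise ValueError("MLPA ratio must be >= 0")
    lo, mid, hi = bands
    if ratio < lo:
        return 0
    if ratio < mid:
        return 1
    if ratio < hi:
        return 2
    return 3


def read_mlpa_ratios(path: str | Path) -> pd.DataFrame:
    """Read a probe-ratio TSV with columns probe_id, target, ratio."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["probe_id", "target", "ratio"]:
            raise ValueError(f"{path.name} line 1: expected columns "
                             f"probe_id/target/ratio, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path.name} line {lineno}: expected 3 columns")
            try:
                ratio = float(parts[2])
            except ValueError:
                raise ValueError(f"{path.name} line {lineno}: "
                                 f"ratio {parts[2]!r} is not a number") from None
            if ratio < 0:
                raise ValueError(f"{path.name} line {lineno}: negative ratio")
            rows.append((parts[0], parts[1], ratio))
    return pd.DataFrame(rows, columns=["probe_id", "target", "ratio"])


def mlpa_copy_table(ratios: pd.DataFrame,
                    bands: tuple[float, float, float] = MLPA_BANDS) -> CopyCallTable:
    """Per-target copies from MLPA ratios (median ratio over probes)."""
    table = CopyCallTable()
    for target, grp in ratios.groupby("target", sort=False):
        med = float(grp["ratio"].median())
        pseudo_log2 = math.log2((med + _EPS) / (1.0 + _EPS))
        table[target] = CopyCall(target, classify_mlpa(med, bands), pseudo_log2, "mlpa")
    return table


def simulate_target_depths(true_copies: dict[str, int],
                           targets: dict[str, list[str]],
                           mean_depth: float, seed: int,
                           amplicon_log_sd: float = 0.2,
                           n_controls: int = 3,
                           ) -> tuple[dict[str, float], list[dict[str, float]]]:
    """Synthetic per-amplicon depth tables for a sample and matched controls.

    Each amplicon has a fixed lognormal efficiency shared by sample and
    controls (as in a real panel, where efficiency cancels in the ratio);
    read counts are Poisson with mean depth * efficiency * copies / 2.
    """
    rng = np.random.default_rng(seed)
    amps = sorted({a for lst in targets.values() for a in lst})
    eff = {a: float(rng.lognormal(0.0, amplicon_log_sd)) for a in amps}
    copies_of = {a: c for t, c in true_copies.items() for a in targets[t]}

    def one(copies_map) -> dict[str, float]:
        return {a: float(rng.poisson(mean_depth * eff[a] * copies_map.get(a, 2) / 2.0))
                for a in amps}

    sample = one(copies_of)
    controls = [one({}) for _ in range(n_controls)]
    return sample, controls
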