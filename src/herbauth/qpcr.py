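"""In-silico primer specificity, qPCR Ct presence calls, and digital-PCR math.

Specificity is scored with a mismatch-count rule rather than a melting model:
a primer binds a site when its total mismatches are within budget AND its
3'-terminal window (last 4 bases) is clean. Congener assays typically share
a 5' motif and diverge 3'-ward, which exactly this rule discriminates.

Presence from real-time PCR is Ct < 32 cycles (Ct equal to the threshold, or
no amplification at all, scores absent).

Digital PCR: with fraction p of positive wells, lambda = -ln(1 - p) copies
per well; concentration = lambda / well_volume * dilution, with a 95% CI from
the Clopper-Pearson interval on p propagated through -ln(1 - p).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._dp import revcomp

DEFAULT_CT_THRESHOLD = 32.0
THREE_PRIME_WINDOW = 4


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_amplicon: int = 1000

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if not (15 <= len(primer) <= 35):
                raise ValueError(f"{self.name}: {label} primer must be 15-35 nt")
            if set(primer.upper()) - set("ACGT"):
                raise ValueError(f"{self.name}: {label} primer must be ACGT only")


@dataclass(frozen=True)
class BindingSite:
    position: int  # 0-based position of the primer 5' end on the plus strand
    strand: str
    mismatches: int
    three_prime_mismatches: int

    def __post_init__(self) -> None:
        if self.mismatches < 0 or self.three_prime_mismatches < 0:
            raise ValueError("mismatch counts must be >= 0")
        if self.three_prime_mismatches > self.mismatches:
            raise ValueError("3'-window mismatches cannot exceed total")


@dataclass(frozen=True)
class QPCRCall:
    sample: str
    assay: str
    ct: float | None
    present: bool


@dataclass(frozen=True)
class DPCRChip:
    total_wells: int
    positive_wells: int
    well_volume_ul: float = 0.000809  # QuantStudio 3D-style ~809 pL wells
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.positive_wells <= self.total_wells):
            raise ValueError("need 0 <= positive_wells <= total_wells")
        if self.well_volume_ul <= 0 or self.dilution <= 0:
            raise ValueError("well volume and dilution must be positive")


def _mismatch_counts(primer: str, site: str) -> tuple[int, int]:
    total = sum(1 for a, b in zip(primer, site) if a != b)
    w = THREE_PRIME_WINDOW
    three = sum(1 for a, b in zip(primer[-w:], site[-w:]) if a != b)
    return total, three


def find_binding(primer: str, template: str) -> dict[str, BindingSite | None]:
    """Exhaustive ungapped scan for the best site on each strand.

    The best site has the fewest total mismatches; ties prefer fewer
    3'-window mismatches, then the leftmost plus-strand position.
    On the minus strand the primer anneals to the plus strand's reverse
    complement; reported positions index the plus strand 5' end of the
    covered span.
    """
    primer = primer.upper()
    template = template.upper()
    k = len(primer)
    out: dict[str, BindingSite | None] = {}
    for strand, scan_seq in (("+", template), ("-", revcomp(template))):
        best: BindingSite | None = None
        for pos in range(len(scan_seq) - k + 1):
            total, three = _mismatch_counts(primer, scan_seq[pos : pos + k])
            plus_pos = pos if strand == "+" else len(template) - pos - k
            cand = BindingSite(plus_pos, strand, total, three)
            if (
                best is None
                or cand.mismatches < best.mismatches
                or (cand.mismatches == best.mismatches and cand.three_prime_mismatches < best.three_prime_mismatches)
                or (
                    cand.mismatches == best.mismatches
                    and cand.three_prime_mismatches == best.three_prime_mismatches
                    and cand.position < best.position
                )
            ):
                best = cand
        out[strand] = best
    return out


def predict_amplification(
    pair: PrimerPair,
    template: str,
    max_total_mm: int = 2,
    max_3p_mm: int = 0,
) -> tuple[bool, tuple[int, int] | None]:
    """Would this primer pair produce a product from this template?

    Amplifies iff the forward primer binds the plus strand, the reverse
    primer binds the minus strand downstream of it, both within the mismatch
    budgets, and the product (including both primers) is <= max_amplicon bp.
    Returns (amplifies, (start, end) span of the product or None).
    """
    fwd_sites = find_binding(pair.forward, template)
    rev_sites = find_binding(pair.reverse, template)
    f = fwd_sites["+"]
    r = rev_sites["-"]

    def ok(site: BindingSite | None) -> bool:
        return (
            site is not None
            and site.mismatches <= max_total_mm
            and site.three_prime_mismatches <= max_3p_mm
        )

    if not (ok(f) and ok(r)):
        return False, None
    start = f.position
    end = r.position + len(pair.reverse)
    if end <= start or (end - start) > pair.max_amplicon:
        return False, None
    return True, (start, end)


def specificity_matrix(pairs, templates, max_total_mm: int = 2, max_3p_mm: int = 0) -> pd.DataFrame:
    """Amplify/no-amplify call for every (primer pair, template).

    ``templates`` is a mapping name -> sequence or an iterable of
    (name, sequence). Returns a boolean DataFrame (rows = pairs,
    columns = templates).
    """
    if isinstance(templates, dict):
        items = list(templates.items())
    else:
        items = list(templates)
    data = {}
    for name, seq in items:
        data[name] = [
            predict_amplification(pair, seq, max_total_mm, max_3p_mm)[0] for pair in pairs
        ]
    return pd.DataFrame(data, index=[p.name for p in pairs])


def call_presence(ct: float | None, ct_threshold: float = DEFAULT_CT_THRESHOLD) -> bool:
    """Target present iff an amplification signal with Ct strictly below threshold.

    Ct exactly equal to the threshold, or no amplification (ct=None/NaN),
    scores absent.
    """
    if ct is None:
        return False
    ct = float(ct)
    if np.isnan(ct):
        return False
    return ct < ct_threshold


def call_ct_table(df: pd.DataFrame, ct_threshold: float = DEFAULT_CT_THRESHOLD) -> list[QPCRCall]:
    """Interpret a Ct table with columns sample, assay, ct."""
    calls = []
    for _, row in df.iterrows():
        ct = None if pd.isna(row["ct"]) else float(row["ct"])
        calls.append(QPCRCall(str(row["sample"]), str(row["assay"]), ct, call_presence(ct, ct_threshold)))
    return calls


@dataclass(frozen=True)
class DPCRResult:
    copies_per_well: float
    copies_per_ul: float
    ci_low: float
    ci_high: float
    p_positive: float


def dpcr_quantify(chip: DPCRChip, confidence: float = 0.95) -> DPCRResult:
    """Poisson quantification of a digital-PCR chip.

    p = positive/total wells; lambda = -ln(1-p) mean copies per well;
    concentration = lambda / well_volume * dilution. The CI is the
    Clopper-Pearson binomial interval on p mapped through -ln(1-p). A fully
    positive chip is saturated and unquantifiable.
    """
    if chip.positive_wells == chip.total_wells:
        raise ValueError("saturated chip (all wells positive): unquantifiable")
    p = chip.positive_wells / chip.total_wells
    lam = -log(1.0 - p)
    scale = chip.dilution / chip.well_volume_ul
    ci = stats.binomtest(chip.positive_wells, chip.total_wells).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    lo = -log(1.0 - ci.low) * scale
    hi = -log(1.0 - min(ci.high, 1.0 - 1e-12)) * scale
    return DPCRResult(
        copies_per_well=lam,
        copies_per_ul=lam * scale,
        ci_low=lo,
        ci_high=hi,
        p_positive=p,
    )


def load_primers_tsv(path: str | Path) -> list[PrimerPair]:
    """Primer table with columns name, forward, reverse [, max_amplicon]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                name=row["name"],
                forward=row["forward"].upper(),
                reverse=row["reverse"].upper(),
                max_amplicon=int(row["max_amplicon"]) if "max_amplicon" in df.columns else 1000,
            )
        )
    return pairs
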