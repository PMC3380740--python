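"""Hotspot-vs-coldspot enrichment: the O_hc odds ratio and its significance.

For each DNA-binding protein the scan yields a 2x2 table of regions with and
without a motif occurrence: HM hotspots with a hit, HN = N_H - HM without,
and likewise CM / CN for coldspots.  Because coldspots are redrawn several
times and CM is averaged over the draws, the coldspot cells may be
fractional; the odds ratio O_hc = (HM/HN)/(CM/CN) and the Yates-corrected
chi-square are computed on the fractional cells as-is.  Candidate
trans-regulators (the HG set) are the proteins with O_hc above a cutoff and
a significant chi-square p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """Region counts: hotspot row integral, coldspot row possibly fractional."""

    HM: float
    HN: float
    CM: float
    CN: float

    def __post_init__(self) -> None:
        for name in ("HM", "HN", "CM", "CN"):
            if getattr(self, name) < 0:
                raise EnrichmentError(f"negative cell {name}")
        for name in ("HM", "HN"):
            v = getattr(self, name)
            if v != int(v):
                raise EnrichmentError(f"hotspot cell {name} must be an integer, got {v}")

    @property
    def n_hot(self) -> float:
        return self.HM + self.HN

    @property
    def n_cold(self) -> float:
        return self.CM + self.CN

    @property
    def n(self) -> float:
        return self.n_hot + self.n_cold


@dataclass(frozen=True)
class OddsRatio:
    value: float
    flag: str | None = None  # None | "infinite" | "zero-numerator"

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    p_value: float
    flag: str | None = None  # None | "degenerate"


@dataclass
class EnrichmentResult:
    gene: str
    table: ContingencyTable
    o_hc: OddsRatio
    chi2: float
    p_value: float


def average_replicates(per_replicate_cm: Sequence[float], n_cold: float) -> tuple[float, float]:
    """Mean coldspot-with-hit count over replicate draws and its complement CN."""
    if len(per_replicate_cm) == 0:
        raise EnrichmentError("no coldspot replicates given")
    for v in per_replicate_cm:
        if not (0 <= v <= n_cold):
            raise EnrichmentError(f"replicate CM {v} outside [0, {n_cold}]")
    cm = sum(per_replicate_cm) / len(per_replicate_cm)
    return cm, n_cold - cm


def odds_ratio(t: ContingencyTable) -> OddsRatio:
    """O_hc = (HM/HN) / (CM/CN); degenerate cells come back flagged."""
    if t.HN == 0 and t.CN == 0:
        # every region on both sides has a hit (e.g. p-threshold 1): no preference
        return OddsRatio(1.0, "saturated")
    if t.HM == 0:
        return OddsRatio(0.0, "zero-numerator")
    if t.HN == 0 or t.CM == 0:
        return OddsRatio(math.inf, "infinite")
    return OddsRatio((t.HM / t.HN) / (t.CM / t.CN))


def yates_chisq(t: ContingencyTable) -> ChisqResult:
    """Yates continuity-corrected chi-square on a (possibly fractional) 2x2 table.

    chi2 = N (|HM*CN - HN*CM| - N/2)^2 / (N_H N_C (HM+CM)(HN+CN)) with the
    corrected difference floored at zero, and a two-sided p-value from the
    upper tail of chi-square with 1 df.
    """
    margins = (t.n_hot, t.n_cold, t.HM + t.CM, t.HN + t.CN)
    if any(m == 0 for m in margins):
        return ChisqResult(float("nan"), float("nan"), "degenerate")
    n = t.n
    diff = max(0.0, abs(t.HM * t.CN - t.HN * t.CM) - n / 2)
    chi2 = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return ChisqResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def evaluate(gene: str, table: ContingencyTable) -> EnrichmentResult:
    o = odds_ratio(table)
    c = yates_chisq(table)
    return EnrichmentResult(gene, table, o, c.chi2, c.p_value)


def select_candidates(
    results: Sequence[EnrichmentResult],
    or_min: float = 1.20,
    p_max: float = 0.05,
) -> list[EnrichmentResult]:
    """The HG set: O_hc > or_min and p < p_max, ranked by ascending p then
    descending odds ratio."""
    if not results:
        raise EnrichmentError("no enrichment results to select from")
    kept = [
        r
        for r in results
        if r.o_hc.flag != "zero-numerator"
        and r.o_hc.value > or_min
        and not math.isnan(r.p_value)
        and r.p_value < p_max
    ]
    if not kept:
        warnings.warn("no candidate passed the odds-ratio/p-value thresholds", stacklevel=2)
    kept.sort(key=lambda r: (r.p_value, -r.o_hc.value, r.gene))
    return kept


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Report table with the conventional column order; O_hc rounded to 3 dp."""
    rows = [
        (
            r.gene,
            int(r.table.HM),
            int(r.table.HN),
            r.table.CM,
            r.table.CN,
            round(r.o_hc.value, 3) if r.o_hc.flag is None else r.o_hc.value,
            r.p_value,
        )
        for r in results
    ]
    return pd.DataFrame(rows, columns=["Gene", "HM", "HN", "CM", "CN", "O_hc", "p_value"])
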