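"""Genomic intervals, BED/FASTA I/O and matched control-region ("coldspot") sampling.

Recombination hotspots arrive as BED intervals on a genome.  The enrichment
statistic needs a matched set of control regions: for every hotspot, one
coldspot of identical length on the same chromosome, lying at least
``min_distance`` bp away from every hotspot, with coldspots pairwise
non-overlapping.  Length and chromosome matching preserves both the length
distribution and the per-chromosome count distribution of the hotspot set.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

HOTSPOT = "hotspot"
COLDSPOT = "coldspot"

_DNA_CLEAN = bytes(
    (b if b in b"ACGT" else ord("N")) for b in (bytes([c]).upper()[0] for c in range(256))
)


class RegionError(ValueError):
    """Malformed interval data or an unsatisfiable sampling request."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> int:
        """End-to-start gap in bp; 0 if the intervals touch or overlap."""
        if self.chrom != other.chrom:
            raise RegionError("gap undefined across chromosomes")
        return max(0, other.start - self.end, self.start - other.end)


@dataclass
class RegionSet:
    """A named collection of intervals playing one role (hotspot or coldspot)."""

    role: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    genome_id: str = ""

    def __post_init__(self) -> None:
        ids = [iv.id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            raise RegionError(f"duplicate interval ids in {self.role} set")
        # coldspot non-overlap is checked by validate_coldspots, which must be
        # able to report violations rather than fail to construct its input

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def mean_length(self) -> float:
        if not self.intervals:
            raise RegionError("mean length of an empty region set")
        return self.total_length() / len(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def _first_overlap(intervals: Sequence[GenomicInterval]) -> str | None:
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            return f"{a.id} overlaps {b.id}"
    return None


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a chromosome-length table (``.fai`` or two-column name/length TSV)."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise RegionError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise RegionError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return sizes


def read_bed(
    path: str | Path,
    genome: Mapping[str, int],
    role: str = HOTSPOT,
    genome_id: str = "",
) -> RegionSet:
    """Read a 3+ column BED file into a :class:`RegionSet`.

    Coordinates are taken as BED-native 0-based half-open.  When a fourth
    column is present it is used as the interval id; otherwise ids are
    ``chrom:start-end``.
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise RegionError(f"{path}:{lineno}: expected >=3 BED columns, got {len(parts)}")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise RegionError(f"{path}:{lineno}: non-integer coordinates") from exc
        if chrom not in genome:
            raise RegionError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end > genome[chrom]:
            raise RegionError(
                f"{path}:{lineno}: interval end {end} beyond {chrom} length {genome[chrom]}"
            )
        name = parts[3] if len(parts) >= 4 and parts[3] not in (".", "") else ""
        try:
            intervals.append(GenomicInterval(chrom, start, end, name))
        except RegionError as exc:
            raise RegionError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(role=role, intervals=intervals, genome_id=genome_id)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


def _genome_mapping(genome) -> Mapping[str, str]:
    """Accept a chrom->sequence mapping, a FASTA path, or a pyfaidx.Fasta."""
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        return Fasta(str(genome), as_raw=True, sequence_always_upper=False)
    return genome


def extract_sequences(regions: RegionSet, genome) -> dict[str, str]:
    """Slice interval sequences from the genome, uppercased with non-ACGT as N."""
    src = _genome_mapping(genome)
    out: dict[str, str] = {}
    for iv in regions:
        try:
            chrom_seq = src[iv.chrom]
        except KeyError as exc:
            raise RegionError(f"chromosome {iv.chrom!r} not in genome") from exc
        raw = str(chrom_seq[iv.start : iv.end])
        if len(raw) != iv.length:
            raise RegionError(
                f"{iv.id}: extracted {len(raw)} bp, expected {iv.length} (interval out of bounds?)"
            )
        out[iv.id] = raw.encode("ascii").translate(_DNA_CLEAN).decode("ascii")
    return out


# ---------------------------------------------------------------------------
# Coldspot sampling


def _merge(zones: list[tuple[int, int]]) -> tuple[list[int], list[int]]:
    zones.sort()
    starts: list[int] = []
    ends: list[int] = []
    for s, e in zones:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return starts, ends


def _hits_zone(starts: list[int], ends: list[int], s: int, e: int) -> bool:
    """True if [s, e) intersects any merged zone."""
    i = bisect.bisect_right(starts, s)
    if i > 0 and ends[i - 1] > s:
        return True
    return i < len(starts) and starts[i] < e


def sample_coldspots(
    hotspots: RegionSet,
    genome: Mapping[str, int],
    min_distance: int = 50_000,
    seed: int = 0,
    max_attempts: int = 10_000,
    sequences: Mapping[str, str] | None = None,
    max_n_fraction: float = 0.5,
) -> RegionSet:
    """Sample one coldspot per hotspot by uniform rejection sampling.

    Each coldspot lies on its hotspot's chromosome with identical length,
    keeps an end-to-end gap of at least ``min_distance`` bp from every
    hotspot, and coldspots never overlap each other.  Hotspots are processed
    in descending length order (long intervals are hardest to place).  When
    ``sequences`` (chrom -> DNA) is given, candidates whose N fraction
    exceeds ``max_n_fraction`` are rejected, since scan hit counts in
    assembly gaps are meaningless.
    """
    rng = np.random.default_rng(seed)
    # exclusion zones: hotspots widened by min_distance on both sides
    excl: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in hotspots.by_chrom().items():
        zones = [(max(0, iv.start - min_distance), iv.end + min_distance) for iv in ivs]
        excl[chrom] = _merge(zones)
    placed_starts: dict[str, list[int]] = {c: [] for c in excl}
    placed_ends: dict[str, list[int]] = {c: [] for c in excl}

    order = sorted(hotspots, key=lambda iv: (-iv.length, iv.chrom, iv.start))
    out: list[GenomicInterval] = []
    for hs in order:
        chrom_len = genome[hs.chrom]
        hi = chrom_len - hs.length
        if hi < 0:
            raise RegionError(f"chromosome {hs.chrom} shorter than hotspot {hs.id}")
        zs, ze = excl[hs.chrom]
        ps, pe = placed_starts[hs.chrom], placed_ends[hs.chrom]
        for _ in range(max_attempts):
            s = int(rng.integers(0, hi + 1))
            e = s + hs.length
            if _hits_zone(zs, ze, s, e):
                continue
            # overlap with already-placed coldspots (touching allowed)
            i = bisect.bisect_right(ps, s)
            if i > 0 and pe[i - 1] > s:
                continue
            if i < len(ps) and ps[i] < e:
                continue
            if sequences is not None:
                frac_n = sequences[hs.chrom][s:e].upper().count("N") / hs.length
                if frac_n > max_n_fraction:
                    continue
            bisect.insort(ps, s)
            pe.insert(bisect.bisect_left(ps, s), e)
            out.append(GenomicInterval(hs.chrom, s, e, f"cold_{hs.id}"))
            break
        else:
            raise RegionError(
                f"could not place a {hs.length}-bp coldspot on {hs.chrom} "
                f"within {max_attempts} attempts"
            )
    return RegionSet(role=COLDSPOT, intervals=out, genome_id=hotspots.genome_id)


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    violation: str | None = None

    def __bool__(self) -> bool:
        return self.passed


def validate_coldspots(
    coldspots: RegionSet,
    hotspots: RegionSet,
    min_distance: int = 50_000,
) -> ValidationReport:
    """Check the three coldspot constraints; report the first violation found.

    Pass requires (i) the per-chromosome length multiset of coldspots to
    match the hotspots', (ii) every coldspot at least ``min_distance`` bp
    from every hotspot, (iii) no two coldspots overlapping.
    """
    hot_by = hotspots.by_chrom()
    cold_by = coldspots.by_chrom()
    for chrom in set(hot_by) | set(cold_by):
        hl = sorted(iv.length for iv in hot_by.get(chrom, []))
        cl = sorted(iv.length for iv in cold_by.get(chrom, []))
        if hl != cl:
            return ValidationReport(False, f"length multiset mismatch on {chrom}")
    for chrom, ivs in cold_by.items():
        zs, ze = _merge(
            [(max(0, h.start - min_distance), h.end + min_distance) for h in hot_by.get(chrom, [])]
        )
        for c in ivs:
            if _hits_zone(zs, ze, c.start, c.end):
                return ValidationReport(False, f"{c.id} within {min_distance} bp of a hotspot")
    viol = _first_overlap(coldspots.intervals)
    if viol is not None:
        return ValidationReport(False, f"coldspot overlap: {viol}")
    return ValidationReport(True)
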