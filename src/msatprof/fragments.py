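"""Peak-table data model and normal-tissue genotyping.

Fragment-analysis software (capillary electrophoresis) exports, per sample,
locus and tissue, a list of sized fluorescence peaks.  This module reads
those tables, merges sub-bp sizing jitter into integer-bp allele bins, and
genotypes the matched normal tissue after removing noise and PCR stutter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Peak",
    "PeakSet",
    "GenotypeCall",
    "CallingParams",
    "read_peak_table",
    "write_peak_table",
    "bin_peaks",
    "call_genotype",
]

PEAK_COLUMNS = ("sample_id", "locus_id", "tissue", "size_bp", "height")

_TISSUE_ALIASES = {
    "NORMAL": "NORMAL",
    "N": "NORMAL",
    "TUMOR": "TUMOR",
    "TUMOUR": "TUMOR",
    "T": "TUMOR",
}


@dataclass(frozen=True)
class Peak:
    """A sized fluorescence peak: fragment length (bp) and height (a.u.)."""

    size_bp: float
    height: float

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError(f"size_bp must be positive, got {self.size_bp}")
        if self.height < 0:
            raise ValueError(f"height must be non-negative, got {self.height}")


@dataclass
class PeakSet:
    """All peaks for one (sample, locus, tissue) electropherogram."""

    sample_id: str
    locus_id: str
    tissue: str  # NORMAL or TUMOR
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tissue not in ("NORMAL", "TUMOR"):
            raise ValueError(f"tissue must be NORMAL or TUMOR, got {self.tissue!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)

    def height_at(self, size: float, tol: float = 0.5) -> float:
        """Height of the peak at a binned size (0.0 if absent)."""
        for p in self.peaks:
            if abs(p.size_bp - size) <= tol:
                return p.height
        return 0.0


@dataclass(frozen=True)
class GenotypeCall:
    """Germline genotype of a locus from the normal electropherogram.

    ``informative`` (== heterozygous) is the precondition for assessing
    loss of heterozygosity in the matched tumor.
    """

    alleles: tuple[int, ...]
    allele_heights: tuple[float, ...]
    heterozygous: bool
    informative: bool
    qc: str  # PASS, LOW_SIGNAL or FAILED

    def __post_init__(self) -> None:
        if self.qc == "PASS":
            if not 1 <= len(self.alleles) <= 2:
                raise ValueError("a PASS genotype has 1 or 2 alleles")
            if self.heterozygous != (len(self.alleles) == 2):
                raise ValueError("heterozygous iff two alleles")
            if self.informative != self.heterozygous:
                raise ValueError("informative iff heterozygous")


@dataclass(frozen=True)
class CallingParams:
    """Thresholds for genotyping and somatic-event calling.

    min_rel_height
        Peaks below this fraction of the tallest peak are noise (0.10).
    stutter_ratio
        Max height, relative to its anchor allele, for a peak one repeat
        unit shorter to be dismissed as PCR stutter (0.15).
    loh_loss_threshold
        Fractional signal loss of one heterozygous allele required to call
        LOH; losses strictly greater than 35% (retained fraction < 0.65)
        count.
    size_bin_bp
        Bin width for allele-size equality (1.0 bp): sizing software
        reports sub-bp fragment sizes, alleles live on an integer lattice.
    """

    min_rel_height: float = 0.10
    stutter_ratio: float = 0.15
    loh_loss_threshold: float = 0.35
    size_bin_bp: float = 1.0

    def __post_init__(self) -> None:
        for name in ("min_rel_height", "stutter_ratio", "loh_loss_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.size_bin_bp <= 0:
            raise ValueError("size_bin_bp must be positive")


def bin_peaks(peaks: Sequence[Peak], size_bin_bp: float = 1.0) -> list[Peak]:
    """Merge peaks that round into the same size bin.

    Colliding peaks are merged by summing heights; the merged size is the
    height-weighted mean rounded to the nearest integer bp.  Output is
    sorted by size.
    """
    if size_bin_bp <= 0:
        raise ValueError("size_bin_bp must be positive")
    bins: dict[int, list[Peak]] = {}
    for p in peaks:
        bins.setdefault(round(p.size_bp / size_bin_bp), []).append(p)
    merged = []
    for group in bins.values():
        total = sum(p.height for p in group)
        if total > 0:
            size = round(sum(p.size_bp * p.height for p in group) / total)
        else:
            size = round(group[0].size_bp)
        merged.append(Peak(size_bp=float(size), height=total))
    return sorted(merged, key=lambda p: p.size_bp)


def filter_noise(peaks: Sequence[Peak], min_rel_height: float) -> list[Peak]:
    """Drop peaks strictly below ``min_rel_height`` x the tallest peak."""
    if not peaks:
        return []
    floor = min_rel_height * max(p.height for p in peaks)
    return [p for p in peaks if p.height >= floor]


def filter_stutter(
    peaks: Sequence[Peak],
    motif_length: int,
    stutter_ratio: float,
    extra_anchors: Sequence[Peak] = (),
) -> list[Peak]:
    """Remove minus-one-repeat stutter peaks.

    A peak is stutter when a strictly taller anchor peak sits exactly one
    repeat unit above it and the candidate's relative height is at most
    ``stutter_ratio``.  Anchors are the noise-retained peaks themselves
    (single pass: a peak removed as stutter still anchors deeper stutter)
    plus any ``extra_anchors`` — used on the tumor side where the normal
    alleles anchor stutter of a diminished allele.
    """
    anchors = {round(p.size_bp): p.height for p in peaks}
    for p in extra_anchors:
        size = round(p.size_bp)
        anchors[size] = max(anchors.get(size, 0.0), p.height)
    kept = []
    for p in peaks:
        anchor_h = anchors.get(round(p.size_bp) + motif_length)
        if (
            anchor_h is not None
            and anchor_h > p.height
            and p.height <= stutter_ratio * anchor_h
        ):
            continue
        kept.append(p)
    return kept


def call_genotype(normal: PeakSet, locus, params: CallingParams) -> GenotypeCall:
    """Genotype a locus from its normal-tissue peaks.

    Pipeline: noise filter, minus-one-repeat stutter filter, then the
    surviving peaks are the alleles.  Zero survivors give qc LOW_SIGNAL,
    more than two give qc FAILED (ambiguous electropherogram, treated as
    not assayed downstream).
    """
    if normal.tissue != "NORMAL":
        raise ValueError(f"call_genotype expects NORMAL tissue, got {normal.tissue}")
    peaks = bin_peaks(normal.peaks, params.size_bin_bp)
    peaks = filter_noise(peaks, params.min_rel_height)
    peaks = filter_stutter(peaks, locus.motif_length, params.stutter_ratio)
    if not peaks:
        return GenotypeCall((), (), False, False, "LOW_SIGNAL")
    if len(peaks) > 2:
        return GenotypeCall((), (), False, False, "FAILED")
    alleles = tuple(int(p.size_bp) for p in peaks)
    heights = tuple(p.height for p in peaks)
    het = len(alleles) == 2
    return GenotypeCall(alleles, heights, het, het, "PASS")


def read_peak_table(path: str | Path) -> list[PeakSet]:
    """Read a peak table TSV into grouped, binned-ready :class:`PeakSet`s.

    Expected header: ``sample_id locus_id tissue size_bp height``; one row
    per peak; tissue accepts the aliases N/T/NORMAL/TUMOR (any case).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    header = tuple(lines[start].rstrip("\n").split("\t"))
    if header != PEAK_COLUMNS:
        raise ValueError(f"{path}: bad header {header!r}, expected {list(PEAK_COLUMNS)}")
    groups: dict[tuple[str, str, str], list[Peak]] = {}
    for lineno, raw in enumerate(lines[start + 1 :], start=start + 2):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields")
        sample_id, locus_id, tissue_tok, size_tok, height_tok = fields
        tissue = _TISSUE_ALIASES.get(tissue_tok.strip().upper())
        if tissue is None:
            raise ValueError(f"{path}:{lineno}: unknown tissue token {tissue_tok!r}")
        try:
            size = float(size_tok)
            height = float(height_tok)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparseable size/height") from None
        try:
            peak = Peak(size_bp=size, height=height)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        groups.setdefault((sample_id, locus_id, tissue), []).append(peak)
    return [
        PeakSet(sample_id=s, locus_id=l, tissue=t, peaks=pk)
        for (s, l, t), pk in groups.items()
    ]


def write_peak_table(
    peaksets: Iterable[PeakSet], path: str | Path, header_comment: str | None = None
) -> None:
    """Write peak sets in the TSV dialect read by :func:`read_peak_table`."""
    with Path(path).open("w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(PEAK_COLUMNS) + "\n")
        for ps in peaksets:
            for p in ps.peaks:
                fh.write(
                    f"{ps.sample_id}\t{ps.locus_id}\t{ps.tissue}\t"
                    f"{p.size_bp:.2f}\t{p.height:.1f}\n"
                )
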