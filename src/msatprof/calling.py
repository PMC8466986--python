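"""Per-locus tumor-vs-normal MSI and LOH calling.

Two somatic event types are distinguished on a capillary electropherogram:

* **MSI** — replication slippage creating de novo alleles: tumor peaks at
  binned sizes absent from the normal genotype, including pre-existing
  alleles slipped by whole repeat units.
* **LOH** — allelic imbalance at a locus heterozygous in the normal: a
  partial (>35%) to complete loss of one allele's relative signal,
  quantified by the ratio of tumor to normal allelic ratios.

MSI takes precedence: one event per locus-sample pair, and allelic ratios
are unreliable once novel alleles are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .catalog import LocusDef
from .fragments import (
    CallingParams,
    GenotypeCall,
    Peak,
    PeakSet,
    bin_peaks,
    call_genotype,
    filter_noise,
    filter_stutter,
)

__all__ = [
    "LocusMutationCall",
    "call_msi",
    "call_loh",
    "call_locus",
    "call_cohort",
    "write_call_table",
    "read_call_table",
]

#: LocusMutationCall.status values.
STATUSES = ("MSI", "LOH", "STABLE", "NON_INFORMATIVE", "FAILED")

#: LocusMutationCall.loh values.
LOH_VERDICTS = ("TRUE", "FALSE", "NON_INFORMATIVE")


@dataclass
class LocusMutationCall:
    """The per-locus tumor-vs-normal verdict with its evidence trail."""

    sample_id: str
    locus_id: str
    msi: bool
    loh: str  # TRUE / FALSE / NON_INFORMATIVE
    status: str  # MSI / LOH / STABLE / NON_INFORMATIVE / FAILED
    novel_alleles: list[int] = field(default_factory=list)
    imbalance_ratio: Optional[float] = None
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.loh not in LOH_VERDICTS:
            raise ValueError(f"unknown loh verdict {self.loh!r}")
        if self.msi != (self.status == "MSI"):
            raise ValueError("status == MSI iff msi is true")
        if self.status == "LOH" and (self.msi or self.loh != "TRUE"):
            raise ValueError("status LOH requires msi false and loh TRUE")


def _filtered_tumor_peaks(
    tumor: PeakSet,
    normal_gt: GenotypeCall,
    locus: LocusDef,
    params: CallingParams,
) -> list[Peak]:
    """Noise- and stutter-filter the tumor peaks.

    Stutter anchors are the retained tumor peaks plus the tumor signal at
    the normal allele positions, so stutter of an LOH-diminished allele is
    still recognized and cannot masquerade as a novel allele.
    """
    peaks = bin_peaks(tumor.peaks, params.size_bin_bp)
    retained = filter_noise(peaks, params.min_rel_height)
    normal_anchor_sizes = set(normal_gt.alleles)
    extra = [p for p in peaks if round(p.size_bp) in normal_anchor_sizes]
    return filter_stutter(retained, locus.motif_length, params.stutter_ratio, extra)


def call_msi(
    normal_gt: GenotypeCall,
    tumor: PeakSet,
    locus: LocusDef,
    params: CallingParams,
) -> tuple[bool, list[int]]:
    """Detect de novo tumor alleles relative to the normal genotype.

    Any noise/stutter-surviving tumor peak whose binned size is not a
    normal allele is a novel allele; one or more novel alleles make the
    locus MSI.  A pre-existing allele slipped by whole repeat units is
    automatically captured as a novel size.  No cap is placed on the shift
    distance.
    """
    if normal_gt.qc != "PASS":
        raise ValueError("call_msi requires a PASS normal genotype")
    if tumor.tissue != "TUMOR":
        raise ValueError(f"call_msi expects TUMOR tissue, got {tumor.tissue}")
    kept = _filtered_tumor_peaks(tumor, normal_gt, locus, params)
    normal_sizes = set(normal_gt.alleles)
    novel = sorted(int(p.size_bp) for p in kept if round(p.size_bp) not in normal_sizes)
    return (len(novel) >= 1, novel)


def call_loh(
    normal_gt: GenotypeCall,
    tumor: PeakSet,
    params: CallingParams,
) -> tuple[str, Optional[float]]:
    """Assess loss of heterozygosity from allelic imbalance.

    With normal allele heights (n1, n2) and tumor heights (t1, t2) at the
    same binned sizes (missing tumor allele = height 0), the imbalance
    ratio is R = (t1/t2)/(n1/n2) and the retained fraction of the
    diminished allele is r = min(R, 1/R).  LOH is called when r < 0.65,
    strictly — i.e. strictly more than 35% of one allele's relative signal
    is lost — including complete loss (r = 0).  Returns the folded ratio r.

    Homozygous-normal loci are non-informative; so is a tumor with no
    retained signal at either allele position (amplification failure or
    total allelic dropout cannot be told apart).
    """
    if not normal_gt.heterozygous:
        return ("NON_INFORMATIVE", None)
    peaks = bin_peaks(tumor.peaks, params.size_bin_bp)
    retained = filter_noise(peaks, params.min_rel_height)
    if not retained:
        return ("NON_INFORMATIVE", None)
    a1, a2 = normal_gt.alleles
    n1, n2 = normal_gt.allele_heights
    tset = PeakSet(tumor.sample_id, tumor.locus_id, "TUMOR", peaks=retained)
    t1 = tset.height_at(a1)
    t2 = tset.height_at(a2)
    if t1 == 0.0 and t2 == 0.0:
        return ("NON_INFORMATIVE", None)
    if t1 == 0.0 or t2 == 0.0:
        r = 0.0
    else:
        # both orientations computed from height products directly, so the
        # folded ratio is exactly symmetric and boundary cases like a flat
        # 35% loss do not drift across the threshold by a rounding ulp
        r = min((t1 * n2) / (t2 * n1), (t2 * n1) / (t1 * n2))
    loh = "TRUE" if r < 1.0 - params.loh_loss_threshold else "FALSE"
    return (loh, r)


def call_locus(
    normal: PeakSet,
    tumor: PeakSet,
    locus: LocusDef,
    params: CallingParams | None = None,
) -> LocusMutationCall:
    """Full per-locus verdict for one tumor-normal pair.

    Genotypes the normal, then applies MSI detection; MSI precedence makes
    MSI and LOH mutually exclusive per locus-sample event.  Failed normal
    genotyping yields status FAILED (locus not assayed).
    """
    params = params or CallingParams()
    if normal.sample_id != tumor.sample_id or normal.locus_id != tumor.locus_id:
        raise ValueError(
            f"mismatched pair: {normal.sample_id}/{normal.locus_id} vs "
            f"{tumor.sample_id}/{tumor.locus_id}"
        )
    if normal.tissue != "NORMAL" or tumor.tissue != "TUMOR":
        raise ValueError("call_locus expects a (NORMAL, TUMOR) pair")

    gt = call_genotype(normal, locus, params)
    if gt.qc != "PASS":
        return LocusMutationCall(
            sample_id=normal.sample_id,
            locus_id=normal.locus_id,
            msi=False,
            loh="NON_INFORMATIVE",
            status="FAILED",
            evidence=f"normal genotyping {gt.qc}",
        )

    msi, novel = call_msi(gt, tumor, locus, params)
    if msi:
        return LocusMutationCall(
            sample_id=normal.sample_id,
            locus_id=normal.locus_id,
            msi=True,
            loh="NON_INFORMATIVE",
            status="MSI",
            novel_alleles=novel,
            evidence=(
                f"novel alleles {novel} vs normal {list(gt.alleles)}; "
                "MSI precedence: allelic ratio not assessed"
            ),
        )

    loh, ratio = call_loh(gt, tumor, params)
    if loh == "TRUE":
        status = "LOH"
        evidence = f"retained fraction {ratio:.3f} < {1 - params.loh_loss_threshold:.2f}"
    elif loh == "FALSE":
        status = "STABLE"
        evidence = f"retained fraction {ratio:.3f}, no allelic loss > {params.loh_loss_threshold:.0%}"
    else:
        # Homozygous-normal loci (and tumors with no retained allele
        # signal) cannot be assessed for LOH; they still counted for MSI.
        status = "NON_INFORMATIVE"
        if gt.heterozygous:
            evidence = "no retained tumor signal at either allele"
        else:
            evidence = "homozygous normal: LOH not assessable, no novel alleles"
    return LocusMutationCall(
        sample_id=normal.sample_id,
        locus_id=normal.locus_id,
        msi=False,
        loh=loh,
        status=status,
        imbalance_ratio=ratio,
        evidence=evidence,
    )


def call_cohort(
    peaksets: Iterable[PeakSet],
    catalog,
    params: CallingParams | None = None,
) -> list[LocusMutationCall]:
    """Pair normal/tumor peak sets by (sample, locus) and call every pair.

    Pairs missing one tissue are skipped; loci absent from the catalog
    raise.
    """
    params = params or CallingParams()
    by_key: dict[tuple[str, str], dict[str, PeakSet]] = {}
    for ps in peaksets:
        if ps.locus_id not in catalog:
            raise KeyError(f"locus {ps.locus_id!r} not in catalog")
        by_key.setdefault((ps.sample_id, ps.locus_id), {})[ps.tissue] = ps
    calls = []
    for (sample_id, locus_id), pair in sorted(by_key.items()):
        if "NORMAL" not in pair or "TUMOR" not in pair:
            continue
        calls.append(
            call_locus(pair["NORMAL"], pair["TUMOR"], catalog[locus_id], params)
        )
    return calls


CALL_COLUMNS = (
    "sample_id",
    "locus_id",
    "status",
    "msi",
    "loh",
    "imbalance_ratio",
    "novel_alleles",
    "evidence",
)


def write_call_table(
    calls: Iterable[LocusMutationCall], path: str | Path, header_comment: str | None = None
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            ratio = "" if c.imbalance_ratio is None else f"{c.imbalance_ratio:.4f}"
            novel = ",".join(str(a) for a in c.novel_alleles)
            fh.write(
                f"{c.sample_id}\t{c.locus_id}\t{c.status}\t"
                f"{int(c.msi)}\t{c.loh}\t{ratio}\t{novel}\t{c.evidence}\n"
            )


def read_call_table(path: str | Path) -> list[LocusMutationCall]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [l for l in lines if l.strip() and not l.startswith("#")]
    header = tuple(rows[0].split("\t"))
    if header != CALL_COLUMNS:
        raise ValueError(f"{path}: bad header {header!r}")
    calls = []
    for raw in rows[1:]:
        f = raw.split("\t")
        calls.append(
            LocusMutationCall(
                sample_id=f[0],
                locus_id=f[1],
                status=f[2],
                msi=bool(int(f[3])),
                loh=f[4],
                imbalance_ratio=float(f[5]) if f[5] else None,
                novel_alleles=[int(a) for a in f[6].split(",") if a],
                evidence=f[7] if len(f) > 7 else "",
            )
        )
    return calls
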