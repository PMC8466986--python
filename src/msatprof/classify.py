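"""Patient-level classification from per-locus calls.

Three marker-based classes are derived per patient:

* **B5 MSI class** — MSI-H (>= 2 of the five Bethesda loci unstable),
  MSI-L (exactly 1), MSS (0).
* **B5 LOH class** — the exact analog on LOH calls: LOH-H (>= 2), LOH-L
  (1), non-LOH (0).
* **MMR class** — MMR-deficient when any microsatellite locus inside an
  MMR gene (MLH1/MSH2/MSH6/PMS2) shows MSI, else MMR-proficient.

Failed loci shrink the effective panel instead of counting as stable; a
patient with fewer than two assayable Bethesda loci gets a missing class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .calling import LocusMutationCall
from .catalog import LocusCatalog

__all__ = [
    "PatientProfile",
    "classify_b5_msi",
    "classify_b5_loh",
    "classify_mmr",
    "build_profile",
    "build_profiles",
    "write_profile_table",
]

B5_MSI_CLASSES = ("MSI_H", "MSI_L", "MSS")
B5_LOH_CLASSES = ("LOH_H", "LOH_L", "NON_LOH")
MMR_CLASSES = ("MMR_D", "MMR_P")

#: Minimum number of assayable Bethesda loci to assign a panel class.
MIN_ASSAYABLE_B5 = 2


@dataclass
class PatientProfile:
    """All locus calls for one patient plus panel classes and tallies.

    Event tallies (``n_msi_events`` etc.) run over tumor-related-gene loci
    only; the Bethesda markers contribute solely to the panel classes.
    """

    patient_id: str
    calls: dict[str, LocusMutationCall] = field(default_factory=dict)
    b5_msi_class: Optional[str] = None
    b5_loh_class: Optional[str] = None
    mmr_class: Optional[str] = None
    n_msi_events: int = 0
    n_loh_events: int = 0
    n_genes_with_msi: int = 0
    n_genes_with_loh: int = 0


def _assayable(calls: Iterable[LocusMutationCall]) -> list[LocusMutationCall]:
    return [c for c in calls if c.status != "FAILED"]


def classify_b5_msi(calls: Iterable[LocusMutationCall]) -> Optional[str]:
    """Bethesda MSI class from the patient's B5 locus calls.

    k = number of assayable B5 loci with status MSI: k >= 2 -> MSI_H,
    k == 1 -> MSI_L, k == 0 -> MSS.  Returns None (missing) when fewer
    than two B5 loci are assayable.
    """
    usable = _assayable(calls)
    if len(usable) < MIN_ASSAYABLE_B5:
        return None
    k = sum(c.status == "MSI" for c in usable)
    return "MSI_H" if k >= 2 else ("MSI_L" if k == 1 else "MSS")


def classify_b5_loh(calls: Iterable[LocusMutationCall]) -> Optional[str]:
    """Bethesda LOH class: at least two B5 loci with LOH -> LOH_H, one ->
    LOH_L, none -> NON_LOH; None when fewer than two loci are assayable."""
    usable = _assayable(calls)
    if len(usable) < MIN_ASSAYABLE_B5:
        return None
    k = sum(c.status == "LOH" for c in usable)
    return "LOH_H" if k >= 2 else ("LOH_L" if k == 1 else "NON_LOH")


def classify_mmr(
    calls: Mapping[str, LocusMutationCall], catalog: LocusCatalog
) -> Optional[str]:
    """MMR_D iff any MSI call at a locus whose gene_class is MMR.

    The grouping is marker-based (microsatellite status of MMR-gene loci),
    not immunohistochemical.  None when the catalog has no MMR loci.
    """
    mmr_ids = set(catalog.mmr_locus_ids)
    if not mmr_ids:
        return None
    for locus_id, call in calls.items():
        if locus_id in mmr_ids and call.status == "MSI":
            return "MMR_D"
    return "MMR_P"


def build_profile(
    patient_id: str,
    calls: Iterable[LocusMutationCall],
    catalog: LocusCatalog,
) -> PatientProfile:
    """Assemble one patient's profile from their locus calls."""
    call_map: dict[str, LocusMutationCall] = {}
    for c in calls:
        if c.sample_id != patient_id:
            raise ValueError(f"call for {c.sample_id!r} passed to patient {patient_id!r}")
        if c.locus_id in call_map:
            raise ValueError(f"duplicate call for locus {c.locus_id!r}")
        if c.locus_id not in catalog:
            raise KeyError(f"locus {c.locus_id!r} not in catalog")
        call_map[c.locus_id] = c

    b5_ids = set(catalog.b5_ids)
    b5_calls = [c for lid, c in call_map.items() if lid in b5_ids]
    gene_calls = {lid: c for lid, c in call_map.items() if lid not in b5_ids}

    msi_genes = {
        catalog[lid].gene for lid, c in gene_calls.items() if c.status == "MSI"
    }
    loh_genes = {
        catalog[lid].gene for lid, c in gene_calls.items() if c.status == "LOH"
    }
    return PatientProfile(
        patient_id=patient_id,
        calls=call_map,
        b5_msi_class=classify_b5_msi(b5_calls),
        b5_loh_class=classify_b5_loh(b5_calls),
        mmr_class=classify_mmr(call_map, catalog),
        n_msi_events=sum(c.status == "MSI" for c in gene_calls.values()),
        n_loh_events=sum(c.status == "LOH" for c in gene_calls.values()),
        n_genes_with_msi=len(msi_genes),
        n_genes_with_loh=len(loh_genes),
    )


def build_profiles(
    calls: Iterable[LocusMutationCall], catalog: LocusCatalog
) -> list[PatientProfile]:
    """Group a flat call list by sample and build every patient profile."""
    by_patient: dict[str, list[LocusMutationCall]] = {}
    for c in calls:
        by_patient.setdefault(c.sample_id, []).append(c)
    return [
        build_profile(pid, pcalls, catalog)
        for pid, pcalls in sorted(by_patient.items())
    ]


PROFILE_COLUMNS = (
    "patient_id",
    "b5_msi_class",
    "b5_loh_class",
    "mmr_class",
    "n_msi_events",
    "n_loh_events",
    "n_genes_with_msi",
    "n_genes_with_loh",
)


def write_profile_table(
    profiles: Iterable[PatientProfile], path: str | Path, header_comment: str | None = None
) -> None:
    """One CSV row per patient with classes and tallies (missing class = empty)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(",".join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            fh.write(
                ",".join(
                    [
                        p.patient_id,
                        p.b5_msi_class or "",
                        p.b5_loh_class or "",
                        p.mmr_class or "",
                        str(p.n_msi_events),
                        str(p.n_loh_events),
                        str(p.n_genes_with_msi),
                        str(p.n_genes_with_loh),
                    ]
                )
                + "\n"
            )
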