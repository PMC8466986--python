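"""Cohort-level mutation-profile statistics.

Event counts per locus roll up to genes, gene classes, genomic regions and
repeat-motif groups; frequencies divide event counts by (number of loci in
the group x number of tumor samples), the convention used throughout this
kind of marker-panel profiling.  Denominators always use the full sample
count, matching the convention that every assayed tumor contributes one
trial per locus; an informative-pair denominator mode exists as an option
for LOH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .catalog import LocusCatalog, loci_in_group
from .classify import PatientProfile

__all__ = [
    "EventCounts",
    "GroupFrequency",
    "SpectrumSummary",
    "tally_events",
    "locus_occurrence_rate",
    "group_frequency",
    "overall_rate",
    "pattern_partition",
    "spectrum_summary",
    "compare_group_frequencies",
]

EVENT_TYPES = ("MSI", "LOH")


@dataclass
class EventCounts:
    """Per-locus somatic event counts over a cohort.

    ``counts[locus_id][event_type]`` is the number of samples with that
    event at that locus.  ``n_samples`` is the cohort size and ``n_loci``
    the number of tumor-related-gene loci (B5 markers are tallied in
    ``counts`` too but excluded from gene-locus rollups).
    """

    counts: dict[str, dict[str, int]]
    n_samples: int
    n_loci: int

    def __post_init__(self) -> None:
        for locus_id, by_type in self.counts.items():
            for etype, k in by_type.items():
                if etype not in EVENT_TYPES:
                    raise ValueError(f"unknown event type {etype!r}")
                if not 0 <= k <= self.n_samples:
                    raise ValueError(
                        f"{locus_id}/{etype}: count {k} outside [0, {self.n_samples}]"
                    )

    def count(self, locus_id: str, event_type: str) -> int:
        return self.counts.get(locus_id, {}).get(event_type, 0)

    def group_total(self, locus_ids: Iterable[str], event_type: str) -> int:
        return sum(self.count(lid, event_type) for lid in locus_ids)


@dataclass
class GroupFrequency:
    """An event frequency over a locus group: n_events / (n_loci x n_samples)."""

    axis: str
    key: object
    event_type: str
    n_events: int
    n_loci_in_group: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_loci_in_group <= 0 or self.n_samples <= 0:
            raise ZeroDivisionError(
                f"empty group or cohort for {self.axis}={self.key!r}"
            )
        if not 0 <= self.frequency <= 1:
            raise ValueError("frequency outside [0, 1]")

    @property
    def n_trials(self) -> int:
        return self.n_loci_in_group * self.n_samples

    @property
    def frequency(self) -> float:
        return self.n_events / self.n_trials


@dataclass
class SpectrumSummary:
    """Per-patient event spectrum for one event type.

    ``events_per_patient`` maps patient id -> event count (over
    tumor-related-gene loci); the mean runs over *affected* patients
    (>= 1 event) only, e.g. 217 events in 48 affected patients = 4.52.
    """

    event_type: str
    events_per_patient: dict[str, int]
    genes_per_patient: dict[str, int]
    n_patients: int
    n_affected: int
    total_events: int
    mean_events_per_affected: Optional[float]
    fraction_patients_affected: float
    fraction_loci_affected: float
    event_count_distribution: dict[int, int] = field(default_factory=dict)


def tally_events(
    profiles: Iterable[PatientProfile], catalog: LocusCatalog
) -> EventCounts:
    """Count MSI and LOH events per locus over all patient profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("tally_events requires at least one profile")
    counts: dict[str, dict[str, int]] = {
        lid: {"MSI": 0, "LOH": 0} for lid in catalog.locus_ids
    }
    for prof in profiles:
        for locus_id, call in prof.calls.items():
            if locus_id not in counts:
                raise KeyError(f"locus {locus_id!r} not in catalog")
            if call.status in EVENT_TYPES:
                counts[locus_id][call.status] += 1
    return EventCounts(
        counts=counts,
        n_samples=len(profiles),
        n_loci=len(catalog.gene_locus_ids),
    )


def locus_occurrence_rate(
    counts: EventCounts, locus_id: str, event_type: str
) -> float:
    """Fraction of samples with the event at one locus (count / n_samples)."""
    if counts.n_samples == 0:
        raise ZeroDivisionError("empty cohort")
    if locus_id not in counts.counts:
        raise KeyError(f"locus {locus_id!r} not tallied")
    return counts.count(locus_id, event_type) / counts.n_samples


def group_frequency(
    counts: EventCounts,
    catalog: LocusCatalog,
    axis: str,
    key,
    event_type: str,
) -> GroupFrequency:
    """Event frequency within a catalog group.

    The denominator's locus count is the number of catalog loci in the
    group (e.g. all 26 TS loci), not the number of loci that showed an
    event.
    """
    locus_ids = loci_in_group(catalog, axis, key)
    return GroupFrequency(
        axis=axis,
        key=key,
        event_type=event_type,
        n_events=counts.group_total(locus_ids, event_type),
        n_loci_in_group=len(locus_ids),
        n_samples=counts.n_samples,
    )


def overall_rate(counts: EventCounts, event_type: str, catalog: LocusCatalog | None = None) -> float:
    """Cohort-wide rate: total events / (n gene loci x n samples).

    Runs over tumor-related-gene loci only; with a catalog the gene-locus
    subset is read from it, otherwise all tallied loci count.
    """
    if counts.n_loci == 0 or counts.n_samples == 0:
        raise ZeroDivisionError("zero loci or samples")
    locus_ids = (
        catalog.gene_locus_ids if catalog is not None else list(counts.counts)
    )
    total = counts.group_total(locus_ids, event_type)
    return total / (counts.n_loci * counts.n_samples)


def pattern_partition(
    counts: EventCounts, catalog: LocusCatalog | None = None
) -> dict:
    """Partition all events into MSI vs LOH shares, with per-locus labels.

    Returns ``{"n_msi", "n_loh", "msi_share", "loh_share", "locus_labels"}``
    where a locus label is MSI_ONLY / LOH_ONLY / BOTH / NONE.  Shares are
    None when there are no events.
    """
    locus_ids = (
        catalog.gene_locus_ids if catalog is not None else list(counts.counts)
    )
    n_msi = counts.group_total(locus_ids, "MSI")
    n_loh = counts.group_total(locus_ids, "LOH")
    total = n_msi + n_loh
    labels = {}
    for lid in locus_ids:
        has_msi = counts.count(lid, "MSI") > 0
        has_loh = counts.count(lid, "LOH") > 0
        labels[lid] = (
            "BOTH"
            if has_msi and has_loh
            else "MSI_ONLY"
            if has_msi
            else "LOH_ONLY"
            if has_loh
            else "NONE"
        )
    return {
        "n_msi": n_msi,
        "n_loh": n_loh,
        "msi_share": n_msi / total if total else None,
        "loh_share": n_loh / total if total else None,
        "locus_labels": labels,
    }


def spectrum_summary(
    profiles: Iterable[PatientProfile],
    event_type: str = "MSI",
    catalog: LocusCatalog | None = None,
) -> SpectrumSummary:
    """Per-patient event spectrum for one event type.

    Affected = patients with at least one event of the given type among
    tumor-related-gene loci; the mean event count runs over affected
    patients only.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("spectrum_summary requires at least one profile")
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")

    epp: dict[str, int] = {}
    gpp: dict[str, int] = {}
    affected_loci: set[str] = set()
    universe: set[str] = set(catalog.gene_locus_ids) if catalog else set()
    b5_ids = set(catalog.b5_ids) if catalog else set()
    for prof in profiles:
        if event_type == "MSI":
            epp[prof.patient_id] = prof.n_msi_events
            gpp[prof.patient_id] = prof.n_genes_with_msi
        else:
            epp[prof.patient_id] = prof.n_loh_events
            gpp[prof.patient_id] = prof.n_genes_with_loh
        for lid, call in prof.calls.items():
            if lid in b5_ids:
                continue
            if catalog is None:
                universe.add(lid)
            if call.status == event_type:
                affected_loci.add(lid)

    total = sum(epp.values())
    affected = [pid for pid, k in epp.items() if k > 0]
    dist: dict[int, int] = {}
    for k in epp.values():
        if k > 0:
            dist[k] = dist.get(k, 0) + 1
    return SpectrumSummary(
        event_type=event_type,
        events_per_patient=epp,
        genes_per_patient=gpp,
        n_patients=len(profiles),
        n_affected=len(affected),
        total_events=total,
        mean_events_per_affected=(total / len(affected)) if affected else None,
        fraction_patients_affected=len(affected) / len(profiles),
        fraction_loci_affected=(
            len(affected_loci & universe) / len(universe) if universe else 0.0
        ),
        event_count_distribution=dict(sorted(dist.items())),
    )


def compare_group_frequencies(
    a: GroupFrequency, b: GroupFrequency
) -> tuple[Optional[float], float, str]:
    """Chi-square (or Fisher) comparison of two group event frequencies.

    Builds the 2x2 table [[events, trials - events]] per group, with
    trials = n_loci_in_group x n_samples, and applies Pearson's chi-square
    without continuity correction, or Fisher's exact test when any
    expected cell is below 5.  Returns (statistic, p, method); the
    statistic is None for Fisher.
    """
    if a.n_samples != b.n_samples:
        raise ValueError("groups must share the same cohort")
    table = [
        [a.n_events, a.n_trials - a.n_events],
        [b.n_events, b.n_trials - b.n_events],
    ]
    from .clinstats import contingency_test  # shared switch rule

    return contingency_test(table)
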