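"""Synthetic paired tumor-normal cohort generator with ground truth.

Emulates fragment-analysis peak tables for a cohort genotyped at the
bundled 66-locus panel: germline genotypes drawn on each locus's
repeat-unit lattice, minus-one-repeat stutter, multiplicative peak-height
noise and sub-bp sizing jitter; somatic MSI events (novel or shifted
alleles) and LOH events (one heterozygous allele's signal scaled down)
drawn per locus-pair with configurable probabilities; clinical covariates
drawn to typical colorectal-cohort marginals; and survival times whose
hazards depend on configurable marker effects.

MSI and LOH are generated mutually exclusively per locus pair, matching
the calling model's one-event-per-locus convention; a stress mode that
draws both on the same locus exists to probe the MSI-precedence rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import LocusCatalog, LocusDef, default_catalog
from .classify import MIN_ASSAYABLE_B5
from .fragments import Peak, PeakSet

__all__ = ["SimConfig", "SimTruth", "generate_cohort", "recovery_report"]

#: Default per-(locus, sample) MSI probability — the cohort-wide MSI rate
#: of 1.39% over 61 loci x 256 samples (217 events) this generator anchors.
DEFAULT_MSI_PROB = 0.0139

#: Default overall LOH rate over all locus-sample pairs (5.82%, i.e. 909
#: events over 61 x 256); the per-heterozygous-locus LOH probability is
#: calibrated from it.
DEFAULT_LOH_RATE = 0.0582


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Probabilities are per (patient, locus) pair.  ``loh_prob_het`` (the
    LOH probability at loci heterozygous in the normal) defaults to the
    value making the *overall* expected LOH rate across all pairs equal
    ``target_loh_rate``, i.e. target / ((1 - msi_prob) x het_rate).
    """

    seed: int
    n_patients: int = 256
    msi_prob: float = DEFAULT_MSI_PROB
    msi_prob_per_locus: dict = field(default_factory=dict)
    target_loh_rate: float = DEFAULT_LOH_RATE
    loh_prob_het: Optional[float] = None
    het_rate: float = 0.7
    stutter_ratio_gen: float = 0.10
    height_cv: float = 0.05
    size_jitter_sd: float = 0.06
    #: repeat-unit shift magnitudes for novel MSI alleles -> probability
    novel_shift_probs: tuple = ((1, 0.5), (2, 0.3), (3, 0.2))
    #: fraction of MSI events that replace (slip) an allele rather than add one
    slip_fraction: float = 0.5
    loh_retained_range: tuple = (0.0, 0.6)
    median_os_months: float = 80.0
    pfs_hazard_multiplier: float = 1.3
    #: marker -> log hazard ratio; marker is a locus id ("<locus>:MSI" /
    #: "<locus>:LOH") or "b5_msi_class" / "b5_loh_class" (H vs rest)
    marker_effects: dict = field(default_factory=dict)
    censor_range: tuple = (36.0, 120.0)
    #: stress mode: allow MSI and LOH on the same locus pair
    allow_coincident_events: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("msi_prob", "target_loh_rate", "het_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.loh_prob_het is not None and not 0 <= self.loh_prob_het <= 1:
            raise ValueError("loh_prob_het must be in [0, 1]")
        if not 0 <= self.loh_retained_range[0] <= self.loh_retained_range[1] <= 1:
            raise ValueError("loh_retained_range must be within [0, 1]")

    def effective_loh_prob_het(self) -> float:
        if self.loh_prob_het is not None:
            return self.loh_prob_het
        if self.het_rate == 0:
            return 0.0
        p = self.target_loh_rate / ((1.0 - self.msi_prob) * self.het_rate)
        if p > 1:
            raise ValueError(
                "target_loh_rate unreachable at this heterozygosity rate"
            )
        return p

    def locus_msi_prob(self, locus_id: str) -> float:
        return self.msi_prob_per_locus.get(locus_id, self.msi_prob)


@dataclass
class SimTruth:
    """Ground truth for one generated cohort.

    ``pair_truth`` has one row per (patient, locus): the true event
    (MSI/LOH/NONE), the germline alleles, and the LOH retained fraction.
    ``patient_truth`` holds per-patient B5 classes (recomputed from the
    per-locus truths with the classifier's own thresholds) and the true
    hazard multiplier.
    """

    pair_truth: pd.DataFrame
    patient_truth: pd.DataFrame

    def event(self, patient_id: str, locus_id: str) -> str:
        return self._index[(patient_id, locus_id)]

    def __post_init__(self) -> None:
        self._index = dict(
            zip(
                zip(self.pair_truth["patient_id"], self.pair_truth["locus_id"]),
                self.pair_truth["event"],
            )
        )

    def write(self, path: str | Path) -> None:
        self.pair_truth.to_csv(path, sep="\t", index=False)


def _allele_lattice(locus: LocusDef) -> np.ndarray:
    n = (locus.size_max - locus.size_min) // locus.motif_length
    return locus.size_min + locus.motif_length * np.arange(n + 1)


def _emit_peaks(
    rng: np.random.Generator,
    alleles_heights: list[tuple[int, float]],
    locus: LocusDef,
    cfg: SimConfig,
) -> list[Peak]:
    """Peaks for a set of alleles: each allele plus its stutter, with
    multiplicative height noise and sub-bp sizing jitter."""
    peaks = []
    for size, height in alleles_heights:
        h = height * math.exp(rng.normal(0.0, cfg.height_cv))
        peaks.append(
            Peak(size_bp=size + rng.normal(0.0, cfg.size_jitter_sd), height=h)
        )
        if cfg.stutter_ratio_gen > 0:
            stutter_size = size - locus.motif_length
            if stutter_size > 0:
                sh = cfg.stutter_ratio_gen * h * math.exp(
                    rng.normal(0.0, cfg.height_cv)
                )
                peaks.append(
                    Peak(
                        size_bp=stutter_size + rng.normal(0.0, cfg.size_jitter_sd),
                        height=sh,
                    )
                )
    return peaks


def _draw_novel_size(
    rng: np.random.Generator,
    anchor: int,
    forbidden: set[int],
    locus: LocusDef,
    cfg: SimConfig,
) -> int:
    """A slipped-allele size: the anchor shifted by +-1..3 repeat units,
    redrawn until it avoids the germline alleles (and stays positive)."""
    mags = [m for m, _ in cfg.novel_shift_probs]
    probs = np.array([p for _, p in cfg.novel_shift_probs], dtype=float)
    probs /= probs.sum()
    for _ in range(32):
        mag = int(rng.choice(mags, p=probs))
        sign = 1 if rng.random() < 0.5 else -1
        size = anchor + sign * mag * locus.motif_length
        if size > locus.motif_length and size not in forbidden:
            return size
    return anchor + max(mags) * locus.motif_length + locus.motif_length


def generate_cohort(
    config: SimConfig, catalog: LocusCatalog | None = None
) -> tuple[list[PeakSet], pd.DataFrame, SimTruth]:
    """Generate paired peak sets, a clinical table and the ground truth.

    Identical config + seed give identical output (one PCG64 stream,
    fixed iteration order over patients then catalog loci).
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    loh_p = config.effective_loh_prob_het()

    peaksets: list[PeakSet] = []
    pair_rows = []
    b5_ids = set(catalog.b5_ids)
    truth_msi_b5: dict[str, int] = {}
    truth_loh_b5: dict[str, int] = {}
    truth_events: dict[str, dict[str, str]] = {}

    patient_ids = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    for pid in patient_ids:
        truth_events[pid] = {}
        truth_msi_b5[pid] = 0
        truth_loh_b5[pid] = 0
        for locus in catalog:
            lattice = _allele_lattice(locus)
            het = rng.random() < config.het_rate
            if het:
                a1, a2 = sorted(rng.choice(len(lattice), size=2, replace=False))
                alleles = [int(lattice[a1]), int(lattice[a2])]
            else:
                alleles = [int(lattice[rng.integers(len(lattice))])]

            base = rng.uniform(900.0, 1500.0)
            if het:
                normal_ah = [(alleles[0], base), (alleles[1], base)]
            else:
                normal_ah = [(alleles[0], 1.9 * base)]

            # somatic event draw: MSI takes the first slice of probability,
            # LOH the next (only at heterozygous loci) — mutually exclusive
            # unless the coincident-event stress mode is on
            p_msi = config.locus_msi_prob(locus.locus_id)
            u = rng.random()
            is_msi = u < p_msi
            if config.allow_coincident_events:
                is_loh = het and rng.random() < loh_p
            else:
                is_loh = (not is_msi) and het and u < p_msi + loh_p * (1 - p_msi)
            retained = None

            tumor_ah = list(normal_ah)
            if is_loh:
                retained = float(rng.uniform(*config.loh_retained_range))
                which = int(rng.integers(2))
                size, h = tumor_ah[which]
                tumor_ah[which] = (size, h * retained)
            if is_msi:
                anchor_idx = int(rng.integers(len(alleles)))
                novel = _draw_novel_size(
                    rng, alleles[anchor_idx], set(alleles), locus, config
                )
                novel_h = base * rng.uniform(0.7, 1.0)
                if rng.random() < config.slip_fraction and not is_loh:
                    # slipped allele: the pre-existing allele is replaced
                    tumor_ah = [
                        (s, h) for s, h in tumor_ah if s != alleles[anchor_idx]
                    ]
                tumor_ah.append((novel, novel_h))

            event = "MSI" if is_msi else ("LOH" if is_loh else "NONE")
            truth_events[pid][locus.locus_id] = event
            if locus.locus_id in b5_ids:
                truth_msi_b5[pid] += event == "MSI"
                truth_loh_b5[pid] += event == "LOH"

            peaksets.append(
                PeakSet(
                    sample_id=pid,
                    locus_id=locus.locus_id,
                    tissue="NORMAL",
                    peaks=_emit_peaks(rng, normal_ah, locus, config),
                )
            )
            peaksets.append(
                PeakSet(
                    sample_id=pid,
                    locus_id=locus.locus_id,
                    tissue="TUMOR",
                    peaks=_emit_peaks(rng, tumor_ah, locus, config),
                )
            )
            pair_rows.append(
                dict(
                    patient_id=pid,
                    locus_id=locus.locus_id,
                    event=event,
                    heterozygous=int(het),
                    alleles=",".join(str(a) for a in alleles),
                    retained_fraction="" if retained is None else f"{retained:.4f}",
                )
            )

    clinical, hazard_mult = _generate_clinical(
        rng, patient_ids, truth_events, truth_msi_b5, truth_loh_b5, catalog, config
    )

    patient_rows = []
    for pid in patient_ids:
        k_msi, k_loh = truth_msi_b5[pid], truth_loh_b5[pid]
        patient_rows.append(
            dict(
                patient_id=pid,
                b5_msi_class=(
                    "MSI_H" if k_msi >= MIN_ASSAYABLE_B5 else "MSI_L" if k_msi == 1 else "MSS"
                ),
                b5_loh_class=(
                    "LOH_H" if k_loh >= MIN_ASSAYABLE_B5 else "LOH_L" if k_loh == 1 else "NON_LOH"
                ),
                hazard_multiplier=hazard_mult[pid],
            )
        )
    truth = SimTruth(
        pair_truth=pd.DataFrame(pair_rows),
        patient_truth=pd.DataFrame(patient_rows),
    )
    return peaksets, clinical, truth


def _marker_positive(
    marker: str,
    events: dict[str, str],
    k_msi_b5: int,
    k_loh_b5: int,
) -> bool:
    if marker == "b5_msi_class":
        return k_msi_b5 >= MIN_ASSAYABLE_B5
    if marker == "b5_loh_class":
        return k_loh_b5 >= MIN_ASSAYABLE_B5
    locus_id, _, etype = marker.partition(":")
    return events.get(locus_id) == (etype or "MSI")


def _generate_clinical(
    rng: np.random.Generator,
    patient_ids: list[str],
    truth_events: dict[str, dict[str, str]],
    truth_msi_b5: dict[str, int],
    truth_loh_b5: dict[str, int],
    catalog: LocusCatalog,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Clinical covariates at typical colorectal-cohort marginals (57.5%
    male, 34.5% smoking, 22.4% drinking, 51.2% chemotherapy, stage II/III
    57.7/42.3%, 54.7% colon) and exponential survival times whose hazard
    is scaled by exp(sum of the configured marker effects)."""
    base_rate = math.log(2.0) / cfg.median_os_months
    rows = []
    hazard_mult = {}
    for pid in patient_ids:
        log_hr = sum(
            eff
            for marker, eff in cfg.marker_effects.items()
            if _marker_positive(
                marker, truth_events[pid], truth_msi_b5[pid], truth_loh_b5[pid]
            )
        )
        mult = math.exp(log_hr)
        hazard_mult[pid] = mult
        os_true = rng.exponential(1.0 / (base_rate * mult))
        pfs_true = min(
            rng.exponential(1.0 / (base_rate * mult * cfg.pfs_hazard_multiplier)),
            os_true,
        )
        censor = rng.uniform(*cfg.censor_range)
        stage = "II" if rng.random() < 0.5773 else "III"
        rows.append(
            dict(
                patient_id=pid,
                age=round(float(np.clip(rng.normal(67.4, 8.0), 40, 90)), 1),
                sex="male" if rng.random() < 0.5748 else "female",
                smoking=int(rng.random() < 0.3451),
                drinking=int(rng.random() < 0.2235),
                tnm_stage=stage,
                path_type=str(
                    rng.choice(
                        ["adenocarcinoma", "mucinous", "signet_ring", "other"],
                        p=[0.83, 0.12, 0.03, 0.02],
                    )
                ),
                location="colon" if rng.random() < 0.5469 else "rectum",
                lymph_node=int(
                    rng.random() < (0.9 if stage in ("III", "IV") else 0.1)
                ),
                chemotherapy=int(rng.random() < 0.5117),
                os_months=round(min(os_true, censor), 2),
                os_event=int(os_true <= censor),
                pfs_months=round(min(pfs_true, censor), 2),
                pfs_event=int(pfs_true <= censor),
            )
        )
    return pd.DataFrame(rows), hazard_mult


@dataclass
class RecoveryReport:
    """Agreement between pipeline calls and simulation ground truth."""

    confusion: pd.DataFrame  # truth x called counts
    sensitivity: dict[str, float]  # per event type
    specificity: float
    locus_call_agreement: float
    b5_msi_agreement: float
    b5_loh_agreement: float
    n_pairs: int
    n_failed: int


_CALL_TO_TRUTH = {
    "MSI": "MSI",
    "LOH": "LOH",
    "STABLE": "NONE",
    "NON_INFORMATIVE": "NONE",
}


def recovery_report(truth: SimTruth, calls, profiles=None) -> RecoveryReport:
    """Confusion matrix and sensitivity/specificity of the locus calls
    against the simulation truth, plus B5 class agreement when patient
    profiles are supplied.  FAILED calls are excluded (locus not assayed).
    """
    call_map = {(c.sample_id, c.locus_id): c for c in calls}
    truth_keys = set(
        zip(truth.pair_truth["patient_id"], truth.pair_truth["locus_id"])
    )
    unknown = set(call_map) - truth_keys
    if unknown:
        raise ValueError(f"calls outside the truth universe, e.g. {sorted(unknown)[:3]}")

    labels = ("MSI", "LOH", "NONE")
    conf = pd.DataFrame(0, index=labels, columns=labels)
    n_failed = 0
    for _, row in truth.pair_truth.iterrows():
        call = call_map.get((row["patient_id"], row["locus_id"]))
        if call is None:
            continue
        if call.status == "FAILED":
            n_failed += 1
            continue
        conf.loc[row["event"], _CALL_TO_TRUTH[call.status]] += 1

    sens = {}
    for etype in ("MSI", "LOH"):
        n_true = int(conf.loc[etype].sum())
        sens[etype] = float(conf.loc[etype, etype] / n_true) if n_true else float("nan")
    n_none = int(conf.loc["NONE"].sum())
    spec = float(conf.loc["NONE", "NONE"] / n_none) if n_none else float("nan")
    agree = float(np.diag(conf).sum() / conf.to_numpy().sum())

    b5_msi_agree = b5_loh_agree = float("nan")
    if profiles is not None:
        tp = truth.patient_truth.set_index("patient_id")
        msi_hits = msi_tot = loh_hits = loh_tot = 0
        for prof in profiles:
            trow = tp.loc[prof.patient_id]
            if prof.b5_msi_class is not None:
                msi_tot += 1
                msi_hits += prof.b5_msi_class == trow["b5_msi_class"]
            if prof.b5_loh_class is not None:
                loh_tot += 1
                loh_hits += prof.b5_loh_class == trow["b5_loh_class"]
        if msi_tot:
            b5_msi_agree = msi_hits / msi_tot
        if loh_tot:
            b5_loh_agree = loh_hits / loh_tot

    return RecoveryReport(
        confusion=conf,
        sensitivity=sens,
        specificity=spec,
        locus_call_agreement=agree,
        b5_msi_agreement=b5_msi_agree,
        b5_loh_agreement=b5_loh_agree,
        n_pairs=int(conf.to_numpy().sum()),
        n_failed=n_failed,
    )
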