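"""End-to-end orchestration: read, genotype, call, classify, profile, test.

`run_all` chains the stages on the standard file dialects and writes all
result tables, a JSON cohort summary, and an append-only plain-text log
recording every parameter and decision mode, so any run is reconstructible
from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .calling import call_cohort, write_call_table
from .catalog import AXES, LocusCatalog, default_catalog, load_catalog
from .classify import build_profiles, write_profile_table
from .clinstats import marker_outcome_scan, read_clinical_table
from .fragments import CallingParams, read_peak_table
from .profile import (
    group_frequency,
    locus_occurrence_rate,
    overall_rate,
    pattern_partition,
    spectrum_summary,
    tally_events,
)

__all__ = ["RunConfig", "run_all", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative configuration for a full analysis run."""

    peaks: str
    out_dir: str
    catalog: Optional[str] = None  # None -> bundled default catalog
    clinical: Optional[str] = None
    params: CallingParams = field(default_factory=CallingParams)
    truncate_5y: bool = True
    bh_correct: bool = False
    informative_denominator: bool = False
    b5_grouping: str = "high_vs_rest"  # or "any_vs_none"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a declarative YAML config; keyword overrides (e.g. from
        CLI flags) take precedence over file values."""
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        params = data.pop("params", {})
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if params:
            cfg.params = CallingParams(**params)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (thresholds, modes,
        seed) — not of file locations, so reruns of the same analysis in
        a different directory stamp the same hash."""
        d = self.to_dict()
        for key in ("peaks", "out_dir", "catalog", "clinical", "log_level"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_all(config: RunConfig) -> dict:
    """Execute the whole analysis; returns the summary dict it also writes.

    Outputs under ``out_dir``: calls.tsv, profiles.csv, per_locus.tsv,
    group_frequencies.tsv, summary.json, survival_scan.tsv (when a
    clinical table is given), and run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"msatprof v{__version__} config={config.config_hash()} seed={config.seed}"
    log_path = out / "run.log"

    def log(msg: str) -> None:
        with log_path.open("a", encoding="utf-8") as fh:
            fh.write(msg + "\n")
        logger.info(msg)

    # start the log fresh per run so reruns are byte-identical
    log_path.write_text("", encoding="utf-8")
    log(f"run: {tag}")
    for key, val in sorted(config.to_dict().items()):
        log(f"config {key} = {val!r}")

    catalog = _load_catalog_stage(config)
    log(f"catalog: {len(catalog)} loci ({len(catalog.gene_locus_ids)} gene loci, "
        f"{len(catalog.b5_ids)} B5)")

    peaksets = _read_stage(config)
    log(f"peaks: {len(peaksets)} peak sets")
    if not peaksets:
        raise PipelineError("stage 'read' failed: empty cohort, nothing to analyze")

    calls = _call_stage(peaksets, catalog, config)
    write_call_table(calls, out / "calls.tsv", header_comment=tag)
    log(f"calls: {len(calls)} locus calls")

    profiles = build_profiles(calls, catalog)
    write_profile_table(profiles, out / "profiles.csv", header_comment=tag)
    log(f"profiles: {len(profiles)} patients")

    summary = _profile_stage(profiles, catalog, config, out, tag, log)

    if config.clinical:
        summary["survival"] = _clinstats_stage(profiles, catalog, config, out, tag, log)

    summary["run"] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients": len(profiles),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    log("summary.json written")
    return summary


@_stage("catalog")
def _load_catalog_stage(config: RunConfig) -> LocusCatalog:
    return load_catalog(config.catalog) if config.catalog else default_catalog()


@_stage("read")
def _read_stage(config: RunConfig):
    return read_peak_table(config.peaks)


@_stage("call")
def _call_stage(peaksets, catalog, config: RunConfig):
    return call_cohort(peaksets, catalog, config.params)


@_stage("profile")
def _profile_stage(profiles, catalog, config, out: Path, tag: str, log) -> dict:
    counts = tally_events(profiles, catalog)

    per_locus_rows = []
    for lid in catalog.locus_ids:
        per_locus_rows.append(
            dict(
                locus_id=lid,
                is_b5=int(catalog[lid].is_b5),
                n_msi=counts.count(lid, "MSI"),
                n_loh=counts.count(lid, "LOH"),
                msi_rate=locus_occurrence_rate(counts, lid, "MSI"),
                loh_rate=locus_occurrence_rate(counts, lid, "LOH"),
            )
        )
    _write_tsv(pd.DataFrame(per_locus_rows), out / "per_locus.tsv", tag)

    group_rows = []
    freqs = {}
    for axis in ("gene", "gene_class", "region", "motif_length"):
        for key in catalog.group_keys(axis):
            for etype in ("MSI", "LOH"):
                gf = group_frequency(counts, catalog, axis, key, etype)
                group_rows.append(
                    dict(
                        axis=axis, key=str(key), event_type=etype,
                        n_events=gf.n_events, n_loci=gf.n_loci_in_group,
                        n_samples=gf.n_samples, frequency=gf.frequency,
                    )
                )
                freqs.setdefault(axis, {}).setdefault(str(key), {})[etype] = gf.frequency
    _write_tsv(pd.DataFrame(group_rows), out / "group_frequencies.tsv", tag)

    partition = pattern_partition(counts, catalog)
    spec_msi = spectrum_summary(profiles, "MSI", catalog)
    spec_loh = spectrum_summary(profiles, "LOH", catalog)
    log(f"profile: {partition['n_msi']} MSI / {partition['n_loh']} LOH events")

    class_counts = {
        "b5_msi": _class_counts(profiles, "b5_msi_class"),
        "b5_loh": _class_counts(profiles, "b5_loh_class"),
        "mmr": _class_counts(profiles, "mmr_class"),
    }
    return {
        "overall_rates": {
            "MSI": overall_rate(counts, "MSI", catalog),
            "LOH": overall_rate(counts, "LOH", catalog),
        },
        "pattern_partition": {
            "n_msi": partition["n_msi"],
            "n_loh": partition["n_loh"],
            "msi_share": partition["msi_share"],
            "loh_share": partition["loh_share"],
        },
        "group_frequencies": freqs,
        "spectrum": {
            "MSI": _spectrum_dict(spec_msi),
            "LOH": _spectrum_dict(spec_loh),
        },
        "classes": class_counts,
    }


@_stage("clinstats")
def _clinstats_stage(profiles, catalog, config: RunConfig, out: Path, tag: str, log) -> dict:
    records = read_clinical_table(config.clinical)
    markers = list(catalog.locus_ids) + ["b5_msi_class", "b5_loh_class"]
    scans = []
    for endpoint in ("OS", "PFS"):
        scan = marker_outcome_scan(
            profiles,
            records,
            markers,
            endpoint=endpoint,
            truncate_months=60.0 if config.truncate_5y else None,
            bh_correct=config.bh_correct,
        )
        scans.append(scan)
    scan_df = pd.concat(scans, ignore_index=True)
    _write_tsv(scan_df, out / "survival_scan.tsv", tag)
    log(f"clinstats: {len(scan_df)} marker x stratum x endpoint tests "
        f"(5-year truncation {'on' if config.truncate_5y else 'off'}, "
        f"BH {'on' if config.bh_correct else 'off'})")
    sig = scan_df[(scan_df["p"] < 0.05) & (scan_df["skipped"] == "")]
    return {
        "n_tests": int(len(scan_df)),
        "n_significant_raw": int(len(sig)),
        "truncate_5y": config.truncate_5y,
    }


def _class_counts(profiles, attr: str) -> dict:
    counts: dict[str, int] = {}
    for p in profiles:
        key = getattr(p, attr) or "missing"
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))


def _spectrum_dict(s) -> dict:
    return {
        "total_events": s.total_events,
        "n_affected": s.n_affected,
        "mean_events_per_affected": s.mean_events_per_affected,
        "fraction_patients_affected": s.fraction_patients_affected,
        "fraction_loci_affected": s.fraction_loci_affected,
        "event_count_distribution": {
            str(k): v for k, v in s.event_count_distribution.items()
        },
    }


def _write_tsv(df: pd.DataFrame, path: Path, tag: str) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
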