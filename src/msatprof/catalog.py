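"""Microsatellite locus catalog: definitions, grouping metadata, and TSV I/O.

A :class:`LocusCatalog` is the locus universe every downstream computation
reads.  The bundled default catalog holds 61 microsatellite loci in 19
colorectal-cancer-related genes (26 tumor-suppressor, 20 oncogene, 9
mismatch-repair and 6 DNA-repair loci; 53 intronic, 1 exonic, 5 noncoding
and 2 in 3'-UTRs) plus the five NCI Bethesda markers (BAT25, BAT26,
D2S123, D5S346, D17S250) used for panel-level MSI classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "GENE_CLASSES",
    "REGIONS",
    "B5_LOCI",
    "LocusDef",
    "LocusCatalog",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "default_catalog",
    "loci_in_group",
]

logger = logging.getLogger(__name__)

GENE_CLASSES = frozenset({"TS", "ONCOGENE", "MMR", "DNAR", "NONE"})
REGIONS = frozenset({"INTRON", "EXON", "UTR3", "NONCODING", "NA"})

#: The five Bethesda reference markers for MSI testing.
B5_LOCI = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250")

#: Genes whose microsatellite loci define the mismatch-repair (MMR) class.
MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})

CATALOG_COLUMNS = (
    "locus_id",
    "gene",
    "gene_class",
    "region",
    "motif",
    "motif_length",
    "is_b5",
    "size_min",
    "size_max",
)

#: Valid grouping axes for :func:`loci_in_group`.
AXES = ("gene", "gene_class", "region", "motif_length", "b5")


class CatalogError(ValueError):
    """Raised for malformed catalog files or invalid locus definitions."""


@dataclass(frozen=True)
class LocusDef:
    """One microsatellite locus and its grouping metadata.

    Parameters
    ----------
    locus_id : str
        Unique short identifier, e.g. ``"BRAF-9"`` or ``"BAT26"``.
    gene : str
        Gene symbol, or ``""`` for anonymous panel markers.
    gene_class : str
        ``TS``, ``ONCOGENE``, ``MMR``, ``DNAR``, or ``NONE`` (anonymous).
    region : str
        Genomic context: ``INTRON``, ``EXON``, ``UTR3``, ``NONCODING``, ``NA``.
    motif : str
        Repeat unit, e.g. ``"CA"``; single base for mononucleotide runs.
    motif_length : int
        Length of the repeat unit in bp (``len(motif)``).
    is_b5 : bool
        True for the five Bethesda panel markers.
    size_min, size_max : int
        Expected amplicon size range in bp.
    """

    locus_id: str
    gene: str
    gene_class: str
    region: str
    motif: str
    motif_length: int
    is_b5: bool
    size_min: int
    size_max: int

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise CatalogError("locus_id must be non-empty")
        if self.gene_class not in GENE_CLASSES:
            raise CatalogError(
                f"{self.locus_id}: unknown gene_class {self.gene_class!r}"
            )
        if self.region not in REGIONS:
            raise CatalogError(f"{self.locus_id}: unknown region {self.region!r}")
        if self.motif_length != len(self.motif) or self.motif_length < 1:
            raise CatalogError(
                f"{self.locus_id}: motif {self.motif!r} does not match "
                f"motif_length {self.motif_length}"
            )
        if (self.gene_class == "NONE") != (self.gene == ""):
            raise CatalogError(
                f"{self.locus_id}: gene_class NONE iff gene is empty"
            )
        if not (0 < self.size_min < self.size_max):
            raise CatalogError(
                f"{self.locus_id}: invalid size range "
                f"[{self.size_min}, {self.size_max}]"
            )


class LocusCatalog:
    """Ordered, uniquely keyed collection of :class:`LocusDef`.

    Maintains derived indexes by gene, gene class, region and motif length
    so that group denominators (e.g. "26 tumor-suppressor loci") are read
    straight from the catalog rather than hard-coded.
    """

    def __init__(self, loci: Iterable[LocusDef]):
        self._loci: list[LocusDef] = list(loci)
        self._by_id: dict[str, LocusDef] = {}
        for locus in self._loci:
            if locus.locus_id in self._by_id:
                raise CatalogError(f"duplicate locus_id {locus.locus_id!r}")
            self._by_id[locus.locus_id] = locus

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[LocusDef]:
        return iter(self._loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def __getitem__(self, locus_id: str) -> LocusDef:
        try:
            return self._by_id[locus_id]
        except KeyError:
            raise KeyError(f"locus {locus_id!r} not in catalog") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocusCatalog):
            return NotImplemented
        return self._loci == other._loci

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self._loci]

    @property
    def b5_ids(self) -> list[str]:
        return [loc.locus_id for loc in self._loci if loc.is_b5]

    @property
    def gene_locus_ids(self) -> list[str]:
        """Tumor-related-gene loci, i.e. everything outside the B5 panel."""
        return [loc.locus_id for loc in self._loci if not loc.is_b5]

    @property
    def mmr_locus_ids(self) -> list[str]:
        return [
            loc.locus_id
            for loc in self._loci
            if not loc.is_b5 and loc.gene_class == "MMR"
        ]

    def group_keys(self, axis: str) -> list:
        """Distinct keys present on a grouping axis (B5 loci excluded
        everywhere except on the ``b5`` axis itself)."""
        _check_axis(axis)
        seen: dict = {}
        for loc in self._loci:
            if axis != "b5" and loc.is_b5:
                continue
            key = loc.is_b5 if axis == "b5" else getattr(loc, axis)
            seen.setdefault(key, None)
        return list(seen)

    def subset(self, locus_ids: Iterable[str]) -> "LocusCatalog":
        return LocusCatalog(self._by_id[i] for i in locus_ids)


def _check_axis(axis: str) -> None:
    if axis not in AXES:
        raise CatalogError(f"unknown grouping axis {axis!r}; expected one of {AXES}")


def loci_in_group(catalog: LocusCatalog, axis: str, key) -> set[str]:
    """Locus ids belonging to ``key`` on a grouping axis.

    Group denominators in frequency computations come from ``len()`` of the
    returned set.  The B5 markers carry no gene/region annotation and are
    excluded from every axis except ``b5``.
    """
    _check_axis(axis)
    if axis == "b5":
        return {loc.locus_id for loc in catalog if loc.is_b5 == bool(key)}
    # closed vocabularies accept any domain token (possibly an empty group);
    # open axes (gene, motif_length) require a key the catalog carries
    domain = {"gene_class": GENE_CLASSES, "region": REGIONS}.get(axis)
    if domain is not None:
        if key not in domain:
            raise CatalogError(f"unknown {axis} token {key!r}")
    elif key not in catalog.group_keys(axis):
        raise CatalogError(f"no loci with {axis} == {key!r} in catalog")
    return {
        loc.locus_id
        for loc in catalog
        if not loc.is_b5 and getattr(loc, axis) == key
    }


def load_catalog(path: str | Path) -> LocusCatalog:
    """Read a catalog TSV (header ``locus_id gene gene_class region motif
    motif_length is_b5 size_min size_max``; booleans as 0/1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CatalogError(f"{path}: empty file, expected a header line")
    header = lines[0].rstrip("\n").split("\t")
    if tuple(header) != CATALOG_COLUMNS:
        raise CatalogError(
            f"{path}: bad header {header!r}, expected {list(CATALOG_COLUMNS)}"
        )
    loci = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(CATALOG_COLUMNS):
            raise CatalogError(f"{path}:{lineno}: expected {len(CATALOG_COLUMNS)} fields")
        try:
            loci.append(
                LocusDef(
                    locus_id=fields[0],
                    gene=fields[1],
                    gene_class=fields[2],
                    region=fields[3],
                    motif=fields[4],
                    motif_length=int(fields[5]),
                    is_b5=_parse_bool(fields[6]),
                    size_min=int(fields[7]),
                    size_max=int(fields[8]),
                )
            )
        except CatalogError as exc:
            raise CatalogError(f"{path}:{lineno}: {exc}") from None
        except ValueError as exc:
            raise CatalogError(f"{path}:{lineno}: {exc}") from None
    if not loci:
        logger.warning("%s: catalog file contains a header but no loci", path)
    try:
        return LocusCatalog(loci)
    except CatalogError as exc:
        raise CatalogError(f"{path}: {exc}") from None


def _parse_bool(token: str) -> bool:
    if token in ("0", "1"):
        return token == "1"
    raise ValueError(f"expected 0/1 boolean, got {token!r}")


def write_catalog(catalog: LocusCatalog, path: str | Path) -> None:
    """Write a catalog in the TSV dialect read by :func:`load_catalog`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for loc in catalog:
            fh.write(
                "\t".join(
                    [
                        loc.locus_id,
                        loc.gene,
                        loc.gene_class,
                        loc.region,
                        loc.motif,
                        str(loc.motif_length),
                        "1" if loc.is_b5 else "0",
                        str(loc.size_min),
                        str(loc.size_max),
                    ]
                )
                + "\n"
            )


def default_catalog() -> LocusCatalog:
    """The bundled 66-locus default catalog (61 gene loci + 5 Bethesda)."""
    with resources.as_file(
        resources.files("msatprof.data").joinpath("default_catalog.tsv")
    ) as p:
        return load_catalog(p)
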