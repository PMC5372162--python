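"""Data model and I/O for coral colonies, exosymbiont taxa and occupancy tables.

A *colony* is one coral host with stratum labels (biogeographic region, reef
site, ontogenetic stage, host mitochondrial type) and the assemblage of
decapod exosymbionts found inside it.  An :class:`IncidenceMatrix` is the
binary colonies x taxa occupancy table that the null-model and ordination
machinery consumes; an abundance variant carries individual counts.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

REGIONS = ("RI", "NC")
SITES = ("LI", "HI")
STAGES = ("adult", "juvenile")
HOST_TYPES = ("alpha", "beta")

__all__ = [
    "Taxon",
    "ColonyRecord",
    "Stratum",
    "IncidenceMatrix",
    "planar_area",
    "load_colony_tables",
    "write_colony_tables",
    "load_taxa",
    "select_stratum",
    "to_incidence",
]


@dataclass(frozen=True)
class Taxon:
    """One exosymbiont species or molecular lineage."""

    taxon_id: str
    genus: str
    label: str
    is_key: bool = False


@dataclass
class ColonyRecord:
    """One coral colony with stratum labels, optional sizes and its assemblage.

    ``assemblage`` maps taxon_id -> individual count (>= 1).  Colonies without
    exosymbionts carry an empty mapping.  ``L`` and ``l`` are the maximum and
    maximum perpendicular diameters in cm; both are optional because the
    packaged survey table does not report per-colony sizes.
    """

    colony_id: str
    region: str
    site: str
    stage: str
    host_type: str
    L: float | None = None
    l: float | None = None
    assemblage: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.host_type not in HOST_TYPES:
            raise ValueError(f"unknown host_type {self.host_type!r}")
        for tid, n in self.assemblage.items():
            if n < 1:
                raise ValueError(
                    f"colony {self.colony_id}: count for {tid} must be >= 1, got {n}"
                )
        # size-class conventions: juveniles <= 5 cm diameter, adults > 10 cm.
        # Sizes are optional, so violations warn rather than fail.
        if self.L is not None:
            if self.stage == "juvenile" and self.L > 5:
                warnings.warn(
                    f"colony {self.colony_id}: juvenile with diameter {self.L} cm > 5 cm",
                    stacklevel=2,
                )
            if self.stage == "adult" and self.L <= 10:
                warnings.warn(
                    f"colony {self.colony_id}: adult with diameter {self.L} cm <= 10 cm",
                    stacklevel=2,
                )

    @property
    def richness(self) -> int:
        return len(self.assemblage)


@dataclass(frozen=True)
class Stratum:
    """An analysis unit: region x stage x host type (site optional)."""

    region: str | None = None
    site: str | None = None
    stage: str | None = None
    host_type: str | None = None

    def matches(self, rec: ColonyRecord) -> bool:
        return (
            (self.region is None or rec.region == self.region)
            and (self.site is None or rec.site == self.site)
            and (self.stage is None or rec.stage == self.stage)
            and (self.host_type is None or rec.host_type == self.host_type)
        )

    def label(self) -> str:
        parts = [p for p in (self.region, self.site, self.stage, self.host_type) if p]
        return "-".join(parts) if parts else "all"


def planar_area(L: float, l: float) -> float:
    """Planar area of a colony from its two diameters, as an ellipse.

    S = pi * (L/2) * (l/2) with L the maximum diameter and l the maximum
    perpendicular diameter, both in cm; the result is in cm^2.
    """
    if L < 0 or l < 0:
        raise ValueError("diameters must be non-negative")
    if l > L:
        raise ValueError(
            f"perpendicular diameter l={l} exceeds maximum diameter L={L}"
        )
    return math.pi * L * l / 4.0


class IncidenceMatrix:
    """Binary colonies x taxa occupancy matrix with an abundance variant.

    Rows follow the input colony order; columns follow the supplied taxon
    order.  ``incidence`` is 0/1; ``abundance`` holds individual counts with
    ``incidence == (abundance > 0)``.
    """

    def __init__(
        self,
        colony_ids: Sequence[str],
        taxon_ids: Sequence[str],
        abundance: np.ndarray,
    ):
        abundance = np.asarray(abundance, dtype=np.int64)
        if abundance.shape != (len(colony_ids), len(taxon_ids)):
            raise ValueError("abundance shape does not match row/column labels")
        if (abundance < 0).any():
            raise ValueError("abundance cells must be non-negative")
        self.colony_ids = list(colony_ids)
        self.taxon_ids = list(taxon_ids)
        self.abundance = abundance
        self.incidence = (abundance > 0).astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    def column_sums(self) -> np.ndarray:
        """Species occurrence frequencies f_s."""
        return self.incidence.sum(axis=0)

    def row_sums(self) -> np.ndarray:
        """Per-colony richness r_i."""
        return self.incidence.sum(axis=1)

    def grand_total(self) -> int:
        """Total number of presences F."""
        return int(self.incidence.sum())

    def column_index(self, taxon_id: str) -> int:
        try:
            return self.taxon_ids.index(taxon_id)
        except ValueError:
            raise KeyError(f"taxon {taxon_id!r} not in matrix") from None


def load_taxa(taxa_csv: str | Path) -> list[Taxon]:
    """Read a taxon set from ``taxa.csv`` (taxon_id,genus,label,is_key)."""
    taxa: list[Taxon] = []
    seen: set[str] = set()
    with open(taxa_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            tid = row["taxon_id"]
            if tid in seen:
                raise ValueError(f"duplicate taxon_id {tid!r} in {taxa_csv}")
            seen.add(tid)
            taxa.append(
                Taxon(tid, row["genus"], row["label"], row["is_key"] in ("1", "True", "true"))
            )
    return taxa


def load_colony_tables(
    colony_csv: str | Path,
    occupancy_csv: str | Path,
    taxa: Iterable[Taxon] | None = None,
) -> list[ColonyRecord]:
    """Read colony metadata + long-format occupancy into ColonyRecords.

    Colonies absent from the occupancy table get empty assemblages; input row
    order is preserved.  When ``taxa`` is given, occupancy taxon_ids must
    resolve against it.
    """
    known = {t.taxon_id for t in taxa} if taxa is not None else None

    records: list[ColonyRecord] = []
    index: dict[str, ColonyRecord] = {}
    with open(colony_csv, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            cid = row["colony_id"]
            if cid in index:
                raise ValueError(f"{colony_csv} line {i}: duplicate colony_id {cid!r}")
            rec = ColonyRecord(
                colony_id=cid,
                region=row["region"],
                site=row["site"],
                stage=row["stage"],
                host_type=row["host_type"],
                L=float(row["L_cm"]) if row.get("L_cm") else None,
                l=float(row["l_cm"]) if row.get("l_cm") else None,
            )
            records.append(rec)
            index[cid] = rec

    with open(occupancy_csv, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            cid, tid = row["colony_id"], row["taxon_id"]
            if cid not in index:
                raise ValueError(
                    f"{occupancy_csv} line {i}: unknown colony_id {cid!r}"
                )
            if known is not None and tid not in known:
                raise ValueError(
                    f"{occupancy_csv} line {i}: unknown taxon_id {tid!r}"
                )
            n = int(row["count"])
            if n < 1:
                raise ValueError(f"{occupancy_csv} line {i}: count must be >= 1, got {n}")
            index[cid].assemblage[tid] = index[cid].assemblage.get(tid, 0) + n
    return records


def write_colony_tables(
    records: Sequence[ColonyRecord],
    colony_csv: str | Path,
    occupancy_csv: str | Path,
) -> None:
    """Write records back to the two-CSV schema (inverse of load)."""
    with open(colony_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["colony_id", "region", "site", "stage", "host_type", "L_cm", "l_cm"])
        for r in records:
            w.writerow(
                [
                    r.colony_id,
                    r.region,
                    r.site,
                    r.stage,
                    r.host_type,
                    "" if r.L is None else f"{r.L:g}",
                    "" if r.l is None else f"{r.l:g}",
                ]
            )
    with open(occupancy_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["colony_id", "taxon_id", "count"])
        for r in records:
            for tid, n in r.assemblage.items():
                w.writerow([r.colony_id, tid, n])


def select_stratum(
    records: Iterable[ColonyRecord],
    region: str | None = None,
    site: str | None = None,
    stage: str | None = None,
    host_type: str | None = None,
) -> list[ColonyRecord]:
    """Filter records by any combination of stratum selectors."""
    stratum = Stratum(region=region, site=site, stage=stage, host_type=host_type)
    return [r for r in records if stratum.matches(r)]


def to_incidence(
    records: Sequence[ColonyRecord],
    taxa: Sequence[Taxon | str],
    drop_empty: bool = False,
) -> IncidenceMatrix:
    """Build the colonies x taxa occupancy matrix over a chosen taxon subset.

    With ``drop_empty`` rows that are all-zero over the chosen taxa are removed
    (the correspondence-analysis convention); null models keep every colony.
    """
    taxon_ids = [t.taxon_id if isinstance(t, Taxon) else t for t in taxa]
    if not taxon_ids:
        raise ValueError("taxa must be non-empty")
    ab = np.zeros((len(records), len(taxon_ids)), dtype=np.int64)
    col = {tid: j for j, tid in enumerate(taxon_ids)}
    for i, rec in enumerate(records):
        for tid, n in rec.assemblage.items():
            j = col.get(tid)
            if j is not None:
                ab[i, j] = n
    ids = [r.colony_id for r in records]
    if drop_empty:
        keep = ab.sum(axis=1) > 0
        ab = ab[keep]
        ids = [cid for cid, k in zip(ids, keep) if k]
    return IncidenceMatrix(ids, taxon_ids, ab)
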