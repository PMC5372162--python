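"""Packaged survey data: 234 *Pocillopora damicornis* colonies and their
decapod exosymbionts from Reunion Island and New Caledonia.

The fixture is a colony-level transcription of the published assemblage
composition table; see ``data/NOTES.md`` for the transcription conventions and
how ambiguous composite rows were read.  Five taxa are flagged as *key
species* (two *Alpheus lottini* lineages and three *Trapezia* crabs); these
are the species whose richness and co-occurrence the null models interrogate.
"""

from __future__ import annotations

from importlib import resources

from .community import ColonyRecord, Stratum, Taxon, load_colony_tables, load_taxa

__all__ = ["load_survey", "load_survey_taxa", "ANALYSIS_STRATA", "KEY_TAXA"]

#: The five analysis strata with their colony counts (region, stage, host type).
ANALYSIS_STRATA: dict[str, Stratum] = {
    "RI-adult": Stratum(region="RI", stage="adult"),
    "NC-adult-alpha": Stratum(region="NC", stage="adult", host_type="alpha"),
    "NC-adult-beta": Stratum(region="NC", stage="adult", host_type="beta"),
    "RI-juvenile": Stratum(region="RI", stage="juvenile"),
    "NC-juvenile-alpha": Stratum(region="NC", stage="juvenile", host_type="alpha"),
}

#: Key-species taxon ids in canonical column order.
KEY_TAXA = ["AlotL1", "AlotL2", "Tgut", "Tsept", "Tspe"]


def _data_path(name: str):
    return resources.files("coralguild.data").joinpath(name)


def load_survey_taxa() -> list[Taxon]:
    """The 13-entry taxon set (10 Trapezia species/lineages, 2 A. lottini
    lineages, 1 unresolved A. lottini placeholder)."""
    with resources.as_file(_data_path("taxa.csv")) as p:
        return load_taxa(p)


def load_survey() -> tuple[list[ColonyRecord], list[Taxon]]:
    """Load the packaged 234-colony survey.

    Returns ``(records, taxa)``.  Record order groups colonies by the source
    table's assemblage rows; stratum totals are 61 (RI adults), 48 (NC adult
    alpha), 11 (NC adult beta), 56 (RI juveniles), 40 (NC juvenile alpha) and
    18 (NC juvenile beta, excluded from null-model analysis).
    """
    taxa = load_survey_taxa()
    with resources.as_file(_data_path("colonies.csv")) as pc, resources.as_file(
        _data_path("occupancy.csv")
    ) as po:
        records = load_colony_tables(pc, po, taxa)
    return records, taxa
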