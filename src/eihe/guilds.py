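"""Guild definitions: named sets of bacterial genera sharing a functional role.

A *guild* here is the set of genera treated as potential hydrocarbon
degraders when computing the ecological index of hydrocarbon exposure
(EIHE). The packaged default guild holds 63 genera with at least one
described hydrocarbon-degrading strain, spanning the phyla Proteobacteria,
Actinobacteria, Bacteroidetes and Firmicutes. The guild is a plain TSV data
asset: users can export it, edit it, and load their own variant, or extend
the default programmatically as knowledge of hydrocarbon-degrading taxa
grows.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "GuildGenus",
    "GuildDefinition",
    "load_guild_list",
    "write_guild_list",
    "default_guild",
    "phylum_composition",
    "extend_guild",
]

_VALID_ENVIRONMENTS = frozenset({"marine", "terrestrial", "both", "unknown"})

#: Default mapping from logical fields to guild-file column names.
DEFAULT_DIALECT: Mapping[str, str] = {
    "genus": "genus",
    "phylum": "phylum",
    "isolation_environment": "isolation_environment",
    "synonyms": "synonyms",
    "evidence_note": "evidence_note",
}


@dataclass(frozen=True)
class GuildGenus:
    """One guild member: a Latin genus label plus descriptive metadata.

    ``synonyms`` are alternate labels (e.g. legacy genus names) accepted
    during name matching against taxonomy tables; they never participate in
    uniqueness of the genus itself but must not collide with other entries.
    """

    genus_name: str
    phylum: str = "unknown"
    isolation_environment: str = "unknown"
    evidence_note: str = ""
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.genus_name or not self.genus_name.strip():
            raise ValueError("genus_name must be non-empty")
        if self.isolation_environment not in _VALID_ENVIRONMENTS:
            raise ValueError(
                f"isolation_environment must be one of {sorted(_VALID_ENVIRONMENTS)}, "
                f"got {self.isolation_environment!r}"
            )


@dataclass(frozen=True)
class GuildDefinition:
    """A validated, versioned set of :class:`GuildGenus` entries.

    Genus names are unique case-insensitively; synonyms may not shadow
    another entry's genus name. The definition is immutable — use
    :func:`extend_guild` to derive a new version.
    """

    name: str
    version: str
    entries: tuple[GuildGenus, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a guild must contain at least one genus")
        seen: dict[str, str] = {}
        for entry in self.entries:
            key = entry.genus_name.casefold()
            if key in seen:
                raise ValueError(
                    f"duplicate genus in guild (case-insensitive): {entry.genus_name!r}"
                )
            seen[key] = entry.genus_name
        for entry in self.entries:
            for syn in entry.synonyms:
                key = syn.casefold()
                if key in seen and seen[key] != entry.genus_name:
                    raise ValueError(
                        f"synonym {syn!r} of {entry.genus_name!r} collides with "
                        f"guild genus {seen[key]!r}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, genus: str) -> bool:
        key = genus.casefold()
        return any(e.genus_name.casefold() == key for e in self.entries)

    @property
    def genus_names(self) -> tuple[str, ...]:
        """Genus labels in guild order (the order computations report)."""
        return tuple(e.genus_name for e in self.entries)


def load_guild_list(
    source: TextIO | str,
    dialect: Mapping[str, str] | None = None,
    name: str = "custom",
    version: str = "1.0",
) -> GuildDefinition:
    """Read a guild definition from a delimited text table.

    The table must carry at least a genus column; phylum, isolation
    environment, synonyms (semicolon-separated) and evidence-note columns
    are optional. ``dialect`` remaps logical field names to the file's
    column names. Lines starting with ``#`` are comments.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    if cols["genus"] not in df.columns:
        raise ValueError(
            f"guild table lacks a genus column (expected {cols['genus']!r})"
        )
    if len(df) == 0:
        raise ValueError("empty guild list")

    entries: list[GuildGenus] = []
    for _, row in df.iterrows():
        genus = str(row[cols["genus"]]).strip()
        phylum = str(row.get(cols["phylum"], "")).strip() or "unknown"
        env = str(row.get(cols["isolation_environment"], "")).strip() or "unknown"
        note = str(row.get(cols["evidence_note"], "")).strip()
        raw_syn = str(row.get(cols["synonyms"], "")).strip()
        synonyms = tuple(s.strip() for s in raw_syn.split(";") if s.strip())
        entries.append(
            GuildGenus(
                genus_name=genus,
                phylum=phylum,
                isolation_environment=env,
                evidence_note=note,
                synonyms=synonyms,
            )
        )
    return GuildDefinition(name=name, version=version, entries=tuple(entries))


def write_guild_list(guild: GuildDefinition, sink: TextIO) -> None:
    """Write a guild as a headered TSV readable by :func:`load_guild_list`."""
    sink.write("genus\tphylum\tisolation_environment\tsynonyms\tevidence_note\n")
    for e in guild.entries:
        sink.write(
            f"{e.genus_name}\t{e.phylum}\t{e.isolation_environment}\t"
            f"{';'.join(e.synonyms)}\t{e.evidence_note}\n"
        )


@functools.lru_cache(maxsize=1)
def default_guild() -> GuildDefinition:
    """The packaged 63-genus hydrocarbon-biodegradation guild."""
    text = (
        resources.files("eihe.data").joinpath("hydrocarbon_guild.tsv").read_text("utf-8")
    )
    return load_guild_list(
        io.StringIO(text), name="hydrocarbon-biodegradation", version="1.0"
    )


def phylum_composition(guild: GuildDefinition) -> dict[str, float]:
    """Percent of guild entries per phylum, rounded to one decimal.

    Values sum to 100 within rounding slack (±0.2).
    """
    counts: dict[str, int] = {}
    for entry in guild.entries:
        counts[entry.phylum] = counts.get(entry.phylum, 0) + 1
    total = len(guild)
    return {
        phylum: round(100.0 * n / total, 1)
        for phylum, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def _bump_version(version: str) -> str:
    base, sep, suffix = version.rpartition("+")
    if sep and suffix.isdigit():
        return f"{base}+{int(suffix) + 1}"
    return f"{version}+1"


def extend_guild(
    guild: GuildDefinition, additions: Iterable[GuildGenus]
) -> GuildDefinition:
    """Return a new guild with ``additions`` appended and the version bumped.

    The original definition is untouched. Additions that collide
    (case-insensitively) with existing members raise ``ValueError``.
    """
    additions = tuple(additions)
    if not additions:
        return guild
    return GuildDefinition(
        name=guild.name,
        version=_bump_version(guild.version),
        entries=guild.entries + additions,
    )
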