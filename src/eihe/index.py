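"""The ecological index of hydrocarbon exposure (EIHE).

The index for a sample is the sum, over the genera of a hydrocarbon-
biodegradation guild, of their relative abundances expressed as a
percentage of the sample's total classified reads:

    EIHE = sum_i 100 * reads(genus_i) / total_reads

It therefore estimates the fraction of the bacterial community potentially
capable of degrading hydrocarbons. The denominator is the root count of the
taxonomy table (all classified reads), not the sum of genus-level rows, so
reads left unclassified below the root still dilute the index.

Genus labels from classifiers vary in casing and decoration (quotes,
candidate-status markers, bracketed qualifiers); matching against the guild
is controlled by :class:`NameMatchPolicy` and is always exact on the
normalized genus token — no substring or fuzzy matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .guilds import GuildDefinition
from .io import TaxonCountTable

__all__ = [
    "NameMatchPolicy",
    "SamplePercentProfile",
    "EIHEResult",
    "AmbiguousMatchError",
    "ZeroReadsError",
    "percent_abundances",
    "match_genus_names",
    "compute_eihe",
]


class AmbiguousMatchError(ValueError):
    """Two or more table labels normalize onto the same guild genus."""


class ZeroReadsError(ValueError):
    """A sample has zero total reads; percentages are undefined."""


@dataclass(frozen=True)
class NameMatchPolicy:
    """Configuration for matching table genus labels against guild names.

    ``strip_decorations`` removes surrounding quotes, a leading
    ``Candidatus`` marker, and trailing bracketed or parenthesized
    qualifiers before comparison.
    """

    case_sensitive: bool = False
    use_synonyms: bool = True
    strip_decorations: bool = True

    def normalize(self, label: str) -> str:
        s = label.strip()
        if self.strip_decorations:
            s = s.strip("\"'")
            s = re.sub(r"\s*\[[^\]]*\]\s*$", "", s)
            s = re.sub(r"\s*\([^)]*\)\s*$", "", s)
            if s.lower().startswith("candidatus "):
                s = s[len("candidatus "):]
            s = s.strip().strip("\"'")
        if not self.case_sensitive:
            s = s.casefold()
        return s


DEFAULT_POLICY = NameMatchPolicy()


@dataclass(frozen=True)
class SamplePercentProfile:
    """Per-sample genus-level relative abundances (percent of total reads)."""

    sample_name: str
    total_reads: int
    genus_percents: dict[str, float]


@dataclass(frozen=True)
class EIHEResult:
    """Index value for one sample plus the per-genus breakdown.

    ``contributions`` covers every guild genus (zeros for absent ones) and
    sums to ``eihe``; ``matched``/``unmatched`` partition the guild by
    whether the genus was found in the table.
    """

    sample_name: str
    eihe: float
    contributions: dict[str, float]
    matched: tuple[str, ...]
    unmatched: tuple[str, ...]


def percent_abundances(table: TaxonCountTable) -> list[SamplePercentProfile]:
    """Genus-rank percent abundances per sample.

    A genus label occurring under several parents (e.g. ``unclassified``)
    is aggregated before the percentage is taken. Samples with zero total
    reads are rejected.
    """
    roots = table.root_counts()
    counts = table.genus_counts()
    profiles = []
    for sample in table.sample_names:
        total = roots[sample]
        if total == 0:
            raise ZeroReadsError(f"sample {sample!r} has zero total reads")
        percents = {
            genus: 100.0 * int(c) / total for genus, c in counts[sample].items()
        }
        profiles.append(
            SamplePercentProfile(
                sample_name=sample, total_reads=total, genus_percents=percents
            )
        )
    return profiles


def match_genus_names(
    table_taxa: Sequence[str],
    guild: GuildDefinition,
    policy: NameMatchPolicy = DEFAULT_POLICY,
) -> dict[str, str | None]:
    """Map each guild genus to the table label it matches, or ``None``.

    Matching is deterministic and exact on normalized tokens. If several
    distinct table labels normalize onto the same guild genus the match is
    ambiguous and raises :class:`AmbiguousMatchError` rather than silently
    picking one.
    """
    by_norm: dict[str, list[str]] = {}
    for label in table_taxa:
        by_norm.setdefault(policy.normalize(label), []).append(label)

    mapping: dict[str, str | None] = {}
    for entry in guild.entries:
        keys = [entry.genus_name]
        if policy.use_synonyms:
            keys += list(entry.synonyms)
        hits: list[str] = []
        for key in keys:
            hits.extend(by_norm.get(policy.normalize(key), []))
        unique_hits = sorted(set(hits))
        if len(unique_hits) > 1:
            raise AmbiguousMatchError(
                f"guild genus {entry.genus_name!r} matches multiple table "
                f"labels: {unique_hits}"
            )
        mapping[entry.genus_name] = unique_hits[0] if unique_hits else None
    return mapping


def compute_eihe(
    table: TaxonCountTable,
    guild: GuildDefinition,
    policy: NameMatchPolicy = DEFAULT_POLICY,
) -> list[EIHEResult]:
    """Compute the index for every sample in the table.

    For each sample, the percent abundance of every guild genus is looked
    up (0 when absent) and the index is their sum; by construction
    0 ≤ EIHE ≤ 100.
    """
    profiles = percent_abundances(table)
    table_labels = list(table.genus_counts().index)
    mapping = match_genus_names(table_labels, guild, policy)
    matched = tuple(g for g, lbl in mapping.items() if lbl is not None)
    unmatched = tuple(g for g, lbl in mapping.items() if lbl is None)

    results = []
    for profile in profiles:
        contributions = {
            genus: (profile.genus_percents.get(label, 0.0) if label else 0.0)
            for genus, label in mapping.items()
        }
        results.append(
            EIHEResult(
                sample_name=profile.sample_name,
                eihe=sum(contributions.values()),
                contributions=contributions,
                matched=matched,
                unmatched=unmatched,
            )
        )
    return results
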