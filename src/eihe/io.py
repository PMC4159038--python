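"""Readers and writers for taxonomy count tables and index reports.

Supported inputs:

* mothur-style hierarchical taxonomy summaries (``.tax.summary``, the
  output of ``classify.seqs`` / ``summary.tax``), both multi-sample and
  demultiplexed one-sample-per-file variants;
* generic genus × sample count matrices (headered TSV).

Counts are kept as integers; percent abundances are computed on demand
and never stored in files that are read back as counts. Files are read
with any line ending and written UTF-8 with LF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .guilds import GuildDefinition
    from .index import EIHEResult

__all__ = [
    "FormatError",
    "TaxonRow",
    "TaxonCountTable",
    "read_mothur_tax_summary",
    "read_single_sample_summaries",
    "read_genus_matrix",
    "write_index_file",
    "write_contribution_table",
    "write_tax_summary",
]


class FormatError(ValueError):
    """A file violates the structural contract of its declared format."""


@dataclass
class TaxonRow:
    """One row of a hierarchical taxonomy summary.

    ``rank_id`` is the mothur dotted path ("0", "0.3", "0.3.1", ...); its
    depth (dots) equals ``tax_level``. ``counts`` maps sample name to a
    non-negative integer read count.
    """

    tax_level: int
    rank_id: str
    taxon_name: str
    daughter_levels: int
    counts: dict[str, int]


@dataclass
class TaxonCountTable:
    """Hierarchical taxon × sample read counts.

    Invariants enforced by :meth:`validate`: exactly one root row
    (tax_level 0); per sample, every count ≤ the root count; every internal
    row's count equals the sum of its immediate daughters' counts whenever
    daughters are present. ``rank_of_genus`` designates the depth at which
    genus-level abundances are read.
    """

    sample_names: list[str]
    rows: list[TaxonRow]
    rank_of_genus: int

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if not self.sample_names:
            raise FormatError("table has no samples")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise FormatError("duplicate sample names")
        roots = [r for r in self.rows if r.tax_level == 0]
        if len(roots) != 1:
            raise FormatError(
                "missing root row" if not roots else "multiple root rows"
            )
        root = roots[0]
        for row in self.rows:
            if row.rank_id.count(".") != row.tax_level:
                raise FormatError(
                    f"rank_id {row.rank_id!r} depth does not match tax_level "
                    f"{row.tax_level} for taxon {row.taxon_name!r}"
                )
            for s in self.sample_names:
                c = row.counts.get(s, 0)
                if c < 0:
                    raise FormatError(
                        f"negative count for taxon {row.taxon_name!r}, sample {s!r}"
                    )
                if c > root.counts.get(s, 0):
                    raise FormatError(
                        f"count of {row.taxon_name!r} exceeds root count in sample {s!r}"
                    )
        # hierarchical consistency: parent count == sum of daughters
        children: dict[str, list[TaxonRow]] = {}
        for row in self.rows:
            if row.tax_level == 0:
                continue
            parent = row.rank_id.rpartition(".")[0]
            children.setdefault(parent, []).append(row)
        for row in self.rows:
            kids = children.get(row.rank_id)
            if not kids:
                continue
            for s in self.sample_names:
                total = sum(k.counts.get(s, 0) for k in kids)
                if total != row.counts.get(s, 0):
                    raise FormatError(
                        f"hierarchy inconsistency at {row.taxon_name!r} "
                        f"(rank {row.rank_id}), sample {s!r}: daughters sum to "
                        f"{total}, parent has {row.counts.get(s, 0)}"
                    )

    @property
    def root(self) -> TaxonRow:
        return next(r for r in self.rows if r.tax_level == 0)

    def root_counts(self) -> dict[str, int]:
        """Total reads per sample (the denominator of percent abundances)."""
        return {s: self.root.counts.get(s, 0) for s in self.sample_names}

    def genus_rows(self) -> list[TaxonRow]:
        return [r for r in self.rows if r.tax_level == self.rank_of_genus]

    def genus_counts(self) -> pd.DataFrame:
        """Genus-level counts, aggregated by taxon name, as genus × sample.

        The same genus label can occur under several parents (notably
        ``unclassified``); counts are summed across those rows.
        """
        agg: dict[str, np.ndarray] = {}
        for row in self.genus_rows():
            vec = np.array(
                [row.counts.get(s, 0) for s in self.sample_names], dtype=np.int64
            )
            if row.taxon_name in agg:
                agg[row.taxon_name] = agg[row.taxon_name] + vec
            else:
                agg[row.taxon_name] = vec
        return pd.DataFrame.from_dict(
            agg, orient="index", columns=list(self.sample_names)
        )


_MOTHUR_COLUMNS = ["taxlevel", "rankID", "taxon", "daughterlevels", "total"]


def _as_int(value, taxon: str, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"non-numeric count {value!r} for taxon {taxon!r}, column {column!r}"
        ) from None
    if f != int(f):
        raise FormatError(
            f"non-integer count {value!r} for taxon {taxon!r}, column {column!r}"
        )
    if f < 0:
        raise FormatError(
            f"negative count {value!r} for taxon {taxon!r}, column {column!r}"
        )
    return int(f)


def read_mothur_tax_summary(
    source: TextIO | str, rank_of_genus: int | None = None
) -> TaxonCountTable:
    """Parse a mothur ``.tax.summary`` hierarchical taxonomy table.

    Columns are ``taxlevel  rankID  taxon  daughterlevels  total`` followed
    by one column per sample. The ``total`` column is recomputed as the
    per-sample row sum; a mismatch is surfaced as a warning, not an error,
    because hand-edited summaries are common. ``rank_of_genus`` defaults to
    the deepest level present.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in _MOTHUR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"taxonomy summary lacks columns: {missing}")
    sample_names = [c for c in df.columns if c not in _MOTHUR_COLUMNS]
    if not sample_names:
        raise FormatError("taxonomy summary has no sample columns")
    if len(df) == 0:
        raise FormatError("missing root row")

    rows: list[TaxonRow] = []
    for _, rec in df.iterrows():
        taxon = str(rec["taxon"])
        counts = {s: _as_int(rec[s], taxon, s) for s in sample_names}
        stated_total = _as_int(rec["total"], taxon, "total")
        if stated_total != sum(counts.values()):
            warnings.warn(
                f"stated total {stated_total} for taxon {taxon!r} differs from "
                f"per-sample sum {sum(counts.values())}; the per-sample counts are used",
                stacklevel=2,
            )
        rows.append(
            TaxonRow(
                tax_level=_as_int(rec["taxlevel"], taxon, "taxlevel"),
                rank_id=str(rec["rankID"]),
                taxon_name=taxon,
                daughter_levels=_as_int(rec["daughterlevels"], taxon, "daughterlevels"),
                counts=counts,
            )
        )
    if rank_of_genus is None:
        rank_of_genus = max(r.tax_level for r in rows)
    return TaxonCountTable(
        sample_names=sample_names, rows=rows, rank_of_genus=rank_of_genus
    )


def read_single_sample_summaries(
    sources: Sequence[tuple[str, TextIO | str]], rank_of_genus: int | None = None
) -> TaxonCountTable:
    """Merge demultiplexed one-sample taxonomy summaries into one table.

    Each source is a ``(sample_name, stream)`` pair whose stream is a valid
    single-sample ``.tax.summary``. The merged taxon set is the union across
    files (matched on the full name path from the root); taxa absent from a
    file get count 0 for that sample, and the hierarchy is re-validated
    after the merge.
    """
    names = [n for n, _ in sources]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"duplicate sample names: {sorted(dupes)}")
    if not sources:
        raise FormatError("no input files")

    # path (tuple of taxon names root->node) -> {sample: count}
    merged: dict[tuple[str, ...], dict[str, int]] = {}
    for sample, stream in sources:
        table = read_mothur_tax_summary(stream)
        if len(table.sample_names) != 1:
            raise FormatError(
                f"file for sample {sample!r} contains {len(table.sample_names)} "
                "sample columns; expected exactly one"
            )
        col = table.sample_names[0]
        by_rank = {r.rank_id: r for r in table.rows}
        seen_paths: set[tuple[str, ...]] = set()
        for row in table.rows:
            path_parts = []
            rid = row.rank_id
            while True:
                path_parts.append(by_rank[rid].taxon_name)
                parent = rid.rpartition(".")[0]
                if not parent:
                    break
                if parent not in by_rank:
                    raise FormatError(
                        f"orphan rank_id {row.rank_id!r} in sample {sample!r}"
                    )
                rid = parent
            path = tuple(reversed(path_parts))
            if path in seen_paths:
                raise FormatError(
                    f"conflicting rows for taxon path {'|'.join(path)} in "
                    f"sample {sample!r}"
                )
            seen_paths.add(path)
            merged.setdefault(path, {})[sample] = row.counts.get(col, 0)

    # rebuild a deterministic hierarchy: children numbered in sorted order
    paths = sorted(merged)
    rank_ids: dict[tuple[str, ...], str] = {}
    child_counter: dict[tuple[str, ...], int] = {}
    n_children: dict[tuple[str, ...], int] = {}
    for path in paths:
        if len(path) == 1:
            rank_ids[path] = "0"
        else:
            parent = path[:-1]
            if parent not in rank_ids:
                raise FormatError(
                    f"taxon path {'|'.join(path)} has no parent row in any input"
                )
            idx = child_counter.get(parent, 0) + 1
            child_counter[parent] = idx
            rank_ids[path] = f"{rank_ids[parent]}.{idx}"
            n_children[parent] = idx

    rows = [
        TaxonRow(
            tax_level=len(path) - 1,
            rank_id=rank_ids[path],
            taxon_name=path[-1],
            daughter_levels=n_children.get(path, 0),
            counts={s: merged[path].get(s, 0) for s in names},
        )
        for path in paths
    ]
    if rank_of_genus is None:
        rank_of_genus = max(r.tax_level for r in rows)
    return TaxonCountTable(sample_names=list(names), rows=rows, rank_of_genus=rank_of_genus)


def read_genus_matrix(source: TextIO | str) -> TaxonCountTable:
    """Read a headered genus × sample TSV into a two-level count table.

    First column: genus names; remaining columns: integer counts per
    sample. A synthetic root row holding the column sums becomes the
    percent-abundance denominator.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed genus matrix: {exc}") from exc
    if df.isna().any().any():
        raise FormatError("malformed genus matrix: ragged or missing cells")
    if len(df) == 0 or len(df.columns) == 0:
        raise FormatError("genus matrix has no data")
    sample_names = [str(c) for c in df.columns]
    genus_rows = []
    totals = {s: 0 for s in sample_names}
    for genus, rec in df.iterrows():
        counts = {s: _as_int(rec[s], str(genus), s) for s in sample_names}
        for s in sample_names:
            totals[s] += counts[s]
        genus_rows.append((str(genus), counts))
    rows = [
        TaxonRow(
            tax_level=0,
            rank_id="0",
            taxon_name="Root",
            daughter_levels=len(genus_rows),
            counts=totals,
        )
    ]
    rows += [
        TaxonRow(
            tax_level=1,
            rank_id=f"0.{i}",
            taxon_name=genus,
            daughter_levels=0,
            counts=counts,
        )
        for i, (genus, counts) in enumerate(genus_rows, start=1)
    ]
    return TaxonCountTable(sample_names=sample_names, rows=rows, rank_of_genus=1)


def _fmt(value: float, precision: str) -> str:
    if precision == "report":
        return f"{value:.1f}"
    if precision == "machine":
        return repr(float(value))
    raise ValueError(f"unknown precision mode {precision!r}")


def write_index_file(
    results: Sequence["EIHEResult"], sink: TextIO, precision: str = "report"
) -> None:
    """Write the per-sample index file: ``<sample> <value>``, one per line.

    ``precision='report'`` prints one decimal; ``'machine'`` prints full
    float precision for lossless round-trips.
    """
    if not results:
        raise ValueError("no results to write")
    for res in results:
        sink.write(f"{res.sample_name} {_fmt(res.eihe, precision)}\n")


def write_contribution_table(
    results: Sequence["EIHEResult"],
    guild: "GuildDefinition",
    sink: TextIO,
    precision: str = "report",
) -> None:
    """Write the per-genus percent-abundance table behind the index.

    Rows are all guild genera in guild order (absent genera as 0), columns
    are samples, and a final ``EIHE`` row holds the column sums — i.e. the
    index values themselves.
    """
    if not results:
        raise ValueError("no results to write")
    sink.write("genus\t" + "\t".join(r.sample_name for r in results) + "\n")
    for genus in guild.genus_names:
        cells = [_fmt(r.contributions.get(genus, 0.0), precision) for r in results]
        sink.write(genus + "\t" + "\t".join(cells) + "\n")
    sink.write("EIHE\t" + "\t".join(_fmt(r.eihe, precision) for r in results) + "\n")


def write_tax_summary(table: TaxonCountTable, sink: TextIO) -> None:
    """Write a table back out in the mothur ``.tax.summary`` dialect."""
    sink.write("\t".join(_MOTHUR_COLUMNS + list(table.sample_names)) + "\n")
    for row in table.rows:
        counts = [row.counts.get(s, 0) for s in table.sample_names]
        sink.write(
            f"{row.tax_level}\t{row.rank_id}\t{row.taxon_name}\t"
            f"{row.daughter_levels}\t{sum(counts)}\t"
            + "\t".join(str(c) for c in counts)
            + "\n"
        )
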