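"""Synthetic genus-level communities with known ground truth.

Emulates a two-condition amplicon study (pristine vs polluted sediment):
a base genus composition is drawn from a symmetric Dirichlet, a designated
guild subset is enriched by a controlled fold in the polluted condition,
and each sample is a multinomial draw at a configurable sequencing depth.
Because compositions must renormalize after enrichment, the nominal fold is
only approximate; the recorded ground truth is always the exact
post-renormalization expectation.

Generators are pure functions of their seed, so simulated studies are
bit-reproducible fixtures for the index, statistics and diversity modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .guilds import GuildDefinition, GuildGenus
from .io import TaxonCountTable, TaxonRow, write_tax_summary
from .diversity import OTUVector

__all__ = [
    "CommunitySimSpec",
    "SimulatedStudy",
    "simulate_two_group_study",
    "simulate_otu_vector",
    "write_fixture_tax_summary",
]


@dataclass(frozen=True)
class CommunitySimSpec:
    """Parameters of a simulated two-condition study.

    ``baseline_concentration`` is the symmetric Dirichlet parameter of the
    base composition; small values give skewed, realistic rank-abundance
    shapes. ``guild_baseline_proportion``, when set, rescales the base
    composition so the guild sums to exactly that proportion before
    enrichment. ``enrichment_fold`` multiplies guild proportions in the
    polluted condition (1 encodes the null). ``overdispersion``, when set,
    draws each sample's composition from a Dirichlet centered on its
    condition's composition with that concentration mass (a
    Dirichlet-multinomial sample instead of a plain multinomial).
    """

    n_genera: int = 500
    guild_size: int = 50
    baseline_concentration: float = 0.5
    enrichment_fold: float = 4.0
    depth: int = 25_000
    n_per_group: int = 1
    seed: int = 0
    guild_baseline_proportion: float | None = None
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if self.guild_size < 1:
            raise ValueError("guild_size must be >= 1")
        if self.guild_size > self.n_genera:
            raise ValueError("guild_size cannot exceed n_genera")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        if self.baseline_concentration <= 0:
            raise ValueError("baseline_concentration must be positive")
        if self.depth < 1 or self.n_per_group < 1:
            raise ValueError("depth and n_per_group must be >= 1")
        if self.guild_baseline_proportion is not None and not (
            0.0 < self.guild_baseline_proportion < 1.0
        ):
            raise ValueError("guild_baseline_proportion must be in (0, 1)")


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated study: count table, guild, and exact expectations.

    ``truth`` records, per condition, the exact post-renormalization guild
    proportion and the expected index value (100× that proportion).
    """

    table: TaxonCountTable
    guild: GuildDefinition
    truth: dict[str, dict[str, float]]
    spec: CommunitySimSpec


def _genus_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"Genus{i:0{width}d}" for i in range(1, n + 1)]


def simulate_two_group_study(spec: CommunitySimSpec) -> SimulatedStudy:
    """Simulate pristine and polluted samples from one base community.

    The first ``guild_size`` genera are the designated guild. Sample names
    are ``pristine_1..`` and ``polluted_1..``; every sample's counts sum to
    ``depth`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.dirichlet(np.full(spec.n_genera, spec.baseline_concentration))
    guild_mask = np.zeros(spec.n_genera, dtype=bool)
    guild_mask[: spec.guild_size] = True

    if spec.guild_baseline_proportion is not None:
        target = spec.guild_baseline_proportion
        g = base[guild_mask].sum()
        base = base.copy()
        base[guild_mask] *= target / g
        base[~guild_mask] *= (1.0 - target) / (1.0 - g)

    polluted = base.copy()
    polluted[guild_mask] *= spec.enrichment_fold
    polluted /= polluted.sum()

    compositions = {"pristine": base, "polluted": polluted}
    names = _genus_names(spec.n_genera)

    sample_names: list[str] = []
    columns: list[np.ndarray] = []
    for condition in ("pristine", "polluted"):
        comp = compositions[condition]
        for i in range(1, spec.n_per_group + 1):
            if spec.overdispersion is not None:
                comp_i = rng.dirichlet(comp * spec.overdispersion)
            else:
                comp_i = comp
            counts = rng.multinomial(spec.depth, comp_i)
            sample_names.append(f"{condition}_{i}")
            columns.append(counts)

    matrix = np.column_stack(columns)
    root = TaxonRow(
        tax_level=0,
        rank_id="0",
        taxon_name="Root",
        daughter_levels=spec.n_genera,
        counts={s: int(matrix[:, j].sum()) for j, s in enumerate(sample_names)},
    )
    rows = [root] + [
        TaxonRow(
            tax_level=1,
            rank_id=f"0.{i + 1}",
            taxon_name=names[i],
            daughter_levels=0,
            counts={s: int(matrix[i, j]) for j, s in enumerate(sample_names)},
        )
        for i in range(spec.n_genera)
    ]
    table = TaxonCountTable(sample_names=sample_names, rows=rows, rank_of_genus=1)

    guild = GuildDefinition(
        name="simulated-guild",
        version="1.0",
        entries=tuple(
            GuildGenus(genus_name=names[i], phylum="Simulated")
            for i in range(spec.guild_size)
        ),
    )
    truth = {
        condition: {
            "guild_proportion": float(comp[guild_mask].sum()),
            "expected_eihe": 100.0 * float(comp[guild_mask].sum()),
        }
        for condition, comp in compositions.items()
    }
    return SimulatedStudy(table=table, guild=guild, truth=truth, spec=spec)


def simulate_otu_vector(
    true_richness: int,
    shape: str = "uniform",
    depth: int = 25_000,
    seed: int = 0,
    shape_param: float | None = None,
    sample_name: str = "sim",
) -> tuple[OTUVector, dict[str, float]]:
    """Draw one OTU count vector from a community of known richness.

    ``shape='uniform'`` gives equally probable OTUs; ``'logseries'`` gives
    the classic skewed rank-abundance curve with probability ∝ θ^k/k for
    rank k (0 < θ < 1, default 0.999). The returned truth carries the true
    richness for estimator-recovery tests.
    """
    if true_richness < 1 or depth < 1:
        raise ValueError("true_richness and depth must be >= 1")
    if shape == "uniform":
        probs = np.full(true_richness, 1.0 / true_richness)
    elif shape == "logseries":
        theta = 0.999 if shape_param is None else shape_param
        if not 0.0 < theta < 1.0:
            raise ValueError("log-series parameter must lie in (0, 1)")
        k = np.arange(1, true_richness + 1, dtype=float)
        probs = theta**k / k
        probs /= probs.sum()
    else:
        raise ValueError(f"unknown abundance model {shape!r}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, probs)
    vector = OTUVector(
        sample_name=sample_name, counts=tuple(int(c) for c in counts if c > 0)
    )
    return vector, {"true_richness": float(true_richness)}


def write_fixture_tax_summary(study: SimulatedStudy, sink: TextIO) -> None:
    """Emit the study's table as a mothur-dialect ``.tax.summary`` fixture.

    The written file round-trips losslessly through
    :func:`eihe.io.read_mothur_tax_summary`.
    """
    write_tax_summary(study.table, sink)
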