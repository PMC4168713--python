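"""Community abundance-profile generation.

Two routes are provided, mirroring how simulated metagenome compositions are
built in practice:

* a fast parametric route that assigns rank-abundance values from a power
  law ``abundance(r) proportional to r**(-gamma)`` at three preset community
  complexities (low / medium / high), and
* a homology route that turns a taxonomy-annotated hit table (query id,
  bit score, lineage) into per-species read counts via lowest-common-ancestor
  (LCA) assignment, keeping for each query only the hits whose bit score
  lies within a configurable neighborhood of that query's best score.

A *low*-complexity community has a few dominant species (steep decay, large
gamma); a *high*-complexity community has no dominant species (shallow
decay, small gamma).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import AbundanceProfile, FormatError, HitRecord

__all__ = [
    "PowerLawParams",
    "TaxAssignment",
    "DEFAULT_GAMMAS",
    "DEFAULT_NEIGHBORHOOD",
    "DEFAULT_SPECIES_DEPTH",
    "generate_power_profile",
    "lca",
    "assign_taxonomy",
    "profile_from_assignments",
]

#: Default decay exponents per complexity preset.  These are this package's
#: defaults (user-overridable); steeper decay = fewer dominant species.
DEFAULT_GAMMAS = {"low": 1.5, "medium": 1.0, "high": 0.5}

#: Keep hits scoring at least this fraction of the per-query best bit score.
DEFAULT_NEIGHBORHOOD = 0.9

#: 0-based lineage index of the species rank under the common 7-rank
#: (domain..species) convention.
DEFAULT_SPECIES_DEPTH = 6


@dataclass
class PowerLawParams:
    """Decay exponent of the rank-abundance power law."""

    gamma: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


@dataclass
class TaxAssignment:
    """LCA taxonomic assignment of one query read."""

    query_id: str
    lineage: list[str]
    species: Optional[str] = None


def generate_power_profile(
    genome_ids: Sequence[str],
    complexity: str = "medium",
    params: Optional[PowerLawParams] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    shuffle: bool = False,
) -> AbundanceProfile:
    """Assign power-law abundances to genomes by rank.

    The rank-r genome receives abundance proportional to ``r**(-gamma)``
    (r = 1 for the first genome), normalised to sum to 1.  Ranks follow the
    input order unless ``shuffle`` is set (then ``rng`` is required).
    """
    ids = list(genome_ids)
    if not ids:
        raise ValueError("need at least one genome id")
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique")
    if params is None:
        if complexity not in DEFAULT_GAMMAS:
            raise ValueError(
                f"complexity must be one of {sorted(DEFAULT_GAMMAS)}, got {complexity!r}"
            )
        params = PowerLawParams(gamma=DEFAULT_GAMMAS[complexity], label=complexity)
    if shuffle:
        if rng is None:
            raise ValueError("shuffle=True requires an rng")
        ids = list(ids)
        rng.shuffle(ids)
    ranks = np.arange(1, len(ids) + 1, dtype=float)
    weights = ranks ** (-params.gamma)
    weights /= weights.sum()
    return AbundanceProfile(entries=list(zip(ids, weights.tolist())))


def lca(lineages: Sequence[Sequence[str]]) -> list[str]:
    """Longest common root-first prefix of the given lineages.

    Disjoint lineages yield the empty list, meaning "unclassified/root".
    """
    if not lineages:
        raise ValueError("lca of an empty set of lineages is undefined")
    prefix = list(lineages[0])
    for lineage in lineages[1:]:
        depth = 0
        for a, b in zip(prefix, lineage):
            if a != b:
                break
            depth += 1
        prefix = prefix[:depth]
        if not prefix:
            break
    return prefix


def assign_taxonomy(
    hits: Sequence[HitRecord],
    neighborhood: float = DEFAULT_NEIGHBORHOOD,
    *,
    species_depth: int = DEFAULT_SPECIES_DEPTH,
) -> list[TaxAssignment]:
    """LCA-assign each query from its bit-score-filtered hits.

    For every query, hits with ``bit_score >= neighborhood * best`` (best =
    that query's maximum) are retained and the assignment is the LCA of the
    retained lineages.  Queries appear in first-seen order.
    """
    if not 0 < neighborhood <= 1:
        raise ValueError(f"neighborhood must be in (0, 1], got {neighborhood}")
    by_query: "OrderedDict[str, list[HitRecord]]" = OrderedDict()
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    assignments = []
    for query_id, query_hits in by_query.items():
        best = max(h.bit_score for h in query_hits)
        kept = [h for h in query_hits if h.bit_score >= neighborhood * best]
        lineage = lca([h.lineage for h in kept])
        assignments.append(
            TaxAssignment(
                query_id=query_id,
                lineage=lineage,
                species=_species_of(lineage, species_depth),
            )
        )
    return assignments


def profile_from_assignments(
    assignments: Sequence[TaxAssignment],
) -> tuple[AbundanceProfile, int]:
    """Count species-level assignments into an abundance profile.

    Assignments not resolved to species level are dropped; the number dropped
    is returned alongside the profile.  Species are ordered by decreasing
    abundance (ties by name) to match the rank-abundance convention.
    """
    counts: dict[str, int] = {}
    dropped = 0
    for a in assignments:
        if a.species is None:
            dropped += 1
        else:
            counts[a.species] = counts.get(a.species, 0) + 1
    if not counts:
        raise FormatError(
            "no query resolved to species level; cannot build an abundance "
            "profile (all assignments were above the species rank)"
        )
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    profile = AbundanceProfile(entries=[(s, c / total) for s, c in ordered])
    return profile, dropped


def _species_of(lineage: Sequence[str], species_depth: int) -> Optional[str]:
    """Species label of a lineage, or None if not resolved that deep.

    A lineage reaches species level when it is deeper than ``species_depth``
    ranks, or when its terminal rank carries an explicit ``s__`` tag.
    """
    if lineage and lineage[-1].startswith("s__"):
        return lineage[-1]
    if len(lineage) > species_depth:
        return lineage[species_depth]
    return None
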