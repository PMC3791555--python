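"""High-quality chaperone–substrate network from multi-source interaction data.

Affinity pull-down interaction datasets carry substantial false-positive
rates.  Three filters produce a conservative chaperone–substrate set from
BioGRID-like, MIPS-like and STRING-like edge lists:

1. drop chaperone–chaperone pairs (largely co-chaperone contacts, not
   substrates) and pairs touching no chaperone at all;
2. for directed bait–prey evidence, keep a pair only when the reciprocal
   observation exists within the same source dataset;
3. for score-bearing (STRING-like) sources, keep only high-confidence
   edges (score strictly above 0.7).

The per-source survivors are merged by set union into one undirected
chaperone–substrate network with provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: sources whose edges are directed bait→prey observations; reciprocity applies
DIRECTED_SOURCES = frozenset({"biogrid-like", "mips-like"})
#: sources carrying a confidence score; edges are inherently undirected
SCORED_SOURCES = frozenset({"string-like"})


@dataclass(frozen=True)
class InteractionEdge:
    """One observed bait→prey interaction from one source dataset."""

    bait: str
    prey: str
    source: str
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.bait == self.prey:
            raise ValueError("self-interaction edges are not allowed")
        if self.source in SCORED_SOURCES:
            if self.confidence is None:
                raise ValueError(f"{self.source} edge requires a confidence score")
            if not 0.0 <= self.confidence <= 1.0:
                raise ValueError("confidence must lie in [0, 1]")
        elif self.confidence is not None:
            raise ValueError(f"{self.source} edges carry no confidence score")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.bait, self.prey)))


@dataclass
class ChaperoneNetwork:
    """Undirected, deduplicated chaperone–substrate network."""

    chaperones: set[str]
    edges: set[tuple[str, str]]  # (chaperone_orf, substrate_orf)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def substrates(self) -> set[str]:
        return {s for _, s in self.edges}

    @property
    def active_chaperones(self) -> set[str]:
        """Chaperones with at least one substrate."""
        return {c for c, _ in self.edges}

    def targets(self, chaperone: str) -> set[str]:
        if chaperone not in self.chaperones:
            raise KeyError(f"unknown chaperone {chaperone!r}")
        return {s for c, s in self.edges if c == chaperone}

    def target_lists(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {c: set() for c in self.chaperones}
        for c, s in self.edges:
            out[c].add(s)
        return out

    def chaperones_of(self, substrate: str) -> set[str]:
        return {c for c, s in self.edges if s == substrate}

    def summary(self) -> dict[str, int]:
        return {
            "chaperones_with_targets": len(self.active_chaperones),
            "substrates": len(self.substrates),
            "interactions": len(self.edges),
        }


def dedupe_directed(edges: Iterable[InteractionEdge]) -> list[InteractionEdge]:
    """Collapse duplicate directed observations (per source) to one.

    For score-bearing sources the highest-confidence observation wins.
    """
    best: dict[tuple[str, str, str], InteractionEdge] = {}
    order: list[tuple[str, str, str]] = []
    for e in edges:
        key = (e.bait, e.prey, e.source)
        if key not in best:
            best[key] = e
            order.append(key)
        elif (e.confidence or 0.0) > (best[key].confidence or 0.0):
            best[key] = e
    return [best[k] for k in order]


def filter_chaperone_pairs(
    edges: Sequence[InteractionEdge], chaperones: set[str]
) -> list[InteractionEdge]:
    """Keep only edges linking exactly one chaperone to a non-chaperone."""
    if not chaperones:
        raise ValueError("chaperone set is empty")
    return [e for e in edges if (e.bait in chaperones) != (e.prey in chaperones)]


def filter_reciprocal(
    edges: Sequence[InteractionEdge],
    within_source: bool = True,
    exempt_scored: bool = True,
) -> list[InteractionEdge]:
    """Keep directed-evidence edges whose reverse was also observed.

    Reciprocity is assessed within one source dataset by default: the pair
    {a, b} survives iff both a→b and b→a occur in the same source
    (``within_source=False`` counts the reverse observation from any
    source).  Score-bearing sources are inherently undirected so their
    edges are exempt unless ``exempt_scored=False`` (strict mode).
    """
    if within_source:
        directed = {(e.bait, e.prey, e.source) for e in edges}
        reverse = lambda e: (e.prey, e.bait, e.source)
    else:
        directed = {(e.bait, e.prey) for e in edges}
        reverse = lambda e: (e.prey, e.bait)
    out = []
    for e in edges:
        if e.source in SCORED_SOURCES and exempt_scored:
            out.append(e)
        elif reverse(e) in directed:
            out.append(e)
    return out


def filter_confidence(
    edges: Sequence[InteractionEdge], threshold: float = 0.7
) -> list[InteractionEdge]:
    """Keep score-bearing edges strictly above the confidence threshold."""
    out = []
    for e in edges:
        if e.source in SCORED_SOURCES:
            if e.confidence is None:
                raise ValueError("scored edge missing confidence")
            if e.confidence > threshold:
                out.append(e)
        else:
            out.append(e)
    return out


def build_hq_network(
    sources: Sequence[Sequence[InteractionEdge]],
    chaperones: set[str],
    confidence_threshold: float = 0.7,
    strict_reciprocity: bool = False,
) -> ChaperoneNetwork:
    """Filter each source and union the survivors into one network.

    Per source: chaperone-pair filter → reciprocity filter → confidence
    filter; surviving directed observations collapse to undirected
    (chaperone, substrate) pairs, then the per-source pair sets are merged
    by set union with per-pair provenance.
    """
    if not sources:
        raise ValueError("need at least one source")
    pairs: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], set[str]] = {}
    for source_edges in sources:
        filtered = dedupe_directed(source_edges)
        filtered = filter_chaperone_pairs(filtered, chaperones)
        filtered = filter_reciprocal(filtered, exempt_scored=not strict_reciprocity)
        filtered = filter_confidence(filtered, threshold=confidence_threshold)
        for e in filtered:
            chap = e.bait if e.bait in chaperones else e.prey
            sub = e.prey if e.bait in chaperones else e.bait
            pairs.add((chap, sub))
            provenance.setdefault((chap, sub), set()).add(e.source)
    return ChaperoneNetwork(chaperones=set(chaperones), edges=pairs, provenance=provenance)
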