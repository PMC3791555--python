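"""Abundance-weighted subcellular localisation profiles and enrichment tests.

Proteins annotated to several compartments are split pro rata between them,
weighted either by count (each protein = 1), by abundance (copies per
cell), or by synthesis flux.  Per-class profiles over chaperone substrates
expose localisation specialisation, tested per compartment with the
EASE-modified one-sided Fisher exact test (overlap decremented by one gene,
a conservative variant standard in gene-set enrichment) and across classes
with Kruskal–Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom, kruskal

from .flux import ProteinRecord
from .interactome import ChaperoneNetwork

_BASES = ("count", "abundance", "flux")


@dataclass
class LocalisationProfile:
    """Normalised location→fraction weights for one scope."""

    weights: dict[str, float]
    basis: str
    scope: str
    n_unassigned: int = 0

    def collapsed(self, min_fraction: float = 0.02) -> dict[str, float]:
        """Reporting view: locations below ``min_fraction`` pooled as 'other'."""
        out: dict[str, float] = {}
        other = 0.0
        for loc, w in self.weights.items():
            if w < min_fraction:
                other += w
            else:
                out[loc] = w
        if other > 0:
            out["other"] = other
        return dict(sorted(out.items(), key=lambda kv: -kv[1]))


def _weight(record: ProteinRecord, basis: str) -> float:
    if basis == "count":
        return 1.0
    if basis == "abundance":
        return record.cpc or 0.0
    if basis == "flux":
        return record.k_syn or 0.0
    raise ValueError(f"unknown basis {basis!r}")


def pro_rata_profile(
    records: list[ProteinRecord], basis: str = "count", scope: str = "proteome"
) -> LocalisationProfile:
    """Location profile with multi-locus proteins split equally across loci.

    Each protein contributes w/|loci| to each of its annotated loci, where
    w is 1, cpc, or k_syn depending on ``basis``; the profile is normalised
    to sum to 1.  Proteins without loci are counted as unassigned and
    excluded from the normalisation.
    """
    if basis not in _BASES:
        raise ValueError(f"basis must be one of {_BASES}")
    if not records:
        raise ValueError("no records supplied")
    weights: dict[str, float] = {}
    n_unassigned = 0
    for r in records:
        if not r.loci:
            n_unassigned += 1
            continue
        w = _weight(r, basis) / len(r.loci)
        for loc in sorted(r.loci):
            weights[loc] = weights.get(loc, 0.0) + w
    total = sum(weights.values())
    if total > 0:
        weights = {k: v / total for k, v in weights.items()}
    return LocalisationProfile(
        weights=dict(sorted(weights.items())), basis=basis, scope=scope,
        n_unassigned=n_unassigned,
    )


def class_profiles(
    network: ChaperoneNetwork,
    records: dict[str, ProteinRecord],
    basis: str = "abundance",
    classes: dict[str, str] | None = None,
) -> dict[str, LocalisationProfile]:
    """Per-class localisation profile over each class's substrate set.

    Profiles are conditional on the class: a substrate shared between
    classes contributes its full weight to each class's own profile (no
    partitioning between classes here).
    """
    if classes is None:
        classes = {
            o: r.chaperone_class
            for o, r in records.items()
            if r.chaperone_class is not None
        }
    class_targets: dict[str, set[str]] = {}
    for chap in network.active_chaperones:
        cls = classes.get(chap)
        if cls is None:
            raise ValueError(f"chaperone {chap!r} has no class")
        class_targets.setdefault(cls, set()).update(network.targets(chap))
    out: dict[str, LocalisationProfile] = {}
    for cls, targets in sorted(class_targets.items()):
        recs = [records[t] for t in sorted(targets) if t in records]
        if not recs:
            out[cls] = LocalisationProfile({}, basis=basis, scope=f"class:{cls}")
            continue
        prof = pro_rata_profile(recs, basis=basis, scope=f"class:{cls}")
        out[cls] = prof
    return out


def ease_test(overlap: int, list_size: int, category_size: int, background: int) -> float:
    """EASE-modified one-sided Fisher exact p-value for enrichment.

    The classical test asks how likely it is to draw at least ``overlap``
    members of a category of ``category_size`` when sampling ``list_size``
    genes from ``background``.  EASE removes one gene from the overlap cell
    before computing the tail, which penalises enrichments supported by
    very few genes; an overlap of 0 or 1 is never significant (p = 1).
    """
    if not (0 <= overlap <= min(list_size, category_size) <= background):
        raise ValueError("inconsistent 2x2 table counts")
    if list_size > background or category_size > background:
        raise ValueError("list/category larger than background")
    if overlap <= 1:
        return 1.0
    k = overlap - 1
    # P(X >= k) for X ~ Hypergeom(background, category_size, list_size)
    return float(hypergeom.sf(k - 1, background, category_size, list_size))


def class_enrichment(
    network: ChaperoneNetwork,
    records: dict[str, ProteinRecord],
    classes: dict[str, str] | None = None,
) -> list[dict]:
    """EASE enrichment of each class's substrate set in each location.

    The background is the set of proteins with both localisation and
    abundance data.  A protein counts toward a location if any of its loci
    match (no pro-rata split for the categorical test).  Bonferroni
    adjustment is applied over all (class, location) tests.
    """
    if classes is None:
        classes = {
            o: r.chaperone_class
            for o, r in records.items()
            if r.chaperone_class is not None
        }
    background = {
        o for o, r in records.items() if r.loci and r.cpc is not None
    }
    locations = sorted({loc for o in background for loc in records[o].loci})
    class_targets: dict[str, set[str]] = {}
    for chap in network.active_chaperones:
        class_targets.setdefault(classes[chap], set()).update(
            network.targets(chap) & background
        )
    rows = []
    for cls, targets in sorted(class_targets.items()):
        for loc in locations:
            in_loc = {o for o in background if loc in records[o].loci}
            overlap = len(targets & in_loc)
            p = ease_test(overlap, len(targets), len(in_loc), len(background))
            rows.append({
                "chaperone_class": cls, "location": loc, "overlap": overlap,
                "list_size": len(targets), "category_size": len(in_loc),
                "background": len(background), "p": p,
            })
    n_tests = len(rows)
    for row in rows:
        row["p_adjusted"] = min(1.0, row["p"] * n_tests)
    return rows


def per_chaperone_profiles(
    network: ChaperoneNetwork,
    records: dict[str, ProteinRecord],
    basis: str = "abundance",
) -> dict[str, LocalisationProfile]:
    """Localisation profile of each individual chaperone's substrate set."""
    out = {}
    for chap in sorted(network.active_chaperones):
        recs = [records[t] for t in sorted(network.targets(chap)) if t in records]
        if recs:
            out[chap] = pro_rata_profile(recs, basis=basis, scope=f"chaperone:{chap}")
    return out


def specialisation_test(
    per_chaperone: dict[str, LocalisationProfile],
    classes: dict[str, str],
) -> dict:
    """Kruskal–Wallis test of class specialisation in substrate localisation.

    For each location, per-chaperone fractional target weight at that
    location is compared across classes; per-location p-values are
    Bonferroni-adjusted, and the overall p is the smallest adjusted
    per-location p (union–intersection: classes differ somewhere).
    Requires at least two classes with two or more chaperones each.
    """
    groups: dict[str, list[str]] = {}
    for chap in per_chaperone:
        cls = classes.get(chap)
        if cls is None:
            raise ValueError(f"chaperone {chap!r} has no class")
        groups.setdefault(cls, []).append(chap)
    usable = {cls: chaps for cls, chaps in groups.items() if len(chaps) >= 2}
    if len(usable) < 2:
        raise ValueError("need >=2 classes with >=2 chaperones each")

    locations = sorted({
        loc for prof in per_chaperone.values() for loc in prof.weights
    })
    per_location = {}
    n_tests = 0
    for loc in locations:
        samples = [
            [per_chaperone[c].weights.get(loc, 0.0) for c in chaps]
            for chaps in usable.values()
        ]
        flat = [v for s in samples for v in s]
        if len(set(flat)) == 1:  # identical values: no variation, H undefined
            per_location[loc] = {"H": 0.0, "p": 1.0}
            n_tests += 1
            continue
        h, p = kruskal(*samples)
        per_location[loc] = {"H": float(h), "p": float(p)}
        n_tests += 1
    for loc, res in per_location.items():
        res["p_adjusted"] = min(1.0, res["p"] * n_tests)
    overall_p = min((r["p_adjusted"] for r in per_location.values()), default=1.0)
    return {"per_location": per_location, "overall_p": overall_p,
            "classes_tested": sorted(usable)}
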