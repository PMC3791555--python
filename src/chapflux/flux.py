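"""Steady-state folding workload, efficiency, and class-level throughput.

Under the steady-state assumption, each protein's synthesis flux equals its
degradation flux, k_syn = k_deg * abundance (copies/cell/minute).  Summing
the abundance of a chaperone's substrates gives its substrate *volume* V_c;
summing their synthesis fluxes gives its *workload* F_c, the molecules per
minute whose folding that chaperone mediates.  Dividing F_c by the
chaperone's own copy number yields a per-copy *efficiency*.  When a
substrate has several chaperone "parents" its flux is shared pro rata.

Degradation rates are first-order, from half-lives (k = ln 2 / t_half);
proteins without turnover data receive the geometric-mean rate of the
measured proteome.  Growth dilution is ignored by default but can be added
as a constant rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .interactome import ChaperoneNetwork

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: abundance, turnover, localisation, essentiality."""

    orf: str
    cpc: float | None = None
    k_deg: float | None = None  # per minute; None = not measured
    loci: frozenset[str] = frozenset()
    essential: bool = False
    chaperone_class: str | None = None
    gene: str = ""

    def __post_init__(self) -> None:
        if self.cpc is not None and self.cpc < 0:
            raise ValueError("cpc must be >= 0")
        if self.k_deg is not None and self.k_deg < 0:
            raise ValueError("k_deg must be >= 0")

    @property
    def k_syn(self) -> float | None:
        """Steady-state synthesis flux in copies/cell/minute."""
        if self.cpc is None or self.k_deg is None:
            return None
        return self.cpc * self.k_deg


def kdeg_from_half_life(t_half: float, dilution_rate: float = 0.0) -> float:
    """First-order degradation rate from a half-life in minutes.

    ``dilution_rate`` optionally adds a constant (per minute) for growth
    dilution in a dividing culture.
    """
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return LN2 / t_half + dilution_rate


def impute_kdeg(records: dict[str, ProteinRecord]) -> dict[str, ProteinRecord]:
    """Fill missing degradation rates with the geometric mean of measured ones.

    Turnover rates span orders of magnitude and are roughly log-normal, so
    the geometric mean is the natural central value.  Observed rates are
    left untouched.
    """
    observed = [r.k_deg for r in records.values() if r.k_deg is not None and r.k_deg > 0]
    if not observed:
        raise ValueError("no observed degradation rates to impute from")
    gm = float(gmean(observed))
    return {
        orf: (r if r.k_deg is not None else replace(r, k_deg=gm))
        for orf, r in records.items()
    }


def synthesis_rate(cpc: float, k_deg: float) -> float:
    """k_syn = k_deg * abundance (copies/cell/minute at steady state)."""
    if cpc < 0 or k_deg < 0:
        raise ValueError("cpc and k_deg must be >= 0")
    return cpc * k_deg


def substrate_volume(
    network: ChaperoneNetwork, abundances: dict[str, float], chaperone: str
) -> tuple[float, int, int]:
    """Total substrate abundance V_c for one chaperone.

    Returns (V_c, n_with_data, n_substrates); substrates lacking abundance
    data are skipped and show up in the coverage counts.
    """
    targets = sorted(network.targets(chaperone))
    with_data = [abundances[s] for s in targets if s in abundances]
    return float(sum(with_data)), len(with_data), len(targets)


def substrate_flux(
    network: ChaperoneNetwork,
    records: dict[str, ProteinRecord],
    chaperone: str,
    share_mode: str = "equal_split",
) -> float:
    """Total substrate synthesis flux F_c for one chaperone.

    ``full`` attributes each substrate's whole k_syn to every interacting
    chaperone; ``equal_split`` divides it equally among the substrate's
    chaperones first (pro-rata sharing), so that summing F_c over all
    chaperones conserves the total substrate flux.
    """
    if share_mode not in ("full", "equal_split"):
        raise ValueError(f"unknown share_mode {share_mode!r}")
    total = 0.0
    for s in sorted(network.targets(chaperone)):
        rec = records.get(s)
        if rec is None or rec.k_syn is None:
            continue
        flux = rec.k_syn
        if share_mode == "equal_split":
            flux /= len(network.chaperones_of(s))
        total += flux
    return total


def efficiency(f_c: float, chaperone_cpc: float) -> tuple[float, float | None]:
    """Per-copy workload: F_c / chaperone abundance, and its log2.

    Zero flux gives efficiency 0 with an undefined (None) log2.
    """
    if chaperone_cpc <= 0:
        raise ValueError("chaperone_cpc must be positive")
    eff = f_c / chaperone_cpc
    return eff, (math.log2(eff) if eff > 0 else None)


def flux_table(
    network: ChaperoneNetwork,
    records: dict[str, ProteinRecord],
    share_mode: str = "equal_split",
) -> pd.DataFrame:
    """Per-chaperone workload table over the whole network.

    Columns: gene, chaperone_class, chaperone_cpc, n_substrates (with
    abundance data), n_targets (all network targets), substrate_volume_cpc,
    substrate_flux_cpc_per_min, efficiency, log2_efficiency.  Sorted by
    flux descending, ties broken by ORF name ascending.
    """
    abundances = {o: r.cpc for o, r in records.items() if r.cpc is not None}
    rows = []
    for chap in sorted(network.chaperones):
        v_c, n_data, n_targets = substrate_volume(network, abundances, chap)
        f_c = substrate_flux(network, records, chap, share_mode=share_mode)
        rec = records.get(chap)
        cpc = rec.cpc if rec is not None else None
        if cpc is not None and cpc > 0:
            eff, log2_eff = efficiency(f_c, cpc)
        else:
            eff, log2_eff = np.nan, None
        rows.append({
            "orf": chap,
            "gene": rec.gene if rec is not None else "",
            "chaperone_class": (rec.chaperone_class or "") if rec is not None else "",
            "chaperone_cpc": cpc,
            "n_substrates": n_data,
            "n_targets": n_targets,
            "substrate_volume_cpc": v_c,
            "substrate_flux_cpc_per_min": f_c,
            "efficiency": eff,
            "log2_efficiency": log2_eff if log2_eff is not None else np.nan,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["substrate_flux_cpc_per_min", "orf"], ascending=[False, True]
    ).reset_index(drop=True)
    df.index = pd.RangeIndex(1, len(df) + 1, name="rank")
    return df


def workload_table(
    network: ChaperoneNetwork,
    records: dict[str, ProteinRecord],
    top_k: int = 15,
    share_mode: str = "equal_split",
) -> pd.DataFrame:
    """Top-``top_k`` chaperones ranked by total substrate flux F_c."""
    return flux_table(network, records, share_mode=share_mode).head(top_k)


@dataclass
class ClassBreakdown:
    """Chaperone-mediated fractions of the proteome and per-class shares."""

    # fraction of proteome that is chaperone-mediated, by measure;
    # denominators: all records ("all") vs records with abundance ("quantified")
    mediated_fraction: dict[str, dict[str, float]] = field(default_factory=dict)
    # within the chaperone-mediated portion, per-class pro-rata shares
    class_share: dict[str, dict[str, float]] = field(default_factory=dict)
    # essentiality cross-fractions
    essential: dict[str, float] = field(default_factory=dict)


def class_fractions(
    network: ChaperoneNetwork,
    records: dict[str, ProteinRecord],
    classes: dict[str, str] | None = None,
    per_chaperone_weighting: bool = False,
) -> ClassBreakdown:
    """Class-level throughput with pro-rata sharing between classes.

    A protein is chaperone-mediated iff it appears as a substrate in the
    network.  Within the chaperone-mediated totals, each substrate's count,
    abundance and flux are split equally among the *distinct classes*
    targeting it (or, with ``per_chaperone_weighting``, in proportion to
    the number of that class's chaperones targeting it).
    """
    if classes is None:
        classes = {
            o: r.chaperone_class
            for o, r in records.items()
            if r.chaperone_class is not None
        }
    for chap in network.active_chaperones:
        if chap not in classes:
            raise ValueError(f"chaperone {chap!r} has no class")

    substrates = network.substrates
    measures = {"count": lambda r: 1.0,
                "volume": lambda r: r.cpc or 0.0,
                "flux": lambda r: r.k_syn or 0.0}

    mediated_fraction: dict[str, dict[str, float]] = {}
    for m, weight in measures.items():
        tot_all = sum(weight(r) for r in records.values())
        quant = [r for r in records.values() if r.cpc is not None]
        tot_q = sum(weight(r) for r in quant)
        med = sum(weight(r) for o, r in records.items() if o in substrates)
        mediated_fraction[m] = {
            "all": med / tot_all if tot_all else 0.0,
            "quantified": med / tot_q if tot_q else 0.0,
        }

    class_share: dict[str, dict[str, float]] = {m: {} for m in measures}
    totals = {m: 0.0 for m in measures}
    for s in sorted(substrates):
        rec = records.get(s)
        if rec is None:
            continue
        chaps = sorted(network.chaperones_of(s))
        if per_chaperone_weighting:
            cls_w: dict[str, float] = {}
            for c in chaps:
                cls_w[classes[c]] = cls_w.get(classes[c], 0.0) + 1.0
        else:
            cls_w = {cls: 1.0 for cls in sorted({classes[c] for c in chaps})}
        wsum = sum(cls_w.values())
        for m, weight in measures.items():
            w = weight(rec)
            totals[m] += w
            for cls, cw in cls_w.items():
                class_share[m][cls] = class_share[m].get(cls, 0.0) + w * cw / wsum
    for m in measures:
        if totals[m] > 0:
            class_share[m] = {k: v / totals[m] for k, v in class_share[m].items()}

    ess: dict[str, float] = {}
    for m, weight in measures.items():
        tot_all = sum(weight(r) for r in records.values())
        med_ess = sum(
            weight(r) for o, r in records.items() if o in substrates and r.essential
        )
        free_ess = sum(
            weight(r) for o, r in records.items() if o not in substrates and r.essential
        )
        tot_ess = med_ess + free_ess
        ess[f"mediated_essential_{m}"] = med_ess / tot_all if tot_all else 0.0
        ess[f"unmediated_essential_{m}"] = free_ess / tot_all if tot_all else 0.0
        # same numerators as fractions of the essential subset itself
        ess[f"unmediated_essential_{m}_of_essential"] = (
            free_ess / tot_ess if tot_ess else 0.0
        )

    return ClassBreakdown(
        mediated_fraction=mediated_fraction,
        class_share={m: dict(sorted(v.items())) for m, v in class_share.items()},
        essential=ess,
    )
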