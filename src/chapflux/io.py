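"""TSV/YAML dialects shared by the analysis stages.

All on-disk formats are plain tab-separated text so that synthetic data,
packaged fixtures and user data interchange freely:

* SRM measurements: orf, peptide_id, replicate, ratio, spike_fmol,
  cells_loaded, snr, fdr_pass, standard_detected
* proteome: orf, gene, cpc, t_half_min, k_deg_per_min, essential, loci,
  chaperone_class
* interaction edges (one file per source): bait, prey, source, confidence
* abundance dataset: orf, abundance (+ a YAML manifest of name/unit)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .abundance import AbundanceDataset
from .flux import ProteinRecord, kdeg_from_half_life
from .interactome import InteractionEdge
from .srm import ChaperoneQuant, PeptideMeasurement


def _fmt(x: float) -> str:
    """Stable float formatting so re-runs are byte-identical."""
    return format(float(x), ".10g")


# ---------------------------------------------------------------- SRM tables

def write_srm_measurements(path: str | Path, measurements: Iterable[PeptideMeasurement]) -> None:
    rows = [{
        "orf": m.orf, "peptide_id": m.peptide_id, "replicate": m.replicate,
        "ratio": _fmt(m.ratio_light_heavy), "spike_fmol": _fmt(m.spike_fmol),
        "cells_loaded": _fmt(m.cells_loaded), "snr": _fmt(m.snr),
        "fdr_pass": int(m.fdr_pass), "standard_detected": int(m.standard_detected),
    } for m in measurements]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_srm_measurements(path: str | Path) -> list[PeptideMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideMeasurement(
            orf=r.orf, peptide_id=r.peptide_id, replicate=int(r.replicate),
            ratio_light_heavy=float(r.ratio), spike_fmol=float(r.spike_fmol),
            cells_loaded=float(r.cells_loaded), snr=float(r.snr),
            fdr_pass=bool(r.fdr_pass),
            standard_detected=bool(getattr(r, "standard_detected", True)),
        )
        for r in df.itertuples()
    ]


def write_protein_quants(path: str | Path, quants: Iterable[ChaperoneQuant]) -> None:
    rows = [{
        "chaperone_class": q.chaperone_class, "gene": q.gene_name, "orf": q.orf,
        "cpc": "" if q.cpc is None else _fmt(q.cpc),
        "sem": "" if q.sem is None else _fmt(q.sem),
        "qtype": "/".join(q.peptide_statuses) if q.peptide_statuses else q.qtype,
        "bound_cpc": "" if q.bound_cpc is None else _fmt(q.bound_cpc),
    } for q in quants]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- proteome TSV

def write_proteome(path: str | Path, records: dict[str, ProteinRecord]) -> None:
    rows = []
    for orf in sorted(records):
        r = records[orf]
        rows.append({
            "orf": r.orf, "gene": r.gene,
            "cpc": "" if r.cpc is None else _fmt(r.cpc),
            "k_deg_per_min": "" if r.k_deg is None else _fmt(r.k_deg),
            "essential": int(r.essential),
            "loci": ",".join(sorted(r.loci)),
            "chaperone_class": r.chaperone_class or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_proteome(path: str | Path) -> dict[str, ProteinRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"loci": str, "chaperone_class": str,
                                            "gene": str})
    records: dict[str, ProteinRecord] = {}
    for r in df.itertuples():
        k_deg = None if pd.isna(r.k_deg_per_min) else float(r.k_deg_per_min)
        if k_deg is None and "t_half_min" in df.columns and not pd.isna(r.t_half_min):
            k_deg = kdeg_from_half_life(float(r.t_half_min))
        loci = frozenset() if pd.isna(r.loci) or not r.loci else frozenset(
            str(r.loci).split(","))
        cls = None if pd.isna(r.chaperone_class) or not r.chaperone_class else str(
            r.chaperone_class)
        records[r.orf] = ProteinRecord(
            orf=r.orf, gene="" if pd.isna(r.gene) else str(r.gene),
            cpc=None if pd.isna(r.cpc) else float(r.cpc),
            k_deg=k_deg, essential=bool(r.essential), loci=loci,
            chaperone_class=cls,
        )
    return records


# ------------------------------------------------------------------ edges

def write_edges(path: str | Path, edges: Iterable[InteractionEdge]) -> None:
    rows = [{
        "bait": e.bait, "prey": e.prey, "source": e.source,
        "confidence": "" if e.confidence is None else _fmt(e.confidence),
    } for e in edges]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> list[InteractionEdge]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        conf = None if pd.isna(r.confidence) else float(r.confidence)
        out.append(InteractionEdge(bait=r.bait, prey=r.prey, source=r.source,
                                   confidence=conf))
    return out


def write_network(path: str | Path, edges, provenance) -> None:
    rows = [{
        "chaperone_orf": c, "substrate_orf": s,
        "sources": ";".join(sorted(provenance.get((c, s), set()))),
    } for c, s in sorted(edges)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_network_edges(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {(r.chaperone_orf, r.substrate_orf) for r in df.itertuples()}


# -------------------------------------------------------------- abundances

def read_abundance_dataset(path: str | Path, name: str, unit: str,
                           total_copies: float = 6.0e7) -> AbundanceDataset:
    df = pd.read_csv(path, sep="\t")
    values = {r.orf: float(r.abundance) for r in df.itertuples()}
    return AbundanceDataset(name=name, unit=unit, values=values,
                            total_copies_assumption=total_copies)


def write_abundance_dataset(path: str | Path, dataset: AbundanceDataset) -> None:
    rows = [{"orf": k, "abundance": _fmt(v)}
            for k, v in sorted(dataset.values.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- JSON

def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
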