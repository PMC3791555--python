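"""Protein-level copies-per-cell from SRM/QconCAT peptide measurements.

Absolute quantification by selected reaction monitoring against a spiked
heavy-labelled concatamer standard (QconCAT): each target protein is
quantified through two surrogate tryptic peptides, measured as
analyte:standard ratios over four biological replicates at a ladder of
standard spike levels.  The rules here turn those peptide-level ratios into
a protein-level copies-per-cell (cpc) value with a quantification status:

* Type A — the endogenous (analyte) peptide and the heavy standard were
  both observed; a point estimate is reported.
* Type B — only the heavy standard was observed; an upper abundance bound
  is reported from the lowest spike level at which the standard was seen.
* Type C — neither peptide was observed; no value is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

AVOGADRO = 6.02214076e23

#: basic residues flanking a tryptic cleavage site
_BASIC = frozenset("KR")
_ACIDIC = frozenset("DE")
_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideMeasurement:
    """One surrogate peptide in one biological replicate at one spike level."""

    orf: str
    peptide_id: str
    replicate: int
    ratio_light_heavy: float
    spike_fmol: float
    cells_loaded: float
    snr: float
    fdr_pass: bool
    standard_detected: bool = True

    def __post_init__(self) -> None:
        if self.ratio_light_heavy < 0:
            raise ValueError("analyte:standard ratio must be >= 0")
        if self.spike_fmol <= 0:
            raise ValueError("spike_fmol must be positive")
        if self.cells_loaded <= 0:
            raise ValueError("cells_loaded must be positive")

    @property
    def cpc(self) -> float:
        return peptide_cpc(self.ratio_light_heavy, self.spike_fmol, self.cells_loaded)


@dataclass(frozen=True)
class PeptideSummary:
    """Replicate-gated result for one surrogate peptide."""

    orf: str
    peptide_id: str
    status: str  # "A", "B" or "C"
    n_pass: int = 0
    mean_cpc: float | None = None
    sem_cpc: float | None = None
    bound_cpc: float | None = None


@dataclass(frozen=True)
class ChaperoneQuant:
    """Protein-level quantification (one Table-1-style row)."""

    orf: str
    gene_name: str = ""
    chaperone_class: str = ""
    qtype: str = "C"
    cpc: float | None = None
    sem: float | None = None
    bound_cpc: float | None = None
    peptide_statuses: tuple[str, ...] = field(default_factory=tuple)


def peptide_cpc(ratio: float, spike_fmol: float, cells_loaded: float) -> float:
    """Copies per cell implied by an analyte:standard ratio.

    The heavy standard amount on column (``spike_fmol``) scaled by the
    observed light:heavy ratio gives moles of analyte; Avogadro's number and
    the number of cell equivalents loaded convert to molecules per cell.
    """
    if spike_fmol <= 0 or cells_loaded <= 0:
        raise ValueError("spike_fmol and cells_loaded must be positive")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return ratio * spike_fmol * 1e-15 * AVOGADRO / cells_loaded


def round_cpc(value: float) -> float:
    """Banded round-half-up used for reported cpc values.

    Values above 10 000 round to the nearest 500, values above 1000 to the
    nearest 50, and values of 1000 or less to the nearest 10.  Band edges
    are strict, so exactly 1000 rounds in the nearest-10 band.
    """
    if value < 0:
        raise ValueError("cpc must be >= 0")
    if value > 10_000:
        band = 500
    elif value > 1000:
        band = 50
    else:
        band = 10
    return math.floor(value / band + 0.5) * band


def detection_limit_cpc(spike_fmol: float, cells_loaded: float) -> float:
    """Upper cpc bound for a peptide whose standard was seen without analyte.

    The bound is the cpc equivalent of a 1:1 analyte:standard ratio at the
    given spike level, rounded like any reported value.
    """
    return round_cpc(peptide_cpc(1.0, spike_fmol, cells_loaded))


def _select_per_replicate(
    measurements: Sequence[PeptideMeasurement], snr_min: float
) -> dict[int, PeptideMeasurement | None]:
    """Pick, per replicate, the passing measurement with log-ratio nearest 0.

    Quantification runs span a spike ladder so that at least one loading
    places the analyte:standard ratio near 1; the measurement closest to
    parity carries the replicate's cpc.  Returns None for replicates with
    no passing measurement.
    """
    by_rep: dict[int, list[PeptideMeasurement]] = {}
    for m in measurements:
        by_rep.setdefault(m.replicate, []).append(m)
    chosen: dict[int, PeptideMeasurement | None] = {}
    for rep, ms in by_rep.items():
        passing = [m for m in ms if m.fdr_pass and m.snr > snr_min and m.ratio_light_heavy > 0]
        if not passing:
            chosen[rep] = None
        else:
            chosen[rep] = min(passing, key=lambda m: abs(math.log10(m.ratio_light_heavy)))
    return chosen


def gate_replicates(
    measurements: Sequence[PeptideMeasurement],
    min_pass: int = 3,
    snr_min: float = 5.0,
) -> PeptideSummary:
    """Gate one peptide's replicate measurements into a PeptideSummary.

    A replicate counts as passing iff it has at least one measurement that
    passed peak-scoring FDR and has signal-to-noise strictly above
    ``snr_min``.  With ``min_pass`` or more passing replicates the peptide
    is Type A, quantified as the arithmetic mean of the per-replicate cpc
    values with SEM = sample SD / sqrt(n).  Otherwise it is Type B when the
    heavy standard was detected at some spike level (reporting the
    detection-limit bound at the lowest such spike), or Type C when it was
    not.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    orfs = {m.orf for m in measurements}
    pids = {m.peptide_id for m in measurements}
    if len(orfs) != 1 or len(pids) != 1:
        raise ValueError("gate_replicates expects measurements for a single peptide")
    orf, pid = orfs.pop(), pids.pop()

    chosen = _select_per_replicate(measurements, snr_min)
    passing = [m for m in chosen.values() if m is not None]
    if len(passing) >= min_pass:
        values = [m.cpc for m in passing]
        n = len(values)
        mean = sum(values) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            sem = sd / math.sqrt(n)
        else:
            sem = 0.0
        return PeptideSummary(orf, pid, "A", n_pass=n, mean_cpc=mean, sem_cpc=sem)

    std_spikes = sorted({m.spike_fmol for m in measurements if m.standard_detected})
    if std_spikes:
        cells = measurements[0].cells_loaded
        bound = detection_limit_cpc(std_spikes[0], cells)
        return PeptideSummary(orf, pid, "B", n_pass=len(passing), bound_cpc=bound)
    return PeptideSummary(orf, pid, "C", n_pass=len(passing))


def protein_quant(
    peptide_summaries: Sequence[PeptideSummary],
    gene_name: str = "",
    chaperone_class: str = "",
) -> ChaperoneQuant:
    """Combine the (normally two) surrogate-peptide summaries for a protein.

    When at least one peptide is Type A the protein is Type A with
    cpc = max over the A peptides' means — missed-cleavage losses can only
    depress a surrogate peptide's signal, so the larger sibling is the
    better estimate — carrying the SEM of the selected peptide.  When the
    best status is B the protein carries the smallest detection-limit bound
    among B peptides; all-C proteins report nothing.  cpc, SEM and bounds
    are rounded on output.
    """
    if not peptide_summaries:
        raise ValueError("no peptide summaries supplied")
    orfs = {s.orf for s in peptide_summaries}
    if len(orfs) != 1:
        raise ValueError("peptide summaries must belong to one protein")
    orf = orfs.pop()
    statuses = tuple(sorted(s.status for s in peptide_summaries))

    a_peps = [s for s in peptide_summaries if s.status == "A"]
    if a_peps:
        best = max(a_peps, key=lambda s: s.mean_cpc)
        return ChaperoneQuant(
            orf,
            gene_name,
            chaperone_class,
            qtype="A",
            cpc=round_cpc(best.mean_cpc),
            sem=round_cpc(best.sem_cpc or 0.0),
            peptide_statuses=statuses,
        )
    b_peps = [s for s in peptide_summaries if s.status == "B"]
    if b_peps:
        bound = min(s.bound_cpc for s in b_peps)
        return ChaperoneQuant(
            orf, gene_name, chaperone_class, qtype="B",
            bound_cpc=round_cpc(bound), peptide_statuses=statuses,
        )
    return ChaperoneQuant(orf, gene_name, chaperone_class, qtype="C",
                          peptide_statuses=statuses)


def flag_cleavage_context(peptide: str, n_flank: str = "", c_flank: str = "") -> set[str]:
    """Advisory flags for tryptic-cleavage contexts that depress signal.

    Dibasic runs (KK/KR/RK/RR) spanning either cleavage site, interspersed
    dibasic motifs (e.g. KSK) ending at a site, and acidic residues (D/E)
    adjacent to a site all promote missed cleavage of the endogenous
    peptide, biasing its quantification low.  Flags are advisory only.
    """
    for s, label in ((peptide, "peptide"), (n_flank, "n_flank"), (c_flank, "c_flank")):
        if not set(s) <= _AA:
            raise ValueError(f"non-amino-acid characters in {label}: {s!r}")
    if not peptide:
        raise ValueError("empty peptide")
    flags: set[str] = set()

    # N-terminal site: cleavage between n_flank[-1] and peptide[0]
    if len(n_flank) >= 2 and n_flank[-1] in _BASIC and n_flank[-2] in _BASIC:
        flags.add("dibasic-N")
    elif (
        len(n_flank) >= 3
        and n_flank[-1] in _BASIC
        and n_flank[-3] in _BASIC
        and n_flank[-2] not in _BASIC
    ):
        flags.add("interspersed-dibasic-N")
    if n_flank and (n_flank[-1] in _BASIC) and (
        peptide[0] in _ACIDIC or (len(n_flank) >= 2 and n_flank[-2] in _ACIDIC)
    ):
        flags.add("acidic-N")

    # C-terminal site: cleavage between peptide[-1] and c_flank[0]
    if peptide[-1] in _BASIC:
        if c_flank and c_flank[0] in _BASIC:
            flags.add("dibasic-C")
        elif len(c_flank) >= 2 and c_flank[1] in _BASIC and c_flank[0] not in _BASIC:
            flags.add("interspersed-dibasic-C")
        if (c_flank and c_flank[0] in _ACIDIC) or (len(peptide) >= 2 and peptide[-2] in _ACIDIC):
            flags.add("acidic-C")
    return flags


def quantify_proteins(
    measurements: Iterable[PeptideMeasurement],
    min_pass: int = 3,
    snr_min: float = 5.0,
    annotations: dict[str, tuple[str, str]] | None = None,
) -> list[ChaperoneQuant]:
    """Full peptide-table → protein-table pipeline.

    Groups measurements by (orf, peptide), gates replicates, and combines
    per-protein peptide summaries.  ``annotations`` optionally maps ORF to
    (gene_name, chaperone_class).
    """
    by_pep: dict[tuple[str, str], list[PeptideMeasurement]] = {}
    for m in measurements:
        by_pep.setdefault((m.orf, m.peptide_id), []).append(m)
    by_protein: dict[str, list[PeptideSummary]] = {}
    for (orf, _), ms in sorted(by_pep.items()):
        by_protein.setdefault(orf, []).append(gate_replicates(ms, min_pass, snr_min))
    out = []
    for orf, summaries in sorted(by_protein.items()):
        gene, cls = ("", "")
        if annotations and orf in annotations:
            gene, cls = annotations[orf]
        out.append(protein_quant(summaries, gene_name=gene, chaperone_class=cls))
    return out
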