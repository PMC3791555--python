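"""Synthetic proteome, interactome and SRM data with planted ground truth.

Emulates the statistical structure of the inputs the analysis consumes —
a log-normal abundance proteome, log-normal half-lives with a missing
fraction, a chaperone–substrate interactome whose edge probability scales
with chaperone abundance (the planted workload exponent γ), noisy
multi-source observations of that interactome (directed bait–prey sources
with imperfect reciprocity, a score-bearing undirected source, asymmetric
noise edges), class-biased substrate localisation, essentiality labels,
and replicate SRM ratio tables over a spike ladder — so every analysis
stage can be tested against known truth without any external download.

A single root seed deterministically derives independent per-stage
substreams, so identical (config, seed) always reproduces identical data
and any stage can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flux import ProteinRecord, kdeg_from_half_life
from .interactome import InteractionEdge
from .srm import AVOGADRO, PeptideMeasurement

_LN10 = math.log(10.0)

#: chaperone class sizes mirroring the 63 annotated yeast chaperones
DEFAULT_CLASS_SIZES = {
    "SMALL": 7, "PFD": 6, "HSP90": 2, "HSP70": 14,
    "HSP60": 1, "HSP40": 22, "CCT": 8, "AAA+": 3,
}

#: baseline compartment frequencies for substrate localisation draws
DEFAULT_LOCATION_PROBS = {
    "cytoplasm": 0.40, "nucleus": 0.20, "mitochondrion": 0.12,
    "membrane": 0.10, "ER": 0.06, "vacuole": 0.04, "golgi": 0.03,
    "vacuolar membrane": 0.02, "cell periphery": 0.02, "peroxisome": 0.01,
}

#: planted class→location preference multipliers (specialisation signal)
DEFAULT_CLASS_LOCATION_BIAS = {
    "PFD": {"vacuolar membrane": 12.0, "ER": 3.0},
    "SMALL": {"nucleus": 2.5, "mitochondrion": 2.5},
    "HSP90": {"mitochondrion": 4.0},
}


@dataclass(frozen=True)
class SourceConfig:
    """Observation model of one interaction-evidence source."""

    name: str
    detection_prob: float
    reciprocity_prob: float = 0.0  # directed sources only
    n_noise_edges: int = 0
    score_true: tuple[float, float] | None = None   # Beta(a, b) for true edges
    score_noise: tuple[float, float] | None = None  # Beta(a, b) for noise edges


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_substrates: int = 2000
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    # substrate abundance: log10(cpc) ~ Normal(3.0, 1.0)
    log10_cpc_mean: float = 3.0
    log10_cpc_sd: float = 1.0
    # chaperone abundance echoes the measured dynamic range (250–440 000 cpc)
    chap_log10_cpc_mean: float = 3.75
    chap_log10_cpc_sd: float = 0.85
    chap_cpc_min: float = 250.0
    # half-lives: log-normal, median 43 min, log10 sd 0.4
    half_life_median_min: float = 43.0
    half_life_log10_sd: float = 0.4
    missing_kdeg_fraction: float = 0.2
    # interactome
    workload_exponent: float = 1.0  # γ: edge probability ∝ chaperone cpc^γ
    mean_targets_per_chaperone: float = 30.0
    sources: tuple[SourceConfig, ...] = (
        SourceConfig("biogrid-like", detection_prob=0.7,
                     reciprocity_prob=0.9, n_noise_edges=400),
        SourceConfig("mips-like", detection_prob=0.3,
                     reciprocity_prob=0.9, n_noise_edges=200),
        SourceConfig("string-like", detection_prob=0.5, n_noise_edges=300,
                     score_true=(8.0, 2.0), score_noise=(2.0, 8.0)),
    )
    # localisation / essentiality
    location_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_PROBS))
    class_location_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_CLASS_LOCATION_BIAS.items()})
    multi_locus_prob: float = 0.15
    essential_fraction: float = 0.18
    # SRM emulation
    n_replicates: int = 4
    spike_ladder_fmol: tuple[float, ...] = (0.2, 2.0, 20.0)
    cells_loaded: float = 200_000.0
    ratio_cv: float = 0.1
    snr_scale: float = 100.0  # S/N at analyte:standard parity
    fdr_fail_prob: float = 0.02
    standard_detect_prob: float = 1.0

    @property
    def n_chaperones(self) -> int:
        return sum(self.class_sizes.values())

    def validate(self) -> None:
        probs = [self.missing_kdeg_fraction, self.multi_locus_prob,
                 self.essential_fraction, self.fdr_fail_prob,
                 self.standard_detect_prob]
        probs += [s.detection_prob for s in self.sources]
        probs += [s.reciprocity_prob for s in self.sources]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.workload_exponent < 0:
            raise ValueError("workload exponent must be >= 0")
        if self.n_substrates < 0 or self.n_chaperones <= 0:
            raise ValueError("need >= 1 chaperone and >= 0 substrates")
        if abs(sum(self.location_probs.values()) - 1.0) > 1e-9:
            raise ValueError("location probabilities must sum to 1")


@dataclass
class GroundTruth:
    """Planted values the generator drew from."""

    true_edges: set[tuple[str, str]]  # (chaperone, substrate)
    true_cpc: dict[str, float]
    true_kdeg: dict[str, float]
    workload_exponent: float
    class_location_bias: dict[str, dict[str, float]]
    essential_fraction: float


_STAGES = {"proteome": 1, "interactome": 2, "srm": 3}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for one generation stage."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


def _chaperone_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    """(orf, class) for each chaperone, stable across runs."""
    out = []
    for cls in sorted(config.class_sizes):
        for i in range(config.class_sizes[cls]):
            tag = cls.replace("+", "P")
            out.append((f"CH-{tag}-{i + 1:02d}", cls))
    return out


def generate_proteome(
    config: SimulationConfig,
) -> tuple[dict[str, ProteinRecord], GroundTruth]:
    """Draw chaperones and substrates with abundance, turnover, loci, flags."""
    config.validate()
    rng = _rng(config, "proteome")
    chap_ids = _chaperone_ids(config)
    sub_ids = [f"SUB-{i + 1:04d}" for i in range(config.n_substrates)]

    records: dict[str, ProteinRecord] = {}
    true_cpc: dict[str, float] = {}
    true_kdeg: dict[str, float] = {}

    locations = sorted(config.location_probs)
    base_p = np.array([config.location_probs[l] for l in locations])
    hl_sigma = config.half_life_log10_sd * _LN10
    hl_mu = math.log(config.half_life_median_min)

    def draw_common(orf: str, cpc: float, cls: str | None) -> ProteinRecord:
        t_half = float(np.exp(rng.normal(hl_mu, hl_sigma)))
        kdeg = kdeg_from_half_life(t_half)
        true_cpc[orf] = cpc
        true_kdeg[orf] = kdeg
        observed_kdeg = None if rng.random() < config.missing_kdeg_fraction else kdeg
        n_loci = 2 if rng.random() < config.multi_locus_prob else 1
        loci = frozenset(rng.choice(locations, size=n_loci, replace=False, p=base_p))
        essential = bool(rng.random() < config.essential_fraction)
        return ProteinRecord(
            orf=orf, cpc=cpc, k_deg=observed_kdeg, loci=loci,
            essential=essential, chaperone_class=cls, gene=orf,
        )

    for orf, cls in chap_ids:
        cpc = 10.0 ** rng.normal(config.chap_log10_cpc_mean, config.chap_log10_cpc_sd)
        cpc = max(cpc, config.chap_cpc_min)
        records[orf] = draw_common(orf, cpc, cls)
    for orf in sub_ids:
        cpc = 10.0 ** rng.normal(config.log10_cpc_mean, config.log10_cpc_sd)
        records[orf] = draw_common(orf, cpc, None)

    truth = GroundTruth(
        true_edges=set(), true_cpc=true_cpc, true_kdeg=true_kdeg,
        workload_exponent=config.workload_exponent,
        class_location_bias={k: dict(v)
                             for k, v in config.class_location_bias.items()},
        essential_fraction=config.essential_fraction,
    )
    return records, truth


def generate_interactome(
    config: SimulationConfig,
    records: dict[str, ProteinRecord],
    truth: GroundTruth,
) -> dict[str, list[InteractionEdge]]:
    """Plant true chaperone–substrate edges and emit noisy source observations.

    A chaperone's expected degree scales with cpc^γ (normalised so the mean
    degree is ``mean_targets_per_chaperone``); within a chaperone, substrate
    choice is tilted by the planted class→location bias.  Each source then
    observes each true edge independently: directed sources emit the
    bait→prey observation plus, with the source's reciprocity probability,
    the reciprocal one; the score-bearing source emits one observation with
    a Beta-distributed confidence.  Noise edges are one-directional random
    pairs (low-scored in the score-bearing source).
    """
    config.validate()
    rng = _rng(config, "interactome")
    chaps = [(o, r.chaperone_class) for o, r in sorted(records.items())
             if r.chaperone_class is not None]
    subs = sorted(o for o, r in records.items() if r.chaperone_class is None)
    if not subs:
        truth.true_edges = set()
        return {s.name: [] for s in config.sources}

    gamma = config.workload_exponent
    u = np.array([records[c].cpc ** gamma for c, _ in chaps])
    target_degree = u * (config.mean_targets_per_chaperone * len(chaps) / u.sum())

    loc_bias_rows = {}
    for cls, biases in config.class_location_bias.items():
        loc_bias_rows[cls] = biases

    true_edges: set[tuple[str, str]] = set()
    sub_loci = {s: records[s].loci for s in subs}
    for (chap, cls), deg in zip(chaps, target_degree):
        bias = loc_bias_rows.get(cls, {})
        q = np.array([
            max((bias.get(loc, 1.0) for loc in sub_loci[s]), default=1.0)
            for s in subs
        ])
        p = np.minimum(1.0, deg * q / q.sum())
        hit = rng.random(len(subs)) < p
        for s, h in zip(subs, hit):
            if h:
                true_edges.add((chap, s))
    truth.true_edges = true_edges
    ordered_true = sorted(true_edges)

    all_proteins = [c for c, _ in chaps] + subs
    out: dict[str, list[InteractionEdge]] = {}
    for src in config.sources:
        edges: list[InteractionEdge] = []
        scored = src.score_true is not None
        for chap, sub in ordered_true:
            if rng.random() >= src.detection_prob:
                continue
            if scored:
                conf = float(rng.beta(*src.score_true))
                edges.append(InteractionEdge(chap, sub, src.name, confidence=conf))
            else:
                edges.append(InteractionEdge(chap, sub, src.name))
                if rng.random() < src.reciprocity_prob:
                    edges.append(InteractionEdge(sub, chap, src.name))
        n_noise = 0
        while n_noise < src.n_noise_edges:
            a, b = rng.choice(len(all_proteins), size=2, replace=False)
            bait, prey = all_proteins[a], all_proteins[b]
            if scored:
                conf = float(rng.beta(*src.score_noise))
                edges.append(InteractionEdge(bait, prey, src.name, confidence=conf))
            else:
                edges.append(InteractionEdge(bait, prey, src.name))
            n_noise += 1
        out[src.name] = edges
    return out


def generate_srm_replicates(
    config: SimulationConfig,
    records: dict[str, ProteinRecord],
) -> list[PeptideMeasurement]:
    """Replicate SRM ratio tables for every chaperone over the spike ladder.

    Observed ratio = true_cpc * cells / (spike molecules) times log-normal
    multiplicative noise of coefficient of variation ``ratio_cv``; S/N
    scales with the observed ratio (``snr_scale`` at parity), and FDR peak
    scoring fails with probability ``fdr_fail_prob``.  Chaperones whose
    analyte never rises above the S/N floor at any spike come out Type B/C
    downstream, exactly as in the real gating.
    """
    config.validate()
    rng = _rng(config, "srm")
    sigma = math.sqrt(math.log(1.0 + config.ratio_cv ** 2))
    out: list[PeptideMeasurement] = []
    chaps = sorted(o for o, r in records.items() if r.chaperone_class is not None)
    for orf in chaps:
        cpc = records[orf].cpc or 0.0
        for pep in (f"{orf}_p1", f"{orf}_p2"):
            for rep in range(1, config.n_replicates + 1):
                for spike in config.spike_ladder_fmol:
                    expected = cpc * config.cells_loaded / (spike * 1e-15 * AVOGADRO)
                    noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
                    ratio = expected * noise
                    snr = config.snr_scale * ratio
                    fdr_pass = bool(ratio > 0 and rng.random() >= config.fdr_fail_prob)
                    std_seen = bool(rng.random() < config.standard_detect_prob)
                    out.append(PeptideMeasurement(
                        orf=orf, peptide_id=pep, replicate=rep,
                        ratio_light_heavy=ratio, spike_fmol=spike,
                        cells_loaded=config.cells_loaded, snr=snr,
                        fdr_pass=fdr_pass, standard_detected=std_seen,
                    ))
    return out
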