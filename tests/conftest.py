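from __future__ import annotations

import pytest

from chapflux.flux import ProteinRecord
from chapflux.interactome import ChaperoneNetwork


def make_measurement(orf="YAL005C", pep="p1", rep=1, ratio=1.0, spike=0.2,
                     cells=200_000.0, snr=50.0, fdr=True, std=True):
    from chapflux.srm import PeptideMeasurement
    return PeptideMeasurement(
        orf=orf, peptide_id=pep, replicate=rep, ratio_light_heavy=ratio,
        spike_fmol=spike, cells_loaded=cells, snr=snr, fdr_pass=fdr,
        standard_detected=std,
    )


@pytest.fixture
def toy_records() -> dict[str, ProteinRecord]:
    """Three chaperones, five substrates with known abundance and turnover."""
    recs = {
        "C1": ProteinRecord("C1", cpc=1000.0, k_deg=0.01, chaperone_class="HSP70"),
        "C2": ProteinRecord("C2", cpc=500.0, k_deg=0.01, chaperone_class="CCT"),
        "C3": ProteinRecord("C3", cpc=200.0, k_deg=0.01, chaperone_class="HSP40"),
        "S1": ProteinRecord("S1", cpc=100.0, k_deg=0.10, loci=frozenset({"cytoplasm"})),
        "S2": ProteinRecord("S2", cpc=200.0, k_deg=0.05, loci=frozenset({"nucleus"})),
        "S3": ProteinRecord("S3", cpc=300.0, k_deg=0.02,
                            loci=frozenset({"cytoplasm", "nucleus"})),
        "S4": ProteinRecord("S4", cpc=400.0, k_deg=0.01, essential=True,
                            loci=frozenset({"mitochondrion"})),
        "S5": ProteinRecord("S5", cpc=500.0, k_deg=0.04,
                            loci=frozenset({"cytoplasm"})),
    }
    return recs


@pytest.fixture
def toy_network() -> ChaperoneNetwork:
    """C1 → {S1,S2,S3}, C2 → {S3,S4}, C3 → {S5}; S3 has two parents."""
    edges = {("C1", "S1"), ("C1", "S2"), ("C1", "S3"),
             ("C2", "S3"), ("C2", "S4"), ("C3", "S5")}
    return ChaperoneNetwork(chaperones={"C1", "C2", "C3"}, edges=set(edges))
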