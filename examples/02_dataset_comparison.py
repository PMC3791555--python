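"""Harmonising and comparing protein-abundance datasets.

Converts between ppm-of-proteome and copies-per-cell units, correlates
datasets on their shared proteins, clusters them by rank agreement, and
uses a fixed-stoichiometry complex (the packaged CCT/TRiC subunits) as an
internal consistency check.
"""

import numpy as np

from chapflux import (
    AbundanceDataset,
    cluster_datasets,
    complex_cv,
    correlation_matrix,
    cpc_to_ppm,
    linkage_to_newick,
    load_chaperone_table,
    ppm_to_cpc,
)

print("== unit harmonisation ==")
print(f"Under a 6e7-molecule cell, 1 ppm = {ppm_to_cpc(1.0):.0f} cpc and "
      f"600 cpc = {cpc_to_ppm(600.0):.0f} ppm.\n")

# three synthetic surveys of one latent proteome, with different noise and units
rng = np.random.default_rng(0)
orfs = [f"Y{i:04d}" for i in range(400)]
latent = 10 ** rng.normal(3.0, 1.0, size=len(orfs))


def survey(name, unit, noise_sd, coverage):
    keep = rng.random(len(orfs)) < coverage
    vals = latent * 10 ** rng.normal(0.0, noise_sd, size=len(orfs))
    if unit == "ppm":
        vals = vals / 60.0
    return AbundanceDataset(name, unit,
                            {o: float(v) for o, v, k in zip(orfs, vals, keep) if k})


datasets = [
    survey("ms-a", "cpc", 0.15, 0.9),
    survey("ms-b", "cpc", 0.20, 0.8),
    survey("tag-gfp", "ppm", 0.45, 0.7),
]

print("== pairwise Spearman correlation on shared proteins ==")
comp = correlation_matrix(datasets)
for i, a in enumerate(comp.names):
    for j in range(i + 1, len(comp.names)):
        print(f"  {a} vs {comp.names[j]}: rho = {comp.rho_matrix[i, j]:.2f} "
              f"(n = {comp.n_common[i, j]})")
print("Rank correlation ignores the ppm/cpc unit mismatch entirely.\n")

print("== average-linkage clustering on 1 - rho ==")
clustered = cluster_datasets(comp)
print(linkage_to_newick(clustered.linkage, clustered.names))
print("The two MS surveys pair off; the noisier tagging survey joins last.\n")

print("== complex stoichiometry as an internal control ==")
table = load_chaperone_table()
cct = table[(table["chaperone_class"] == "CCT") & table["cpc"].notna()]
ds = AbundanceDataset("chaperone-table", "cpc",
                      dict(zip(cct["orf"], cct["cpc"].astype(float))))
cv = complex_cv(ds, list(cct["orf"]))
print(f"CV across the {len(cct)} CCT/TRiC subunits: {cv:.2f} "
      "(equimolar subunits of one ring; a large CV would flag calibration "
      "problems)")
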