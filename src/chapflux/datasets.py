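"""Packaged reference tables: the 63-chaperone quantification and the
top-15 workload ranking, as printed.

``load_chaperone_table`` returns the published copies-per-cell table for
the 63 annotated yeast chaperones (Type A point estimates with SEM, Type B
upper bounds, one Type C protein with no value).  ``load_workload_table``
returns the published top-15 chaperones ranked by total substrate flux.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("chapflux.data").joinpath(name)


def load_chaperone_table() -> pd.DataFrame:
    """63-row chaperone quantification table.

    Columns: chaperone_class, gene, orf, uniprot, cpc, sem, qtype
    (per-peptide status such as "A", "B/B", "B/C", "C/C"), bound_cpc
    (upper limit, Type B rows only).
    """
    with resources.as_file(_data_path("table1.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["protein_qtype"] = df["qtype"].str.split("/").str[0]
    return df


def load_workload_table() -> pd.DataFrame:
    """Top-15 chaperones ranked by total substrate flux (cpc/min)."""
    with resources.as_file(_data_path("table2.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def chaperone_summary(df: pd.DataFrame | None = None) -> dict:
    """Headline statistics of the chaperone quantification table.

    Counts quantification outcomes and summarises the Type A abundances
    (min, max, arithmetic mean, and the mean rounded to the nearest 1000).
    """
    if df is None:
        df = load_chaperone_table()
    a_rows = df[df["protein_qtype"] == "A"]
    mean_cpc = float(a_rows["cpc"].mean())
    return {
        "n_chaperones": int(len(df)),
        "n_type_a": int(len(a_rows)),
        "n_type_b": int((df["protein_qtype"] == "B").sum()),
        "n_type_c": int((df["protein_qtype"] == "C").sum()),
        "min_type_a_cpc": float(a_rows["cpc"].min()),
        "max_type_a_cpc": float(a_rows["cpc"].max()),
        "mean_type_a_cpc": mean_cpc,
        "mean_type_a_cpc_rounded_1000": round(mean_cpc / 1000.0) * 1000.0,
    }
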