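"""Packaged transcriptions of the study's printed sequence tables.

Table 1 lists the 76 polyamine oxidase proteins used in the family analysis
(SMO, APAO and PAO classes, with evidence status and database accession);
Table 2 lists the 25 mammalian SMO loci examined for the alternatively
spliced long isoform, with their isoform labels ("no isoform" marks loci
where no long-isoform variant was found).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .isoform_analysis import IsoformRecord

YEAST = "Saccharomyces cerevisiae"


def _data_path(name: str) -> Path:
    return Path(resources.files("paofam").joinpath("data", name))


def table1() -> pd.DataFrame:
    """Sequence inventory: organism, common_name, acronym, enzyme_class
    (SMO|APAO|PAO), evidence, accession."""
    return pd.read_csv(_data_path("table1_sequences.tsv"), sep="\t",
                       dtype=str)


def table2() -> pd.DataFrame:
    """Long-isoform survey: taxon, acronym, accession, isoform_label."""
    return pd.read_csv(_data_path("table2_isoforms.tsv"), sep="\t",
                       dtype=str)


def table2_records() -> list[IsoformRecord]:
    return [IsoformRecord(r.taxon, r.accession, r.isoform_label)
            for r in table2().itertuples()]


def fixture_summary(which: str) -> dict:
    """Exact counts recomputed from the packaged transcription."""
    if which == "table1":
        df = table1()
        by_class = df.enzyme_class.value_counts().to_dict()
        return {
            "total": int(len(df)),
            "smo": int(by_class.get("SMO", 0)),
            "apao": int(by_class.get("APAO", 0)),
            "pao": int(by_class.get("PAO", 0)),
            "pao_metazoan": int(((df.enzyme_class == "PAO")
                                 & (df.organism != YEAST)).sum()),
            "evidence_protein": int((df.evidence == "protein").sum()),
            "n_organisms": int(df.organism.nunique()),
        }
    if which == "table2":
        df = table2()
        with_iso = int((df.isoform_label != "no isoform").sum())
        return {
            "total": int(len(df)),
            "with_long_isoform": with_iso,
            "without_long_isoform": int(len(df)) - with_iso,
        }
    raise ValueError("which must be 'table1' or 'table2'")
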