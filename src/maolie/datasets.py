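"""Packaged reference data for the 11-compound beta-carboline series.

Two tables are shipped with the package:

* ``table1.tsv`` -- MD interaction-energy decomposition per compound:
  bound/free van der Waals and electrostatic means with block-average SDs,
  plus the bound-minus-free difference columns.
* ``table2.tsv`` -- experimental inhibition constants (Ki, micromolar),
  experimental and LIE-predicted binding free energies with uncertainties,
  and the mean ligand RMSD of each production trajectory.

Values are transcribed at printed precision; difference columns are kept
verbatim rather than recomputed (independent rounding makes them differ
from differences of the printed means by up to ~0.15 kcal/mol).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .energy_stats import InteractionEnergySummary, MeanSD, summary_from_table_row
from .lie_engine import Compound
from .profiler import FeatureAnnotation


def _data_path(name: str):
    return resources.files("maolie.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Interaction-energy decomposition as a DataFrame (kcal/mol)."""
    with resources.as_file(_data_path("table1.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_table2() -> pd.DataFrame:
    """Ki values, binding free energies and mean RMSDs as a DataFrame."""
    with resources.as_file(_data_path("table2.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def table1_summaries() -> list[InteractionEnergySummary]:
    """The energy table as per-compound summary objects."""
    out = []
    for _, row in load_table1().iterrows():
        out.append(
            summary_from_table_row(
                compound_id=int(row["compound"]),
                charged=bool(row["charged"]),
                vdw_bound=MeanSD(row["vdw_bound"], row["vdw_bound_sd"]),
                vdw_free=MeanSD(row["vdw_free"], row["vdw_free_sd"]),
                el_bound=MeanSD(row["el_bound"], row["el_bound_sd"]),
                el_free=MeanSD(row["el_free"], row["el_free_sd"]),
                delta_vdw=MeanSD(row["dvdw"], row["dvdw_sd"]),
                delta_el=MeanSD(row["del"], row["del_sd"]),
            )
        )
    return out


def table2_compounds() -> list[Compound]:
    """The compound series with Ki converted from micromolar to molar."""
    out = []
    for _, row in load_table2().iterrows():
        out.append(
            Compound(
                id=int(row["compound"]),
                name=str(row["name"]),
                charged=bool(row["charged"]),
                ki=float(row["ki_um"]) * 1e-6,
                ki_err=float(row["ki_err_um"]) * 1e-6,
            )
        )
    return out


def load_harmine_features() -> list[FeatureAnnotation]:
    """Pharmacophore feature annotations for the harmine-like toy ligand."""
    from .profiler import read_annotations

    with resources.as_file(_data_path("harmine_features.tsv")) as p:
        return read_annotations(p)
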