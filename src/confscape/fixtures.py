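"""Packaged amino-acid reference tables and the benchmark harness.

The tables transcribe, verbatim, the published relative-energy ledgers,
dihedral angles, relaxation assignments, and spectroscopic parameters for
glycine, alanine, serine, threonine, cysteine, aspartic acid and asparagine.
All energies are cm^-1, rotational and quadrupole constants MHz, dipoles
debye, angles degrees.

Known internal inconsistencies of the source tables are kept verbatim and
surfaced by the harness rather than silently repaired, notably:

* cysteine Igg dG differs between the energy ledger (298.5) and the
  spectroscopic table (187.3);
* two cysteine rows (III'gg-, IIgt) and one aspartic row (I'tt) print
  dihedrals that do not match their own conformer labels;
* the alanine III-c and asparagine Igt rows fail their table's own
  column-sum identity (by 100 and 50 cm^-1).
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .refine import BarrierEdge
from .spectro import ComparisonReport, unsigned_error_stats

__all__ = [
    "FIXTURE_IDS",
    "LEDGER_IDS",
    "load_fixture",
    "relaxation_edges",
    "experimental_benchmark",
    "method_benchmark",
    "PARAMETER_CLASSES",
]

#: Ledger-style fixtures (serine column convention) with dihedral columns.
LEDGER_IDS = (
    "serine_ledger",
    "threonine_ledger",
    "cysteine_ledger",
    "aspartic_ledger",
    "asparagine_ledger",
)

_SCHEMAS = {
    "glycine_energies": [
        "conformer", "label", "dE_best", "dE_ChS", "dE_rDSD", "dH0H",
        "dG_H", "dZPE_anh_minus_H", "dTdS_QH_minus_H", "dG",
    ],
    "alanine_energies": [
        "conformer", "label", "dE_ChS", "dE_rDSD", "dH0H",
        "dG_H", "dZPE_anh_minus_H", "dTdS_QH_minus_H", "dG",
    ],
    "glycine_barriers": ["from", "to", "barrier_cm1"],
}
_LEDGER_COLUMNS = [
    "row", "label", "dE_rDSD", "dChS", "dZPE_H", "dTh_H",
    "dZPE_anh_minus_H", "TdS_QH_minus_H", "dG",
    "phi_prime", "psi", "omega", "chi1", "chi2",
]
for _lid in LEDGER_IDS:
    _SCHEMAS[_lid] = list(_LEDGER_COLUMNS)
_SCHEMAS["aspartic_ledger"] = _LEDGER_COLUMNS[:14] + ["chi3"]

_SPECTRO_IDS = (
    "glycine_spectro", "alanine_spectro", "serine_spectro",
    "threonine_spectro", "cysteine_spectro", "aspartic_spectro",
    "asparagine_spectro",
)
for _sid in _SPECTRO_IDS:
    _SCHEMAS[_sid] = ["conformer", "parameter", "calc"]

FIXTURE_IDS = tuple(sorted(_SCHEMAS))

PARAMETER_CLASSES = {
    "rotational": ("A0", "B0", "C0"),
    "quadrupole": ("chi_aa", "chi_bb", "chi_cc"),
    "dipole": ("mu_a", "mu_b", "mu_c"),
}


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load a packaged table by id, with schema validation.

    An unknown id raises with the list of available ids; a malformed table
    raises naming the missing column.
    """
    if table_id not in _SCHEMAS:
        raise KeyError(
            f"unknown fixture {table_id!r}; available: {', '.join(FIXTURE_IDS)}"
        )
    ref = resources.files("confscape") / "data" / f"{table_id}.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    for col in _SCHEMAS[table_id]:
        if col not in df.columns:
            raise ValueError(f"fixture {table_id!r}: missing column {col!r}")
    return df


def relaxation_edges(table_id: str) -> list[BarrierEdge]:
    """Relaxation edges for a molecule.

    Glycine has a dedicated barrier table; the ledger fixtures carry a
    ``relaxes_to`` column whose barrier is blank when the source states the
    relaxation without printing a barrier.
    """
    if table_id == "glycine_barriers" or table_id == "glycine_energies":
        df = load_fixture("glycine_barriers")
        return [
            BarrierEdge(r["from"], r["to"], float(r["barrier_cm1"]))
            for _, r in df.iterrows()
        ]
    df = load_fixture(table_id)
    if "relaxes_to" not in df.columns:
        return []
    edges = []
    for _, r in df.iterrows():
        target = r.get("relaxes_to")
        if isinstance(target, str) and target:
            barrier = r.get("barrier_cm1")
            barrier = None if barrier is None or (
                isinstance(barrier, float) and math.isnan(barrier)
            ) else float(barrier)
            edges.append(BarrierEdge(r["row"], target, barrier))
    return edges


def experimental_benchmark(molecule: str) -> dict[str, ComparisonReport]:
    """Experiment-vs-computation unsigned-error statistics per parameter class.

    Uses every parameter of every conformer for which both an experimental
    and a computed value are tabulated.
    """
    df = load_fixture(f"{molecule}_spectro")
    if "exp" not in df.columns:
        raise ValueError(f"{molecule}: no experimental values tabulated")
    reports = {}
    units = {"rotational": "MHz", "quadrupole": "MHz", "dipole": "D"}
    for cls, params in PARAMETER_CLASSES.items():
        sub = df[df["parameter"].isin(params)].dropna(subset=["exp", "calc"])
        if len(sub) == 0:
            continue
        reports[cls] = unsigned_error_stats(
            sub["exp"].to_numpy(), sub["calc"].to_numpy(), cls, units[cls]
        )
    return reports


def method_benchmark(molecule: str) -> dict[str, ComparisonReport]:
    """Method-vs-method relative-energy deviations (cm^-1), reference row
    excluded (its deviation is zero by construction).

    Glycine is benchmarked against the best available composite energies
    (both the junChSF12 and the double-hybrid columns); alanine compares the
    double-hybrid against junChSF12; the polar amino acids tabulate the
    junChSF12-minus-double-hybrid difference directly.
    """
    if molecule == "glycine":
        df = load_fixture("glycine_energies").iloc[1:]
        return {
            "junChSF12_vs_best": unsigned_error_stats(
                df["dE_ChS"], df["dE_best"], "junChSF12 vs best", "cm-1"
            ),
            "rDSD_vs_best": unsigned_error_stats(
                df["dE_rDSD"], df["dE_best"], "rDSD vs best", "cm-1"
            ),
        }
    if molecule == "alanine":
        df = load_fixture("alanine_energies").iloc[1:]
        return {
            "rDSD_vs_junChSF12": unsigned_error_stats(
                df["dE_rDSD"], df["dE_ChS"], "rDSD vs junChSF12", "cm-1"
            )
        }
    df = load_fixture(f"{molecule}_ledger").iloc[1:]
    diffs = df["dChS"].to_numpy(dtype=float)
    return {
        "rDSD_vs_junChSF12": unsigned_error_stats(
            diffs, np.zeros_like(diffs), "rDSD vs junChSF12", "cm-1"
        )
    }
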