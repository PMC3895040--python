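"""Experimental binding-affinity conversion and comparison.

Converts dissociation constants to standard dissociation free energies,
ΔG_dissoc = -RT ln(Kd / 1 M), forms ΔΔ values against a reference ligand,
and checks rank concordance between computed ΔPMF values and experimental
ΔG — the comparison logic used to judge whether steered-unbinding
simulations reproduce the experimental order of binding strengths.

``LDHA_AFFINITIES`` ships the experimental Kd values (µM) and binding sites
of the human LDHA binders studied here; ``REPORTED_DELTA_PMF`` carries the
published steered-MD ΔPMF values (kJ/mol) for the same ligands, usable as a
reference ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, R_GAS

__all__ = [
    "AffinityRecord",
    "LDHA_AFFINITIES",
    "REPORTED_DELTA_PMF",
    "deltaG_from_kd",
    "delta_vs_reference",
    "ConcordanceReport",
    "rank_concordance",
    "load_affinity_table",
    "affinity_records",
]

SITES = ("A", "S", "dual", "unknown")


def deltaG_from_kd(kd_micromolar: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Standard dissociation free energy -RT ln(Kd / 1 M) in kJ/mol.

    ``kd_micromolar`` is the experimental dissociation constant in µM;
    the 1 M standard state is implied by the unit conversion. The result is
    unrounded; rounding happens only at presentation.
    """
    if kd_micromolar <= 0:
        raise ValueError(f"Kd must be positive, got {kd_micromolar}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -R_GAS * temperature * np.log(kd_micromolar * 1e-6)


@dataclass(frozen=True)
class AffinityRecord:
    """Ligand id, experimental Kd (µM), binding site, and derived ΔG_dissoc."""

    ligand_id: str
    kd: float                 # µM
    site: str = "unknown"
    temperature: float = DEFAULT_TEMPERATURE
    delta_g: float = field(init=False)  # kJ/mol

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        object.__setattr__(self, "delta_g", deltaG_from_kd(self.kd, self.temperature))


#: Experimental dissociation constants (µM) and binding sites of human LDHA
#: binders (PYR is the natural substrate; NADH the cofactor).
LDHA_AFFINITIES: dict[str, tuple[float, str]] = {
    "PYR": (3.9, "S"),
    "NADH": (0.62, "dual"),
    "0SN": (0.093, "dual"),
    "2B4": (210.0, "S"),
    "AJ1": (770.0, "A"),
    "1E4": (0.068, "dual"),
    "6P3": (2300.0, "S"),
    "1E7": (137.0, "A"),
    "NHI": (9.0, "unknown"),
    "FX11": (0.05, "unknown"),
}

#: Published steered-MD ΔPMF values (kJ/mol) for the pulled systems, keyed by
#: ligand and pulled site / starting loop conformation. Reference data for
#: rank-concordance checks; these magnitudes require cluster-scale all-atom
#: MD and are not recomputed by this package.
REPORTED_DELTA_PMF: dict[str, float] = {
    "AJ1": 72.7,
    "1E7": 76.5,
    "NHI_A": 95.0,
    "FX11_A": 92.4,
    "6P3_open": 117.8,
    "6P3_closed": 449.7,
    "2B4_A": 564.1,
    "2B4_B": 546.5,
    "NHI_S": 372.2,
    "FX11_S": 181.7,
    "0SN": 687.4,
    "1E4": 526.6,
}


def affinity_records(temperature: float = DEFAULT_TEMPERATURE) -> list[AffinityRecord]:
    """The shipped experimental affinity table as records with derived ΔG."""
    return [AffinityRecord(lig, kd, site, temperature)
            for lig, (kd, site) in LDHA_AFFINITIES.items()]


def load_affinity_table(path, temperature: float = DEFAULT_TEMPERATURE) -> list[AffinityRecord]:
    """Read a TSV affinity table with columns ligand_id, kd_uM, site."""
    df = pd.read_csv(path, sep="\t")
    required = {"ligand_id", "kd_uM"}
    if not required.issubset(df.columns):
        raise ValueError(f"affinity table needs columns {sorted(required)}, got {list(df.columns)}")
    site = df["site"] if "site" in df.columns else ["unknown"] * len(df)
    return [AffinityRecord(str(lig), float(kd), str(s), temperature)
            for lig, kd, s in zip(df["ligand_id"], df["kd_uM"], site)]


def delta_vs_reference(values: Mapping[str, float], reference_ligand: str) -> dict[str, float]:
    """Each value minus the reference ligand's value; the reference maps to 0."""
    if reference_ligand not in values:
        raise KeyError(f"reference ligand {reference_ligand!r} not in value map")
    ref = values[reference_ligand]
    return {ligand: value - ref for ligand, value in values.items()}


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between a computed and an experimental ligand ordering."""

    identical_order: bool
    kendall_tau: float
    p_value: float
    n_shared: int
    ligands: tuple[str, ...]


def rank_concordance(
    computed: Mapping[str, float],
    experimental: Mapping[str, float],
) -> ConcordanceReport:
    """Do computed values reproduce the experimental order of binding strengths?

    Reports whether the orderings over the shared ligands are identical and
    Kendall's tau with its exact small-sample p-value.
    """
    shared = sorted(set(computed) & set(experimental))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared ligands")
    comp = np.array([computed[l] for l in shared])
    expt = np.array([experimental[l] for l in shared])
    identical = bool(np.array_equal(np.argsort(comp, kind="stable"),
                                    np.argsort(expt, kind="stable")))
    res = stats.kendalltau(comp, expt, method="exact" if len(shared) <= 33 else "auto")
    return ConcordanceReport(
        identical_order=identical,
        kendall_tau=float(res.statistic),
        p_value=float(res.pvalue),
        n_shared=len(shared),
        ligands=tuple(shared),
    )
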