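"""Per-species parameter registry and the study inventory table.

The registry carries the calibration constants used to convert
mutation-scaled quantities into calendar years and effective sizes:
per-site mutation rates by marker class and species generation times.
All values can be overridden per species, since mutation-rate
uncertainty dominates the calibration error budget.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibrate import SpeciesCalibration

#: Default per-site mutation rates by marker class. Mitochondrial rates
#: are per generation; the nuclear rate is per year.
DEFAULT_MUTATION_RATES = {
    "control_region": 1.125e-6,   # /site/generation
    "other_mtdna": 3.4e-7,        # /site/generation
    "nuclear": 1.07e-9,           # /site/year
}

#: Generation times (years) for the species with genome-wide data.
GENERATION_TIMES_YEARS = {
    "Balaenoptera acutorostrata": 21.2,
    "Balaenoptera physalus": 32.5,
    "Eubalaena australis": 27.6,
}

# markers as they appear in the inventory table -> marker class
_MARKER_CLASS = {
    "CR": "control_region",
    "COI": "other_mtdna",
    "CYTB": "other_mtdna",
    "16S": "other_mtdna",
    "ND1": "other_mtdna",
    "DI": "control_region",  # D-loop / control-region fragment
    "SNPs": "nuclear",
}


def load_study_inventory() -> pd.DataFrame:
    """Load the study's species × region × marker sample inventory.

    Columns: species, common_name, ocean, group (whale/prey), data_type
    (mtdna/nuclear), n (sample count), marker, length_bp.
    """
    with resources.files("paleodemo.data").joinpath("study_inventory.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def marker_class_for(marker: str) -> str:
    try:
        return _MARKER_CLASS[marker]
    except KeyError:
        raise ValueError(f"unknown marker {marker!r}; expected one of {sorted(_MARKER_CLASS)}")


def calibration_for(marker: str, generation_time_years: float,
                    mutation_rate: float | None = None) -> SpeciesCalibration:
    """Build a :class:`SpeciesCalibration` from a marker name.

    ``mutation_rate`` overrides the registry default (same units as the
    default for that marker class).
    """
    mclass = marker_class_for(marker)
    rate = DEFAULT_MUTATION_RATES[mclass] if mutation_rate is None else mutation_rate
    if mclass == "nuclear":
        return SpeciesCalibration(
            marker_class=mclass,
            mu_per_site_per_year=rate,
            generation_time_years=generation_time_years,
        )
    return SpeciesCalibration(
        marker_class=mclass,
        mu_per_site_per_generation=rate,
        generation_time_years=generation_time_years,
    )
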