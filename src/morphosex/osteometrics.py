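"""Osteometric measurements of the first sacral vertebra and derived indices.

Measurements follow the classical caliper definitions: sacral width (SW),
corpus width (CW) and corpus depth (CD), approximated on landmark data by
the chord distance between the endpoint landmarks registered in the
template. Derived quantities:

* corporo-basal index        CBI = 100 * CW / SW
* corpus-area index          CAI = 100 * sqrt(CW * CD) / SW
* corpus superior area       A   = CW * CD          (mm^2)

The square-root form of CAI is the one consistent with its published
magnitude (a dimensionless index in the 30s); all indices are invariant to
uniform scaling of the skeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration, TemplateDefinition

__all__ = [
    "LinearMeasurements",
    "compute_indices",
    "measure_from_landmarks",
    "measurements_table",
    "read_measurements_csv",
    "write_measurements_csv",
]

REQUIRED_MEASUREMENTS = ("SW", "CW", "CD")


@dataclass
class LinearMeasurements:
    specimen_id: str
    SW: float
    CW: float
    CD: float
    CBI: float
    CAI: float
    corpus_area: float


def compute_indices(SW: float, CW: float, CD: float) -> tuple[float, float, float]:
    """(CBI, CAI, corpus area) from the three base measurements (mm).

    Warns (does not fail) when CW >= SW, which is anatomically implausible
    for a sacrum but numerically well defined.
    """
    if SW <= 0 or CW <= 0 or CD <= 0:
        raise ValueError(
            f"measurements must be positive, got SW={SW}, CW={CW}, CD={CD}"
        )
    if CW >= SW:
        warnings.warn(
            f"CW ({CW}) >= SW ({SW}): anatomically implausible for a sacrum",
            stacklevel=2,
        )
    cbi = 100.0 * CW / SW
    cai = 100.0 * np.sqrt(CW * CD) / SW
    return float(cbi), float(cai), float(CW * CD)


def measure_from_landmarks(
    config: LandmarkConfiguration, template: TemplateDefinition | None = None
) -> LinearMeasurements:
    """Inter-landmark chord distances (mm) on the raw, unscaled configuration
    using the template's measurement registry, plus the derived indices."""
    tpl = template if template is not None else config.template
    missing = [m for m in REQUIRED_MEASUREMENTS if m not in tpl.measurement_registry]
    if missing:
        raise KeyError(
            f"template {tpl.name!r} lacks measurement registry entries: {missing}"
        )
    vals = {}
    for m in REQUIRED_MEASUREMENTS:
        i, j = tpl.measurement_registry[m]
        vals[m] = float(np.linalg.norm(config.coordinates[i] - config.coordinates[j]))
    cbi, cai, area = compute_indices(vals["SW"], vals["CW"], vals["CD"])
    return LinearMeasurements(
        specimen_id=config.specimen_id,
        SW=vals["SW"], CW=vals["CW"], CD=vals["CD"],
        CBI=cbi, CAI=cai, corpus_area=area,
    )


def measurements_table(
    configs: list[LandmarkConfiguration], template: TemplateDefinition | None = None
) -> pd.DataFrame:
    """Measurement + index table for a whole sample, one specimen per row."""
    rows = [measure_from_landmarks(c, template) for c in configs]
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in rows],
            "SW": [r.SW for r in rows],
            "CW": [r.CW for r in rows],
            "CD": [r.CD for r in rows],
            "CBI": [r.CBI for r in rows],
            "CAI": [r.CAI for r in rows],
            "corpus_area": [r.corpus_area for r in rows],
        }
    )


def read_measurements_csv(path) -> pd.DataFrame:
    """Read a measurement CSV (specimen_id, SW, CW, CD); (re)computes the
    derived indices so they are always consistent with the base values."""
    df = pd.read_csv(path)
    missing = [c for c in ("specimen_id",) + REQUIRED_MEASUREMENTS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing columns: {missing}")
    out = df.copy()
    derived = [
        compute_indices(row.SW, row.CW, row.CD)
        for row in df.itertuples(index=False)
    ]
    out["CBI"] = [d[0] for d in derived]
    out["CAI"] = [d[1] for d in derived]
    out["corpus_area"] = [d[2] for d in derived]
    return out


def write_measurements_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
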