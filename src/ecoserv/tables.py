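"""Per-class parameter tables (LULC attributes and soil erodibility).

The :class:`LULCTable` carries, for every integer LULC code, the habitat /
threat flags, the threat-propagation parameters (maximum influence distance
``d_max`` and degradation weight), the USLE cover-management (C) and support
practice (P) factors, the sediment filtration efficiency, and the four carbon
pools (above-ground biomass, below-ground biomass, soil organic carbon, dead
organic carbon; all Mg/ha).

The bundled default table describes a tropical mining-province mosaic of
forest, Cerrado savanna, rupestrian grassland and water (habitat) interspersed
with pasture, urban, eucalyptus, mining, roads and agriculture (threats).  Its
pool and factor values are synthetic literature-scale defaults chosen to be
realistic for that system; any real application should supply its own CSV.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("code", "name", "is_habitat", "is_threat")
OPTIONAL_COLUMNS = ("d_max_m", "weight", "usle_c", "usle_p", "filt_eff", "agb", "bgb", "soc", "doc")
POOL_COLUMNS = ("agb", "bgb", "soc", "doc")


class TableValidationError(ValueError):
    """A parameter table violates one of its invariants."""


# Synthetic defaults emulating a SE-Brazil mining-province landscape.
# Pools in Mg/ha; distances in m; C, P, filt_eff dimensionless in [0, 1].
_DEFAULT_TABLE_CSV = """\
code,name,is_habitat,is_threat,d_max_m,weight,usle_c,usle_p,filt_eff,agb,bgb,soc,doc
1,forest,1,0,0,0,0.001,1.0,0.60,115.0,22.97,80.0,6.0
2,cerrado,1,0,0,0,0.010,1.0,0.40,25.0,35.0,60.0,3.0
3,rupestrian_grassland,1,0,0,0,0.010,1.0,0.35,8.0,6.0,30.0,1.0
4,water,1,0,0,0,0.0,1.0,0.80,0.0,0.0,0.0,0.0
5,pasture,0,1,2000,0.6,0.080,1.0,0.25,7.0,9.0,45.0,0.5
6,urban,0,1,5000,1.0,0.010,1.0,0.05,5.0,1.44,20.0,0.0
7,eucalyptus,0,1,1000,0.4,0.050,1.0,0.30,60.0,12.0,50.0,4.0
8,mining,0,1,8000,0.9,1.000,1.0,0.00,0.0,0.0,2.0,0.0
9,roads,0,1,3000,0.7,0.100,1.0,0.00,0.0,0.0,0.0,0.0
10,agriculture,0,1,1500,0.5,0.200,0.5,0.15,5.0,2.0,35.0,1.0
11,forest_edge,1,0,0,0,0.003,1.0,0.55,80.0,16.66,80.0,5.0
"""

#: Code used for forest and the derived forest-edge class in the defaults.
FOREST_CODE = 1
FOREST_EDGE_CODE = 11

# Default per-soil-code erodibility K, ton.ha.h/(ha.MJ.mm); synthetic
# literature-scale values for latosol / argisol / cambisol / litholic soils.
_DEFAULT_SOIL_K_CSV = """\
soil_code,name,k_factor
1,latosol,0.010
2,argisol,0.025
3,cambisol,0.035
4,litholic_neosol,0.045
"""


@dataclass
class LULCTable:
    """Validated per-class parameter table, indexed by integer class code."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"missing required columns: {missing}")
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                log.warning("column %r absent from LULC table; defaulting to 0", col)
                df[col] = 0.0
        df = df.astype({"code": int, "is_habitat": int, "is_threat": int})
        both = df[(df.is_habitat == 1) & (df.is_threat == 1)]
        if len(both):
            raise TableValidationError(
                f"classes marked both habitat and threat: {list(both.code)}"
            )
        bad_dmax = df[(df.is_threat == 1) & (df.d_max_m <= 0)]
        if len(bad_dmax):
            raise TableValidationError(
                f"threat classes need d_max_m > 0: {list(bad_dmax.code)}"
            )
        for col in POOL_COLUMNS:
            if (df[col] < 0).any():
                raise TableValidationError(f"negative values in carbon pool column {col!r}")
        for col in ("usle_c", "usle_p", "filt_eff"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise TableValidationError(f"column {col!r} must lie in [0, 1]")
        if df.code.duplicated().any():
            raise TableValidationError("duplicate class codes in table")
        self.frame = df.set_index("code", drop=False)

    # -- lookups -----------------------------------------------------------
    @property
    def codes(self) -> np.ndarray:
        return self.frame.code.to_numpy()

    @property
    def habitat_codes(self) -> np.ndarray:
        return self.frame.loc[self.frame.is_habitat == 1, "code"].to_numpy()

    @property
    def threat_codes(self) -> np.ndarray:
        return self.frame.loc[self.frame.is_threat == 1, "code"].to_numpy()

    def column_for(self, codes: np.ndarray, column: str) -> np.ndarray:
        """Vector lookup: map an integer raster of class codes to a parameter.

        Raises a :class:`KeyError` naming any unmapped code.
        """
        codes = np.asarray(codes)
        known = self.frame.index.to_numpy()
        lut_size = int(max(known.max(), codes.max(initial=0))) + 1
        lut = np.full(lut_size, np.nan)
        lut[known] = self.frame[column].to_numpy(dtype=float)
        if codes.min(initial=0) < 0:
            raise KeyError(f"negative class code {codes.min()} has no table entry")
        out = lut[codes]
        if np.isnan(out).any():
            missing = sorted(set(np.unique(codes)) - set(known))
            raise KeyError(f"class codes missing from table: {missing}")
        return out

    def threat_params(self) -> pd.DataFrame:
        """Rows for threat classes with their d_max and weight."""
        return self.frame.loc[self.frame.is_threat == 1, ["code", "name", "d_max_m", "weight"]]

    def to_csv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, index=False)


def load_lulc_table(path_or_buffer: str | os.PathLike | io.IOBase) -> LULCTable:
    """Load and validate a per-class parameter table from CSV."""
    return LULCTable(pd.read_csv(path_or_buffer))


def default_lulc_table() -> LULCTable:
    """The bundled synthetic default table (see module docstring)."""
    return load_lulc_table(io.StringIO(_DEFAULT_TABLE_CSV))


def load_soil_k_table(path_or_buffer: str | os.PathLike | io.IOBase) -> pd.DataFrame:
    """Load a soil-code -> K-factor table (columns ``soil_code``, ``k_factor``)."""
    df = pd.read_csv(path_or_buffer)
    for col in ("soil_code", "k_factor"):
        if col not in df.columns:
            raise TableValidationError(f"soil table missing column {col!r}")
    if (df.k_factor < 0).any():
        raise TableValidationError("negative K factors in soil table")
    return df.astype({"soil_code": int}).set_index("soil_code", drop=False)


def default_soil_k_table() -> pd.DataFrame:
    return load_soil_k_table(io.StringIO(_DEFAULT_SOIL_K_CSV))
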