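"""Metabolite registry and growth-reference (LMS) tables.

The registry drives everything downstream that needs per-metabolite
constants: limits of detection (LOD), analytical-standard correction
factors, molecular weights for the DEHP molar sum, and the parent-group
label that marks the four DEHP metabolites (MECPP, MEHHP, MEHP, MEOHP).

LODs in the registry are *raw* (pre-correction) concentrations in ug/L;
corrected LODs are obtained by multiplying with the correction factor
during exposure preparation.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "MetaboliteSpec",
    "LMSRow",
    "DEHP_CODES",
    "default_registry",
    "read_registry",
    "write_registry",
    "read_lms",
    "synthetic_lms_path",
]

#: The four DEHP metabolites entering the molar sum, in registry order.
DEHP_CODES = ("MECPP", "MEHHP", "MEHP", "MEOHP")

_REGISTRY_COLUMNS = ["code", "lod", "correction_factor", "mol_weight", "group"]
_LMS_COLUMNS = ["sex", "age_months", "L", "M", "S"]


class SchemaError(ValueError):
    """A CSV is missing required columns or contains unknown codes."""


@dataclasses.dataclass(frozen=True)
class MetaboliteSpec:
    """One registry entry.

    Parameters
    ----------
    code : str
        Short metabolite name (e.g. ``"MEHP"``).
    lod : float
        Raw limit of detection, ug/L (> 0).
    correction_factor : float
        Multiplier correcting for analytical-standard inaccuracy,
        in (0, 1]; 1.0 when no correction applies.
    mol_weight : float
        Molecular weight, g/mol (equivalently ug/umol).
    group : str
        ``"DEHP"`` for the four DEHP metabolites, else ``"single"``.
    """

    code: str
    lod: float
    correction_factor: float
    mol_weight: float
    group: str

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ValueError(f"{self.code}: lod must be > 0, got {self.lod}")
        if not 0 < self.correction_factor <= 1:
            raise ValueError(
                f"{self.code}: correction_factor must be in (0, 1], "
                f"got {self.correction_factor}"
            )
        if not self.mol_weight > 0:
            raise ValueError(f"{self.code}: mol_weight must be > 0")
        if self.group not in ("DEHP", "single"):
            raise ValueError(f"{self.code}: group must be 'DEHP' or 'single'")

    @property
    def corrected_lod(self) -> float:
        """LOD on the corrected concentration scale, ug/L."""
        return self.lod * self.correction_factor


@dataclasses.dataclass(frozen=True)
class LMSRow:
    """One growth-reference row (skewness L, median M, coefficient of
    variation S) for a given sex and age in months."""

    sex: int
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not self.M > 0 or not self.S > 0:
            raise ValueError("LMS parameters M and S must be > 0")


def _validate_specs(specs: list[MetaboliteSpec]) -> list[MetaboliteSpec]:
    codes = [s.code for s in specs]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        raise SchemaError(f"duplicate metabolite codes: {sorted(dupes)}")
    n_dehp = sum(s.group == "DEHP" for s in specs)
    if n_dehp not in (0, 4):
        raise SchemaError(
            f"registry must carry exactly four DEHP metabolites, found {n_dehp}"
        )
    return specs


def read_registry(path: str | Path) -> list[MetaboliteSpec]:
    """Read a metabolite registry CSV.

    The file must have the header ``code,lod,correction_factor,
    mol_weight,group``. Duplicate codes and invalid values are rejected.
    """
    df = pd.read_csv(path)
    missing = set(_REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"registry file missing columns: {sorted(missing)}")
    specs = [
        MetaboliteSpec(
            code=str(r.code),
            lod=float(r.lod),
            correction_factor=float(r.correction_factor),
            mol_weight=float(r.mol_weight),
            group=str(r.group),
        )
        for r in df.itertuples(index=False)
    ]
    return _validate_specs(specs)


def write_registry(specs: list[MetaboliteSpec], path: str | Path) -> None:
    """Write a registry so that ``read_registry`` round-trips it exactly."""
    df = pd.DataFrame([dataclasses.asdict(s) for s in specs],
                      columns=_REGISTRY_COLUMNS)
    df.to_csv(path, index=False)


def default_registry() -> list[MetaboliteSpec]:
    """The nine-metabolite default registry bundled with the package."""
    with resources.as_file(
        resources.files("phthalmix.data") / "registry_default.csv"
    ) as p:
        return read_registry(p)


def read_lms(path: str | Path) -> pd.DataFrame:
    """Read an LMS growth-reference table (sex, age_months, L, M, S).

    Returns a DataFrame indexed by (sex, age_months) for interpolation-free
    nearest-age lookup by the outcome module.
    """
    df = pd.read_csv(path)
    missing = set(_LMS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"LMS file missing columns: {sorted(missing)}")
    if (df["M"] <= 0).any() or (df["S"] <= 0).any():
        raise ValueError("LMS parameters M and S must be > 0")
    return df[_LMS_COLUMNS].copy()


def synthetic_lms_path() -> Path:
    """Path to the bundled *synthetic* LMS reference table.

    This table is a smooth synthetic stand-in with plausible magnitudes for
    childhood BMI references; it is not a published growth reference and
    exists so z-score machinery is testable without external downloads.
    """
    with resources.as_file(
        resources.files("phthalmix.data") / "lms_synthetic.csv"
    ) as p:
        return p
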