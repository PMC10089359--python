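"""Parameter containers, configuration loading, and the shipped city presets.

A scenario bundles three parameter groups:

* :class:`CohortProfile` — summary of a city's treated hypertensive cohort
  (size, sex mix, mean age, CV-risk-category distribution, blood-pressure
  control rates before and after the program).
* :class:`~htncea.risk.RiskParameters` — the event/mortality machinery
  (10-year CVD risks by sex and risk category, hazard ratios for controlled
  patients, stroke fraction, mortality multiplier, life table).
* :class:`~htncea.econ.EconParameters` — unit costs, utilities, disutilities,
  discount rate, and cost-effectiveness thresholds.

Scenarios are stored as YAML (or JSON, a YAML subset) documents with sections
``cohort``, ``risk``, ``economics`` and a ``life_table_path``.  Three city
presets ship with the package as data files.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "CohortProfile",
    "LifeTable",
    "load_life_table",
    "load_scenario",
    "save_scenario",
    "load_preset",
    "available_presets",
    "extrapolate_cohort",
]

RISK_CATEGORIES = ("low", "medium", "high")
SEXES = ("male", "female")


class CohortProfile(BaseModel):
    """Summary of one city's treated hypertensive patient population."""

    model_config = ConfigDict(validate_assignment=True)

    city_label: str
    n_patients: int = Field(gt=0)
    male_fraction: float = Field(ge=0.0, le=1.0)
    mean_age: float = Field(ge=18.0, le=100.0)
    risk_distribution: dict[str, float]
    control_rate_baseline: float = Field(ge=0.0, le=1.0)
    control_rate_end: float = Field(ge=0.0, le=1.0)
    implementation_years: float = Field(gt=0.0)
    hypertension_threshold_label: str = "140/90 mmHg"

    @field_validator("risk_distribution")
    @classmethod
    def _check_distribution(cls, v: dict[str, float]) -> dict[str, float]:
        missing = set(RISK_CATEGORIES) - set(v)
        if missing:
            raise ValueError(f"risk_distribution missing categories: {sorted(missing)}")
        extra = set(v) - set(RISK_CATEGORIES)
        if extra:
            raise ValueError(f"risk_distribution has unknown categories: {sorted(extra)}")
        if any(p < 0 for p in v.values()):
            raise ValueError("risk_distribution entries must be non-negative")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"risk_distribution must sum to 1, got {total!r}")
        return {k: float(v[k]) for k in RISK_CATEGORIES}

    def sex_fractions(self) -> dict[str, float]:
        return {"male": self.male_fraction, "female": 1.0 - self.male_fraction}


class LifeTable:
    """Age-indexed annual death probabilities q(a).

    Ages must be strictly increasing in 1-year steps; lookups below the first
    age clamp to the first row and lookups beyond the last age clamp to the
    last row.
    """

    def __init__(self, ages: Sequence[int], qx: Sequence[float]):
        ages_arr = np.asarray(ages, dtype=int)
        qx_arr = np.asarray(qx, dtype=float)
        if ages_arr.size == 0:
            raise ValueError("life table is empty")
        if ages_arr.size != qx_arr.size:
            raise ValueError("ages and qx must have equal length")
        steps = np.diff(ages_arr)
        if np.any(steps <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        if np.any(steps != 1):
            raise ValueError("life-table ages must be contiguous (1-year steps)")
        if np.any((qx_arr < 0) | (qx_arr > 1)):
            bad = qx_arr[(qx_arr < 0) | (qx_arr > 1)][0]
            raise ValueError(f"life-table death probability outside [0, 1]: {bad}")
        self.ages = ages_arr
        self.qx = qx_arr

    def lookup(self, age: float) -> float:
        """Annual death probability at ``age``, clamped to the table's range."""
        idx = int(round(age)) - int(self.ages[0])
        idx = min(max(idx, 0), len(self.ages) - 1)
        return float(self.qx[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.ages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTable):
            return NotImplemented
        return np.array_equal(self.ages, other.ages) and np.array_equal(self.qx, other.qx)


def load_life_table(path: str | Path) -> LifeTable:
    """Read a life table from a CSV file with header ``age,qx``."""
    df = pd.read_csv(path)
    expected = {"age", "qx"}
    if not expected.issubset(df.columns):
        raise ValueError(f"life-table file must have columns {sorted(expected)}, got {list(df.columns)}")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def extrapolate_cohort(sampled_count: int, centers_sampled: int, centers_total: int) -> int:
    """Scale a cohort count observed in a sample of centers up to all centers.

    Returns ``round(sampled_count * centers_total / centers_sampled)``, e.g.
    patients counted in 6 of 24 health centers are multiplied by 4.
    """
    if sampled_count <= 0 or centers_sampled <= 0 or centers_total <= 0:
        raise ValueError("all counts must be positive")
    if centers_sampled > centers_total:
        raise ValueError("centers_sampled cannot exceed centers_total")
    return round(sampled_count * centers_total / centers_sampled)


# --------------------------------------------------------------------------
# scenario (de)serialization

_KNOWN_TOP_KEYS = {"cohort", "risk", "economics", "life_table_path"}


def _warn_unknown_keys(section: Mapping, known: set[str], prefix: str) -> None:
    for key in section:
        if key not in known:
            warnings.warn(f"unknown configuration key ignored: {prefix}{key}", stacklevel=3)


def load_scenario(source, base_dir: str | Path | None = None):
    """Load and validate a scenario from a YAML/JSON document.

    Parameters
    ----------
    source
        Path to a YAML/JSON file, a YAML/JSON string, or an already-parsed
        mapping with sections ``cohort``, ``risk``, ``economics`` and a
        ``life_table_path``.
    base_dir
        Directory against which a relative ``life_table_path`` is resolved.
        Defaults to the config file's directory when ``source`` is a path.

    Returns
    -------
    (CohortProfile, RiskParameters, EconParameters)
    """
    from .econ import EconParameters
    from .risk import RiskParameters

    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        path = Path(source)
        if path.exists():
            text = path.read_text()
            if base_dir is None:
                base_dir = path.parent
        else:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValueError("scenario document must be a mapping")

    _warn_unknown_keys(doc, _KNOWN_TOP_KEYS, "")
    for section in ("cohort", "risk", "economics"):
        if section not in doc:
            raise ValueError(f"missing configuration section: {section}")

    cohort_doc = dict(doc["cohort"])
    _warn_unknown_keys(cohort_doc, set(CohortProfile.model_fields), "cohort.")
    cohort_doc = {k: v for k, v in cohort_doc.items() if k in CohortProfile.model_fields}
    profile = CohortProfile(**cohort_doc)

    risk_doc = dict(doc["risk"])
    known_risk = set(RiskParameters.model_fields) - {"life_table"}
    _warn_unknown_keys(risk_doc, known_risk, "risk.")
    risk_doc = {k: v for k, v in risk_doc.items() if k in known_risk}

    life_table = None
    lt_path = doc.get("life_table_path")
    if lt_path is not None:
        lt_path = Path(lt_path)
        if not lt_path.is_absolute() and base_dir is not None:
            lt_path = Path(base_dir) / lt_path
        life_table = load_life_table(lt_path)
    risk = RiskParameters(life_table=life_table, **risk_doc)

    econ_doc = dict(doc["economics"])
    _warn_unknown_keys(econ_doc, set(EconParameters.model_fields), "economics.")
    econ_doc = {k: v for k, v in econ_doc.items() if k in EconParameters.model_fields}
    econ = EconParameters(**econ_doc)

    return profile, risk, econ


def _scenario_dict(profile, risk, econ, life_table_path: str | None) -> dict:
    risk_doc = risk.model_dump(exclude={"life_table"})
    doc = {
        "cohort": profile.model_dump(),
        "risk": risk_doc,
        "economics": econ.model_dump(),
    }
    if life_table_path is not None:
        doc["life_table_path"] = str(life_table_path)
    return doc


def save_scenario(profile, risk, econ, path: str | Path, life_table_path: str | Path | None = None) -> None:
    """Serialize a scenario to YAML; the life table is written alongside.

    If ``life_table_path`` is None and the risk parameters carry a life table,
    it is written next to the config as ``<stem>_life_table.csv``.
    """
    path = Path(path)
    if life_table_path is None and risk.life_table is not None:
        life_table_path = path.with_name(path.stem + "_life_table.csv").name
        risk.life_table.to_csv(path.parent / life_table_path)
    doc = _scenario_dict(profile, risk, econ, life_table_path and str(life_table_path))
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


# --------------------------------------------------------------------------
# shipped presets

_PRESETS = ("ulaanbaatar", "dakar", "dakar_alt", "sao_paulo")


def available_presets() -> tuple[str, ...]:
    return _PRESETS


def load_preset(name: str):
    """Load one of the shipped city scenario presets.

    Available presets: ``ulaanbaatar``, ``dakar``, ``dakar_alt`` (the
    alternative Dakar baseline with a 7% starting control rate), and
    ``sao_paulo``.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(_PRESETS)}")
    pkg_files = resources.files("htncea") / "presets"
    cfg = pkg_files / f"{name}.yaml"
    doc = yaml.safe_load(cfg.read_text())
    lt_name = doc.get("life_table_path")
    if lt_name is not None:
        with resources.as_file(pkg_files / lt_name) as lt_path:
            doc = dict(doc)
            doc["life_table_path"] = str(lt_path)
    return load_scenario(doc)
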