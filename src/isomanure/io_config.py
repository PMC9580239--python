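"""Tabular I/O, domain records and run configuration.

Two CSV dialects are read and written here: a modern calibration table
(one row per modern cereal grain sample with known manuring level) and
an archaeological sample table (one row per charred grain sample with
site covariates and a past-rainfall range). Both are plain
comma-separated UTF-8 with a "." decimal mark and a single header row.
Unknown extra columns are carried through untouched as metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: ordinal coding of manuring intensity; larger = more manure
LEVEL_NAMES = ("low", "medium", "high")
LEVEL_CODES = {"low": 1, "medium": 2, "high": 3}
LEVEL_FROM_CODE = {1: "low", 2: "medium", 3: "high"}


class SchemaError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class ValidationError(ValueError):
    """One or more rows violate a declared invariant.

    The message lists *every* violating row, not only the first.
    """


def level_to_code(level) -> int:
    """Map a level label or code to the ordinal code 1/2/3."""
    if isinstance(level, str):
        key = level.strip().lower()
        if key not in LEVEL_CODES:
            raise ValidationError(f"unparseable manuring level {level!r}")
        return LEVEL_CODES[key]
    code = int(level)
    if code not in LEVEL_FROM_CODE:
        raise ValidationError(f"manuring level code {level!r} not in {{1,2,3}}")
    return code


@dataclass(frozen=True)
class ModernObservation:
    """One modern calibration grain sample with a known manuring level.

    Attributes
    ----------
    d15n : float
        Grain δ15N in ‰ vs AIR.
    rainfall_mm : float
        Mean annual rainfall at the growing location, mm/yr (> 0).
    level : int
        Ordinal manuring level, 1 = low < 2 = medium < 3 = high.
    """

    d15n: float
    rainfall_mm: float
    level: int

    def __post_init__(self):
        if not math.isfinite(self.d15n):
            raise ValidationError("d15n must be finite")
        if not (self.rainfall_mm > 0):
            raise ValidationError(
                f"rainfall_mm must be positive, got {self.rainfall_mm}"
            )
        object.__setattr__(self, "level", level_to_code(self.level))


@dataclass(frozen=True)
class ArchSample:
    """One archaeological grain sample with covariates and rainfall range.

    ``d15n`` is the normalized, charring-corrected grain value (‰ vs AIR);
    ``date_calBC`` is a midpoint in years BC (positive, larger = older);
    ``rain_min_mm``/``rain_max_mm`` bound the past mean annual rainfall.
    ``taxon`` and ``extra`` are carried as metadata only.
    """

    sample_id: str
    region: str
    site: str
    phase: str
    date_calBC: float
    size_ha: float
    d15n: float
    rain_min_mm: float
    rain_max_mm: float
    taxon: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        errs = self.violations()
        if errs:
            raise ValidationError("; ".join(errs))

    def violations(self) -> list[str]:
        errs = []
        if not (self.size_ha > 0):
            errs.append(f"size_ha must be positive, got {self.size_ha}")
        if not (self.rain_min_mm > 0):
            errs.append(f"rain_min_mm must be positive, got {self.rain_min_mm}")
        if self.rain_min_mm > self.rain_max_mm:
            errs.append(
                f"rain_min_mm {self.rain_min_mm} > rain_max_mm {self.rain_max_mm}"
            )
        if not math.isfinite(self.d15n):
            errs.append("d15n must be finite")
        return errs


@dataclass
class MCMCConfig:
    """Sampler settings shared by every MCMC run."""

    chains: int = 2
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    thin: int = 1
    # two-stage (cut / SMI) samplers: completed datasets and stage-2 chainlets
    n_imputations: int = 250
    stage2_warmup: int = 100
    stage2_draws: int = 4
    stage2_thin: int = 5

    def __post_init__(self):
        if self.chains < 2:
            raise ValidationError("chains must be >= 2")
        if self.draws < 1:
            raise ValidationError("draws must be >= 1")


@dataclass
class PriorConfig:
    """Prior hyperparameters, all weakly informative by default.

    Calibration: normal(0, ``beta_scale``) level intercepts constrained to
    the low < medium < high ordering, normal(0, ``lambda_scale``) rainfall
    slope, half-normal(``sigma_scale``) residual ‰ scale. Analysis model:
    normal(0, ``alpha_scale``) ordered cutpoints, normal(0, ``coef_scale``)
    size/date coefficients (symmetric about zero so posterior sign odds
    equal the one-sided Bayes factor), half-normal(``sigma_u_scale``) site
    random-effect scale.
    """

    beta_scale: float = 10.0
    lambda_scale: float = 10.0
    sigma_scale: float = 5.0
    alpha_scale: float = 5.0
    coef_scale: float = 2.5
    sigma_u_scale: float = 1.0


@dataclass
class RunConfig:
    """Top-level run configuration.

    ``eta_grid`` lists SMI influence values in [0, 1]; ``size_transform``
    selects the settlement-size covariate (raw hectares or their natural
    log); ``rainfall_grid`` is the number of Gauss-Legendre nodes used to
    integrate the uniform rainfall prior on each sample's range.
    """

    eta_grid: list = field(default_factory=lambda: [round(0.1 * k, 1) for k in range(11)])
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    charring_offset: float = 0.0
    size_transform: str = "log"
    rainfall_prior: str = "uniform_range"
    priors: PriorConfig = field(default_factory=PriorConfig)
    rainfall_grid: int = 15
    calib_mode: str = "draws"  # {"draws", "plugin"} at the imputation stage
    per_level_slope: bool = False
    include_date: bool = True
    random_effects: bool = True
    direction: str = "negative"  # one-sided hypothesis on the size effect

    def __post_init__(self):
        etas = list(self.eta_grid)
        if len(set(etas)) != len(etas):
            raise ValidationError("eta_grid values must be unique")
        if any(not (0.0 <= e <= 1.0) for e in etas):
            raise ValidationError("eta_grid values must lie in [0, 1]")
        if self.size_transform not in ("identity", "log"):
            raise ValidationError(f"unknown size_transform {self.size_transform!r}")
        if self.rainfall_prior != "uniform_range":
            raise ValidationError(f"unknown rainfall_prior {self.rainfall_prior!r}")
        if self.direction not in ("negative", "positive"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "mcmc" in raw:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "priors" in raw:
            raw["priors"] = PriorConfig(**raw["priors"])
        return cls(**raw)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------------
# CSV readers / writers

_MODERN_REQUIRED = ("d15n", "rainfall_mm", "level")
_ARCH_REQUIRED = (
    "sample_id",
    "region",
    "site",
    "phase",
    "size_ha",
    "d15n",
    "rain_min_mm",
    "rain_max_mm",
)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_modern_table(path) -> list[ModernObservation]:
    """Read a modern calibration CSV into :class:`ModernObservation` rows.

    Required columns: ``d15n``, ``rainfall_mm``, ``level`` (labels
    low/medium/high or codes 1/2/3). All invariant violations are
    collected and reported together.
    """
    df = pd.read_csv(path)
    _require_columns(df, _MODERN_REQUIRED, path)
    out, errs = [], []
    for idx, row in df.iterrows():
        try:
            out.append(
                ModernObservation(
                    d15n=float(row["d15n"]),
                    rainfall_mm=float(row["rainfall_mm"]),
                    level=row["level"],
                )
            )
        except (ValidationError, ValueError) as e:
            errs.append(f"row {idx + 2}: {e}")  # +2: header + 1-based
    if errs:
        raise ValidationError(f"{path}: " + "; ".join(errs))
    return out


def read_arch_table(path) -> list[ArchSample]:
    """Read an archaeological sample CSV into :class:`ArchSample` rows.

    Dates are accepted either as a single ``date_calBC`` midpoint column
    or as a ``date_min_calBC``/``date_max_calBC`` pair (midpoint taken).
    Extra columns are preserved in ``ArchSample.extra``. Duplicate
    ``sample_id`` values and rain-range violations are rejected, with all
    offending rows named.
    """
    df = pd.read_csv(path)
    _require_columns(df, _ARCH_REQUIRED, path)
    has_mid = "date_calBC" in df.columns
    has_range = "date_min_calBC" in df.columns and "date_max_calBC" in df.columns
    if not (has_mid or has_range):
        raise SchemaError(
            f"{path}: need either a date_calBC column or "
            "date_min_calBC/date_max_calBC columns"
        )
    if len(df) == 0:
        logger.warning("%s: empty archaeological table", path)
        return []

    known = set(_ARCH_REQUIRED) | {
        "date_calBC",
        "date_min_calBC",
        "date_max_calBC",
        "taxon",
    }
    extra_cols = [c for c in df.columns if c not in known]

    out, errs = [], []
    seen_ids: dict[str, int] = {}
    for idx, row in df.iterrows():
        rownum = idx + 2
        sid = str(row["sample_id"])
        if sid in seen_ids:
            errs.append(f"row {rownum}: duplicate sample_id {sid!r} (first at row {seen_ids[sid]})")
            continue
        seen_ids[sid] = rownum
        date = (
            float(row["date_calBC"])
            if has_mid
            else 0.5 * (float(row["date_min_calBC"]) + float(row["date_max_calBC"]))
        )
        try:
            out.append(
                ArchSample(
                    sample_id=sid,
                    region=str(row["region"]),
                    site=str(row["site"]),
                    phase=str(row["phase"]),
                    date_calBC=date,
                    size_ha=float(row["size_ha"]),
                    d15n=float(row["d15n"]),
                    rain_min_mm=float(row["rain_min_mm"]),
                    rain_max_mm=float(row["rain_max_mm"]),
                    taxon=str(row["taxon"]) if "taxon" in df.columns else "",
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except (ValidationError, ValueError) as e:
            errs.append(f"row {rownum}: {e}")
    if errs:
        raise ValidationError(f"{path}: " + "; ".join(errs))
    return out


def write_modern_table(obs: Sequence[ModernObservation], path) -> None:
    df = pd.DataFrame(
        {
            "d15n": [o.d15n for o in obs],
            "rainfall_mm": [o.rainfall_mm for o in obs],
            "level": [LEVEL_FROM_CODE[o.level] for o in obs],
        }
    )
    df.to_csv(path, index=False)


def write_arch_table(samples: Sequence[ArchSample], path) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "region": s.region,
            "site": s.site,
            "phase": s.phase,
            "date_calBC": s.date_calBC,
            "size_ha": s.size_ha,
            "d15n": s.d15n,
            "rain_min_mm": s.rain_min_mm,
            "rain_max_mm": s.rain_max_mm,
            "taxon": s.taxon,
        }
        row.update(s.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
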