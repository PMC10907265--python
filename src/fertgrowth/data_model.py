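"""Woman-level reproductive records: schema, validation, I/O and predictor transforms.

The working representation is a pair of :class:`pandas.DataFrame` objects —
one row per woman (``woman_id``, ``population_id``, ``age``, ``live_births``,
optional ``birth_year``, plus raw predictor columns) and one row per
population (``population_id``, ``subsistence_type``, ``market_integration``,
``n_women``).  Continuous predictors are standardized *within* population so
that effects compare relative variation inside each site rather than absolute
scale differences between sites; count/amount predictors (livestock, land,
income, years of education) are log(x+1)-transformed first because zeros are
legitimate values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSISTENCE_TYPES = (
    "hunter-gatherer",
    "horticulturalist",
    "agriculturalist",
    "pastoralist",
    "fisher",
)
MI_LEVELS = ("low", "medium", "high")

REQUIRED_COLUMNS = ("woman_id", "population_id", "age", "live_births")

#: minimum age at interview — women are included once reproductively mature
MIN_AGE = 14.0

TRANSFORMS = ("zscore", "log1p_then_zscore", "binary")


class ValidationError(ValueError):
    """A record table violates a hard invariant; message lists offending rows."""


@dataclass(frozen=True)
class PredictorSpec:
    """How one predictor column enters the model.

    ``zscore`` for proportions (already on [0,1]), ``log1p_then_zscore`` for
    counts/amounts that legitimately take 0, ``binary`` for 0/1 codings
    (waged occupation, urban residence, contraception).
    """

    name: str
    transform: str
    direction_note: str = ""

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def zcol(self) -> str:
        """Name of the standardized column this spec produces."""
        return f"{self.name}__z"


@dataclass
class ModelDataset:
    """Arrays ready for likelihood evaluation: one focal predictor subset.

    ``z`` is None for intercept-only / group-level models.  ``pop_index``
    maps each woman to ``pop_ids`` (0-based, dense).
    """

    y: np.ndarray
    age: np.ndarray
    pop_index: np.ndarray
    pop_ids: list
    z: np.ndarray | None = None
    predictor: PredictorSpec | None = None
    meta: pd.DataFrame | None = None
    woman_id: np.ndarray | None = None
    birth_year_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.age = np.asarray(self.age, dtype=float)
        self.pop_index = np.asarray(self.pop_index, dtype=np.intp)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_populations(self) -> int:
        return len(self.pop_ids)

    def n_by_population(self) -> pd.Series:
        counts = np.bincount(self.pop_index, minlength=self.n_populations)
        return pd.Series(counts, index=pd.Index(self.pop_ids, name="population_id"))

    def group_index(self, grouping: str) -> tuple[np.ndarray, list]:
        """Per-population group codes for ``subsistence_type`` or ``market_integration``."""
        if self.meta is None:
            raise ValueError("dataset carries no population metadata")
        if grouping not in ("subsistence_type", "market_integration"):
            raise ValueError(f"unknown grouping {grouping!r}")
        meta = self.meta.set_index("population_id").loc[self.pop_ids]
        values = meta[grouping].tolist()
        if grouping == "market_integration":
            levels = [g for g in MI_LEVELS if g in values]
        else:
            levels = [g for g in SUBSISTENCE_TYPES if g in values]
        code = {g: i for i, g in enumerate(levels)}
        pop_group = np.array([code[v] for v in values], dtype=np.intp)
        return pop_group, levels


def validate_records(
    records: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    specs: Sequence[PredictorSpec] = (),
) -> None:
    """Raise :class:`ValidationError` naming offending rows on hard violations.

    Missing predictor cells are allowed (availability varies by site); the
    hard invariants are age >= 14, integer parity >= 0, known populations,
    proportions on [0,1] and non-negative amounts.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    problems: list[str] = []

    def bad(mask: pd.Series, msg: str) -> None:
        if mask.any():
            rows = records.index[mask].tolist()[:20]
            ids = records.loc[mask, "woman_id"].tolist()[:20]
            problems.append(f"{msg}: rows {rows} (woman_id {ids})")

    age = pd.to_numeric(records["age"], errors="coerce")
    births = pd.to_numeric(records["live_births"], errors="coerce")
    bad(age.isna(), "non-numeric age")
    bad(age.notna() & (age < MIN_AGE), f"age below {MIN_AGE:g}")
    bad(births.isna(), "non-numeric live_births")
    with np.errstate(invalid="ignore"):
        bad(births.notna() & ((births < 0) | (births % 1 != 0)), "live_births not a non-negative integer")

    if meta is not None:
        known = set(meta["population_id"])
        bad(~records["population_id"].isin(known), "unknown population_id")
        bad_sub = ~meta["subsistence_type"].isin(SUBSISTENCE_TYPES)
        if bad_sub.any():
            problems.append(f"unknown subsistence_type: {sorted(meta.loc[bad_sub, 'subsistence_type'].unique())}")
        bad_mi = ~meta["market_integration"].isin(MI_LEVELS)
        if bad_mi.any():
            problems.append(f"unknown market_integration: {sorted(meta.loc[bad_mi, 'market_integration'].unique())}")

    for spec in specs:
        if spec.name not in records.columns:
            continue
        x = pd.to_numeric(records[spec.name], errors="coerce")
        present = records[spec.name].notna()
        if spec.transform == "zscore":
            bad(present & ((x < 0) | (x > 1)), f"proportion predictor {spec.name!r} outside [0,1]")
        elif spec.transform == "log1p_then_zscore":
            bad(present & (x < 0), f"amount predictor {spec.name!r} negative")
        elif spec.transform == "binary":
            bad(present & ~x.isin([0, 1]), f"binary predictor {spec.name!r} not 0/1")

    if problems:
        raise ValidationError("; ".join(problems))


def read_records(
    path,
    meta_path=None,
    specs: Sequence[PredictorSpec] = (),
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read the woman-level CSV (and optional population CSV) and validate.

    ``column_map`` renames file columns to canonical names before validation.
    Missing predictor cells are preserved as NaN, never imputed.
    """
    try:
        records = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    if column_map:
        records = records.rename(columns=dict(column_map))
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
    validate_records(records, meta, specs)
    if meta is not None:
        counts = records.groupby("population_id").size()
        if "n_women" in meta.columns:
            declared = meta.set_index("population_id")["n_women"]
            mismatch = declared.reindex(counts.index).fillna(-1) != counts
            if mismatch.any():
                raise ValidationError(
                    f"n_women mismatch for populations {counts.index[mismatch].tolist()}"
                )
        else:
            meta = meta.assign(n_women=meta["population_id"].map(counts).fillna(0).astype(int))
    return records, meta


def write_records(records: pd.DataFrame, path, meta: pd.DataFrame | None = None, meta_path=None) -> None:
    """Write the CSV dialect :func:`read_records` reads (round-trip safe)."""
    records.to_csv(path, index=False)
    if meta is not None and meta_path is not None:
        meta.to_csv(meta_path, index=False)


def standardize(
    records: pd.DataFrame,
    spec: PredictorSpec,
    min_nonmissing: int = 2,
) -> pd.DataFrame:
    """Add the within-population standardized column ``spec.zcol``.

    Continuous predictors are z-scored inside each population (sample SD,
    denominator n−1); ``log1p_then_zscore`` applies log(x+1) first.  Binary
    predictors pass through as 0/1.  Populations with fewer than
    ``min_nonmissing`` observed values, or zero variance, get NaN for the
    whole population (dropped from that model's subset) with a logged warning.
    """
    if spec.name not in records.columns:
        raise KeyError(f"predictor column {spec.name!r} not in records")
    out = records.copy()
    x = pd.to_numeric(out[spec.name], errors="coerce")

    if spec.transform == "binary":
        out[spec.zcol] = x
        return out
    if spec.transform == "log1p_then_zscore":
        x = np.log1p(x)

    z = pd.Series(np.nan, index=out.index, dtype=float)
    for pop, idx in out.groupby("population_id").groups.items():
        xi = x.loc[idx]
        obs = xi.dropna()
        if len(obs) < min_nonmissing:
            if len(obs) > 0:
                logger.warning(
                    "predictor %s: population %s has %d non-missing values (<%d); dropped",
                    spec.name, pop, len(obs), min_nonmissing,
                )
            continue
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning(
                "predictor %s: population %s has zero within-population variance; dropped",
                spec.name, pop,
            )
            continue
        z.loc[idx] = (xi - obs.mean()) / sd
    out[spec.zcol] = z
    return out


def build_model_subset(
    records: pd.DataFrame,
    meta: pd.DataFrame | None,
    spec: PredictorSpec | None = None,
    birth_year_control: bool = False,
) -> ModelDataset:
    """Listwise-delete to the women with a usable focal-predictor value.

    With ``spec=None`` the full table is used (intercept-only / group-level
    models).  The returned dataset records per-population sample sizes and the
    populations' subsistence type and market-integration level for reporting.
    """
    df = records
    z = None
    if spec is not None:
        col = spec.zcol if spec.zcol in df.columns else None
        if col is None:
            df = standardize(df, spec)
            col = spec.zcol
        keep = df[col].notna()
        dropped_pops = sorted(set(df["population_id"]) - set(df.loc[keep, "population_id"]))
        if dropped_pops:
            logger.info("predictor %s: no usable data in populations %s", spec.name, dropped_pops)
        df = df.loc[keep]
        if df.empty:
            raise ValueError(f"no populations provide predictor {spec.name!r}")
        z = df[col].to_numpy(dtype=float)

    pop_ids = sorted(df["population_id"].unique())
    code = {p: i for i, p in enumerate(pop_ids)}
    pop_index = df["population_id"].map(code).to_numpy(dtype=np.intp)
    sub_meta = None
    if meta is not None:
        sub_meta = meta[meta["population_id"].isin(pop_ids)].reset_index(drop=True)

    byz = None
    if birth_year_control:
        if "birth_year" not in df.columns:
            raise ValueError("birth_year_control requested but no birth_year column")
        by = pd.to_numeric(df["birth_year"], errors="coerce")
        byz = ((by - by.mean()) / by.std(ddof=1)).to_numpy(dtype=float)

    return ModelDataset(
        y=df["live_births"].to_numpy(),
        age=df["age"].to_numpy(dtype=float),
        pop_index=pop_index,
        pop_ids=pop_ids,
        z=z,
        predictor=spec,
        meta=sub_meta,
        woman_id=df["woman_id"].to_numpy(),
        birth_year_z=byz,
    )
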