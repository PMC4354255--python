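"""Experimental design, tabular I/O, exclusion filters and QC diagnostics.

The experiments are community-module feeding trials: one focal amphipod
predator (native *Gammarus duebeni celticus* or invasive *G. pulex*,
parasitised or not) in a pot of prey at a fixed density, inside an aquarium
with or without a higher-order fish predator whose cues reach the pot.  For
each of three prey species the design is fully factorial:
2 predators x 2 parasitism states x 2 fish states x 7 densities
(2, 4, 6, 8, 10, 20, 30) x 4 replicates = 224 pots per prey species.

Trial tables are plain CSV, one row per pot.  Booleans are written as
``true``/``false``; categorical levels use the exact strings in
:data:`PREY_SPECIES` and :data:`PREDATOR_SPECIES`.  Unknown columns are
preserved on read and written back unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PREY_SPECIES",
    "PREDATOR_SPECIES",
    "DENSITY_LADDER",
    "INFECTION_STAGES",
    "TRIAL_COLUMNS",
    "CONTROL_COLUMNS",
    "SchemaError",
    "ValidationError",
    "enumerate_design",
    "read_records",
    "write_records",
    "read_controls",
    "write_controls",
    "validate_trials",
    "validate_controls",
    "filter_replicates",
    "control_survival_qc",
    "day_bias_diagnostic",
    "QCReport",
    "DayBiasResult",
]

PREY_SPECIES = ("A_aquaticus", "Simulium", "B_rhodani")
PREDATOR_SPECIES = ("G_d_celticus", "G_pulex")
DENSITY_LADDER = (2, 4, 6, 8, 10, 20, 30)
INFECTION_STAGES = (
    "none",
    "single_cystacanth",
    "acanthella",
    "multiple_cystacanths",
    "spore_mass",
)

#: mandatory trial-table columns, in canonical order
TRIAL_COLUMNS = [
    "pot_id",
    "prey_species",
    "predator_species",
    "parasitised",
    "fish_present",
    "density",
    "replicate",
    "day",
    "killed",
    "partially_eaten",
    "moulted",
    "infection_stage",
]

#: mandatory control-table columns
CONTROL_COLUMNS = ["prey_species", "density", "fish_present", "dead"]

_BOOL_COLUMNS = ("parasitised", "fish_present", "moulted")

#: pots started per batch, one batch every three days
POTS_PER_DAY_BATCH = 22
DAY_BATCH_SPACING = 3


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a record invariant (e.g. killed > density)."""


def enumerate_design(
    predator_levels=PREDATOR_SPECIES,
    parasitism_levels=(False, True),
    fish_levels=(False, True),
    density_ladder=DENSITY_LADDER,
    replicates=4,
    prey_list=PREY_SPECIES,
    seed=None,
):
    """Enumerate the factorial design as one row per experimental pot.

    Returns a DataFrame with columns ``pot_id, prey_species, predator_species,
    parasitised, fish_present, density, replicate, day`` in a deterministic
    order (prey, predator, parasitism, fish, density, replicate).  Start days
    follow the staggered schedule of 22 pots initiated every three days,
    allocated per prey species; the allocation is randomised only when a
    ``seed`` is supplied, otherwise it follows enumeration order.
    """
    for name, levels in (
        ("predator_levels", predator_levels),
        ("parasitism_levels", parasitism_levels),
        ("fish_levels", fish_levels),
        ("density_ladder", density_ladder),
        ("prey_list", prey_list),
    ):
        if len(tuple(levels)) == 0:
            raise ValueError(f"{name} must be nonempty")
    densities = tuple(density_ladder)
    if len(set(densities)) != len(densities):
        raise ValueError(f"density ladder contains duplicates: {densities}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")

    rng = np.random.default_rng(seed) if seed is not None else None
    frames = []
    for prey in prey_list:
        rows = [
            {
                "prey_species": prey,
                "predator_species": pred,
                "parasitised": bool(par),
                "fish_present": bool(fish),
                "density": int(n0),
                "replicate": int(rep),
            }
            for pred, par, fish, n0, rep in itertools.product(
                predator_levels,
                parasitism_levels,
                fish_levels,
                densities,
                range(1, replicates + 1),
            )
        ]
        df = pd.DataFrame(rows)
        n = len(df)
        order = np.arange(n)
        if rng is not None:
            rng.shuffle(order)
        day = np.empty(n, dtype=int)
        day[order] = 1 + DAY_BATCH_SPACING * (np.arange(n) // POTS_PER_DAY_BATCH)
        df["day"] = day
        df.insert(0, "pot_id", [f"{prey}-{i + 1:04d}" for i in range(n)])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[
        [
            "pot_id",
            "prey_species",
            "predator_species",
            "parasitised",
            "fish_present",
            "density",
            "replicate",
            "day",
        ]
    ]


def _require_columns(df, columns, what):
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing mandatory column {col!r}")


def _coerce_bool(series, col):
    def parse(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in ("true", "1"):
            return True
        if s in ("false", "0"):
            return False
        raise ValidationError(f"column {col!r}: cannot parse boolean value {v!r}")

    return series.map(parse).astype(bool)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type-coerce a trial table; returns a fresh DataFrame.

    Raises :class:`SchemaError` for missing mandatory columns and
    :class:`ValidationError` (naming the 0-based data row) for invariant
    breaches.  Unknown columns are kept untouched.
    """
    _require_columns(df, TRIAL_COLUMNS, "trial")
    df = df.copy()
    for col in _BOOL_COLUMNS:
        df[col] = _coerce_bool(df[col], col)
    for col in ("density", "replicate", "day", "killed", "partially_eaten"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    for col in ("pot_id", "prey_species", "predator_species", "infection_stage"):
        df[col] = df[col].astype(str)

    for i, row in enumerate(df.itertuples(index=False)):
        if row.density <= 0:
            raise ValidationError(f"row {i}: density must be positive, got {row.density}")
        if not 0 <= row.killed <= row.density:
            raise ValidationError(
                f"row {i}: killed={row.killed} outside [0, density={row.density}]"
            )
        if not 0 <= row.partially_eaten <= row.killed:
            raise ValidationError(
                f"row {i}: partially_eaten={row.partially_eaten} outside "
                f"[0, killed={row.killed}]"
            )
        if row.partially_eaten > 0 and row.killed < 2:
            raise ValidationError(
                f"row {i}: partial consumption recorded with fewer than 2 kills"
            )
        if row.infection_stage not in INFECTION_STAGES:
            raise ValidationError(
                f"row {i}: unknown infection_stage {row.infection_stage!r}"
            )
    return df


def validate_controls(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, CONTROL_COLUMNS, "control")
    df = df.copy()
    df["fish_present"] = _coerce_bool(df["fish_present"], "fish_present")
    for col in ("density", "dead"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    df["prey_species"] = df["prey_species"].astype(str)
    for i, row in enumerate(df.itertuples(index=False)):
        if not 0 <= row.dead <= row.density:
            raise ValidationError(
                f"row {i}: dead={row.dead} outside [0, density={row.density}]"
            )
    return df


def _write_csv(df, path, bool_cols):
    out = df.copy()
    for col in bool_cols:
        if col in out.columns:
            out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read and validate a trial CSV (UTF-8, comma-delimited, header row)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        _require_columns(df, TRIAL_COLUMNS, "trial")
        return validate_trials(df.astype(object))
    return validate_trials(df)


def write_records(records: pd.DataFrame, path) -> None:
    """Write a trial table; ``write_records`` then :func:`read_records` is identity."""
    _write_csv(records, path, _BOOL_COLUMNS)


def read_controls(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CONTROL_COLUMNS, "control")
    return validate_controls(df)


def write_controls(controls: pd.DataFrame, path) -> None:
    _write_csv(controls, path, ("fish_present",))


# exclusion reasons, in the priority order they are assigned
EXCLUSION_REASONS = (
    "moulted",
    "acanthella",
    "multiple_cystacanths",
    "parasite_status_mismatch",
)


def filter_replicates(records: pd.DataFrame, exclude_status_mismatch: bool = True):
    """Partition trials into (kept, excluded-with-reasons).

    Exclusion rules mirror the experimental protocol: pots where the amphipod
    moulted, and parasitised pots whose post-trial dissection found pre-infective
    acanthella or multiple cystacanths, are removed.  Pots whose dissection
    contradicts the initial parasite-status assignment are excluded by default
    (``exclude_status_mismatch=False`` keeps them, leaving reassignment to the
    caller).  Every excluded row carries an ``exclusion_reason``; kept and
    excluded rows partition the input.
    """
    records = records.reset_index(drop=True)
    reasons = pd.Series([""] * len(records), dtype=object)

    moulted = records["moulted"]
    acanthella = records["infection_stage"] == "acanthella"
    multiple = records["infection_stage"] == "multiple_cystacanths"
    mismatch = (records["parasitised"] & (records["infection_stage"] == "none")) | (
        ~records["parasitised"] & (records["infection_stage"] != "none")
    )

    reasons[mismatch & exclude_status_mismatch] = "parasite_status_mismatch"
    reasons[multiple] = "multiple_cystacanths"
    reasons[acanthella] = "acanthella"
    reasons[moulted] = "moulted"

    excluded_mask = reasons != ""
    kept = records[~excluded_mask].reset_index(drop=True)
    excluded = records[excluded_mask].reset_index(drop=True)
    excluded = excluded.assign(exclusion_reason=reasons[excluded_mask].to_numpy())
    return kept, excluded


@dataclass
class QCReport:
    """Control-pot survival, per (prey, fish) stratum and overall."""

    table: pd.DataFrame
    overall_survival: float
    threshold: float
    passed: bool


def control_survival_qc(controls: pd.DataFrame, threshold: float = 0.965) -> QCReport:
    """Prey survival in predator-free control pots.

    Survival per stratum is ``1 - sum(dead) / sum(density)``; the QC passes
    when overall survival exceeds ``threshold`` (default 0.965, the reported
    benchmark that attributes treatment mortality to amphipod predation).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(controls) == 0:
        raise ValueError("control table is empty: survival QC is impossible")
    rows = []
    for (prey, fish), grp in controls.groupby(["prey_species", "fish_present"]):
        exposed = grp["density"].sum()
        dead = grp["dead"].sum()
        rows.append(
            {
                "prey_species": prey,
                "fish_present": fish,
                "n_pots": len(grp),
                "prey_exposed": int(exposed),
                "prey_dead": int(dead),
                "survival": 1.0 - dead / exposed,
            }
        )
    table = pd.DataFrame(rows)
    overall = 1.0 - controls["dead"].sum() / controls["density"].sum()
    return QCReport(
        table=table,
        overall_survival=float(overall),
        threshold=threshold,
        passed=bool(overall > threshold),
    )


@dataclass
class DayBiasResult:
    """Spearman rank correlation between start day and kills within a module."""

    rho: float
    p: float
    n: int
    method: str  # "asymptotic", "exact", or "not_assessable"
    assessable: bool
    table: pd.DataFrame = field(repr=False, default=None)


def _spearman_rho(x_rank, y_rank):
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


#: sample size at or below which the day-bias p-value is computed by full
#: permutation enumeration rather than the large-sample approximation
EXACT_PERMUTATION_N = 8


def day_bias_diagnostic(records: pd.DataFrame) -> DayBiasResult:
    """Check for drift of kill counts across experiment start days.

    Trials are run in staggered batches; a trend of kills with start day would
    confound treatment comparisons.  Returns the Spearman correlation between
    ``day`` and ``killed`` for the supplied (single-module) records, with a
    plot-ready ``(day, killed)`` table.  The p-value uses the large-sample
    t approximation, or exact permutation enumeration when n <= 8.  Constant
    kills (or a single day with >= 3 rows) give rho = 0 by convention; fewer
    than 3 distinct days with tiny n is flagged not assessable.
    """
    table = records[["day", "killed"]].reset_index(drop=True)
    n = len(table)
    days = table["day"].to_numpy(dtype=float)
    kills = table["killed"].to_numpy(dtype=float)
    if n < 3 or len(np.unique(days)) < 2:
        if n >= 3 and len(np.unique(days)) == 1:
            return DayBiasResult(0.0, 1.0, n, "not_assessable", False, table)
        return DayBiasResult(np.nan, np.nan, n, "not_assessable", False, table)

    if np.ptp(kills) == 0 or np.ptp(days) == 0:
        return DayBiasResult(0.0, 1.0, n, "degenerate", True, table)

    x_rank = stats.rankdata(days)
    y_rank = stats.rankdata(kills)
    rho = _spearman_rho(x_rank, y_rank)

    if n <= EXACT_PERMUTATION_N:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(x_rank, y_rank[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return DayBiasResult(rho, count / total, n, "exact", True, table)

    rho_s, p = stats.spearmanr(days, kills)
    return DayBiasResult(float(rho_s), float(p), n, "asymptotic", True, table)
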