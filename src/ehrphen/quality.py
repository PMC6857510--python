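"""Data-quality gates: patient acceptability, practice up-to-standard dates,
and continuous-measurement harmonization.

Linked primary-care research conventionally restricts to (a) patients whose
records pass basic plausibility checks ("acceptable for research") and
(b) periods during which a practice's recording is judged continuously
research-quality — the practice's *up-to-standard* (UTS) date.  The UTS date
rests on two detectors: gap analysis (prolonged unexplained pauses in event
recording) and death-recording analysis (observed vs expected deaths); the
UTS date is the latest date flagged by either detector, falling back to the
first recording date when neither fires.

Continuous measurements arrive with mixed units, wrong-scale values recorded
under an incorrect unit label (e.g. values on a g/L scale labelled g/dL),
and zeros that mean "missing" for some analytes (ferritin) but are true
undetectable values for others (basophils).  :func:`harmonize_measurements`
normalizes each value to a canonical unit, applies per-analyte zero
semantics, optional factor-10 scale correction, and a valid-range filter,
labelling every value with an explicit status rather than silently dropping
anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoDataError

ACCEPTABILITY_REASONS = (
    "missing_registration",
    "registration_before_birth",
    "invalid_gender",
    "malformed_date",
    "future_date",
    "noncontinuous_followup",
)

VALID_GENDERS = frozenset({"M", "F", "I"})  # male / female / indeterminate

MEASUREMENT_STATUSES = (
    "valid",
    "rescaled",
    "converted",
    "zero_missing",
    "out_of_range",
    "unit_unknown",
)


@dataclass
class AcceptabilityResult:
    patient_id: str
    accepted: bool
    reasons: tuple[str, ...]


def _parse_date(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        ts = pd.Timestamp(str(value))
    except (ValueError, TypeError):
        return "malformed"
    if pd.isna(ts):
        return None
    return ts


def assess_acceptability(
    patients: pd.DataFrame, last_collection_date: str | None = None
) -> pd.DataFrame:
    """Apply patient-level plausibility rules; one result row per patient.

    Rules (each violated rule is listed independently):

    * ``missing_registration`` — empty first registration date;
    * ``registration_before_birth`` — first registration precedes birth;
    * ``invalid_gender`` — gender outside {M, F, I};
    * ``malformed_date`` — any unparseable date field;
    * ``future_date`` — any date after ``last_collection_date``;
    * ``noncontinuous_followup`` — a later registration period starts after
      the previous one ended (an uncovered gap in follow-up).

    Returns a DataFrame with columns patient_id, accepted, reasons
    (semicolon-joined); ``accepted`` is true iff reasons is empty.
    """
    last = pd.Timestamp(last_collection_date) if last_collection_date else None
    rows = []
    date_cols = [c for c in patients.columns if "date" in c or c.startswith("reg_")]
    for rec in patients.to_dict("records"):
        reasons: list[str] = []
        birth = _parse_date(rec.get("birth_date"))
        reg = _parse_date(rec.get("reg_start"))
        malformed = False
        for col in date_cols:
            if _parse_date(rec.get(col)) == "malformed":
                malformed = True
        if malformed:
            reasons.append("malformed_date")
        if reg is None:
            reasons.append("missing_registration")
        elif reg != "malformed" and isinstance(birth, pd.Timestamp) and reg < birth:
            reasons.append("registration_before_birth")
        if str(rec.get("gender", "")) not in VALID_GENDERS:
            reasons.append("invalid_gender")
        if last is not None:
            for col in date_cols:
                d = _parse_date(rec.get(col))
                if isinstance(d, pd.Timestamp) and d > last:
                    reasons.append("future_date")
                    break
        end1 = _parse_date(rec.get("reg_end"))
        start2 = _parse_date(rec.get("reg_start_2"))
        if (
            isinstance(end1, pd.Timestamp)
            and isinstance(start2, pd.Timestamp)
            and start2 > end1
        ):
            reasons.append("noncontinuous_followup")
        reasons = sorted(set(reasons))
        rows.append(
            {
                "patient_id": rec["patient_id"],
                "accepted": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "accepted", "reasons"])


# ---------------------------------------------------------------------------
# Practice up-to-standard date
# ---------------------------------------------------------------------------

@dataclass
class UtsParams:
    """Thresholds for the two UTS detectors.

    gap_days
        a pause in event recording longer than this flags a gap.
    window_days
        length of the rolling window for the death-recording detector.
    death_ratio_min
        flag a window when observed/expected deaths falls below this.
    """

    gap_days: int = 90
    window_days: int = 365
    death_ratio_min: float = 0.5


@dataclass
class UtsResult:
    practice_id: object
    gap_date: pd.Timestamp | None
    death_date: pd.Timestamp | None
    uts_date: pd.Timestamp


def derive_uts(
    event_dates,
    death_dates,
    reference_death_rate: float,
    params: UtsParams | None = None,
    practice_id=None,
    person_years_per_day: float | None = None,
) -> UtsResult:
    """Derive a practice's up-to-standard date from its recording history.

    Gap analysis scans the daily event-count series for pauses longer than
    ``params.gap_days``; ``gap_date`` is the day after the end of the last
    such pause.  Death-recording analysis slides a ``window_days`` window
    over the series span and compares recorded deaths with the expected
    count ``reference_death_rate x person-time``; ``death_date`` is the end
    of the last under-recording window.  The UTS date is the latest of the
    two detector dates, else the first recording date.

    Parameters
    ----------
    event_dates : iterable of date-like
        all recorded event dates at the practice.
    death_dates : iterable of date-like
        death dates recorded *by the practice*.
    reference_death_rate : float
        expected deaths per person-year in the practice population.
    person_years_per_day : float, optional
        practice person-time contributed per calendar day (population size /
        365.25); defaults to treating ``reference_death_rate`` as expected
        deaths per day.
    """
    params = params or UtsParams()
    events = pd.to_datetime(pd.Series(list(event_dates)), errors="coerce").dropna()
    if events.empty:
        raise NoDataError("practice has no recorded events")
    deaths = pd.to_datetime(pd.Series(list(death_dates)), errors="coerce").dropna()

    first = events.min().normalize()
    last = events.max().normalize()
    n_days = (last - first).days + 1
    counts = np.zeros(n_days, dtype="int64")
    idx = ((events.dt.normalize() - first).dt.days).to_numpy()
    np.add.at(counts, idx, 1)

    # --- gap detector: last run of zero-count days longer than gap_days ----
    gap_date = None
    zero = counts == 0
    if zero.any():
        # run-length encode the zero mask
        change = np.flatnonzero(np.diff(zero.astype("int8")))
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [n_days - 1]])
        for s, e in zip(starts, ends):
            if zero[s] and (e - s + 1) > params.gap_days:
                gap_date = first + pd.Timedelta(days=int(e) + 1)

    # --- death-recording detector ------------------------------------------
    death_date = None
    if reference_death_rate > 0 and n_days >= params.window_days:
        dcounts = np.zeros(n_days, dtype="int64")
        within = deaths[(deaths >= first) & (deaths <= last)]
        didx = ((within.dt.normalize() - first).dt.days).to_numpy()
        np.add.at(dcounts, didx, 1)
        csum = np.concatenate([[0], np.cumsum(dcounts)])
        w = params.window_days
        observed = csum[w:] - csum[:-w]  # deaths in [i, i+w)
        py_per_day = (
            person_years_per_day if person_years_per_day is not None else 1.0
        )
        expected = reference_death_rate * py_per_day * w
        flagged = np.flatnonzero(observed / expected < params.death_ratio_min)
        if flagged.size:
            end_idx = int(flagged[-1]) + w - 1  # last day of last flagged window
            death_date = first + pd.Timedelta(days=end_idx)

    components = [d for d in (gap_date, death_date) if d is not None]
    uts_date = max(components) if components else first
    return UtsResult(
        practice_id=practice_id,
        gap_date=gap_date,
        death_date=death_date,
        uts_date=uts_date,
    )


# ---------------------------------------------------------------------------
# Measurement harmonization
# ---------------------------------------------------------------------------

@dataclass
class MeasurementPolicy:
    """Per-analyte harmonization rules.

    ``unit_factors`` maps a recorded unit label to the multiplicative factor
    converting it to the canonical unit (the canonical label itself is
    implicitly 1).  ``valid_range`` is expressed in the canonical unit.
    ``zero_is_missing`` encodes the analyte's zero semantics: an impossible
    zero (ferritin) is treated as missing; a plausible zero (basophils) is a
    true undetectable value.  ``scale_correction_enabled`` turns on
    factor-10 rescue of out-of-range values.
    """

    analyte: str
    canonical_unit: str
    valid_range: tuple[float, float]
    unit_factors: dict[str, float] = field(default_factory=dict)
    zero_is_missing: bool = False
    scale_correction_enabled: bool = True

    def __post_init__(self):
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"valid range for {self.analyte} must satisfy lo < hi")
        if any(f <= 0 for f in self.unit_factors.values()):
            raise ValueError("unit conversion factors must be positive")


def harmonize_measurements(
    measurements: pd.DataFrame, policies: dict[str, MeasurementPolicy]
) -> pd.DataFrame:
    """Normalize raw measurements to canonical units with explicit statuses.

    Per-value pipeline: (1) convert to the canonical unit when the recorded
    unit label has a known factor (unknown labels get status
    ``unit_unknown``); (2) apply zero semantics; (3) if the value is outside
    the valid range and scale correction is enabled, try dividing or
    multiplying by 10 — if exactly one candidate lands in range, adopt it
    with status ``rescaled``; if both candidates are in range the value is
    ambiguous and is kept with status ``out_of_range`` and ``ambiguous``
    True; (4) remaining out-of-range values get ``out_of_range``.

    Returns a copy with columns ``value`` (canonical unit; NaN when
    ``zero_missing``), ``unit`` (canonical), ``status`` and ``ambiguous``.
    """
    missing = sorted(set(measurements["analyte"]) - set(policies))
    if missing:
        raise KeyError(f"no harmonization policy for analytes: {missing}")

    out = measurements.copy().reset_index(drop=True)
    values = out["value"].astype(float).to_numpy()
    statuses = np.full(len(out), "", dtype=object)
    ambiguous = np.zeros(len(out), dtype=bool)
    units = out["unit"].astype(str).to_numpy(dtype=object).copy()

    for analyte, policy in policies.items():
        rows = np.flatnonzero((out["analyte"] == analyte).to_numpy())
        lo, hi = policy.valid_range
        for i in rows:
            v, unit = values[i], units[i]
            status = "valid"
            if unit != policy.canonical_unit:
                factor = policy.unit_factors.get(unit)
                if factor is None:
                    statuses[i] = "unit_unknown"
                    continue
                v *= factor
                status = "converted"
            if v == 0.0 and policy.zero_is_missing:
                values[i] = np.nan
                units[i] = policy.canonical_unit
                statuses[i] = "zero_missing"
                continue
            if not lo <= v <= hi and policy.scale_correction_enabled and v != 0.0:
                down, up = v / 10.0, v * 10.0
                down_ok = lo <= down <= hi
                up_ok = lo <= up <= hi
                if down_ok and up_ok:
                    ambiguous[i] = True
                elif down_ok:
                    v, status = down, "rescaled"
                elif up_ok:
                    v, status = up, "rescaled"
            if not lo <= v <= hi:
                status = "out_of_range"
            values[i] = v
            units[i] = policy.canonical_unit
            statuses[i] = status

    out["value"] = values
    out["unit"] = units
    out["status"] = statuses
    out["ambiguous"] = ambiguous
    return out


def clean_values(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for analysis: statuses valid, rescaled or converted."""
    return harmonized[harmonized["status"].isin(["valid", "rescaled", "converted"])]
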