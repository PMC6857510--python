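"""Deterministic generator of synthetic linked multi-source EHR extracts.

Real UK linked-EHR research joins four source roles: a primary-care database
(Read-coded consultations), hospital episode statistics (ICD-10 diagnoses in
up to 20 positions plus OPCS-4 procedures), a disease registry, and national
mortality records (an underlying cause plus up to 14 secondary causes,
ICD-9-coded before 2000).  No real data ships with this package; instead
this module emulates the statistical structure those sources exhibit and
that the validation suite assumes:

* per-event *capture patterns* — which subset of sources records a true
  disease event — drawn from a configurable multinomial;
* inter-source date offsets (a discretized normal, truncated);
* miscoding (a recorded diagnosis replaced by a look-alike non-case code);
* practice-level pathologies: recording gaps and death under-recording;
* messy continuous measurements: wrong-scale values under an incorrectly
  recorded unit, ambiguous zeros, alternative units, unknown units,
  malformed dates;
* patient-level data-quality defects (missing registration, registration
  before birth, invalid gender, malformed/future dates, non-continuous
  follow-up);
* age-band mortality with ICD-9 coding of deaths before 2000-01-01.

Every draw comes from one seeded :class:`numpy.random.Generator`, so a
config + seed pair reproduces the extract byte for byte.  All date columns
are ISO-8601 strings (malformed dates are part of what the generator must
be able to emit); downstream modules parse them.

The generator records ground truth (case status, drawn pattern, injected
defects) in ``LinkedCohort.truth`` so tests can compare pipeline output with
what was actually planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .terminology import CodeList, CodeListEntry, TermCode

SOURCES = ("primary", "hospital", "registry", "death")

N_DIAG_POSITIONS = 20
N_SECONDARY_CAUSES = 14
ICD9_CUTOVER = "2000-01-01"


def pattern_key(sources) -> str:
    """Canonical string for a capture pattern, e.g. ``primary+hospital``."""
    unknown = set(sources) - set(SOURCES)
    if unknown:
        raise ConfigError(f"unknown sources in pattern: {sorted(unknown)}")
    order = {s: i for i, s in enumerate(SOURCES)}
    items = sorted(set(sources), key=order.__getitem__)
    if not items:
        raise ConfigError("capture pattern must contain at least one source")
    return "+".join(items)


def pattern_sources(key: str) -> frozenset[str]:
    return frozenset(key.split("+"))


# ---------------------------------------------------------------------------
# Toy terminologies
# ---------------------------------------------------------------------------

def _toy_codes(prefix: str, n: int, desc: str) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def toy_dictionaries(disease: str = "heart failure") -> dict[str, list[TermCode]]:
    """Small (~50 codes each) synthetic code dictionaries per terminology.

    Real Read/ICD dictionaries are licensed; these synthetic stand-ins carry
    the same shape: a block of true disease codes, a block of *look-alike*
    codes (used for miscoding), and unrelated background codes.
    """
    out: dict[str, list[TermCode]] = {}
    specs = {
        "READ": ("R", 50),
        "ICD10": ("I", 50),
        "ICD9": ("N", 50),
        "OPCS4": ("K", 30),
        "DRUG": ("D", 50),
    }
    for system, (prefix, n) in specs.items():
        terms = []
        for i in range(n):
            if i < 8:
                desc = f"{disease} diagnosis variant {i}"
            elif i < 12:
                desc = f"{disease} monitoring, administrative {i}"
            elif i < 16:
                desc = f"look-alike non-{disease} condition {i}"
            else:
                desc = f"unrelated condition or item {i}"
            terms.append(TermCode(system, f"{prefix}{i:03d}", desc))
        out[system] = terms
    return out


def toy_disease_codes() -> dict[str, dict[str, list[str]]]:
    """Code blocks per terminology: true case codes, look-alikes, noise."""
    blocks = {}
    for system, prefix in (("READ", "R"), ("ICD10", "I"), ("ICD9", "N"),
                           ("OPCS4", "K"), ("DRUG", "D")):
        blocks[system] = {
            "case": [f"{prefix}{i:03d}" for i in range(8)],
            "lookalike": [f"{prefix}{i:03d}" for i in range(12, 16)],
            "noise": [f"{prefix}{i:03d}" for i in range(16, 50 if prefix != "K" else 30)],
        }
    return blocks


def icd9_equivalence() -> dict[str, str]:
    """ICD-10 -> ICD-9 mapping for the toy disease codes (pre-2000 deaths)."""
    blocks = toy_disease_codes()
    i10 = blocks["ICD10"]["case"] + blocks["ICD10"]["lookalike"] + blocks["ICD10"]["noise"]
    i9 = blocks["ICD9"]["case"] + blocks["ICD9"]["lookalike"] + blocks["ICD9"]["noise"]
    return dict(zip(i10, i9))


def toy_codelist(system: str, disease: str = "heart failure") -> CodeList:
    """A curated code list over the toy dictionary for one terminology.

    The first case codes are ``incident`` (the first two carrying subtype
    labels), the rest ``prevalent``; monitoring codes are ``possible``.
    """
    dictionary = {t.code: t for t in toy_dictionaries(disease)[system]}
    blocks = toy_disease_codes()[system]
    entries = []
    subtypes = ["reduced ejection fraction", "preserved ejection fraction"]
    for i, code in enumerate(blocks["case"]):
        category = "incident" if i < 5 else "prevalent"
        subtype = subtypes[i] if i < len(subtypes) and system == "READ" else None
        entries.append(CodeListEntry(dictionary[code], category, subtype))
    prefix = blocks["case"][0][0]
    for i in range(8, 12):
        entries.append(CodeListEntry(dictionary[f"{prefix}{i:03d}"], "possible"))
    return CodeList(
        metadata={
            "name": f"{disease} ({system})",
            "version": "1.0",
            "authors": "synthetic",
            "timestamp": "2020-01-01T00:00:00",
            "terminology": system,
        },
        entries=entries,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSpec:
    """How one synthetic disease is planted in the cohort."""

    name: str = "heart failure"
    case_probability: float = 0.3
    #: multinomial over capture patterns (keys from :func:`pattern_key`).
    pattern_probs: dict[str, float] = field(
        default_factory=lambda: {
            "primary": 0.26,
            "primary+hospital": 0.27,
            "hospital": 0.34,
            "death": 0.13,
        }
    )
    offset_mean_days: float = 0.0
    offset_sd_days: float = 10.0
    offset_max_days: int = 365
    miscode_prob: float = 0.0
    #: probability a hospital case diagnosis lands in position 1.
    hospital_primary_position_prob: float = 0.8
    #: probability a death-source case code is the underlying cause (else a
    #: secondary cause).
    death_underlying_prob: float = 0.9


@dataclass
class GapSpec:
    practice_id: int = 0
    start: str = "2004-06-01"
    length_days: int = 400


@dataclass
class DeathUnderrecordingSpec:
    practice_id: int = 0
    start: str = "2006-01-01"
    fraction: float = 0.8


@dataclass
class PracticeSpec:
    n_practices: int = 5
    recording_gap: GapSpec | None = None
    death_underrecording: DeathUnderrecordingSpec | None = None


@dataclass
class MeasurementSpec:
    """Distribution and contamination profile for one analyte.

    Defaults model hemoglobin in g/dL with a wrong-scale (x10, as if g/L)
    contamination under the canonical unit label — the classic pathology.
    """

    analyte: str = "hemoglobin"
    mean: float = 14.0
    sd: float = 1.5
    canonical_unit: str = "g/dL"
    valid_range: tuple[float, float] = (4.0, 25.0)
    per_patient_prob: float = 0.5
    wrong_scale_fraction: float = 0.0
    wrong_scale_factor: float = 10.0
    #: (label, factor-to-canonical, fraction) for genuinely different units.
    alt_unit: tuple[str, float, float] | None = None
    unknown_unit_fraction: float = 0.0
    zero_probability: float = 0.0
    invalid_date_fraction: float = 0.0


@dataclass
class DefectSpec:
    """Fractions of patients given each acceptability defect (disjoint)."""

    missing_registration: float = 0.0
    registration_before_birth: float = 0.0
    invalid_gender: float = 0.0
    malformed_date: float = 0.0
    future_date: float = 0.0
    noncontinuous_followup: float = 0.0


@dataclass
class MortalitySpec:
    """Baseline annual all-cause death probability by attained-age band."""

    annual_rate_by_age_band: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 50): 0.002, (50, 70): 0.01, (70, 200): 0.05}
    )


@dataclass
class GeneratorConfig:
    n_patients: int = 1000
    seed: int = 0
    start_date: str = "1995-01-01"
    end_date: str = "2010-12-31"
    phenotype: PhenotypeSpec = field(default_factory=PhenotypeSpec)
    practices: PracticeSpec = field(default_factory=PracticeSpec)
    measurements: list[MeasurementSpec] = field(default_factory=list)
    defects: DefectSpec = field(default_factory=DefectSpec)
    mortality: MortalitySpec = field(default_factory=MortalitySpec)
    #: fraction of GP-recorded death dates shifted from the certificate date,
    #: and the maximum absolute shift in days.
    gp_death_discrepancy_fraction: float = 0.0
    gp_death_discrepancy_max_days: int = 14

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        probs = list(self.phenotype.pattern_probs.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError("pattern probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"pattern probabilities sum to {sum(probs)!r}, expected 1"
            )
        for key in self.phenotype.pattern_probs:
            pattern_key(key.split("+"))  # raises on unknown source
        for p in (
            self.phenotype.case_probability,
            self.phenotype.miscode_prob,
            self.gp_death_discrepancy_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p!r} outside [0, 1]")
        for m in self.measurements:
            if m.valid_range[0] >= m.valid_range[1]:
                raise ConfigError(f"invalid range for {m.analyte}")


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

TABLE_NAMES = (
    "patients",
    "primary_care",
    "hospital",
    "registry",
    "deaths",
    "prescriptions",
    "measurements",
    "truth",
)


@dataclass
class LinkedCohort:
    """The joined multi-source record set for a synthetic population.

    Tables (all dates ISO-8601 strings):

    patients
        patient_id, birth_date, gender, practice_id, reg_start, reg_end,
        gp_death_date (the practice's own record of death, possibly missing
        or discrepant with the certificate).
    primary_care
        patient_id, date, code (READ).
    hospital
        patient_id, admission_date, diag_01..diag_20 (ICD-10),
        proc_01..proc_03 (OPCS-4).
    registry
        patient_id, date, diagnosis (free-text label).
    deaths
        patient_id, death_date, terminology (ICD9 before 2000-01-01 else
        ICD10), underlying_cause, secondary_01..secondary_14.
    prescriptions
        patient_id, date, code (DRUG).
    measurements
        patient_id, date, analyte, value, unit.
    truth
        generator bookkeeping: patient_id, is_case, pattern, event_date,
        miscoded_sources, defects, gp_death_discrepancy_days.
    """

    patients: pd.DataFrame
    primary_care: pd.DataFrame
    hospital: pd.DataFrame
    registry: pd.DataFrame
    deaths: pd.DataFrame
    prescriptions: pd.DataFrame
    measurements: pd.DataFrame
    truth: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def equals(self, other: "LinkedCohort") -> bool:
        for name in TABLE_NAMES:
            a = self.table(name).reset_index(drop=True)
            b = other.table(name).reset_index(drop=True)
            try:
                pd.testing.assert_frame_equal(a, b, check_dtype=False)
            except AssertionError:
                return False
        return True


def _iso(dates) -> np.ndarray:
    """Format an int64 array of days-since-epoch as ISO date strings."""
    return np.datetime_as_string(
        np.asarray(dates, dtype="int64").astype("datetime64[D]"), unit="D"
    )


def _day(date_str: str) -> int:
    return int(np.datetime64(date_str, "D").astype("int64"))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> LinkedCohort:
    """Generate a linked cohort; deterministic given ``config.seed``.

    For each true case a capture pattern is drawn from the pattern
    multinomial and one record per captured source is emitted, its date the
    case's event date plus a truncated discretized-normal offset.  All
    configured pathologies are injected and logged in ``truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    spec = config.phenotype
    blocks = toy_disease_codes()

    t0, t1 = _day(config.start_date), _day(config.end_date)
    horizon = t1 - t0

    # --- patients ---------------------------------------------------------
    patient_ids = np.array([f"P{i:07d}" for i in range(n)])
    birth = t0 - rng.integers(25 * 365, 85 * 365, n)  # ages ~25-85 at start
    gender = rng.choice(np.array(["M", "F"]), n)
    practice = rng.integers(0, config.practices.n_practices, n)
    reg_start = t0 + rng.integers(0, max(horizon // 10, 1), n)
    reg_end = np.full(n, t1)

    # --- case structure ----------------------------------------------------
    is_case = rng.random(n) < spec.case_probability
    pattern_keys = [pattern_key(k.split("+")) for k in spec.pattern_probs]
    pattern_p = np.array(list(spec.pattern_probs.values()), dtype=float)
    pattern_idx = rng.choice(len(pattern_keys), size=n, p=pattern_p / pattern_p.sum())
    patterns = np.array(pattern_keys, dtype=object)[pattern_idx]
    patterns[~is_case] = ""

    # event dates leave room for +-offset_max inside the horizon
    margin = min(spec.offset_max_days, horizon // 4)
    event_day = reg_start + margin + (
        rng.random(n) * (t1 - margin - (reg_start + margin))
    ).astype("int64")
    event_day = np.minimum(event_day, t1 - margin)

    def offsets(size):
        raw = np.rint(rng.normal(spec.offset_mean_days, spec.offset_sd_days, size))
        return np.clip(raw, -spec.offset_max_days, spec.offset_max_days).astype("int64")

    case_idx = np.flatnonzero(is_case)
    in_source = {
        s: np.array([s in pattern_sources(patterns[i]) for i in case_idx])
        for s in SOURCES
    }
    miscoded: dict[int, list[str]] = {}

    def case_records(source):
        """(patient indices, record days, miscode mask) for one source."""
        sel = case_idx[in_source[source]]
        days = np.clip(event_day[sel] + offsets(sel.size), t0, t1)
        mis = rng.random(sel.size) < spec.miscode_prob
        for i in sel[mis]:
            miscoded.setdefault(int(i), []).append(source)
        return sel, days, mis

    def pick(codes, size):
        return rng.choice(np.array(codes, dtype=object), size)

    # --- primary care ------------------------------------------------------
    sel, days, mis = case_records("primary")
    pc_codes = pick(blocks["READ"]["case"], sel.size)
    pc_codes[mis] = pick(blocks["READ"]["lookalike"], int(mis.sum()))
    noise_sel = np.flatnonzero(rng.random(n) < 0.8)  # background consultations
    noise_days = reg_start[noise_sel] + (
        rng.random(noise_sel.size) * (t1 - reg_start[noise_sel])
    ).astype("int64")
    primary_care = pd.DataFrame(
        {
            "patient_id": np.concatenate([patient_ids[sel], patient_ids[noise_sel]]),
            "date": np.concatenate([_iso(days), _iso(noise_days)]),
            "code": np.concatenate([pc_codes, pick(blocks["READ"]["noise"], noise_sel.size)]),
        }
    ).sort_values(["patient_id", "date", "code"], kind="stable").reset_index(drop=True)

    # practice-level recording gap: drop primary-care events in the window
    gap = config.practices.recording_gap
    if gap is not None:
        g0, g1 = _day(gap.start), _day(gap.start) + gap.length_days
        pr = pd.Series(practice, index=patient_ids)
        in_gap_practice = primary_care["patient_id"].map(pr) == gap.practice_id
        d = pd.to_datetime(primary_care["date"]).astype("int64") // 86_400_000_000_000
        primary_care = primary_care[~(in_gap_practice & (d >= g0) & (d < g1))]
        primary_care = primary_care.reset_index(drop=True)

    # --- hospital -----------------------------------------------------------
    sel, days, mis = case_records("hospital")
    hcodes = pick(blocks["ICD10"]["case"], sel.size)
    hcodes[mis] = pick(blocks["ICD10"]["lookalike"], int(mis.sum()))
    in_pos1 = rng.random(sel.size) < spec.hospital_primary_position_prob
    pos = np.where(in_pos1, 1, rng.integers(2, N_DIAG_POSITIONS + 1, sel.size))
    noise_sel = np.flatnonzero(rng.random(n) < 0.3)
    noise_days = reg_start[noise_sel] + (
        rng.random(noise_sel.size) * (t1 - reg_start[noise_sel])
    ).astype("int64")
    n_epi = sel.size + noise_sel.size
    diag = np.full((n_epi, N_DIAG_POSITIONS), "", dtype=object)
    # primary diagnosis always present
    diag[:, 0] = pick(blocks["ICD10"]["noise"], n_epi)
    extra = rng.integers(0, 4, n_epi)  # a few secondary noise diagnoses
    for j in range(1, 4):
        rows = extra >= j
        diag[rows, j] = pick(blocks["ICD10"]["noise"], int(rows.sum()))
    diag[np.arange(sel.size), pos - 1] = hcodes
    procs = np.full((n_epi, 3), "", dtype=object)
    has_proc = rng.random(n_epi) < 0.2
    procs[has_proc, 0] = pick(blocks["OPCS4"]["noise"], int(has_proc.sum()))
    hospital = pd.DataFrame(
        {
            "patient_id": np.concatenate([patient_ids[sel], patient_ids[noise_sel]]),
            "admission_date": _iso(np.concatenate([days, noise_days])),
            **{f"diag_{j + 1:02d}": diag[:, j] for j in range(N_DIAG_POSITIONS)},
            **{f"proc_{j + 1:02d}": procs[:, j] for j in range(3)},
        }
    ).sort_values(["patient_id", "admission_date"], kind="stable").reset_index(drop=True)

    # --- registry ------------------------------------------------------------
    sel, days, mis = case_records("registry")
    labels = np.full(sel.size, spec.name, dtype=object)
    labels[mis] = "other condition"
    registry = pd.DataFrame(
        {
            "patient_id": patient_ids[sel],
            "date": _iso(days),
            "diagnosis": labels,
        }
    ).sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    # --- deaths ---------------------------------------------------------------
    # background mortality from age-band annual rates over follow-up
    age_at_start = (t0 - birth) / 365.25
    annual = np.zeros(n)
    for (lo, hi), rate in config.mortality.annual_rate_by_age_band.items():
        band = (age_at_start >= lo) & (age_at_start < hi)
        annual[band] = rate
    follow_years = (t1 - reg_start) / 365.25
    p_death = np.clip(annual * follow_years, 0, 0.95)
    dies_bg = rng.random(n) < p_death
    bg_day = reg_start + (rng.random(n) * (t1 - reg_start)).astype("int64")

    death_case = np.zeros(n, dtype=bool)
    death_case[case_idx[in_source["death"]]] = True
    sel, days, mis = case_records("death")
    case_death_day = np.zeros(n, dtype="int64")
    case_death_day[sel] = np.maximum(days, event_day[sel])
    death_mis = np.zeros(n, dtype=bool)
    death_mis[sel[mis]] = True

    dies = dies_bg | death_case
    died_idx = np.flatnonzero(dies)
    death_day = np.where(death_case, case_death_day, bg_day)[died_idx]
    pre2000 = death_day < _day(ICD9_CUTOVER)

    i10_case = pick(blocks["ICD10"]["case"], died_idx.size)
    i10_look = pick(blocks["ICD10"]["lookalike"], died_idx.size)
    i10_noise = pick(blocks["ICD10"]["noise"], died_idx.size)
    is_dcase = death_case[died_idx]
    is_dmis = death_mis[died_idx]
    cause10 = np.where(is_dcase, np.where(is_dmis, i10_look, i10_case), i10_noise)
    underlying_flag = rng.random(died_idx.size) < spec.death_underlying_prob
    n_sec = rng.integers(0, 4, died_idx.size)
    secondary = np.full((died_idx.size, N_SECONDARY_CAUSES), "", dtype=object)
    for j in range(3):
        rows = n_sec > j
        secondary[rows, j] = pick(blocks["ICD10"]["noise"], int(rows.sum()))
    underlying = np.where(
        is_dcase & ~underlying_flag, i10_noise, cause10
    ).astype(object)
    # a case code demoted to a secondary-cause slot
    demote = np.flatnonzero(is_dcase & ~underlying_flag)
    secondary[demote, 3] = cause10[demote]

    eq9 = icd9_equivalence()
    term_col = np.where(pre2000, "ICD9", "ICD10")

    def to9(row):
        return [eq9.get(c, c) if c else "" for c in row]

    underlying = np.array(
        [eq9.get(c, c) if p else c for c, p in zip(underlying, pre2000)], dtype=object
    )
    for r in np.flatnonzero(pre2000):
        secondary[r] = to9(secondary[r])

    deaths = pd.DataFrame(
        {
            "patient_id": patient_ids[died_idx],
            "death_date": _iso(death_day),
            "terminology": term_col,
            "underlying_cause": underlying,
            **{
                f"secondary_{j + 1:02d}": secondary[:, j]
                for j in range(N_SECONDARY_CAUSES)
            },
        }
    ).sort_values("patient_id", kind="stable").reset_index(drop=True)

    # GP-recorded death date: equal to certificate except injected
    # discrepancies and practice-level under-recording.
    gp_death = pd.Series("", index=patient_ids, dtype=object)
    disc_days = np.zeros(died_idx.size, dtype="int64")
    disc = rng.random(died_idx.size) < config.gp_death_discrepancy_fraction
    shift = rng.integers(1, config.gp_death_discrepancy_max_days + 1, died_idx.size)
    sign = rng.choice(np.array([-1, 1]), died_idx.size)
    disc_days[disc] = (shift * sign)[disc]
    gp_day = death_day + disc_days
    gp_death.loc[patient_ids[died_idx]] = _iso(gp_day)
    under = config.practices.death_underrecording
    if under is not None:
        u0 = _day(under.start)
        at_pr = practice[died_idx] == under.practice_id
        dropped = at_pr & (death_day >= u0) & (rng.random(died_idx.size) < under.fraction)
        gp_death.loc[patient_ids[died_idx[dropped]]] = ""

    # --- prescriptions -----------------------------------------------------------
    # cases captured in primary care tend to receive disease drugs
    pc_case = case_idx[in_source["primary"]]
    on_drug = pc_case[rng.random(pc_case.size) < 0.7]
    rx_rows = np.repeat(on_drug, 3)  # repeat prescriptions
    rx_days = np.clip(
        event_day[rx_rows] + rng.integers(0, 180, rx_rows.size), t0, t1
    )
    noise_rx = np.flatnonzero(rng.random(n) < 0.4)
    noise_days = reg_start[noise_rx] + (
        rng.random(noise_rx.size) * (t1 - reg_start[noise_rx])
    ).astype("int64")
    prescriptions = pd.DataFrame(
        {
            "patient_id": np.concatenate([patient_ids[rx_rows], patient_ids[noise_rx]]),
            "date": _iso(np.concatenate([rx_days, noise_days])),
            "code": np.concatenate(
                [
                    pick(blocks["DRUG"]["case"], rx_rows.size),
                    pick(blocks["DRUG"]["noise"], noise_rx.size),
                ]
            ),
        }
    ).sort_values(["patient_id", "date", "code"], kind="stable").reset_index(drop=True)

    # --- measurements -----------------------------------------------------------
    meas_frames = []
    for m in config.measurements:
        who = np.flatnonzero(rng.random(n) < m.per_patient_prob)
        true_vals = np.abs(rng.normal(m.mean, m.sd, who.size))
        vals = true_vals.copy()
        units = np.full(who.size, m.canonical_unit, dtype=object)
        u = rng.random(who.size)
        wrong = u < m.wrong_scale_fraction
        vals[wrong] = true_vals[wrong] * m.wrong_scale_factor
        cursor = m.wrong_scale_fraction
        if m.alt_unit is not None:
            label, factor, frac = m.alt_unit
            alt = (u >= cursor) & (u < cursor + frac)
            vals[alt] = true_vals[alt] / factor
            units[alt] = label
            cursor += frac
        unk = (u >= cursor) & (u < cursor + m.unknown_unit_fraction)
        units[unk] = "??"
        zero = rng.random(who.size) < m.zero_probability
        vals[zero] = 0.0
        mdays = reg_start[who] + (rng.random(who.size) * (t1 - reg_start[who])).astype("int64")
        dates = _iso(mdays).astype(object)
        bad = rng.random(who.size) < m.invalid_date_fraction
        dates[bad] = "0000-00-00"
        meas_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[who],
                    "date": dates,
                    "analyte": m.analyte,
                    "value": np.round(vals, 4),
                    "unit": units,
                }
            )
        )
    measurements = (
        pd.concat(meas_frames, ignore_index=True)
        .sort_values(["analyte", "patient_id", "date"], kind="stable")
        .reset_index(drop=True)
        if meas_frames
        else pd.DataFrame(
            columns=["patient_id", "date", "analyte", "value", "unit"]
        )
    )

    # --- patient-level defects -----------------------------------------------------
    d = config.defects
    fractions = [
        ("missing_registration", d.missing_registration),
        ("registration_before_birth", d.registration_before_birth),
        ("invalid_gender", d.invalid_gender),
        ("malformed_date", d.malformed_date),
        ("future_date", d.future_date),
        ("noncontinuous_followup", d.noncontinuous_followup),
    ]
    total_frac = sum(f for _, f in fractions)
    if total_frac > 1.0:
        raise ConfigError("defect fractions sum to more than 1")
    perm = rng.permutation(n)
    defect_label = np.full(n, "", dtype=object)
    cursor = 0
    for name, frac in fractions:
        k = int(round(frac * n))
        defect_label[perm[cursor : cursor + k]] = name
        cursor += k

    reg_start_str = _iso(reg_start).astype(object)
    reg_end_str = _iso(reg_end).astype(object)
    reg_start2 = np.full(n, "", dtype=object)  # second registration period
    reg_end2 = np.full(n, "", dtype=object)
    for i in np.flatnonzero(defect_label == "missing_registration"):
        reg_start_str[i] = ""
    for i in np.flatnonzero(defect_label == "registration_before_birth"):
        reg_start_str[i] = _iso([birth[i] - 100])[0]
    gender = gender.astype(object)
    for i in np.flatnonzero(defect_label == "invalid_gender"):
        gender[i] = "?"
    for i in np.flatnonzero(defect_label == "malformed_date"):
        reg_start_str[i] = "2003-02-30"
    for i in np.flatnonzero(defect_label == "future_date"):
        reg_end_str[i] = _iso([t1 + 400])[0]
    for i in np.flatnonzero(defect_label == "noncontinuous_followup"):
        # split follow-up with an uncovered gap between two periods
        mid = (reg_start[i] + t1) // 2
        reg_end_str[i] = _iso([mid])[0]
        reg_start2[i] = _iso([mid + 200])[0]
        reg_end2[i] = _iso([t1])[0]

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_date": _iso(birth),
            "gender": gender,
            "practice_id": practice,
            "reg_start": reg_start_str,
            "reg_end": reg_end_str,
            "reg_start_2": reg_start2,
            "reg_end_2": reg_end2,
            "gp_death_date": gp_death.to_numpy(),
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "is_case": is_case,
            "pattern": patterns,
            "event_date": np.where(is_case, _iso(event_day), ""),
            "miscoded_sources": [
                "+".join(miscoded.get(i, [])) for i in range(n)
            ],
            "defects": defect_label,
            "gp_death_discrepancy_days": pd.Series(0, index=range(n))
            .to_numpy()
            .astype("int64"),
        }
    )
    truth.loc[died_idx, "gp_death_discrepancy_days"] = disc_days

    manifest = {
        "seed": config.seed,
        "config": _config_to_dict(config),
        "n_patients": n,
    }
    return LinkedCohort(
        patients=patients,
        primary_care=primary_care,
        hospital=hospital,
        registry=registry,
        deaths=deaths,
        prescriptions=prescriptions,
        measurements=measurements,
        truth=truth,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# I/O: one delimited text table per source + a JSON manifest
# ---------------------------------------------------------------------------

def _config_to_dict(config: GeneratorConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return encode(config)


def write_cohort(cohort: LinkedCohort, directory) -> None:
    """Write each table as CSV plus ``manifest.json`` recording config+seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in TABLE_NAMES:
        cohort.table(name).to_csv(directory / f"{name}.csv", index=False)
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.manifest, fh, indent=1, sort_keys=True, default=str)


def read_cohort(directory) -> LinkedCohort:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    tables = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FormatError(f"missing cohort table file: {name}.csv")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if name == "measurements" and len(df):
            df["value"] = df["value"].astype(float)
        if name == "patients" and len(df):
            df["practice_id"] = df["practice_id"].astype(int)
        if name == "truth" and len(df):
            df["is_case"] = df["is_case"].map({"True": True, "False": False})
            df["gp_death_discrepancy_days"] = df["gp_death_discrepancy_days"].astype(
                "int64"
            )
        tables[name] = df
    manifest_path = directory / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
    return LinkedCohort(manifest=manifest, **tables)
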