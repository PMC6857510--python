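"""Declarative phenotype definitions and their execution against a cohort.

A phenotype algorithm translates the clinical requirements for a patient to
be considered a case into queries over the linked sources: code sets per
source (with a diagnosis-position rule for hospital data and a cause rule
for death certificates), threshold rules over harmonized continuous
measurements, prescription-count rules, and a boolean combination of those
named components.  Executing a definition yields one case record per
patient: case status, the index date (earliest qualifying event), the
contributing sources, an ascertainment category and, where available, a
disease subtype resolved by source precedence — the source with the highest
clinical resolution wins.

Codes classified ``possible`` never satisfy the logic on their own; they are
recorded as supporting evidence only.

The logic grammar supports AND / OR / NOT, parentheses and
``at_least(k, a, b, ...)``; there are no temporal sequencing operators
beyond the per-rule ``within_days`` windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidArgumentError, NoDataError
from .quality import MeasurementPolicy, clean_values, harmonize_measurements
from .synth import N_DIAG_POSITIONS, N_SECONDARY_CAUSES, SOURCES, LinkedCohort
from .terminology import CodeList

CATEGORY_RANK_DEFAULT = ("incident", "prevalent", "possible")


# ---------------------------------------------------------------------------
# Logic expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Name:
    name: str

    def names(self):
        return {self.name}

    def render(self, parent: str = "") -> str:
        return self.name


@dataclass(frozen=True)
class Not:
    operand: object

    def names(self):
        return self.operand.names()

    def render(self, parent: str = "") -> str:
        return f"NOT {self.operand.render('NOT')}"


@dataclass(frozen=True)
class And:
    operands: tuple

    def names(self):
        return set().union(*(o.names() for o in self.operands))

    def render(self, parent: str = "") -> str:
        body = " AND ".join(o.render("AND") for o in self.operands)
        return f"({body})" if parent in ("NOT", "AND") else body


@dataclass(frozen=True)
class Or:
    operands: tuple

    def names(self):
        return set().union(*(o.names() for o in self.operands))

    def render(self, parent: str = "") -> str:
        body = " OR ".join(o.render("OR") for o in self.operands)
        return f"({body})" if parent in ("NOT", "AND") else body


@dataclass(frozen=True)
class AtLeast:
    k: int
    components: tuple

    def names(self):
        return set(self.components)

    def render(self, parent: str = "") -> str:
        return f"at_least({self.k}, {', '.join(self.components)})"


_TOKEN = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<comma>,)|(?P<int>\d+)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_]*))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos and not text[pos:].strip():
            break
        if not m:
            raise InvalidArgumentError(f"bad character in logic at {text[pos:]!r}")
        pos = m.end()
        kind = m.lastgroup
        if kind is None:
            break
        tokens.append((kind, m.group(kind)))
    if text[pos:].strip():
        raise InvalidArgumentError(f"bad character in logic at {text[pos:]!r}")
    return tokens


def parse_logic(text: str):
    """Parse a logic expression into its AST (n-ary AND/OR, flattened)."""
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def take(kind=None, value=None):
        nonlocal pos
        k, v = peek()
        if kind and k != kind or value and (v or "").upper() != value:
            raise InvalidArgumentError(
                f"logic syntax error near token {v!r} (expected {value or kind})"
            )
        pos += 1
        return v

    def parse_or():
        parts = [parse_and()]
        while peek()[0] == "word" and peek()[1].upper() == "OR":
            take("word", "OR")
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and():
        parts = [parse_factor()]
        while peek()[0] == "word" and peek()[1].upper() == "AND":
            take("word", "AND")
            parts.append(parse_factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_factor():
        kind, value = peek()
        if kind == "word" and value.upper() == "NOT":
            take()
            return Not(parse_factor())
        if kind == "word" and value == "at_least":
            take()
            take("lpar")
            k = int(take("int"))
            names = []
            while peek()[0] == "comma":
                take("comma")
                names.append(take("word"))
            take("rpar")
            if not names:
                raise InvalidArgumentError("at_least needs component names")
            return AtLeast(k, tuple(names))
        if kind == "lpar":
            take("lpar")
            inner = parse_or()
            take("rpar")
            return inner
        if kind == "word":
            return Name(take())
        raise InvalidArgumentError(f"logic syntax error near {value!r}")

    ast = parse_or()
    if pos != len(tokens):
        raise InvalidArgumentError(
            f"trailing tokens in logic: {tokens[pos:]}"
        )
    return ast


def evaluate_logic(node, env: dict[str, pd.Series]) -> pd.Series:
    """Evaluate an AST over an environment of boolean per-patient Series."""
    if isinstance(node, Name):
        if node.name not in env:
            raise ConfigError(f"logic references undeclared component {node.name!r}")
        return env[node.name]
    if isinstance(node, Not):
        return ~evaluate_logic(node.operand, env)
    if isinstance(node, And):
        out = evaluate_logic(node.operands[0], env)
        for o in node.operands[1:]:
            out = out & evaluate_logic(o, env)
        return out
    if isinstance(node, Or):
        out = evaluate_logic(node.operands[0], env)
        for o in node.operands[1:]:
            out = out | evaluate_logic(o, env)
        return out
    if isinstance(node, AtLeast):
        for name in node.components:
            if name not in env:
                raise ConfigError(f"logic references undeclared component {name!r}")
        total = sum(env[name].astype(int) for name in node.components)
        return total >= node.k
    raise TypeError(f"unknown logic node {node!r}")


# ---------------------------------------------------------------------------
# Definition components
# ---------------------------------------------------------------------------

@dataclass
class CodedComponent:
    """A per-source code set.

    ``codes`` maps code -> (category, subtype); for the registry source the
    "codes" are diagnosis labels.  ``position_rule`` applies to hospital
    episodes (``primary_only`` restricts to diagnosis position 1);
    ``cause_rule`` applies to death certificates (``underlying_only`` vs
    ``any``).
    """

    name: str
    source: str
    codes: dict[str, tuple[str, str | None]]
    position_rule: str = "any"
    cause_rule: str = "underlying_only"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ConfigError(f"unknown source {self.source!r}")
        if self.position_rule not in ("any", "primary_only"):
            raise ConfigError(f"bad position_rule {self.position_rule!r}")
        if self.cause_rule not in ("any", "underlying_only"):
            raise ConfigError(f"bad cause_rule {self.cause_rule!r}")

    @classmethod
    def from_codelist(
        cls, name: str, source: str, codelist: CodeList, **kwargs
    ) -> "CodedComponent":
        codes = {
            e.term.code: (e.category, e.subtype) for e in codelist.entries
        }
        return cls(name=name, source=source, codes=codes, **kwargs)


@dataclass
class MeasurementRule:
    """Threshold rule over a harmonized analyte: satisfied when at least
    ``min_occasions`` qualifying values occur (within ``within_days`` when
    set)."""

    name: str
    analyte: str
    comparator: str
    threshold: float
    min_occasions: int = 1
    within_days: int | None = None

    _OPS = {
        ">": np.greater,
        ">=": np.greater_equal,
        "<": np.less,
        "<=": np.less_equal,
    }

    def __post_init__(self):
        if self.comparator not in self._OPS:
            raise ConfigError(f"bad comparator {self.comparator!r}")

    def passes(self, values) -> np.ndarray:
        return self._OPS[self.comparator](np.asarray(values, dtype=float), self.threshold)


@dataclass
class PrescriptionRule:
    name: str
    codes: frozenset
    min_prescriptions: int = 1
    within_days: int | None = None


@dataclass
class PhenotypeDefinition:
    """A declarative, executable phenotype algorithm."""

    name: str
    version: str
    components: dict[str, object]
    logic: str
    source_precedence: tuple[str, ...] = SOURCES
    category_precedence: tuple[str, ...] = CATEGORY_RANK_DEFAULT
    index_date_rule: str = "earliest_qualifying_event"

    def __post_init__(self):
        ast = parse_logic(self.logic)
        undeclared = ast.names() - set(self.components)
        if undeclared:
            raise ConfigError(
                f"logic references undeclared components: {sorted(undeclared)}"
            )
        if sorted(self.category_precedence) != sorted(CATEGORY_RANK_DEFAULT):
            raise ConfigError("category_precedence must permute the three categories")
        if set(self.source_precedence) - set(SOURCES):
            raise ConfigError("source_precedence contains unknown sources")

    @property
    def ast(self):
        return parse_logic(self.logic)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

EVENT_COLUMNS = (
    "patient_id",
    "component",
    "source",
    "date",
    "code",
    "category",
    "subtype",
    "supporting",
)


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def _coded_events(cohort: LinkedCohort, comp: CodedComponent) -> pd.DataFrame:
    if comp.source == "primary":
        df = cohort.primary_care
        hits = df[df["code"].isin(comp.codes)][["patient_id", "date", "code"]]
    elif comp.source == "hospital":
        df = cohort.hospital
        n_pos = 1 if comp.position_rule == "primary_only" else N_DIAG_POSITIONS
        frames = []
        for j in range(1, n_pos + 1):
            col = f"diag_{j:02d}"
            sub = df[df[col].isin(comp.codes)]
            if len(sub):
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": sub["patient_id"],
                            "date": sub["admission_date"],
                            "code": sub[col],
                        }
                    )
                )
        hits = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["patient_id", "date", "code"])
        )
    elif comp.source == "registry":
        df = cohort.registry
        sub = df[df["diagnosis"].isin(comp.codes)]
        hits = pd.DataFrame(
            {
                "patient_id": sub["patient_id"],
                "date": sub["date"],
                "code": sub["diagnosis"],
            }
        )
    else:  # death
        df = cohort.deaths
        cols = ["underlying_cause"]
        if comp.cause_rule == "any":
            cols += [f"secondary_{j:02d}" for j in range(1, N_SECONDARY_CAUSES + 1)]
        frames = []
        for col in cols:
            if col not in df.columns:
                continue
            sub = df[df[col].isin(comp.codes)]
            if len(sub):
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": sub["patient_id"],
                            "date": sub["death_date"],
                            "code": sub[col],
                        }
                    )
                )
        hits = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["patient_id", "date", "code"])
        )

    hits = hits.copy()
    hits["date"] = pd.to_datetime(hits["date"], errors="coerce")
    hits = hits.dropna(subset=["date"])
    cat = hits["code"].map(lambda c: comp.codes[c][0])
    sub = hits["code"].map(lambda c: comp.codes[c][1])
    hits["component"] = comp.name
    hits["source"] = comp.source
    hits["category"] = cat
    hits["subtype"] = sub
    hits["supporting"] = cat == "possible"
    return hits[list(EVENT_COLUMNS)]


def _window_satisfaction(
    df: pd.DataFrame, k: int, within_days: int | None
) -> pd.DataFrame:
    """Earliest date at which >=k occasions (within the window) accumulate.

    Returns a frame with one row per satisfying patient: patient_id, date of
    the completing occasion.
    """
    if df.empty or k < 1:
        return pd.DataFrame(columns=["patient_id", "date"])
    df = df.sort_values(["patient_id", "date"], kind="stable")
    grp = df.groupby("patient_id")["date"]
    anchor = grp.shift(k - 1)
    if within_days is None:
        ok = anchor.notna()
    else:
        ok = (df["date"] - anchor) <= pd.Timedelta(days=within_days)
    sat = df[ok.fillna(False)]
    return sat.groupby("patient_id", as_index=False)["date"].min()


def _measurement_events(
    cohort: LinkedCohort,
    rule: MeasurementRule,
    policies: dict[str, MeasurementPolicy] | None,
) -> pd.DataFrame:
    if policies is None or rule.analyte not in policies:
        raise ConfigError(
            f"measurement rule {rule.name!r} references analyte "
            f"{rule.analyte!r} with no harmonization policy"
        )
    meas = cohort.measurements
    meas = meas[meas["analyte"] == rule.analyte]
    if meas.empty:
        return _empty_events()
    clean = clean_values(
        harmonize_measurements(meas, {rule.analyte: policies[rule.analyte]})
    ).copy()
    clean["date"] = pd.to_datetime(clean["date"], errors="coerce")
    clean = clean.dropna(subset=["date"])
    passing = clean[rule.passes(clean["value"])]
    sat = _window_satisfaction(
        passing[["patient_id", "date"]], rule.min_occasions, rule.within_days
    )
    sat["component"] = rule.name
    sat["source"] = "primary"
    sat["code"] = rule.name
    sat["category"] = "incident"
    sat["subtype"] = None
    sat["supporting"] = False
    return sat[list(EVENT_COLUMNS)] if len(sat) else _empty_events()


def _prescription_events(
    cohort: LinkedCohort, rule: PrescriptionRule
) -> pd.DataFrame:
    rx = cohort.prescriptions
    rx = rx[rx["code"].isin(rule.codes)].copy()
    if rx.empty:
        return _empty_events()
    rx["date"] = pd.to_datetime(rx["date"], errors="coerce")
    rx = rx.dropna(subset=["date"])
    sat = _window_satisfaction(
        rx[["patient_id", "date"]], rule.min_prescriptions, rule.within_days
    )
    sat["component"] = rule.name
    sat["source"] = "primary"
    sat["code"] = rule.name
    sat["category"] = "incident"
    sat["subtype"] = None
    sat["supporting"] = False
    return sat[list(EVENT_COLUMNS)] if len(sat) else _empty_events()


@dataclass
class PhenotypeResult:
    """Per-patient case records plus the long table of qualifying events."""

    case_records: pd.DataFrame
    qualifying_events: pd.DataFrame
    definition: PhenotypeDefinition = field(repr=False, default=None)

    def cases(self) -> pd.DataFrame:
        return self.case_records[self.case_records["is_case"]]


def apply_phenotype(
    cohort: LinkedCohort,
    definition: PhenotypeDefinition,
    measurement_policies: dict[str, MeasurementPolicy] | None = None,
) -> PhenotypeResult:
    """Execute a phenotype definition; one case record per patient.

    A patient is a case iff the definition's logic is satisfied by their
    events, where a coded component counts as satisfied only if it has at
    least one matching event whose category is not ``possible``.  The index
    date is the earliest non-supporting qualifying event across the
    satisfied components; the category is the highest-precedence category
    among those events; the subtype comes from the highest-precedence source
    carrying a label.
    """
    patient_ids = cohort.patients["patient_id"]
    universe = pd.Index(patient_ids.unique(), name="patient_id")

    all_events = []
    env: dict[str, pd.Series] = {}
    for name, comp in definition.components.items():
        if isinstance(comp, CodedComponent):
            ev = _coded_events(cohort, comp)
        elif isinstance(comp, MeasurementRule):
            ev = _measurement_events(cohort, comp, measurement_policies)
        elif isinstance(comp, PrescriptionRule):
            ev = _prescription_events(cohort, comp)
        else:
            raise ConfigError(f"unknown component type for {name!r}")
        all_events.append(ev)
        effective = ev[~ev["supporting"].astype(bool)]
        sat = pd.Series(False, index=universe)
        present = pd.Index(effective["patient_id"].unique())
        sat.loc[present.intersection(universe)] = True
        env[name] = sat

    events = (
        pd.concat(all_events, ignore_index=True) if all_events else _empty_events()
    )
    is_case = evaluate_logic(definition.ast, env).reindex(universe, fill_value=False)

    # restrict index-date material to satisfied components' effective events
    sat_lookup = pd.DataFrame(env)
    ev = events.copy()
    if len(ev):
        comp_sat = sat_lookup.stack()
        key = pd.MultiIndex.from_frame(ev[["patient_id", "component"]])
        ev["component_satisfied"] = comp_sat.reindex(key).to_numpy()
        effective = ev[
            ev["component_satisfied"].astype(bool) & ~ev["supporting"].astype(bool)
        ]
    else:
        effective = ev

    records = pd.DataFrame(index=universe)
    records["is_case"] = is_case
    if len(effective):
        cat_rank = {c: i for i, c in enumerate(definition.category_precedence)}
        src_rank = {s: i for i, s in enumerate(definition.source_precedence)}
        effective = effective.assign(
            _cat_rank=effective["category"].map(cat_rank),
            _src_rank=effective["source"].map(src_rank),
        )
        grp = effective.groupby("patient_id")
        records["index_date"] = grp["date"].min()
        records["sources"] = grp["source"].agg(
            lambda s: "+".join(sorted(set(s), key=lambda x: SOURCES.index(x)))
        )
        best_cat = grp["_cat_rank"].min()
        inv = {i: c for c, i in cat_rank.items()}
        records["category"] = best_cat.map(inv)
        labelled = effective.dropna(subset=["subtype"]).sort_values(
            ["_src_rank", "date"], kind="stable"
        )
        records["subtype"] = labelled.groupby("patient_id")["subtype"].first()
        records["n_qualifying_events"] = grp.size()
    else:
        records["index_date"] = pd.NaT
        records["sources"] = None
        records["category"] = None
        records["subtype"] = None
        records["n_qualifying_events"] = 0

    # non-cases carry no index date or sources
    not_case = ~records["is_case"]
    records.loc[not_case, ["index_date", "sources", "category", "subtype"]] = [
        pd.NaT,
        None,
        None,
        None,
    ]
    records.loc[not_case, "n_qualifying_events"] = 0
    records = records.reset_index()
    records["n_qualifying_events"] = (
        records["n_qualifying_events"].fillna(0).astype(int)
    )

    case_ids = set(records.loc[records["is_case"], "patient_id"])
    qualifying = (
        effective[effective["patient_id"].isin(case_ids)]
        .drop(columns=["component_satisfied", "_cat_rank", "_src_rank"], errors="ignore")
        .reset_index(drop=True)
        if len(effective)
        else _empty_events()
    )
    return PhenotypeResult(
        case_records=records, qualifying_events=qualifying, definition=definition
    )


def resolve_subtype(
    qualifying_events: pd.DataFrame, source_precedence=SOURCES
) -> str | None:
    """Subtype from the qualifying event of the highest-precedence source
    that carries a label; None when no source does."""
    labelled = qualifying_events.dropna(subset=["subtype"])
    if labelled.empty:
        return None
    rank = {s: i for i, s in enumerate(source_precedence)}
    labelled = labelled.sort_values(
        by=["source", "date"],
        key=lambda col: col.map(rank) if col.name == "source" else col,
        kind="stable",
    )
    return labelled.iloc[0]["subtype"]


def mortality_reconcile(gp_date, certificate_date):
    """Pick the authoritative death date; the certificate is gold standard.

    Returns ``(date, discrepancy_days)`` where the discrepancy (GP minus
    certificate, in days) is reported only when both dates are present.
    """
    gp = _as_ts(gp_date)
    cert = _as_ts(certificate_date)
    if gp is None and cert is None:
        raise NoDataError("no death date from either source")
    if cert is None:
        return gp, None
    if gp is None:
        return cert, None
    return cert, int((gp - cert).days)


def _as_ts(value):
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    ts = pd.Timestamp(str(value))
    return None if pd.isna(ts) else ts


def reconcile_death_dates(cohort: LinkedCohort) -> pd.DataFrame:
    """Vectorized reconciliation over a cohort's GP and certificate dates."""
    gp = cohort.patients[["patient_id", "gp_death_date"]].copy()
    cert = cohort.deaths[["patient_id", "death_date"]].copy()
    merged = gp.merge(cert, on="patient_id", how="outer")
    merged["gp"] = pd.to_datetime(merged["gp_death_date"], errors="coerce")
    merged["cert"] = pd.to_datetime(merged["death_date"], errors="coerce")
    merged = merged.dropna(subset=["gp", "cert"], how="all")
    merged["authoritative"] = merged["cert"].fillna(merged["gp"])
    both = merged["gp"].notna() & merged["cert"].notna()
    merged["discrepancy_days"] = np.where(
        both, (merged["gp"] - merged["cert"]).dt.days, np.nan
    )
    return merged[["patient_id", "authoritative", "discrepancy_days"]]


# ---------------------------------------------------------------------------
# Dissemination document
# ---------------------------------------------------------------------------

def export_documentation(
    definition: PhenotypeDefinition, validation_report=None
) -> str:
    """Render a phenotype definition (and optional validation evidence) as a
    clinician-readable structured text document with a pseudocode block."""
    lines = [
        f"PHENOTYPE: {definition.name}",
        f"version: {definition.version}",
        "",
        "== Components ==",
    ]
    for name, comp in definition.components.items():
        if isinstance(comp, CodedComponent):
            lines.append(
                f"  [{name}] coded, source={comp.source}, "
                f"{len(comp.codes)} codes"
                + (
                    f", position_rule={comp.position_rule}"
                    if comp.source == "hospital"
                    else ""
                )
                + (
                    f", cause_rule={comp.cause_rule}"
                    if comp.source == "death"
                    else ""
                )
            )
            for code, (cat, sub) in comp.codes.items():
                lines.append(
                    f"      {code}  [{cat}]" + (f"  subtype={sub}" if sub else "")
                )
        elif isinstance(comp, MeasurementRule):
            win = f" within {comp.within_days}d" if comp.within_days else ""
            lines.append(
                f"  [{name}] measurement: {comp.analyte} {comp.comparator} "
                f"{comp.threshold} on >= {comp.min_occasions} occasions{win}"
            )
        elif isinstance(comp, PrescriptionRule):
            win = f" within {comp.within_days}d" if comp.within_days else ""
            lines.append(
                f"  [{name}] prescription: >= {comp.min_prescriptions} of "
                f"{{{', '.join(sorted(comp.codes))}}}{win}"
            )
    lines += [
        "",
        "== Pseudocode ==",
        f"  CASE IF {definition.ast.render()}",
        f"  INDEX DATE = {definition.index_date_rule}",
        f"  SUBTYPE from first labelled source in "
        f"({', '.join(definition.source_precedence)})",
        f"  CATEGORY precedence: {' > '.join(definition.category_precedence)}",
        "",
        "== Validation evidence ==",
    ]
    if validation_report is None:
        lines.append("  (none attached)")
    else:
        lines.append(validation_report.summary_text())
    return "\n".join(lines) + "\n"

# ---------------------------------------------------------------------------
# Definition serialization (YAML) and a ready-made toy definition
# ---------------------------------------------------------------------------

def definition_to_dict(definition: PhenotypeDefinition) -> dict:
    comps = {}
    for name, comp in definition.components.items():
        if isinstance(comp, CodedComponent):
            comps[name] = {
                "type": "coded",
                "source": comp.source,
                "position_rule": comp.position_rule,
                "cause_rule": comp.cause_rule,
                "codes": {
                    code: {"category": cat, **({"subtype": sub} if sub else {})}
                    for code, (cat, sub) in comp.codes.items()
                },
            }
        elif isinstance(comp, MeasurementRule):
            comps[name] = {
                "type": "measurement",
                "analyte": comp.analyte,
                "comparator": comp.comparator,
                "threshold": comp.threshold,
                "min_occasions": comp.min_occasions,
                "within_days": comp.within_days,
            }
        elif isinstance(comp, PrescriptionRule):
            comps[name] = {
                "type": "prescription",
                "codes": sorted(comp.codes),
                "min_prescriptions": comp.min_prescriptions,
                "within_days": comp.within_days,
            }
    return {
        "name": definition.name,
        "version": definition.version,
        "logic": definition.logic,
        "source_precedence": list(definition.source_precedence),
        "category_precedence": list(definition.category_precedence),
        "index_date_rule": definition.index_date_rule,
        "components": comps,
    }


def definition_from_dict(data: dict) -> PhenotypeDefinition:
    comps: dict[str, object] = {}
    for name, c in data.get("components", {}).items():
        kind = c.get("type", "coded")
        if kind == "coded":
            raw = c.get("codes", {})
            if isinstance(raw, list):
                codes = {code: ("incident", None) for code in raw}
            else:
                codes = {
                    code: (v.get("category", "incident"), v.get("subtype"))
                    if isinstance(v, dict)
                    else (str(v), None)
                    for code, v in raw.items()
                }
            comps[name] = CodedComponent(
                name=name,
                source=c["source"],
                codes=codes,
                position_rule=c.get("position_rule", "any"),
                cause_rule=c.get("cause_rule", "underlying_only"),
            )
        elif kind == "measurement":
            comps[name] = MeasurementRule(
                name=name,
                analyte=c["analyte"],
                comparator=c["comparator"],
                threshold=float(c["threshold"]),
                min_occasions=int(c.get("min_occasions", 1)),
                within_days=c.get("within_days"),
            )
        elif kind == "prescription":
            comps[name] = PrescriptionRule(
                name=name,
                codes=frozenset(c["codes"]),
                min_prescriptions=int(c.get("min_prescriptions", 1)),
                within_days=c.get("within_days"),
            )
        else:
            raise ConfigError(f"unknown component type {kind!r} for {name!r}")
    return PhenotypeDefinition(
        name=data["name"],
        version=str(data.get("version", "1.0")),
        components=comps,
        logic=data["logic"],
        source_precedence=tuple(data.get("source_precedence", SOURCES)),
        category_precedence=tuple(
            data.get("category_precedence", CATEGORY_RANK_DEFAULT)
        ),
        index_date_rule=data.get("index_date_rule", "earliest_qualifying_event"),
    )


def load_definition(path) -> PhenotypeDefinition:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return definition_from_dict(yaml.safe_load(fh))


def save_definition(definition: PhenotypeDefinition, path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(definition_to_dict(definition), fh, sort_keys=False)


def toy_definition(disease: str = "heart failure") -> PhenotypeDefinition:
    """A cross-source definition over the shipped toy terminologies."""
    from .synth import icd9_equivalence, toy_codelist, toy_disease_codes

    blocks = toy_disease_codes()
    eq9 = icd9_equivalence()
    gp = CodedComponent.from_codelist("gp", "primary", toy_codelist("READ", disease))
    hosp = CodedComponent.from_codelist(
        "hosp", "hospital", toy_codelist("ICD10", disease), position_rule="any"
    )
    reg = CodedComponent(
        name="reg", source="registry", codes={disease: ("incident", None)}
    )
    death_codes = {}
    for code in blocks["ICD10"]["case"]:
        death_codes[code] = ("incident", None)
        death_codes[eq9[code]] = ("incident", None)
    death = CodedComponent(
        name="death_cert", source="death", codes=death_codes, cause_rule="any"
    )
    return PhenotypeDefinition(
        name=disease,
        version="1.0",
        components={"gp": gp, "hosp": hosp, "reg": reg, "death_cert": death},
        logic="gp OR hosp OR reg OR death_cert",
        source_precedence=("primary", "registry", "hospital", "death"),
    )
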