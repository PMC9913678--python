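"""Scan-sampling records: domain types, CSV I/O, validation, stratification.

The observational unit is an instantaneous scan: at fixed timepoints (every
2 minutes within a 20-minute session) the current behavior of every visible
individual is recorded, together with the social partner and direction for
social behaviors.  A long-format table of such records is the input to every
downstream stage.  Records are stratified into (phase, season) cells — a
*phase* is a period of constant group composition, a *season* is a climatic
half of the year — and all response variables are later computed per
individual within each stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("groomnet")

#: Column order of the standard scan CSV.
SCAN_COLUMNS = [
    "session_id",
    "timestamp",
    "timepoint",
    "individual",
    "behavior",
    "sub_behavior",
    "partner",
    "direction",
]

#: Stratum label columns appended by :func:`assign_strata`.
STRATUM_COLUMNS = ["phase", "season"]

ACTIVE = "active"
INACTIVE = "inactive"
GIVEN = "given"
RECEIVED = "received"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorCatalog:
    """The ethogram: behavior codes, their activity class and special roles.

    Parameters
    ----------
    items
        All top-level behavior codes.
    sub_behaviors
        Optional finer codes (free vocabulary, not classified).
    class_map
        Maps every behavior code to ``"active"`` or ``"inactive"``.
    undesired_set
        Codes counted as undesired (abnormal plus self-directed behaviors);
        must be a subset of the inactive codes.
    grooming_code
        The code denoting directed allogrooming; must be active and social.
    social_codes
        Codes for which a partner is expected; all others must not carry one.
    """

    items: tuple[str, ...]
    sub_behaviors: tuple[str, ...]
    class_map: Mapping[str, str]
    undesired_set: frozenset[str]
    grooming_code: str
    social_codes: frozenset[str]

    def __post_init__(self) -> None:
        missing = set(self.items) - set(self.class_map)
        if missing:
            raise ValueError(f"behavior codes without activity class: {sorted(missing)}")
        bad = {c for c, k in self.class_map.items() if k not in (ACTIVE, INACTIVE)}
        if bad:
            raise ValueError(f"class_map values must be active/inactive, got {sorted(bad)}")
        stray = self.undesired_set - {c for c in self.items if self.class_map[c] == INACTIVE}
        if stray:
            raise ValueError(
                f"undesired codes must be classified inactive: {sorted(stray)}"
            )
        if self.class_map.get(self.grooming_code) != ACTIVE:
            raise ValueError("grooming code must be classified active")
        if self.grooming_code not in self.social_codes:
            raise ValueError("grooming code must be social")

    @property
    def active_codes(self) -> frozenset[str]:
        return frozenset(c for c in self.items if self.class_map[c] == ACTIVE)

    @property
    def inactive_codes(self) -> frozenset[str]:
        return frozenset(c for c in self.items if self.class_map[c] == INACTIVE)


@dataclass(frozen=True)
class Individual:
    """One group member with the covariates used by the models."""

    id: str
    sex: str  # "M" | "F"
    birth_year: int
    origin: str  # "wild_caught" | "captive_born"
    join_date: date
    exit_date: date | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.id}: sex must be M or F")
        if self.origin not in ("wild_caught", "captive_born"):
            raise ValueError(f"{self.id}: origin must be wild_caught or captive_born")
        if self.exit_date is not None and self.exit_date <= self.join_date:
            raise ValueError(f"{self.id}: exit_date must be after join_date")


ALL_MALE = "all_male"
MIXED_SEX = "mixed_sex"


@dataclass(frozen=True)
class StudyPhase:
    """A period of constant group composition.

    ``start_date``/``end_date`` are inclusive; phases must not overlap.
    """

    label: str
    start_date: date
    end_date: date
    roster: tuple[str, ...]
    sex_ratio: str  # ALL_MALE | MIXED_SEX

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError(f"{self.label}: end_date must be after start_date")
        if len(self.roster) < 2:
            raise ValueError(f"{self.label}: need at least 2 individuals")
        if len(set(self.roster)) != len(self.roster):
            raise ValueError(f"{self.label}: duplicate roster ids")
        if self.sex_ratio not in (ALL_MALE, MIXED_SEX):
            raise ValueError(f"{self.label}: bad sex_ratio {self.sex_ratio!r}")

    @property
    def n(self) -> int:
        """Group size."""
        return len(self.roster)

    def contains(self, ts: date | datetime) -> bool:
        d = ts.date() if isinstance(ts, datetime) else ts
        return self.start_date <= d <= self.end_date


def check_phases(phases: Sequence[StudyPhase], roster: Sequence[Individual]) -> None:
    """Validate a phase chronology against a roster.

    Raises ``ValueError`` on overlapping/unordered phases, roster members not
    in the roster list, sex-ratio labels inconsistent with member sexes, or
    membership dates excluding a rostered phase.
    """
    by_id = {ind.id: ind for ind in roster}
    prev_end: date | None = None
    for ph in phases:
        if prev_end is not None and ph.start_date <= prev_end:
            raise ValueError(f"phase {ph.label} overlaps or precedes the previous phase")
        prev_end = ph.end_date
        sexes = set()
        for pid in ph.roster:
            ind = by_id.get(pid)
            if ind is None:
                raise ValueError(f"phase {ph.label}: {pid} not in roster")
            if ind.join_date > ph.start_date or (
                ind.exit_date is not None and ind.exit_date < ph.end_date
            ):
                raise ValueError(
                    f"phase {ph.label}: {pid} membership dates do not cover the phase"
                )
            sexes.add(ind.sex)
        all_male = sexes == {"M"}
        if all_male != (ph.sex_ratio == ALL_MALE):
            raise ValueError(f"phase {ph.label}: sex_ratio label inconsistent with roster")


COLD = "cold"
WARM = "warm"


@dataclass(frozen=True)
class SeasonRule:
    """Maps calendar month (1-12) to ``"cold"`` or ``"warm"``."""

    month_to_season: Mapping[int, str]

    def __post_init__(self) -> None:
        if set(self.month_to_season) != set(range(1, 13)):
            raise ValueError("month_to_season must cover months 1..12")
        seasons = set(self.month_to_season.values())
        if seasons != {COLD, WARM}:
            raise ValueError("both seasons must be non-empty and named cold/warm")

    def season_of(self, ts: date | datetime) -> str:
        return self.month_to_season[ts.month]

    def months(self, season: str) -> list[int]:
        return [m for m, s in self.month_to_season.items() if s == season]


@dataclass
class ScanTable:
    """Long-format scan records (one row per session x timepoint x individual).

    Wraps a :class:`pandas.DataFrame` with columns :data:`SCAN_COLUMNS`, plus
    ``phase``/``season`` once stratified.
    """

    df: pd.DataFrame
    report: "ValidationReport | None" = None

    def __post_init__(self) -> None:
        missing = [c for c in SCAN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"scan table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def stratified(self) -> bool:
        return all(c in self.df.columns for c in STRATUM_COLUMNS)

    def copy(self) -> "ScanTable":
        return ScanTable(self.df.copy(), report=self.report)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``line`` is the 1-based CSV line (header = 1)."""

    kind: str
    message: str
    line: int | None = None


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, kind: str, message: str, line: int | None = None) -> None:
        self.findings.append(Finding(kind, message, line))

    def __len__(self) -> int:
        return len(self.findings)

    @property
    def ok(self) -> bool:
        return not self.findings

    def kinds(self) -> list[str]:
        return [f.kind for f in self.findings]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.kind, f.line, f.message) for f in self.findings],
            columns=["kind", "line", "message"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_scans(path: str | Path, catalog: BehaviorCatalog | None = None) -> ScanTable:
    """Read a scan CSV, collecting row-level problems into a report.

    A missing required column is a hard error.  Rows with unparseable
    timestamps or timepoints are dropped and reported with their CSV line
    number; unknown behavior codes are reported but kept (strictness is the
    caller's decision).  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    report = ValidationReport()
    # CSV line = dataframe position + 2 (header is line 1)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    for pos in ts.index[ts.isna()]:
        report.add(
            "bad_timestamp",
            f"unparseable timestamp {df.at[pos, 'timestamp']!r}",
            line=int(pos) + 2,
        )
    tp = pd.to_numeric(df["timepoint"], errors="coerce")
    for pos in tp.index[tp.isna()]:
        report.add(
            "bad_timepoint",
            f"unparseable timepoint {df.at[pos, 'timepoint']!r}",
            line=int(pos) + 2,
        )
    keep = ts.notna() & tp.notna()

    out = df.loc[keep, :].copy()
    out["timestamp"] = ts[keep]
    out["timepoint"] = tp[keep].astype(int)
    for col in ("sub_behavior", "partner", "direction"):
        out[col] = out[col].replace("", pd.NA)

    if catalog is not None:
        known = set(catalog.items)
        for pos, code in out["behavior"].items():
            if code not in known:
                report.add(
                    "unknown_behavior", f"unknown behavior code {code!r}", line=int(pos) + 2
                )

    cols = SCAN_COLUMNS + [c for c in STRATUM_COLUMNS if c in out.columns]
    table = ScanTable(out[cols].reset_index(drop=True), report=report)
    if len(report):
        logger.warning("read_scans: %d finding(s) while parsing %s", len(report), path)
    return table


def write_scans(table: ScanTable, path: str | Path) -> None:
    """Write the standard scan CSV (ISO-8601 timestamps, empty cells for NA)."""
    df = table.df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_scans(
    table: ScanTable,
    catalog: BehaviorCatalog,
    phases: Sequence[StudyPhase],
) -> ValidationReport:
    """Check protocol structure; pure report, the table is not modified.

    Findings: unknown behavior codes, partner on a non-social behavior,
    social behavior without partner, self-partnering, partner absent from the
    phase roster, duplicate (session, timepoint, individual) slots, and
    timestamps outside every phase.
    """
    report = ValidationReport()
    df = table.df
    known = set(catalog.items)
    roster_by_phase = {ph.label: set(ph.roster) for ph in phases}

    ts = pd.to_datetime(df["timestamp"])
    phase_of = _phase_labels(ts, phases)

    dup = df.duplicated(subset=["session_id", "timepoint", "individual"], keep="first")
    for pos in df.index:
        line = int(pos) + 2
        behavior = df.at[pos, "behavior"]
        partner = df.at[pos, "partner"]
        has_partner = pd.notna(partner) and partner != ""
        if behavior not in known:
            report.add("unknown_behavior", f"unknown behavior code {behavior!r}", line)
        else:
            social = behavior in catalog.social_codes
            if has_partner and not social:
                report.add(
                    "partner_on_nonsocial",
                    f"partner {partner!r} on non-social behavior {behavior!r}",
                    line,
                )
            if social and not has_partner:
                report.add(
                    "social_without_partner",
                    f"social behavior {behavior!r} without partner",
                    line,
                )
        if has_partner and partner == df.at[pos, "individual"]:
            report.add("self_partner", f"{partner!r} recorded as its own partner", line)
        label = phase_of[pos]
        if label is None:
            report.add(
                "timestamp_outside_phases",
                f"timestamp {df.at[pos, 'timestamp']} falls in no phase",
                line,
            )
        else:
            roster = roster_by_phase[label]
            if df.at[pos, "individual"] not in roster:
                report.add(
                    "individual_off_roster",
                    f"{df.at[pos, 'individual']!r} not on roster of {label}",
                    line,
                )
            if has_partner and partner != df.at[pos, "individual"] and partner not in roster:
                report.add(
                    "partner_off_roster",
                    f"partner {partner!r} not on roster of {label}",
                    line,
                )
        if dup.loc[pos]:
            report.add(
                "duplicate_slot",
                "duplicate (session {}, timepoint {}, individual {})".format(
                    df.at[pos, "session_id"], df.at[pos, "timepoint"], df.at[pos, "individual"]
                ),
                line,
            )
    return report


def _phase_labels(ts: pd.Series, phases: Sequence[StudyPhase]) -> list[str | None]:
    dates = ts.dt.date
    out: list[str | None] = []
    for d in dates:
        label = None
        for ph in phases:
            if ph.start_date <= d <= ph.end_date:
                label = ph.label
                break
        out.append(label)
    return out


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def assign_strata(
    table: ScanTable,
    phases: Sequence[StudyPhase],
    season_rule: SeasonRule,
) -> ScanTable:
    """Label every record with its (phase, season) stratum.

    Labeling is a pure function of the timestamp, hence idempotent.  A
    timestamp inside no phase is an error listing the offenders.
    """
    df = table.df.copy()
    ts = pd.to_datetime(df["timestamp"])
    labels = _phase_labels(ts, phases)
    bad = sorted({str(df.at[pos, "timestamp"]) for pos, lab in zip(df.index, labels) if lab is None})
    if bad:
        raise ValueError(f"timestamps outside all phases: {bad[:10]}" + ("..." if len(bad) > 10 else ""))
    df["phase"] = labels
    df["season"] = [season_rule.month_to_season[m] for m in ts.dt.month]
    return ScanTable(df, report=table.report)


def stratum_keys(phases: Sequence[StudyPhase]) -> list[tuple[str, str]]:
    """All (phase label, season) cells of a design, phase-major, cold first."""
    return [(ph.label, season) for ph in phases for season in (COLD, WARM)]
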