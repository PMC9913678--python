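"""Default study design: a sanctuary chimpanzee group observed over ~6 years.

The group went through two alterations — the integration of two adult
females into an all-male group of five, and later the death of two males —
yielding three phases of constant composition.  Crossed with a two-season
climate rule this gives six strata.  These defaults drive the synthetic
generator and the reconstructed design used for collinearity diagnostics;
every piece is replaceable through configuration.
"""

from __future__ import annotations

import itertools
from datetime import date
from typing import Sequence

import pandas as pd

from .scans import (
    ALL_MALE,
    COLD,
    MIXED_SEX,
    WARM,
    BehaviorCatalog,
    Individual,
    SeasonRule,
    StudyPhase,
    check_phases,
)

# ---------------------------------------------------------------------------
# Ethogram: 17 behavior items, 16 sub-behaviors
# ---------------------------------------------------------------------------

_ACTIVE_ITEMS = (
    "groom",                 # directed allogrooming (social)
    "agonistic",             # threats, chases, fights (social)
    "affiliative_contact",   # embrace, social play, contact sitting (social)
    "sociosexual",           # mounting, genital inspection (social)
    "feeding",
    "foraging",
    "drinking",
    "locomotion",
    "enrichment_manipulation",
    "human_directed",
    "solitary_play",
    "nest_building",
)
_INACTIVE_ITEMS = (
    "resting",
    "sleeping",
    "vigilance",       # stationary vigilance
    "abnormal",        # excessive self-grooming, coprophagy, ...
    "self_directed",   # yawning, self-scratching, attention to self
)

_SUB_BEHAVIORS = (
    "excessive_self_groom",
    "repetitive_scratch",
    "coprophagy",
    "self_poke",
    "eat",
    "process_food",
    "patrol",
    "climb",
    "walk",
    "run",
    "groom_head",
    "groom_back",
    "mount",
    "inspect_genitals",
    "play_chase",
    "scratch",
)


def default_catalog() -> BehaviorCatalog:
    """Ethogram with activity classes, undesired set and social codes.

    Undesired behaviors are the abnormal plus self-directed codes; both are
    classified inactive.  Allogrooming is the edge-defining social behavior.
    """
    class_map = {c: "active" for c in _ACTIVE_ITEMS}
    class_map.update({c: "inactive" for c in _INACTIVE_ITEMS})
    return BehaviorCatalog(
        items=_ACTIVE_ITEMS + _INACTIVE_ITEMS,
        sub_behaviors=_SUB_BEHAVIORS,
        class_map=class_map,
        undesired_set=frozenset({"abnormal", "self_directed"}),
        grooming_code="groom",
        social_codes=frozenset({"groom", "agonistic", "affiliative_contact", "sociosexual"}),
    )


# ---------------------------------------------------------------------------
# Roster and phase chronology
# ---------------------------------------------------------------------------


def default_roster() -> tuple[Individual, ...]:
    """Seven individuals: five males, two females; two wild-caught."""
    return (
        Individual("AFR", "F", 2000, "wild_caught", date(2017, 1, 1)),
        Individual("BON", "M", 2000, "captive_born", date(2009, 1, 1)),
        Individual("CHA", "M", 1989, "captive_born", date(2001, 1, 1), date(2020, 12, 31)),
        Individual("JUA", "M", 2003, "captive_born", date(2003, 1, 1)),
        Individual("MAR", "M", 1984, "captive_born", date(2001, 1, 1)),
        Individual("TON", "M", 1983, "wild_caught", date(2001, 1, 1), date(2020, 12, 31)),
        Individual("WAT", "F", 2002, "captive_born", date(2017, 1, 1)),
    )


def default_phases() -> tuple[StudyPhase, ...]:
    """Three phases of constant composition; boundaries on calendar years.

    The chronology is printed to year precision only, so phase borders
    default to January 1 of the printed years (the final phase ends with the
    observation window in March of the last year).
    """
    return (
        StudyPhase(
            "phase1", date(2016, 1, 1), date(2016, 12, 31),
            ("BON", "CHA", "JUA", "MAR", "TON"), ALL_MALE,
        ),
        StudyPhase(
            "phase2", date(2017, 1, 1), date(2020, 12, 31),
            ("AFR", "BON", "CHA", "JUA", "MAR", "TON", "WAT"), MIXED_SEX,
        ),
        StudyPhase(
            "phase3", date(2021, 1, 1), date(2022, 3, 31),
            ("AFR", "BON", "JUA", "MAR", "WAT"), MIXED_SEX,
        ),
    )


def default_season_rule() -> SeasonRule:
    """November-April cold, May-October warm (Mediterranean climate)."""
    return SeasonRule({m: (COLD if m in (11, 12, 1, 2, 3, 4) else WARM) for m in range(1, 13)})


def default_design() -> tuple[tuple[Individual, ...], tuple[StudyPhase, ...], SeasonRule]:
    roster, phases = default_roster(), default_phases()
    check_phases(phases, roster)
    return roster, phases, default_season_rule()


# ---------------------------------------------------------------------------
# Design-derived quantities
# ---------------------------------------------------------------------------


def dyad_census(roster: Sequence[Individual]) -> dict[str, int]:
    """Count unordered pairs by sex combination.

    Returns keys ``male_male``, ``male_female``, ``female_female``, ``total``.
    """
    sexes = {ind.id: ind.sex for ind in roster}
    counts = {"male_male": 0, "male_female": 0, "female_female": 0}
    for a, b in itertools.combinations(sorted(sexes), 2):
        pair = {sexes[a], sexes[b]}
        if pair == {"M"}:
            counts["male_male"] += 1
        elif pair == {"F"}:
            counts["female_female"] += 1
        else:
            counts["male_female"] += 1
    counts["total"] = sum(counts.values())
    return counts


def reconstruct_design(
    roster: Sequence[Individual] | None = None,
    phases: Sequence[StudyPhase] | None = None,
) -> pd.DataFrame:
    """The individual x phase x season table with the five binary factors.

    One row per rostered individual per stratum (34 rows for the default
    design: (5 + 7 + 5) x 2 seasons), carrying ``group_size`` (5/7),
    ``sex_ratio``, ``season``, ``sex``, ``origin`` plus identifiers.  This is
    the fixed-effects design the mixed models see, independent of any data.
    """
    roster = default_roster() if roster is None else tuple(roster)
    phases = default_phases() if phases is None else tuple(phases)
    by_id = {ind.id: ind for ind in roster}
    rows = []
    for ph in phases:
        for season in (COLD, WARM):
            for pid in ph.roster:
                ind = by_id[pid]
                rows.append(
                    {
                        "individual": pid,
                        "phase": ph.label,
                        "season": season,
                        "group_size": ph.n,
                        "sex_ratio": ph.sex_ratio,
                        "sex": ind.sex,
                        "origin": ind.origin,
                    }
                )
    return pd.DataFrame(rows)
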