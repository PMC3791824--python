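"""Dataset-level orchestration: score every child and assemble the comparison table.

Glue between the per-child scoring functions and the report stage: builds the
per-child score table (raw HEI-2005 and RC-DQI component points, rescaled
comparable components, subscores, and the demographic strata) that
:func:`childdqi.comparison.stratified_report` and the CLI consume.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import comparison, hei2005, rcdqi
from .intake_model import ChildProfile, UsualIntake, profiles_from_frame, usual_from_frame

log = logging.getLogger(__name__)

#: Columns of the per-child score table, in writing order.
STRATUM_COLUMNS = ("age", "sex", "age_group", "ethnic_group", "income_group")


def score_child(
    profile: ChildProfile,
    usual: UsualIntake,
    table_variant: str = "table_b",
    hei_proration: str = "paper_linear",
    eer_formula: str = "proportional",
) -> dict:
    """Score one child under both indexes and rescale; returns one table row."""
    hei = hei2005.score_hei(usual, proration=hei_proration)
    rc = rcdqi.score_rcdqi(
        profile, usual, table_variant=table_variant, eer_formula=eer_formula
    )
    hei_re, rc_re = comparison.rescale(hei, rc)
    row: dict = {
        "child_id": profile.child_id,
        "age": profile.age,
        "sex": profile.sex,
        "age_group": profile.age_group,
        "ethnic_group": profile.ethnic_group,
        "income_group": profile.income_group,
    }
    for comp, value in hei.as_dict().items():
        row[f"heiraw_{comp}"] = value
    for comp, value in rc.as_dict().items():
        row[f"rcraw_{comp}"] = value
    for comp, value in hei_re.as_dict().items():
        row[f"hei_{comp}"] = value
    for comp, value in rc_re.as_dict().items():
        row[f"rcdqi_{comp}"] = value
    return row


def score_dataset(
    children: pd.DataFrame,
    intake: pd.DataFrame,
    table_variant: str = "table_b",
    hei_proration: str = "paper_linear",
    eer_formula: str = "proportional",
    require_two_days: bool = True,
) -> pd.DataFrame:
    """Score a whole survey: children table + child-day intake table -> score table.

    Children lacking the required number of recall days (or absent from
    either table) are dropped; the count is logged. One row per scored child.
    """
    profiles = {p.child_id: p for p in profiles_from_frame(children)}
    usual = usual_from_frame(intake, require_two_days=require_two_days)
    common = [cid for cid in profiles if cid in usual]
    dropped = len(profiles) - len(common)
    if dropped:
        log.info("dropped %d children without usable intake records", dropped)
    log.info(
        "scoring %d children (variant=%s, proration=%s, eer_formula=%s)",
        len(common), table_variant, hei_proration, eer_formula,
    )
    rows = [
        score_child(
            profiles[cid],
            usual[cid],
            table_variant=table_variant,
            hei_proration=hei_proration,
            eer_formula=eer_formula,
        )
        for cid in common
    ]
    return pd.DataFrame(rows)
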