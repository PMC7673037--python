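"""Drug-screen scoring: z-scores against non-drug controls, 2-SD hit calling,
and the normoxia counter-screen exclusion.

Each drug well's mean granules/cell is normalized to the same arm's control
wells: z = (x - control_mean) / control_SD.  Hits are wells at least
``threshold_sd`` control SDs above the control mean (one-sided by default,
since the screen seeks *retained* granules); drugs that also score as hits in
the unstressed normoxia arm are excluded as likely nonspecific inducers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["ScoredPlate", "compute_zscores", "call_hits", "counter_screen_filter"]

PLATE_COLUMNS = ("well_id", "kind", "mean_granules_per_cell")


@dataclass
class ScoredPlate:
    """A scored plate arm: the well table with z-scores plus control stats."""

    wells: pd.DataFrame  # original columns + z (drug and control wells)
    arm: str
    control_mean: float
    control_sd: float

    def ranked_drugs(self) -> pd.DataFrame:
        drugs = self.wells[self.wells["kind"] == "drug"]
        return drugs.sort_values(
            ["z", "well_id"], ascending=[False, True], kind="stable", ignore_index=True
        )


def _validate_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    bad_kind = set(plate["kind"].unique()) - {"drug", "control"}
    if bad_kind:
        raise ValueError(f"unknown well kinds: {sorted(bad_kind)}")


def compute_zscores(plate: pd.DataFrame, arm: str = "", ddof: int = 1) -> ScoredPlate:
    """z-score every well against the arm's non-drug controls.

    ``ddof=1`` (sample SD over control wells) is the default convention; with
    it the control wells' own z-scores have mean 0 and SD (same ddof) exactly
    1.  z-scores are affine invariant: x -> a*x + b (a > 0) leaves them
    unchanged.
    """
    _validate_plate(plate)
    if arm and "arm" in plate.columns:
        plate = plate[plate["arm"] == arm]
    arm_name = arm or (plate["arm"].iloc[0] if "arm" in plate.columns else "plate")
    controls = plate.loc[plate["kind"] == "control", "mean_granules_per_cell"]
    if len(controls) < 2:
        raise ValueError(f"arm {arm_name!r}: need >= 2 control wells")
    m_c = float(controls.mean())
    s_c = float(controls.std(ddof=ddof))
    if s_c == 0:
        raise ValueError(f"arm {arm_name!r}: control SD is zero; z-scores undefined")
    wells = plate.copy()
    wells["z"] = (wells["mean_granules_per_cell"] - m_c) / s_c
    log.info("arm %s: %d drug wells, %d controls, m_c=%.4g s_c=%.4g",
             arm_name, int((wells["kind"] == "drug").sum()), len(controls), m_c, s_c)
    return ScoredPlate(wells=wells, arm=str(arm_name), control_mean=m_c, control_sd=s_c)


def call_hits(
    scored: ScoredPlate, threshold_sd: float = 2.0, two_sided: bool = False
) -> pd.DataFrame:
    """Hit table: drug wells with z >= threshold (|z| >= threshold if
    two-sided), sorted by z descending with stable well_id tie-break."""
    ranked = scored.ranked_drugs()
    crit = ranked["z"].abs() >= threshold_sd if two_sided else ranked["z"] >= threshold_sd
    return ranked[crit].reset_index(drop=True)


def counter_screen_filter(
    hypoxia_hits: pd.DataFrame,
    normoxia_scored: ScoredPlate,
    threshold_sd: float = 2.0,
    two_sided: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove hypoxia-recovery hits that also induce granules in normoxia.

    A hit whose normoxia-arm z meets the same hit threshold is moved to the
    excluded list (likely stress-independent granule inducer).  Hits absent
    from the normoxia arm are retained with a missing-counter-screen warning.
    Returns (final_candidates, excluded), both sorted by hypoxia z.
    """
    norm_hits = call_hits(normoxia_scored, threshold_sd=threshold_sd, two_sided=two_sided)
    inducers = set(norm_hits["well_id"])
    screened = set(normoxia_scored.wells.loc[normoxia_scored.wells["kind"] == "drug", "well_id"])
    missing = set(hypoxia_hits["well_id"]) - screened
    if missing:
        log.warning(
            "%d hits lack a normoxia counter-screen well; retained: %s",
            len(missing), sorted(missing),
        )
    excluded = hypoxia_hits[hypoxia_hits["well_id"].isin(inducers)].reset_index(drop=True)
    final = hypoxia_hits[~hypoxia_hits["well_id"].isin(inducers)].reset_index(drop=True)
    return final, excluded
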