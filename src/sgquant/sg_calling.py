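"""Dual-marker stress-granule calling.

A candidate punctum only becomes a called stress granule when a punctum in the
second marker channel coincides with it (one-to-one matching within each
cell), the two channels' pixel intensities over the pair's footprint
correlate with Pearson r above the threshold (default r > 0.5), and both
puncta are
sufficiently bright relative to their channel's cytoplasmic background.
Single-channel puncta are never called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .puncta import PunctumRecord

log = logging.getLogger(__name__)

__all__ = [
    "SGCallParams",
    "StressGranule",
    "MatchResult",
    "match_puncta",
    "call_stress_granules",
    "per_cell_sg_counts",
]


@dataclass(frozen=True)
class SGCallParams:
    """Dual-marker calling parameters.

    ``correlation_domain`` selects the pixel set over which the two channels
    are correlated: ``"intersection"`` (default) uses the pixels both puncta
    claim, which isolates the co-localized signal even when a punctum's
    footprint has fused with a single-channel neighbour; ``"union"`` uses all
    pixels of either footprint.
    """

    correlation_threshold: float = 0.5
    match_rule: str = "footprint-overlap"
    max_centroid_distance: float = 5.0
    intensity_sufficiency_k: float = 2.0
    correlation_domain: str = "intersection"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.correlation_threshold <= 1.0):
            raise ValueError("correlation_threshold must lie in [-1, 1]")
        if self.max_centroid_distance <= 0:
            raise ValueError("max_centroid_distance must be positive")
        if self.match_rule not in ("footprint-overlap", "centroid-distance"):
            raise ValueError("unknown match_rule")
        if self.correlation_domain not in ("intersection", "union"):
            raise ValueError("unknown correlation_domain")


@dataclass
class StressGranule:
    sg_id: int
    cell_label: int
    punctum_id_m1: int
    punctum_id_m2: int
    correlation: float
    centroid: tuple[float, float]
    integrated_intensity: float


@dataclass
class MatchResult:
    pairs: list[tuple[PunctumRecord, PunctumRecord]]
    unmatched_m1: list[PunctumRecord]
    unmatched_m2: list[PunctumRecord]


def _footprint_set(p: PunctumRecord) -> set[tuple[int, int]]:
    return {(int(r), int(c)) for r, c in p.footprint}


def _centroid_dist(a: PunctumRecord, b: PunctumRecord) -> float:
    return float(np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1]))


def match_puncta(
    p1: list[PunctumRecord], p2: list[PunctumRecord], params: SGCallParams
) -> MatchResult:
    """One-to-one pairing of the two channels' puncta within each cell.

    Footprint-overlap rule (default): candidate pairs are puncta whose
    footprints intersect; multi-way overlaps are resolved greedily by maximum
    intersection area, ties by smaller centroid distance, then by the lower
    punctum-id pair.  The centroid-distance rule instead pairs by smallest
    centroid distance below ``max_centroid_distance``.  Symmetric in the two
    channels.
    """
    candidates: list[tuple[float, float, int, int, PunctumRecord, PunctumRecord]] = []
    by_cell2: dict[int, list[PunctumRecord]] = {}
    for q in p2:
        by_cell2.setdefault(q.cell_label, []).append(q)
    for a in p1:
        for b in by_cell2.get(a.cell_label, []):
            if params.match_rule == "footprint-overlap":
                overlap = len(_footprint_set(a) & _footprint_set(b))
                if overlap == 0:
                    continue
                primary = -float(overlap)
            else:
                d = _centroid_dist(a, b)
                if d > params.max_centroid_distance:
                    continue
                primary = d
            dist = _centroid_dist(a, b)
            ids = sorted((a.punctum_id, b.punctum_id))
            candidates.append((primary, dist, ids[0], ids[1], a, b))

    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    used1: set[int] = set()
    used2: set[int] = set()
    pairs: list[tuple[PunctumRecord, PunctumRecord]] = []
    for _, _, _, _, a, b in candidates:
        if a.punctum_id in used1 or b.punctum_id in used2:
            continue
        used1.add(a.punctum_id)
        used2.add(b.punctum_id)
        pairs.append((a, b))
    unmatched1 = [p for p in p1 if p.punctum_id not in used1]
    unmatched2 = [p for p in p2 if p.punctum_id not in used2]
    return MatchResult(pairs=pairs, unmatched_m1=unmatched1, unmatched_m2=unmatched2)


def call_stress_granules(
    pairs: list[tuple[PunctumRecord, PunctumRecord]],
    marker1_image: np.ndarray,
    marker2_image: np.ndarray,
    background_m1: tuple[float, float],
    background_m2: tuple[float, float],
    params: SGCallParams,
) -> list[StressGranule]:
    """Keep a matched pair as a stress granule iff the two channels correlate
    (Pearson r over the configured footprint domain, strictly above the
    threshold) and both puncta pass intensity sufficiency: mean intensity >=
    background mean + intensity_sufficiency_k * background SD in their own
    channel.  Pairs whose correlation domain holds fewer than 4 pixels (or is
    intensity-flat) have undefined correlation and are rejected with a log
    note.  The reported centroid and integrated intensity always cover the
    union footprint.
    """
    img1 = np.asarray(marker1_image, dtype=np.float64)
    img2 = np.asarray(marker2_image, dtype=np.float64)
    m1_mean, m1_sd = background_m1
    m2_mean, m2_sd = background_m2
    k = params.intensity_sufficiency_k

    sgs: list[StressGranule] = []
    n_small = 0
    sg_id = 1
    for a, b in pairs:
        union = np.unique(np.concatenate([a.footprint, b.footprint]), axis=0)
        if params.correlation_domain == "intersection":
            fa = {(int(r), int(c)) for r, c in a.footprint}
            fb = {(int(r), int(c)) for r, c in b.footprint}
            domain = np.array(sorted(fa & fb), dtype=np.int64).reshape(-1, 2)
        else:
            domain = union
        if domain.shape[0] < 4:
            n_small += 1
            continue
        v1 = img1[domain[:, 0], domain[:, 1]]
        v2 = img2[domain[:, 0], domain[:, 1]]
        if v1.std() == 0 or v2.std() == 0:
            n_small += 1
            continue
        r = float(np.corrcoef(v1, v2)[0, 1])
        if not r > params.correlation_threshold:
            continue
        if a.mean_intensity < m1_mean + k * m1_sd:
            continue
        if b.mean_intensity < m2_mean + k * m2_sd:
            continue
        centroid = (float(union[:, 0].mean()), float(union[:, 1].mean()))
        sgs.append(
            StressGranule(
                sg_id=sg_id,
                cell_label=a.cell_label,
                punctum_id_m1=a.punctum_id,
                punctum_id_m2=b.punctum_id,
                correlation=r,
                centroid=centroid,
                integrated_intensity=float(v1.sum() + v2.sum()),
            )
        )
        sg_id += 1
    if n_small:
        log.info("%d pairs rejected: correlation undefined (domain < 4 px or flat)", n_small)
    return sgs


def per_cell_sg_counts(sgs: list[StressGranule], cells: np.ndarray) -> pd.DataFrame:
    """One row per retained cell: cell_label, sg_count, sg_positive.

    Stress granules referencing a cell label absent from the cell map (e.g. a
    border cell dropped after detection) are discarded with a log note.
    """
    cells = np.asarray(cells)
    labels = np.unique(cells)
    labels = labels[labels > 0]
    counts = {int(lab): 0 for lab in labels}
    n_dropped = 0
    for sg in sgs:
        if sg.cell_label in counts:
            counts[sg.cell_label] += 1
        else:
            n_dropped += 1
    if n_dropped:
        log.info("%d stress granules referenced dropped cells; discarded", n_dropped)
    df = pd.DataFrame(
        {"cell_label": list(counts.keys()), "sg_count": list(counts.values())}
    ).sort_values("cell_label", ignore_index=True)
    df["sg_positive"] = df["sg_count"] >= 1
    return df
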