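"""Shared fixtures: cached synthetic fields and their segmentations.

Field generation and propagation are the slow steps, so fields keyed by their
spec are generated once per session and reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from sgquant import FieldSpec, PipelineConfig
from sgquant.segmentation import (
    SegmentationParams,
    cytoplasm_mask,
    detect_nuclei,
    filter_nuclei_to_cells,
    propagate_cells,
)
from sgquant.simulate import generate_field


class FieldFactory:
    """Generate-and-cache synthetic fields plus their segmentation."""

    def __init__(self) -> None:
        self._fields: dict[FieldSpec, tuple] = {}
        self._segmented: dict[FieldSpec, tuple] = {}

    def field(self, spec: FieldSpec):
        if spec not in self._fields:
            self._fields[spec] = generate_field(spec)
        return self._fields[spec]

    def segmented(self, spec: FieldSpec, params: SegmentationParams | None = None):
        """(channels, truth, nuclei, cells, cytoplasm) under default params."""
        if params is not None:
            channels, gt = self.field(spec)
            return (channels, gt, *self._segment(channels, params))
        if spec not in self._segmented:
            channels, gt = self.field(spec)
            self._segmented[spec] = (channels, gt, *self._segment(channels, SegmentationParams()))
        return self._segmented[spec]

    @staticmethod
    def _segment(channels, params):
        nuclei = detect_nuclei(channels["nuclei"], params)
        cells = propagate_cells(nuclei, channels["membrane"], params)
        nuclei_kept = filter_nuclei_to_cells(nuclei, cells)
        return nuclei_kept, cells, cytoplasm_mask(cells, nuclei_kept)


@pytest.fixture(scope="session")
def fields() -> FieldFactory:
    return FieldFactory()


@pytest.fixture(scope="session")
def small_spec() -> FieldSpec:
    """A quick 256x256 field with ~14 cells used by many unit tests."""
    return FieldSpec(width=256, height=256, n_cells=14, seed=7)


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


def match_rate(detected_rc: np.ndarray, truth_rc: np.ndarray, tol: float) -> tuple[float, float]:
    """(recall, precision) by greedy one-to-one nearest matching within tol."""
    from scipy.spatial import cKDTree

    if len(detected_rc) == 0 or len(truth_rc) == 0:
        return 0.0, 0.0
    d, idx = cKDTree(detected_rc).query(truth_rc)
    used: set[int] = set()
    tp = 0
    for dist, j in sorted(zip(d, idx)):
        if dist <= tol and j not in used:
            used.add(int(j))
            tp += 1
    return tp / len(truth_rc), tp / len(detected_rc)
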