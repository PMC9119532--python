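"""Shared fixtures.

Scene generation at full working resolution is the expensive step, so
generated scenes and their per-sample analyses are cached per session and
shared across tests that only read them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ectolayers import geometry, pipeline, synthgen
from ectolayers.imgio import BorderPair


def brute_force_dist(point_rc, polyline_rc):
    """Minimum distance from a point to a polyline, segment by segment."""
    p = np.asarray(point_rc, dtype=float)
    best = np.inf
    for a, b in zip(polyline_rc[:-1], polyline_rc[1:]):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


@pytest.fixture
def rect_borders() -> BorderPair:
    """Horizontal borders at rows 10 and 110 spanning cols 0..99 (1 um/px)."""
    return BorderPair(apical=[[10, 0], [10, 99]],
                      basal=[[110, 0], [110, 99]], um_per_px=1.0)


@pytest.fixture
def rect_mask(rect_borders):
    return geometry.epithelium_mask((120, 100), rect_borders)


class SceneCache:
    """Memoizing factory for generated scenes and their analyses."""

    def __init__(self) -> None:
        self._scenes: dict = {}
        self._analyses: dict = {}

    @staticmethod
    def _key(scenario: str, seed: int, overrides: dict) -> tuple:
        return (scenario, seed, repr(sorted(overrides.items())))

    def scene(self, scenario: str, seed: int, **overrides):
        key = self._key(scenario, seed, overrides)
        if key not in self._scenes:
            params = synthgen.scenario_params(scenario, seed=seed)
            if overrides:
                params = dataclasses.replace(params, **overrides)
            self._scenes[key] = synthgen.generate_scene(params)
        return self._scenes[key]

    def analysis(self, scenario: str, seed: int, **overrides):
        """(metric dict, qc, ground truth) for a cached scene."""
        key = self._key(scenario, seed, overrides)
        if key not in self._analyses:
            image, borders, gt = self.scene(scenario, seed, **overrides)
            records, qc = pipeline.run_sample(image, borders)
            metrics = {r.metric_name: r.value for r in records}
            self._analyses[key] = (metrics, qc, gt)
        return self._analyses[key]


@pytest.fixture(scope="session")
def scenes() -> SceneCache:
    return SceneCache()


#: seeds used for the recovery / cohort suites (distinct between arms)
COHORT_SEEDS = {"control_like": list(range(20)),
                "dmpa_like": list(range(100, 120))}


@pytest.fixture(scope="session")
def cohort40(scenes):
    """20 + 20 analysed scenes with cd4_count=400, keyed by (scenario, seed)."""
    out = {}
    for scenario, seeds in COHORT_SEEDS.items():
        for seed in seeds:
            out[(scenario, seed)] = scenes.analysis(scenario, seed, cd4_count=400)
    return out
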