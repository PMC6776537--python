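"""Shared fixtures and independent brute-force oracles.

The oracles re-derive envelope construction, topographic prominence and
one-to-one event matching from their definitions with simple O(n^2)
scans, independent of the scipy-based implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from htrkit import DetectionConfig, ScheduledEvent, SessionSpec, generate_session
from htrkit.simulate import uniform_schedule


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_local_maxima(y: np.ndarray) -> list[int]:
    """Interior local maxima by direct scan; plateau -> midpoint (floor)."""
    n = len(y)
    out = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def brute_envelope_pass(y: np.ndarray) -> np.ndarray:
    """Linear interpolation through local maxima with endpoint anchors."""
    n = len(y)
    anchors = sorted(set([0] + brute_local_maxima(y) + [n - 1]))
    out = np.empty(n)
    for a, b in zip(anchors[:-1], anchors[1:]):
        for k in range(a, b + 1):
            frac = 0.0 if b == a else (k - a) / (b - a)
            out[k] = y[a] + frac * (y[b] - y[a])
    return out


def brute_prominence(y: np.ndarray, peak: int) -> float:
    """Topographic prominence: height above the highest flanking saddle."""
    h = y[peak]
    left_min = h
    for k in range(peak - 1, -1, -1):
        if y[k] > h:
            break
        left_min = min(left_min, y[k])
    right_min = h
    for k in range(peak + 1, len(y)):
        if y[k] > h:
            break
        right_min = min(right_min, y[k])
    return h - max(left_min, right_min)


def brute_min_cost_matching(detected, reference, tol_s):
    """Exhaustive one-to-one matching maximizing pair count, then
    minimizing total |dt|.  Only feasible for <= ~10 events."""
    detected = list(detected)
    reference = list(reference)
    best = (0, 0.0, [])
    k = min(len(detected), len(reference))
    for size in range(k, -1, -1):
        found = None
        for det_sub in itertools.combinations(range(len(detected)), size):
            for ref_perm in itertools.permutations(range(len(reference)), size):
                dts = [abs(detected[i] - reference[j])
                       for i, j in zip(det_sub, ref_perm)]
                if all(d <= tol_s for d in dts):
                    cost = sum(dts)
                    if found is None or cost < found[0]:
                        found = (cost, list(zip(det_sub, ref_perm)))
        if found is not None:
            best = (size, found[0], found[1])
            break
    return best  # (n_pairs, total_cost, pairs)


# ---------------------------------------------------------------------------
# session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_config() -> DetectionConfig:
    return DetectionConfig()


def htr_session(n_events: int, duration_s: float, seed: int,
                amplitude_v: float = 0.3, min_gap_s: float = 1.0,
                dual_channel: bool = False):
    """Standard HTR-only synthetic session: amplitudes >= 20x noise SD,
    pairwise gaps >= 1 s."""
    rng = np.random.default_rng(seed)
    times = uniform_schedule(n_events, duration_s, min_gap_s, rng, edge_s=2.0)
    events = [ScheduledEvent("htr", float(t), amplitude_v, 0.06)
              for t in times]
    spec = SessionSpec(duration_s=duration_s, seed=seed, events=events,
                       dual_channel=dual_channel)
    return generate_session(spec)


@pytest.fixture(scope="session")
def clean_session():
    """20 head twitches in 40 s, single channel, seed 0."""
    return htr_session(20, 40.0, seed=0)
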