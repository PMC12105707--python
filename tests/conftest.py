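"""Shared fixtures and the independent brute-force hydrogen-bond oracle."""

from __future__ import annotations

import numpy as np
import pytest

from cptube.geometry import build_nanotube
from cptube.hbonds import HBondCriteria


@pytest.fixture(scope="session")
def ideal_octamer():
    """The canonical 8-unimer, 8-residue antiparallel nanotube model."""
    return build_nanotube()


@pytest.fixture(scope="session")
def default_criteria():
    return HBondCriteria()


def brute_force_hbonds(frame: np.ndarray, criteria: HBondCriteria):
    """Exhaustive O(n^2) detection over ALL inter-ring N/O pairs.

    Deliberately naive: plain Python loops, no adjacency shortcut, same
    cutoffs and one-bond-per-donor closest-acceptor rule (ties to the lower
    acceptor residue index).  Serves as the independent oracle for the
    optimized detector.
    """
    n_rings, n_res = frame.shape[:2]
    bonds = []
    for dr in range(n_rings):
        for dres in range(n_res):
            n_pos = frame[dr, dres, 0]
            h_pos = frame[dr, dres, 1]
            best = None
            for ar in range(n_rings):
                if ar == dr:
                    continue
                for ares in range(n_res):
                    o_pos = frame[ar, ares, 3]
                    d = float(np.linalg.norm(n_pos - o_pos))
                    if d > criteria.d_max:
                        continue
                    v1 = n_pos - h_pos
                    v2 = o_pos - h_pos
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2))
                    theta = float(np.degrees(
                        np.arccos(np.clip(cosang, -1.0, 1.0))))
                    if theta < criteria.theta_min:
                        continue
                    key = (d, ares, ar)
                    if best is None or key < best[0]:
                        best = (key, (dr, dres, ar, ares))
            if best is not None:
                bonds.append(best[1])
    return sorted(bonds)
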