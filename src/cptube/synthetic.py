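"""Synthetic trajectories and bond-state kinetics with known ground truth.

Real nanotube trajectories come from long atomistic MD runs; everything here
is a controllable stand-in that preserves the observables the analysis layer
consumes: thermal positional jitter, a scripted cap-unbinding event, and a
two-state (formed/broken) Markov process for per-bond occupancy at distinct
cap vs core rates.  Every generator takes an explicit integer seed and uses
its own ``numpy.random.Generator`` (PCG64), so outputs are bit-reproducible
per seed and no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import NanotubeModel

DEFAULT_FRAME_DT = 0.1  # ns between saved frames

#: Cap/core bond split of an ideal octamer: 2 cap interfaces x 8 bonds and
#: 5 core interfaces x 8 bonds.
OCTAMER_CAP_BONDS = 16
OCTAMER_CORE_BONDS = 40


@dataclass(frozen=True)
class Trajectory:
    """Frames of a nanotube model over time.

    ``frames`` has shape (n_frames, n_unimers, n_residues, 4, 3);
    ``frame_dt`` is the saving interval in ns.
    """

    frames: np.ndarray
    frame_dt: float
    n_unimers: int
    n_residues: int
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def simulated_time(self) -> float:
        """Covered time span in ns: (n_frames - 1) * frame_dt."""
        return (self.n_frames - 1) * self.frame_dt


@dataclass(frozen=True)
class BondStateSeries:
    """Boolean bond-presence matrix with cap/core labels.

    ``presence`` is (n_bonds, n_frames); ``labels`` holds ``"cap"`` or
    ``"core"`` per bond.  ``truth`` records the simulated per-class rates
    (ns^-1) when the series came from the Markov generator, and is absent
    for series measured from trajectories.
    """

    presence: np.ndarray
    labels: np.ndarray
    frame_dt: float
    bond_ids: tuple | None = None
    truth: dict | None = field(default=None)

    def __post_init__(self):
        if self.presence.ndim != 2:
            raise ValueError("presence must be a (bonds, frames) matrix")
        if len(self.labels) != self.presence.shape[0]:
            raise ValueError("labels must have one entry per bond")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    @property
    def n_bonds(self) -> int:
        return self.presence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.presence.shape[1]


def jitter_trajectory(model: NanotubeModel, n_frames: int, sigma: float,
                      frame_dt: float = DEFAULT_FRAME_DT,
                      seed: int = 0) -> Trajectory:
    """Thermal-noise trajectory: i.i.d. Gaussian displacement per atom/frame.

    Frame 0 is the unperturbed model; frames 1..n-1 displace every site
    coordinate by independent zero-mean Gaussian noise of s.d. ``sigma``
    (angstrom).  This emulates the frame-to-frame positional fluctuation of
    a stable stack without any correlated dynamics.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if frame_dt <= 0:
        raise ValueError(f"frame_dt must be positive, got {frame_dt}")
    rng = np.random.default_rng(seed)
    frames = np.repeat(model.coords[None, ...], n_frames, axis=0)
    if sigma > 0 and n_frames > 1:
        frames[1:] += rng.normal(0.0, sigma, size=frames[1:].shape)
    return Trajectory(frames=frames, frame_dt=frame_dt,
                      n_unimers=model.n_unimers,
                      n_residues=model.n_residues, seed=seed)


def script_cap_unbinding(traj: Trajectory, event_frame: int,
                         displacement: float,
                         tilt: float = 15.0) -> Trajectory:
    """Scripted dissociation of the terminal capping unimer.

    From ``event_frame`` onward the last ring is tilted by ``tilt`` degrees
    about an in-plane axis through its centroid and translated along +z by
    ``displacement`` angstrom, which removes all hydrogen bonds of the
    terminal interface once the displacement exceeds the detection cutoff
    (any displacement >= 3 angstrom suffices at default criteria).

    The mechanism in solution is a water-attack process; here only its
    geometric signature (a step loss of one interface's bonds) is modelled.
    """
    if not 0 <= event_frame < traj.n_frames:
        raise IndexError(
            f"event_frame {event_frame} outside [0, {traj.n_frames})")
    if displacement <= 0:
        raise ValueError(f"displacement must be positive, got {displacement}")

    frames = traj.frames.copy()
    cap = traj.n_unimers - 1
    phi = np.deg2rad(tilt)
    rot = np.array([[1.0, 0.0, 0.0],
                    [0.0, np.cos(phi), -np.sin(phi)],
                    [0.0, np.sin(phi), np.cos(phi)]])
    ring = frames[event_frame:, cap]                      # (F', res, 4, 3)
    centroid = ring.reshape(ring.shape[0], -1, 3).mean(axis=1)
    ring = (ring - centroid[:, None, None, :]) @ rot.T \
        + centroid[:, None, None, :]
    ring[..., 2] += displacement
    frames[event_frame:, cap] = ring
    return Trajectory(frames=frames, frame_dt=traj.frame_dt,
                      n_unimers=traj.n_unimers, n_residues=traj.n_residues,
                      seed=traj.seed)


def simulate_bond_states(n_cap_bonds: int = OCTAMER_CAP_BONDS,
                         n_core_bonds: int = OCTAMER_CORE_BONDS,
                         k_break_cap: float = 0.05,
                         k_break_core: float = 0.005,
                         k_reform: float = 5.0,
                         frame_dt: float = DEFAULT_FRAME_DT,
                         n_frames: int = 10_000,
                         seed: int = 0) -> BondStateSeries:
    """Simulate independent two-state Markov chains for bond occupancy.

    Each bond flips between formed and broken with per-frame probabilities
    obtained by exact exponential discretization of the continuous rates,

        p_break  = 1 - exp(-k_break  * frame_dt)
        p_reform = 1 - exp(-k_reform * frame_dt)

    so the rates keep their meaning at coarse frame spacing.  All bonds
    start formed.  The stationary formed fraction of the corresponding
    continuous chain is ``k_reform / (k_break + k_reform)``, which makes the
    expected raw break-event rate ``n_bonds * k_break * pi_formed`` in the
    fine-sampling limit -- the closed form used by the recovery tests.

    Rates are in ns^-1; ``truth`` records them alongside the class split.
    """
    for name, val in (("k_break_cap", k_break_cap),
                      ("k_break_core", k_break_core),
                      ("k_reform", k_reform)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
    if frame_dt <= 0:
        raise ValueError(f"frame_dt must be positive, got {frame_dt}")
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if n_cap_bonds < 0 or n_core_bonds < 0:
        raise ValueError("bond counts must be non-negative")

    n_bonds = n_cap_bonds + n_core_bonds
    k_break = np.concatenate([np.full(n_cap_bonds, k_break_cap),
                              np.full(n_core_bonds, k_break_core)])
    p_break = 1.0 - np.exp(-k_break * frame_dt)
    p_reform = 1.0 - np.exp(-k_reform * frame_dt)

    rng = np.random.default_rng(seed)
    u = rng.random((n_frames - 1, n_bonds)) if n_frames > 1 else None
    presence = np.empty((n_bonds, n_frames), dtype=bool)
    state = np.ones(n_bonds, dtype=bool)
    presence[:, 0] = state
    for t in range(1, n_frames):
        flip = np.where(state, u[t - 1] < p_break, u[t - 1] < p_reform)
        state = state ^ flip
        presence[:, t] = state

    labels = np.array(["cap"] * n_cap_bonds + ["core"] * n_core_bonds)
    truth = {"k_break_cap": k_break_cap, "k_break_core": k_break_core,
             "k_reform": k_reform, "n_cap_bonds": n_cap_bonds,
             "n_core_bonds": n_core_bonds}
    return BondStateSeries(presence=presence, labels=labels,
                           frame_dt=frame_dt, truth=truth)


def stationary_formed_fraction(k_break: float, k_reform: float) -> float:
    """Stationary formed probability of the continuous two-state chain."""
    if k_break == 0:
        return 1.0
    return k_reform / (k_break + k_reform)
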