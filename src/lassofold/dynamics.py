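"""Langevin dynamics in reduced units: equilibrium and refolding protocols.

The equation of motion m r̈ = -γ ṙ - ∇V + R(t), with Gaussian white noise of
variance 2 k_B T γ, is integrated with the Grønbech-Jensen–Farago Langevin
velocity-Verlet scheme at Δt = 0.001 reduced time, m = 1 and m/γ = 0.1.
Time is reported in "MD steps", 1 MD step = 24000 integration steps, and
observables (Q, ⟨G′⟩, potential energy, RMSD) are recorded every MD step by
default so both reaction coordinates share one time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .entanglement import HillParams, entanglement_indicator, gauss_pair_matrix
from .forcefield import (Conformation, GoParameters, _kernel_args,
                         fraction_native, kabsch_rmsd, potential_energy)
from .structure_io import NativeTopology

__all__ = ["MD_STEP_INTEGRATIONS", "IntegratorSettings", "ObservableSeries",
           "Trajectory", "run_langevin", "sample_unfolded",
           "run_refolding_batch", "run_equilibrium_ladder"]

#: integration steps per MD step (the paper-scale time unit)
MD_STEP_INTEGRATIONS = 24000


@dataclass(frozen=True)
class IntegratorSettings:
    """Reduced-unit Langevin integrator parameters."""

    dt: float = 0.001
    mass: float = 1.0
    damping: float = 0.1            # m/γ, reduced time
    temperature: float = 1.0        # ε/k_B
    seed: int = 0
    record_every: int = 1           # MD steps between recorded frames
    md_step: int = MD_STEP_INTEGRATIONS

    @property
    def gamma(self) -> float:
        return self.mass / self.damping

    def __post_init__(self):
        if self.dt <= 0 or self.damping <= 0 or self.temperature < 0:
            raise ValueError("require dt > 0, damping > 0, T >= 0")


@dataclass
class ObservableSeries:
    """Per-frame observables of one trajectory (equally spaced MD steps)."""

    step: np.ndarray        # MD-step index of each frame
    q: np.ndarray           # fraction of native contacts
    gprime: np.ndarray      # entanglement indicator ⟨G′⟩
    energy: np.ndarray      # potential energy, ε
    rmsd: np.ndarray        # Å
    formed: np.ndarray      # (n_frames, n_contacts) bool formation matrix
    temperature: float = 0.0
    seed: int = 0

    def __len__(self) -> int:
        return len(self.step)


@dataclass
class Trajectory:
    """Recorded coordinate frames plus provenance metadata."""

    frames: np.ndarray      # (n_frames, N, 3)
    record_every: int       # MD steps
    settings: IntegratorSettings
    velocities: np.ndarray | None = None  # (n_frames, N, 3), reduced units
    status: int = 0         # 0 ok, 1 numerical blow-up

    def final_conformation(self) -> Conformation:
        vel = None if self.velocities is None else self.velocities[-1].copy()
        return Conformation(self.frames[-1].copy(), velocities=vel)


def _observables(frames: np.ndarray, record_every: int,
                 topology: NativeTopology, params: GoParameters,
                 settings: IntegratorSettings,
                 hill: HillParams = HillParams()) -> ObservableSeries:
    n_frames = len(frames)
    q = np.zeros(n_frames)
    gp = np.zeros(n_frames)
    en = np.zeros(n_frames)
    rm = np.zeros(n_frames)
    formed = np.zeros((n_frames, topology.n_contacts), dtype=bool)
    contact_idx = {(i, j): k for k, (i, j, _) in enumerate(topology.contacts)}
    has_contacts = topology.n_contacts > 0
    for t, frame in enumerate(frames):
        conf = Conformation(frame)
        if has_contacts:
            q[t], fc = fraction_native(conf, topology,
                                       g=params.contact_formed_factor)
            for pair in fc:
                formed[t, contact_idx[pair]] = True
            mat = gauss_pair_matrix(frame) if len(frame) > 1 else None
            snap = entanglement_indicator(frame, fc, params=hill,
                                          pair_matrix=mat)
            gp[t] = snap.indicator
        en[t], _ = potential_energy(conf, topology, params)
        rm[t] = kabsch_rmsd(frame, topology.ca_coords)
    return ObservableSeries(
        step=np.arange(n_frames) * record_every, q=q, gprime=gp, energy=en,
        rmsd=rm, formed=formed, temperature=settings.temperature,
        seed=settings.seed)


def _maxwell_boltzmann(n: int, settings: IntegratorSettings,
                       rng: np.random.Generator) -> np.ndarray:
    if settings.temperature == 0.0:
        return np.zeros((n, 3))
    sd = np.sqrt(settings.temperature / settings.mass)
    return rng.normal(0.0, sd, size=(n, 3))


def run_langevin(initial: Conformation, topology: NativeTopology,
                 params: GoParameters, settings: IntegratorSettings,
                 n_md_steps: int,
                 compute_observables: bool = True,
                 ) -> tuple[Trajectory, ObservableSeries | None]:
    """Integrate n_md_steps MD steps of Langevin dynamics from `initial`.

    Velocities are drawn Maxwell–Boltzmann at the run temperature when the
    initial conformation carries none.  Fully reproducible given
    ``settings.seed``.  Raises ``RuntimeError`` on numerical blow-up.
    """
    pos = np.ascontiguousarray(initial.coords, dtype=np.float64).copy()
    rng = np.random.default_rng(settings.seed)
    vel = np.ascontiguousarray(
        initial.velocities.copy() if initial.velocities is not None
        else _maxwell_boltzmann(len(pos), settings, rng), dtype=np.float64)
    n = len(pos)
    kargs = _kernel_args(topology, params)
    noise_sd = np.sqrt(2.0 * settings.gamma * settings.temperature
                       * settings.dt)
    n_rec = n_md_steps // settings.record_every + 1
    frames = np.zeros((n_rec, n, 3))
    vels = np.zeros((n_rec, n, 3))
    frames[0], vels[0] = pos, vel
    f = np.zeros((n, 3))
    f_new = np.zeros((n, 3))
    _kernels.energy_forces_into(pos, f, *kargs)
    zero_noise = np.zeros((settings.md_step, n, 3))
    status = 0
    rec = 1
    for md in range(1, n_md_steps + 1):
        noise = (rng.standard_normal((settings.md_step, n, 3))
                 if settings.temperature > 0.0 else zero_noise)
        etot = _kernels.md_chunk(
            pos, vel, f, f_new, noise, *kargs,
            settings.dt, settings.mass, settings.gamma, noise_sd)
        if md % settings.record_every == 0:
            if not np.isfinite(etot) or np.abs(pos).max() > 1e6:
                status = 1
                frames[rec], vels[rec] = pos, vel
                frames, vels = frames[:rec + 1], vels[:rec + 1]
                break
            frames[rec], vels[rec] = pos, vel
            rec += 1
    traj = Trajectory(frames=frames, record_every=settings.record_every,
                      settings=settings, velocities=vels, status=status)
    if status != 0:
        raise RuntimeError(
            f"numerical blow-up after ~{len(frames) * settings.record_every} "
            f"MD steps (diagnostic frame retained)")
    series = (_observables(frames, settings.record_every, topology, params,
                           settings) if compute_observables else None)
    return traj, series


def sample_unfolded(topology: NativeTopology, params: GoParameters,
                    t_f: float, c: float, n_samples: int,
                    decorrelation_interval: int, seed: int,
                    burn_in: int = 100) -> list[Conformation]:
    """Uncorrelated unfolded conformations from equilibrium at T = c·T_f > T_f.

    Runs from the native structure at c·T_f, discards ``burn_in`` MD steps,
    then keeps snapshots every ``decorrelation_interval`` MD steps.
    """
    if c <= 1.0:
        raise ValueError("require c > 1 (sampling above the folding temperature)")
    settings = IntegratorSettings(temperature=c * t_f, seed=seed,
                                  record_every=decorrelation_interval)
    n_md = burn_in + n_samples * decorrelation_interval
    traj, _ = run_langevin(Conformation(topology.ca_coords.copy()), topology,
                           params, settings, n_md, compute_observables=False)
    first = int(np.ceil(burn_in / decorrelation_interval))
    picks = traj.frames[first:first + n_samples]
    if len(picks) < n_samples:
        raise ValueError("requested samples exceed trajectory capacity")
    return [Conformation(p.copy()) for p in picks]


def run_refolding_batch(topology: NativeTopology, params: GoParameters,
                        temperature: float, initials: list[Conformation],
                        n_md_steps: int, seeds: list[int],
                        record_every: int = 1,
                        ) -> tuple[list[ObservableSeries], list[Conformation], dict]:
    """Independent refolding trajectories from unfolded initial conformations.

    One seed and one initial conformation per trajectory; returns the
    per-trajectory observable series, final conformations, and a metadata
    dict sufficient for an exact re-run.
    """
    if len(initials) != len(seeds):
        raise ValueError("need one initial conformation per seed")
    series_list, finals = [], []
    for conf, seed in zip(initials, seeds):
        settings = IntegratorSettings(temperature=temperature, seed=int(seed),
                                      record_every=record_every)
        traj, series = run_langevin(conf, topology, params, settings,
                                    n_md_steps)
        series_list.append(series)
        finals.append(traj.final_conformation())
    meta = {"temperature": temperature, "n_md_steps": n_md_steps,
            "seeds": [int(s) for s in seeds], "record_every": record_every,
            "lj_flavour": params.lj_flavour,
            "integrator": "gjf-langevin-velocity-verlet"}
    return series_list, finals, meta


def run_equilibrium_ladder(topology: NativeTopology, params: GoParameters,
                           temperatures, n_md_steps: int, seed: int,
                           record_every: int = 1,
                           ) -> list[ObservableSeries]:
    """One equilibrium run per ladder temperature, started from native."""
    out = []
    for k, temp in enumerate(temperatures):
        settings = IntegratorSettings(temperature=float(temp),
                                      seed=seed + 1000 * k,
                                      record_every=record_every)
        _, series = run_langevin(Conformation(topology.ca_coords.copy()),
                                 topology, params, settings, n_md_steps)
        out.append(series)
    return out
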