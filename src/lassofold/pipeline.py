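"""End-to-end orchestration: structure → simulate → analyze from one config.

The config is TOML with one section per stage; stages run in dependency
order and each writes its artifacts plus a JSON sidecar (parameters, seeds,
package version) into the run directory.  Re-running an unchanged config
reproduces deterministic outputs bit-for-bit.  A minimal example::

    [run]
    out_dir = "runs/hairpin"

    [structure]
    fixture_motif = "hairpin"      # or: pdb = "path.pdb"
    n_residues = 12
    flavour = "12-6"

    [simulate]                     # equilibrium ladder (enables wham)
    temperatures = [0.8, 0.9, 1.0, 1.1]
    steps = 200
    seed = 7

    [wham]
    t_min = 0.7
    t_max = 1.2
    t_points = 101

    [refold]                       # refolding batch (enables classify/fitk)
    temp_factor = 0.9              # T = factor · T_f
    unfold_factor = 1.25           # c in T_unfold = c · T_f
    n_traj = 5
    steps = 120
    seed = 11

    [classify]
    window = 25

    [kinetics]
    block_window = 10
    n_unfolded = 50
"""

from __future__ import annotations

import json
import sys
import time
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from . import dynamics, fixtures, forcefield, kinetics, landscape
from . import structure_io, wham
from .entanglement import native_contact_entanglements

__all__ = ["run_pipeline", "RunConfig"]


class RunConfig(dict):
    """Validated pipeline configuration (a thin dict wrapper)."""

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            cfg = cls(tomllib.load(fh))
        cfg.validate()
        return cfg

    def validate(self):
        if "structure" not in self:
            raise ValueError("config needs a [structure] section")
        st = self["structure"]
        if "pdb" in st:
            if not Path(st["pdb"]).exists():
                raise ValueError(f"PDB path does not exist: {st['pdb']}")
        elif "fixture_motif" not in st:
            raise ValueError("[structure] needs 'pdb' or 'fixture_motif'")
        for stage in ("simulate", "refold"):
            if stage in self and "seed" not in self[stage]:
                raise ValueError(f"[{stage}] needs an explicit seed")
        if "refold" in self and "simulate" not in self and "wham" in self:
            raise ValueError("wham requires a [simulate] ladder")


def _log(run_dir: Path, events: list, stage: str, message: str):
    events.append({"t": time.time(), "stage": stage, "msg": message})
    (run_dir / "events.jsonl").write_text(
        "\n".join(json.dumps(e) for e in events) + "\n")
    print(f"[{stage}] {message}", file=sys.stderr)


def _sidecar(run_dir: Path, name: str, payload: dict):
    payload = dict(payload)
    payload["lassofold_version"] = __version__
    (run_dir / f"{name}.meta.json").write_text(json.dumps(payload, indent=1))


def run_pipeline(config_path, dry_run: bool = False) -> Path | None:
    """Execute the configured stages; returns the run directory."""
    cfg = RunConfig.load(config_path)
    stages = [s for s in ("structure", "simulate", "wham", "refold",
                          "landscape", "classify", "kinetics") if s in cfg]
    if dry_run:
        print("execution plan: " + " -> ".join(stages), file=sys.stderr)
        return None
    run_dir = Path(cfg.get("run", {}).get("out_dir", "lassofold_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    events: list = []

    # --- structure ---------------------------------------------------------
    st = cfg["structure"]
    flavour = st.get("flavour", "12-6")
    params = forcefield.GoParameters(lj_flavour=flavour)
    if "pdb" in st:
        topo = structure_io.topology_from_pdb(st["pdb"],
                                              chain=st.get("chain"))
    else:
        topo, _ = fixtures.make_toy_native(int(st.get("n_residues", 30)),
                                           st["fixture_motif"])
    structure_io.write_topology_json(topo, run_dir / "topology.json")
    _sidecar(run_dir, "topology", {"source": st, "flavour": flavour,
                                   "n_residues": topo.n_residues,
                                   "n_contacts": topo.n_contacts})
    _log(run_dir, events, "structure",
         f"{topo.n_residues} residues, {topo.n_contacts} contacts")

    t_f = None
    ladder_series = None

    # --- simulate (equilibrium ladder) -------------------------------------
    if "simulate" in cfg:
        sim = cfg["simulate"]
        temps = [float(t) for t in sim["temperatures"]]
        try:
            ladder_series = dynamics.run_equilibrium_ladder(
                topo, params, temps, int(sim["steps"]), seed=int(sim["seed"]))
        except RuntimeError as err:
            _log(run_dir, events, "simulate", f"FAILED: {err}")
            raise RuntimeError(f"stage 'simulate' failed: {err}") from err
        for k, series in enumerate(ladder_series):
            structure_io.write_observables_tsv(
                series, run_dir / f"equilibrium_T{temps[k]:.4f}.tsv")
        _sidecar(run_dir, "simulate", {"temperatures": temps,
                                       "steps": int(sim["steps"]),
                                       "seed": int(sim["seed"])})
        _log(run_dir, events, "simulate", f"{len(temps)}-run ladder done")

    # --- wham ---------------------------------------------------------------
    if "wham" in cfg and ladder_series is not None:
        wc = cfg["wham"]
        temps = [float(t) for t in cfg["simulate"]["temperatures"]]
        inp = wham.build_wham_input(ladder_series, temps, topo.n_contacts,
                                    n_residues=topo.n_residues)
        sol = wham.solve_wham(inp)
        grid = np.linspace(float(wc.get("t_min", min(temps) * 0.9)),
                           float(wc.get("t_max", max(temps) * 1.1)),
                           int(wc.get("t_points", 101)))
        curves = wham.thermo_curves(sol, grid)
        t_f = curves.t_f
        q, f_tf = wham.free_energy_profile(sol, t_f)
        try:
            d_f = wham.barrier_height(f_tf)
        except ValueError:
            d_f = None
        doc = {"T_f": t_f, "barrier_dF": d_f, "iterations": sol.iterations,
               "profile_Q": q.tolist(), "profile_F": f_tf.tolist(),
               "cv_T": grid.tolist(), "cv": curves.cv.tolist()}
        (run_dir / "wham.json").write_text(json.dumps(doc, indent=1))
        _sidecar(run_dir, "wham", {"t_grid": [grid[0], grid[-1], len(grid)]})
        _log(run_dir, events, "wham",
             f"T_f = {t_f:.4f}" + ("" if d_f is None else f", dF = {d_f:.3f}"))

    # --- refold -------------------------------------------------------------
    refold_series = None
    if "refold" in cfg:
        rf = cfg["refold"]
        t_f_use = float(rf.get("t_f", t_f if t_f is not None else 0.0))
        if t_f_use <= 0:
            raise ValueError("refold needs t_f (explicit or from wham)")
        seed = int(rf["seed"])
        n_traj = int(rf.get("n_traj", 10))
        initials = dynamics.sample_unfolded(
            topo, params, t_f_use, float(rf.get("unfold_factor", 1.25)),
            n_traj, decorrelation_interval=int(rf.get("decorrelation", 20)),
            seed=seed, burn_in=int(rf.get("burn_in", 100)))
        seeds = [seed + 31 * (k + 1) for k in range(n_traj)]
        refold_series, finals, meta = dynamics.run_refolding_batch(
            topo, params, float(rf.get("temp_factor", 0.9)) * t_f_use,
            initials, int(rf["steps"]), seeds)
        for k, series in enumerate(refold_series):
            structure_io.write_observables_tsv(series,
                                               run_dir / f"refold{k:03d}.tsv")
        _sidecar(run_dir, "refold", meta)
        _log(run_dir, events, "refold", f"{n_traj} trajectories done")

    # --- landscape ----------------------------------------------------------
    if "landscape" in cfg and refold_series is not None:
        pts = np.vstack([np.column_stack([s.q, s.gprime])
                         for s in refold_series])
        try:
            grid = landscape.kde_landscape(pts)
            np.savetxt(run_dir / "landscape.tsv",
                       grid.neg_log_density, delimiter="\t")
            _sidecar(run_dir, "landscape",
                     {"bandwidths": list(grid.bandwidths),
                      "n_samples": len(pts)})
            _log(run_dir, events, "landscape", "KDE grid written")
        except ValueError as err:
            _log(run_dir, events, "landscape", f"skipped: {err}")

    # --- classify -----------------------------------------------------------
    if "classify" in cfg and refold_series is not None:
        window = int(cfg["classify"].get("window", 555))
        with open(run_dir / "pathways.tsv", "w") as fh:
            fh.write("trajectory\tlabel\tfolding_time\tvisited\n")
            for k, series in enumerate(refold_series):
                rec = landscape.classify_pathway(series, window=window)
                fh.write(f"{k}\t{rec.label}\t{rec.folding_time}\t"
                         f"{'>'.join(rec.visited)}\n")
        _sidecar(run_dir, "classify", {"window": window})
        _log(run_dir, events, "classify", "pathway table written")

    # --- kinetics -----------------------------------------------------------
    if "kinetics" in cfg and refold_series is not None:
        kin = cfg["kinetics"]
        t_f_use = float(cfg.get("refold", {}).get("t_f",
                                                  t_f if t_f else 0.0))
        unfolded = None
        if t_f_use > 0 and int(kin.get("n_unfolded", 0)) > 0:
            unfolded = dynamics.sample_unfolded(
                topo, params, t_f_use,
                float(cfg.get("refold", {}).get("unfold_factor", 1.25)),
                int(kin["n_unfolded"]), decorrelation_interval=10,
                seed=int(kin.get("seed", 1234)),
                burn_in=int(kin.get("burn_in", 100)))
        native_g = [abs(r.g_prime)
                    for r in native_contact_entanglements(topo).records]
        table = kinetics.contact_kinetics_table(
            refold_series, topo, unfolded_samples=unfolded,
            block_window=int(kin.get("block_window", 100)),
            native_gprime=native_g)
        table.to_csv(run_dir / "contact_kinetics.tsv", sep="\t", index=False)
        _sidecar(run_dir, "kinetics",
                 {"block_window": int(kin.get("block_window", 100))})
        _log(run_dir, events, "kinetics", "per-contact fit table written")

    return run_dir
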