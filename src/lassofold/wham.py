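"""Weighted-histogram analysis on the native-contact coordinate Q.

Histograms N_i(Q) from R equilibrium runs at inverse temperatures β_i are
combined into a dimensionless configurational entropy S(Q) and per-run free
energies f_i via the self-consistent pair

    S(Q) = ln[ Σ_i N_i(Q) ] - ln[ Σ_j n_j exp(-β_j ⟨E⟩_Q + f_j) ]
    exp(-f_k) = Σ_Q exp(-β_k ⟨E⟩_Q + S(Q))

iterated from S = 0, f = 0 until the mean absolute change of both falls
below 10⁻¹⁴.  ⟨E⟩_Q is the run-average of per-run bin-mean energies; Q bins
are the integer formed-contact counts, which bin naturally.  From the
solution: F(Q;T) = ⟨E⟩_Q - T·S(Q), the specific heat
Cv(T) = (⟨E²⟩_T - ⟨E⟩_T²)/(T²N) using bin-mean energies, and the folding
temperature T_f at the Cv peak.  All sums are evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["WhamInput", "WhamSolution", "ThermoCurves", "build_wham_input",
           "solve_wham", "thermo_curves", "free_energy_profile",
           "barrier_height"]


@dataclass
class WhamInput:
    """Shared-bin histograms and bin energies from R equilibrium runs."""

    beta: np.ndarray            # (R,) inverse temperatures
    hist: np.ndarray            # (R, n_bins) counts N_i(Q)
    n_counts: np.ndarray        # (R,) total retained frames per run
    mean_energy: np.ndarray     # (n_bins,) ⟨E⟩_Q; NaN where never sampled
    q_values: np.ndarray        # (n_bins,) Q of each bin (count / n_contacts)
    n_residues: int = 0

    @property
    def occupied(self) -> np.ndarray:
        return self.hist.sum(axis=0) > 0


@dataclass
class WhamSolution:
    """Converged entropy S(Q) (anchored to max 0) and run free energies."""

    entropy: np.ndarray         # (n_bins,), NaN on empty bins
    f_runs: np.ndarray          # (R,)
    mean_energy: np.ndarray     # (n_bins,)
    q_values: np.ndarray
    iterations: int = 0
    residual: float = 0.0
    n_residues: int = 0


@dataclass
class ThermoCurves:
    """Reweighted thermodynamics on a temperature grid."""

    t_grid: np.ndarray
    mean_energy_t: np.ndarray
    cv: np.ndarray              # per-residue specific heat
    t_f: float                  # Cv-peak temperature (quadratic-refined)


def build_wham_input(series_list, temperatures, n_contacts: int,
                     burn_in_fraction: float = 0.10,
                     n_residues: int = 0) -> WhamInput:
    """Histogram observable series into shared integer-count Q bins.

    The first ``burn_in_fraction`` of every series is discarded; each frame's
    bin is its formed-contact count (``round(Q · n_contacts)``); ⟨E⟩_Q is the
    across-run average of the per-run bin-mean energies.
    """
    if len(series_list) == 0:
        raise ValueError("need at least one run")
    if n_contacts < 1:
        raise ValueError("empty bin set: topology has no contacts")
    n_bins = n_contacts + 1
    r = len(series_list)
    hist = np.zeros((r, n_bins))
    e_sum = np.zeros((r, n_bins))
    for i, series in enumerate(series_list):
        drop = int(len(series.q) * burn_in_fraction)
        q = np.asarray(series.q)[drop:]
        e = np.asarray(series.energy)[drop:]
        counts = np.rint(q * n_contacts).astype(int)
        np.add.at(hist[i], counts, 1.0)
        np.add.at(e_sum[i], counts, e)
    with np.errstate(invalid="ignore", divide="ignore"):
        run_means = e_sum / hist          # NaN where a run never saw a bin
    seen = hist > 0
    mean_e = np.full(n_bins, np.nan)
    any_seen = seen.any(axis=0)
    sums = np.where(seen, run_means, 0.0).sum(axis=0)
    mean_e[any_seen] = sums[any_seen] / seen.sum(axis=0)[any_seen]
    beta = 1.0 / np.asarray(list(temperatures), float)
    if len(beta) != r:
        raise ValueError("need one temperature per run")
    return WhamInput(beta=beta, hist=hist,
                     n_counts=hist.sum(axis=1),
                     mean_energy=mean_e,
                     q_values=np.arange(n_bins) / n_contacts,
                     n_residues=n_residues)


def solve_wham(inp: WhamInput, tol: float = 1e-14,
               max_iter: int = 200_000) -> WhamSolution:
    """Iterate the self-consistent entropy/free-energy equations to `tol`."""
    occ = inp.occupied
    if not np.all(inp.hist.sum(axis=1) > 0):
        raise ValueError("every run must contribute a non-empty histogram")
    beta = inp.beta[:, None]                       # (R, 1)
    e_q = inp.mean_energy[None, occ]               # (1, B)
    log_n_tot = np.log(inp.hist[:, occ].sum(axis=0))  # (B,)
    log_n_runs = np.log(inp.n_counts)[:, None]     # (R, 1)

    s = np.zeros(occ.sum())
    f = np.zeros(len(inp.beta))
    it = 0
    resid = np.inf
    for it in range(1, max_iter + 1):
        denom = logsumexp(log_n_runs - beta * e_q + f[:, None], axis=0)
        s_new = log_n_tot - denom
        f_new = -logsumexp(-beta * e_q + s_new[None, :], axis=1)
        resid = max(np.abs(s_new - s).mean(), np.abs(f_new - f).mean())
        s, f = s_new, f_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(final residual {resid:.3e})")

    entropy = np.full(len(occ), np.nan)
    shift = s.max()
    entropy[occ] = s - shift
    return WhamSolution(entropy=entropy, f_runs=f - shift,
                        mean_energy=inp.mean_energy, q_values=inp.q_values,
                        iterations=it, residual=float(resid),
                        n_residues=inp.n_residues)


def free_energy_profile(solution: WhamSolution, temperature: float,
                        shift_min: bool = True,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """F(Q;T) = ⟨E⟩_Q - T·S(Q) on occupied bins; returns (q_values, F)."""
    mask = np.isfinite(solution.entropy)
    f = solution.mean_energy[mask] - temperature * solution.entropy[mask]
    if shift_min:
        f = f - f.min()
    return solution.q_values[mask], f


def thermo_curves(solution: WhamSolution, t_grid) -> ThermoCurves:
    """Reweighted ⟨E⟩_T and per-residue Cv(T); T_f at the refined Cv peak."""
    t_grid = np.asarray(t_grid, float)
    mask = np.isfinite(solution.entropy)
    s = solution.entropy[mask]
    e = solution.mean_energy[mask]
    n_res = max(solution.n_residues, 1)
    mean_e = np.empty_like(t_grid)
    mean_e2 = np.empty_like(t_grid)
    for k, temp in enumerate(t_grid):
        logw = s - e / temp
        logz = logsumexp(logw)
        w = np.exp(logw - logz)
        mean_e[k] = (w * e).sum()
        mean_e2[k] = (w * e * e).sum()
    cv = (mean_e2 - mean_e ** 2) / (t_grid ** 2 * n_res)
    k_max = int(np.argmax(cv))
    t_f = float(t_grid[k_max])
    if 0 < k_max < len(t_grid) - 1:
        # quadratic through the three points around the argmax
        x = t_grid[k_max - 1:k_max + 2]
        y = cv[k_max - 1:k_max + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2])
             + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
             + x[0] ** 2 * (y[1] - y[2])) / denom
        if a < 0:
            t_f = float(-b / (2 * a))
    return ThermoCurves(t_grid=t_grid, mean_energy_t=mean_e, cv=cv, t_f=t_f)


def _local_minima(f: np.ndarray) -> list[int]:
    mins = []
    n = len(f)
    for i in range(n):
        left = f[i - 1] if i > 0 else np.inf
        right = f[i + 1] if i < n - 1 else np.inf
        if f[i] <= left and f[i] <= right and (f[i] < left or f[i] < right):
            if mins and f[mins[-1]] == f[i] and i - mins[-1] == 1:
                continue  # plateau: keep the first index
            mins.append(i)
    return mins


def barrier_height(f_profile: np.ndarray, smooth_window: int = 3,
                   ) -> float:
    """ΔF between the lower-Q minimum and the barrier top separating the two
    lowest minima of F(Q).

    Profiles long enough are smoothed with a centred ``smooth_window``-bin
    moving average before locating extrema; short profiles are used raw.
    Raises ``ValueError`` when the profile is monotone (no barrier).
    """
    f = np.asarray(f_profile, float)
    if len(f) >= 2 * smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        f = np.convolve(f, kernel, mode="same")
        # shrunken windows at the ends
        half = smooth_window // 2
        for i in range(half):
            f[i] = f_profile[:i + half + 1].mean()
            f[-(i + 1)] = f_profile[-(i + half + 1):].mean()
    mins = _local_minima(f)
    if len(mins) < 2:
        raise ValueError("no barrier: free energy profile is monotone")
    order = sorted(mins, key=lambda i: f[i])
    m1, m2 = sorted(order[:2])
    top = f[m1:m2 + 1].max()
    if top <= max(f[m1], f[m2]):
        raise ValueError("no barrier between the two lowest minima")
    return float(top - f[m1])
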