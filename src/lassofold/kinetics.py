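"""Per-contact folding kinetics: formation curves and exponential fits.

For each native contact (i, j) a binary indicator σ_ij(t) marks whether the
contact is formed (r < 1.2·r0) at time t; averaging over refolding
trajectories gives the contact formation probability ⟨σ_ij⟩(t), which rises
from its unfolded-state value p_U towards a folded-state plateau.  After
block-averaging (default 100 MD steps) each curve is fit by nonlinear least
squares to A - B·exp(-k t): A estimates the folded-state formation
probability, A - B the unfolded one, and k is the contact folding rate.
p_U and its binomial standard error come from an independent ensemble of
unfolded conformations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["ContactKineticsRecord", "block_average",
           "contact_formation_curve", "fit_contact_kinetics",
           "unfolded_probability", "contact_kinetics_table"]


@dataclass
class ContactKineticsRecord:
    """Exponential-fit parameters (and p_U) for one native contact."""

    contact: tuple[int, int] | None
    a: float
    b: float
    k: float
    sd_a: float = np.nan
    sd_b: float = np.nan
    sd_k: float = np.nan
    p_u: float = np.nan
    p_u_sd: float = np.nan
    flag: str = "ok"            # or "no-kinetics"


def block_average(step, values, window: int,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping block means over windows of ``window`` MD steps.

    Blocks are timestamped at their centre; a trailing partial block is kept
    as its own mean.  ``window`` ≤ the frame spacing returns the series
    unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1 MD step")
    t = np.asarray(step, float)
    x = np.asarray(values, float)
    if len(t) < 2:
        return t, x
    spacing = t[1] - t[0]
    per_block = max(int(round(window / spacing)), 1)
    if per_block == 1:
        return t, x
    n_blocks = int(np.ceil(len(x) / per_block))
    bt = np.empty(n_blocks)
    bx = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(b * per_block, (b + 1) * per_block)
        bt[b] = t[sl].mean()
        bx[b] = x[sl].mean()
    return bt, bx


def _contact_column(contact, topology) -> int:
    if isinstance(contact, (int, np.integer)):
        return int(contact)
    pairs = [(i, j) for i, j, _ in topology.contacts]
    return pairs.index((int(contact[0]), int(contact[1])))


def contact_formation_curve(trajectories, contact, topology=None,
                            subset=None) -> tuple[np.ndarray, np.ndarray]:
    """⟨σ_ij⟩(t): per-time mean of the binary formation indicator.

    ``trajectories`` are ObservableSeries carrying the per-frame formation
    matrix; ``contact`` is either a column index or an (i, j) pair resolved
    through ``topology``.  ``subset`` restricts to selected trajectory
    indices (e.g. the fast-pathway ones).  Returns (times, curve).
    """
    if subset is not None:
        trajectories = [trajectories[i] for i in subset]
    if len(trajectories) == 0:
        raise ValueError("empty trajectory subset")
    col = _contact_column(contact, topology)
    stack = np.stack([np.asarray(s.formed[:, col], float)
                      for s in trajectories])
    return np.asarray(trajectories[0].step, float), stack.mean(axis=0)


def fit_contact_kinetics(times, curve, block_window: int = 100,
                         contact=None) -> ContactKineticsRecord:
    """Nonlinear least-squares fit of A - B·exp(-k t) to a formation curve.

    The curve is block-averaged first; initial guesses are A₀ = final block,
    B₀ = A₀ - first block, k₀ = 3/time-span, with bounds A, B ∈ [0, 1.2] and
    k > 0 to stabilise noisy low-probability contacts.  Degenerate (flat or
    decreasing) curves return a record flagged ``no-kinetics``.
    """
    bt, bx = block_average(times, curve, block_window)
    if len(bx) < 5:
        raise ValueError("need at least 5 blocks after averaging")
    a0 = float(bx[-1])
    b0 = a0 - float(bx[0])
    span = float(bt[-1] - bt[0])
    if b0 <= 0.0 or span <= 0.0:
        return ContactKineticsRecord(contact=contact, a=float(bx.mean()),
                                     b=0.0, k=np.nan, flag="no-kinetics")
    k0 = 3.0 / span

    def model(t, a, b, k):
        return a - b * np.exp(-k * t)

    try:
        popt, pcov = curve_fit(
            model, bt, bx, p0=[min(a0, 1.2), min(b0, 1.2), k0],
            bounds=([0.0, 0.0, 1e-12], [1.2, 1.2, np.inf]), maxfev=20000)
    except RuntimeError:
        return ContactKineticsRecord(contact=contact, a=float(bx.mean()),
                                     b=0.0, k=np.nan, flag="no-kinetics")
    sd = np.sqrt(np.diag(pcov))
    return ContactKineticsRecord(contact=contact, a=float(popt[0]),
                                 b=float(popt[1]), k=float(popt[2]),
                                 sd_a=float(sd[0]), sd_b=float(sd[1]),
                                 sd_k=float(sd[2]))


def unfolded_probability(unfolded_samples, contact, topology,
                         g: float = 1.2) -> tuple[float, float]:
    """Formation fraction of one contact over unfolded conformations.

    Returns (p_U, binomial standard error sqrt(p(1-p)/n)).
    """
    if len(unfolded_samples) < 2:
        raise ValueError("need at least 2 unfolded samples")
    col = _contact_column(contact, topology)
    i, j, r0 = topology.contacts[col]
    formed = 0
    for conf in unfolded_samples:
        coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf)
        formed += float(np.linalg.norm(coords[j] - coords[i])) < g * r0
    n = len(unfolded_samples)
    p = formed / n
    return p, float(np.sqrt(p * (1.0 - p) / n))


def contact_kinetics_table(trajectories, topology, unfolded_samples=None,
                           subset=None, block_window: int = 100,
                           native_gprime=None):
    """Fig-8-style per-contact table: p_U, fit parameters, native |G′|.

    Returns a pandas DataFrame with one row per native contact.
    """
    import pandas as pd
    rows = []
    for col, (i, j, _) in enumerate(topology.contacts):
        t, curve = contact_formation_curve(trajectories, col, subset=subset)
        rec = fit_contact_kinetics(t, curve, block_window=block_window,
                                   contact=(i, j))
        if unfolded_samples is not None:
            rec.p_u, rec.p_u_sd = unfolded_probability(
                unfolded_samples, col, topology)
        rows.append({
            "i": i, "j": j,
            "label_i": topology.residue_labels[i],
            "label_j": topology.residue_labels[j],
            "g_prime_native_abs": (abs(native_gprime[col])
                                   if native_gprime is not None else np.nan),
            "p_U": rec.p_u, "p_U_sd": rec.p_u_sd,
            "A": rec.a, "B": rec.b, "k": rec.k,
            "sd_A": rec.sd_a, "sd_B": rec.sd_b, "sd_k": rec.sd_k,
            "flag": rec.flag,
        })
    return pd.DataFrame(rows)
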