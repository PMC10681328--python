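"""(Q, ⟨G′⟩) landscapes, ensemble regions, pathway classification.

The two-dimensional refolding landscape is the negative log of a Gaussian
product-kernel density estimate over (Q, ⟨G′⟩) samples, with per-dimension
Scott bandwidths (sample σ · n^{-1/6}), shifted so its minimum is 0.  On that
plane the named ensembles are closed-form areas:

    U   : Q ∈ [0, 0.375],  ⟨G′⟩ ∈ [-0.25, 0.25]
    F   : Q ∈ [0.75, 1],   ⟨G′⟩ ∈ [-1, -0.5]
    IT  : Q ∈ [0.5, 0.75], -0.2·Q < ⟨G′⟩ < -0.2·Q + 0.2   (rhomboid)
    IE- : Q ∈ [0.32, 0.46], -1.07·Q - 0.26 < ⟨G′⟩ < -1.07·Q - 0.11
    TSE : Q ∈ [Q_TSE - δQ, Q_TSE + δQ], Q_TSE = 0.5, δQ = 0.03

Refolding trajectories are classified from a centred 555-MD-step rolling
average of both coordinates: trajectories that reach F without ever visiting
the trap intermediate IT fold "fast"; those that visit IT refold either by
"threading" (last non-F state IT) or by "backtracking" through U; those that
end in IT without reaching F are "trapped".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LandscapeGrid", "RegionSet", "PathwayRecord",
           "ContactProbabilityMap", "kde_landscape", "region_membership",
           "classify_pathway", "folding_time", "ensemble_contact_map",
           "select_special_contacts", "DEFAULT_REGIONS"]


@dataclass
class LandscapeGrid:
    """Negative-log KDE of the (Q, ⟨G′⟩) sample cloud (min shifted to 0)."""

    q_grid: np.ndarray
    g_grid: np.ndarray
    neg_log_density: np.ndarray      # (len(q_grid), len(g_grid))
    bandwidths: tuple[float, float]
    contour_step: float = 0.4


@dataclass(frozen=True)
class RegionSet:
    """Closed-form ensemble definitions on the (Q, ⟨G′⟩) plane."""

    q_tse: float = 0.5
    delta_q_tse: float = 0.03
    u_q: tuple[float, float] = (0.0, 0.375)
    u_g: tuple[float, float] = (-0.25, 0.25)
    f_q: tuple[float, float] = (0.75, 1.0)
    f_g: tuple[float, float] = (-1.0, -0.5)
    it_q: tuple[float, float] = (0.5, 0.75)
    ie_q: tuple[float, float] = (0.32, 0.46)

    def in_tse(self, q: float) -> bool:
        return self.q_tse - self.delta_q_tse <= q <= self.q_tse + self.delta_q_tse

    def membership(self, q: float, g: float) -> str | None:
        # interval bounds are closed, rhomboid inequalities strict
        if self.u_q[0] <= q <= self.u_q[1] and self.u_g[0] <= g <= self.u_g[1]:
            return "U"
        if self.f_q[0] <= q <= self.f_q[1] and self.f_g[0] <= g <= self.f_g[1]:
            return "F"
        if (self.it_q[0] <= q <= self.it_q[1]
                and -0.2 * q < g < -0.2 * q + 0.2):
            return "IT"
        if (self.ie_q[0] <= q <= self.ie_q[1]
                and -1.07 * q - 0.26 < g < -1.07 * q - 0.11):
            return "IE-"
        return None


DEFAULT_REGIONS = RegionSet()


@dataclass
class PathwayRecord:
    """Pathway label, folding time and visited-region sequence of one run."""

    label: str                       # fast_folding / threading / backtracking
    folding_time: float | None       # MD steps; None if never folded
    visited: list[str] = field(default_factory=list)
    window: int = 555


@dataclass
class ContactProbabilityMap:
    """Per-native-contact formation probability within an ensemble."""

    contacts: list[tuple[int, int]]
    probabilities: np.ndarray

    def z_scores(self) -> np.ndarray:
        """(p_i - ⟨p⟩)/σ_p with the population standard deviation."""
        p = self.probabilities
        sd = p.std()
        if sd == 0:
            raise ValueError("zero variance of contact probabilities: "
                             "z-scores undefined")
        return (p - p.mean()) / sd


def kde_landscape(samples, q_grid=None, g_grid=None,
                  contour_step: float = 0.4) -> LandscapeGrid:
    """Gaussian product-kernel negative-log density of (Q, ⟨G′⟩) samples.

    Bandwidth per dimension is Scott's rule for d = 2: sample standard
    deviation times n^{-1/6}.
    """
    pts = np.asarray(samples, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("samples must be (n, 2)")
    n = len(pts)
    if n < 100:
        raise ValueError("need at least 100 samples for a stable KDE")
    sd = pts.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero variance in one KDE dimension")
    h = sd * n ** (-1.0 / 6.0)
    if q_grid is None:
        q_grid = np.linspace(pts[:, 0].min() - 2 * h[0],
                             pts[:, 0].max() + 2 * h[0], 120)
    if g_grid is None:
        g_grid = np.linspace(pts[:, 1].min() - 2 * h[1],
                             pts[:, 1].max() + 2 * h[1], 120)
    qg = np.asarray(q_grid, float)
    gg = np.asarray(g_grid, float)
    # separable kernel: density(x, y) = mean_i K(x - qi) K(y - gi)
    kq = np.exp(-0.5 * ((qg[:, None] - pts[None, :, 0]) / h[0]) ** 2)
    kg = np.exp(-0.5 * ((gg[:, None] - pts[None, :, 1]) / h[1]) ** 2)
    dens = (kq @ kg.T) / (n * 2.0 * np.pi * h[0] * h[1])
    with np.errstate(divide="ignore"):
        neg_log = -np.log(dens)
    neg_log -= neg_log.min()
    return LandscapeGrid(q_grid=qg, g_grid=gg, neg_log_density=neg_log,
                         bandwidths=(float(h[0]), float(h[1])),
                         contour_step=contour_step)


def region_membership(point, regions: RegionSet = DEFAULT_REGIONS,
                      ) -> str | None:
    """Label of the (Q, ⟨G′⟩) point, or None outside every region."""
    q, g = point
    return regions.membership(float(q), float(g))


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling mean; windows shrink near the endpoints."""
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    half = window // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def classify_pathway(series, regions: RegionSet = DEFAULT_REGIONS,
                     window: int = 555) -> PathwayRecord:
    """Classify one refolding trajectory from its (Q, ⟨G′⟩) series.

    Applies a centred rolling mean of ``window`` MD steps to both
    coordinates, maps each frame to a region label (unlabelled frames
    dropped), merges consecutive duplicates, then applies the pathway rules.
    The folding time is attached via :func:`folding_time` in RD1 mode (the
    two-coordinate criterion) unless the series never folds.
    """
    if len(series.q) < window:
        raise ValueError("series shorter than the rolling window")
    q = _rolling_mean(np.asarray(series.q, float), window)
    g = _rolling_mean(np.asarray(series.gprime, float), window)
    labels = []
    for qi, gi in zip(q, g):
        lab = regions.membership(qi, gi)
        if lab is not None and (not labels or labels[-1] != lab):
            labels.append(lab)
    t_fold = folding_time(series, mode="rd1")
    if not labels:
        return PathwayRecord(label="unclassified", folding_time=t_fold,
                             visited=labels, window=window)
    if "F" in labels:
        before_f = labels[:labels.index("F")]
        if "IT" not in before_f:
            label = "fast_folding"
        else:
            # last passage decides: threading straight out of IT, or
            # backtracking through U first
            last_it = max(i for i, s in enumerate(before_f) if s == "IT")
            last_u = max((i for i, s in enumerate(before_f) if s == "U"),
                         default=-1)
            label = "backtracking" if last_u > last_it else "threading"
    else:
        label = "trapped" if labels[-1] == "IT" else "unclassified"
        t_fold = None
    return PathwayRecord(label=label, folding_time=t_fold, visited=labels,
                         window=window)


def folding_time(series, mode: str = "rd1",
                 block_window: int = 250) -> float | None:
    """First block-averaged time at which the folding criterion holds.

    ``rd1`` mode requires Q ≥ 0.75 and ⟨G′⟩ ≤ -0.5 simultaneously; ``sh3``
    mode requires Q ≥ 0.7 only.  Both coordinates are block-averaged over
    ``block_window`` MD steps first.  Returns None when never satisfied.
    """
    from .kinetics import block_average
    t_q, q = block_average(series.step, series.q, block_window)
    _, g = block_average(series.step, series.gprime, block_window)
    if mode == "rd1":
        hit = (q >= 0.75) & (g <= -0.5)
    elif mode == "sh3":
        hit = q >= 0.7
    else:
        raise ValueError(f"unknown folding-time mode {mode!r}")
    idx = np.flatnonzero(hit)
    return float(t_q[idx[0]]) if len(idx) else None


def ensemble_contact_map(conformations, topology,
                         g: float = 1.2) -> ContactProbabilityMap:
    """Per-contact formation probability over an ensemble of conformations."""
    if len(conformations) == 0:
        raise ValueError("empty ensemble")
    contacts = [(i, j) for i, j, _ in topology.contacts]
    r0 = np.array([r for _, _, r in topology.contacts])
    ii = np.array([i for i, _, _ in topology.contacts])
    jj = np.array([j for _, j, _ in topology.contacts])
    counts = np.zeros(len(contacts))
    for conf in conformations:
        coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf)
        d = np.linalg.norm(coords[jj] - coords[ii], axis=1)
        counts += d < g * r0
    return ContactProbabilityMap(contacts=contacts,
                                 probabilities=counts / len(conformations))


def select_special_contacts(map_ie: ContactProbabilityMap,
                            map_it: ContactProbabilityMap,
                            entangled_set,
                            ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Z-score contact selections distinguishing the two intermediates.

    trap-avoiding: z^{IE-} > 1 and z^{IT} < 1 (likely formed in the
    entangled near-unfolded intermediate but not in the trap);
    first-entangling: z^{IE-} > 0 among the natively entangled contacts.
    """
    if map_ie.contacts != map_it.contacts:
        raise ValueError("contact maps must cover the same contact list")
    z_ie = map_ie.z_scores()
    z_it = map_it.z_scores()
    entangled = set(tuple(c) for c in entangled_set)
    trap_avoiding = [c for c, zi, zt in zip(map_ie.contacts, z_ie, z_it)
                     if zi > 1.0 and zt < 1.0]
    first_entangling = [c for c, zi in zip(map_ie.contacts, z_ie)
                        if zi > 0.0 and c in entangled]
    return trap_avoiding, first_entangling
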