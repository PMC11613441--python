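"""Observables and state-point classification.

Covers the radial distribution function, internal-energy / heat-capacity
temperature scans, homogeneous-vs-coexistence phase labeling from
local-density bimodality and the RDF second peak, and morphology labeling
of the minority phase (droplet / cylinder / slab / bubble) by periodic
connected-component analysis of the time-averaged density grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .units import KB, UnitSystem

#: prominence (above the inter-peak minimum) required of a second RDF peak
RDF_SECOND_PEAK_PROMINENCE = 0.05
#: edge of the local-density histogram cells, in reduced length units
#: (large enough that liquid cells hold ~20 particles, lifting the two
#: occupancy modes clear of Poisson noise at desk-scale N)
DENSITY_CELL_EDGE_REDUCED = 3.0
#: edge of the coarse grid used for morphology labeling
MORPHOLOGY_CELL_EDGE_REDUCED = 2.0
#: fraction of frames that must individually look bimodal for coexistence
BIMODALITY_FRAME_FRACTION = 0.6
#: valley-to-smaller-peak ratio separating clear from blurred coexistence
CLEAR_VALLEY_RATIO = 0.5
#: maximum valley ratio for a histogram to count as bimodal at all (the
#: valley must dip at least 25% below the smaller mode; guards against
#: shot-noise dips on homogeneous systems)
BIMODAL_VALLEY_RATIO = 0.75


@dataclass
class PhaseLabel:
    """Phase category plus (for coexistence) the minority-phase shape."""

    category: str  # homogeneous-fluid | coexistence-clear | coexistence-blur
    morphology: str = "none"
    second_peak_score: float = 0.0
    bimodality_score: float = 0.0

    def __post_init__(self) -> None:
        if (self.morphology == "none") != (self.category == "homogeneous-fluid"):
            if self.category != "homogeneous-fluid" and self.morphology == "none":
                raise ValueError("coexistence labels need a morphology")
            raise ValueError("homogeneous fluid cannot carry a morphology")


# ---------------------------------------------------------------------------
# radial distribution function


def rdf(frames, box, r_max: float, n_bins: int = 100) -> pd.DataFrame:
    """g(r) averaged over frames, ideal-gas-shell normalized.

    ``frames``: iterable of (N, 3) position arrays in a fixed periodic box.
    """
    box = np.asarray(box, dtype=float)
    if r_max > 0.5 * box.min():
        raise ValueError("r_max exceeds half the smallest box edge")
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    n = len(frames[0])
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    for pos in frames:
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.rint(d / box)
        r = np.sqrt((d * d).sum(axis=-1))
        iu = np.triu_indices(n, k=1)
        h, _ = np.histogram(r[iu], bins=edges)
        counts += h
    # normalize by the ideal-gas expectation: N(N-1)/2 pairs uniformly
    # distributed give (shell volume / box volume) per shell
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (len(frames) * (n * (n - 1) / 2.0) * shell / np.prod(box))
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r": r_mid, "g": g, "count": counts})


def second_peak_score(g_table: pd.DataFrame) -> float:
    """Prominence of a second RDF peak beyond the first minimum.

    Measured on a 5-point moving-average smoothed curve; 0.0 when no
    second peak exists.
    """
    g = g_table["g"].to_numpy()
    kernel = np.ones(5) / 5.0
    gs = np.convolve(g, kernel, mode="same")
    # skip the leading shot-noise-dominated bins (few pairs per shell)
    start = 0
    if "count" in g_table.columns:
        sampled = np.flatnonzero(g_table["count"].to_numpy() >= 30)
        if len(sampled) == 0:
            return 0.0
        start = int(sampled[0])
    gs = gs[start:]
    # the first coordination peak is the global maximum of g(r)
    first = int(np.argmax(gs))
    peaks, _ = signal.find_peaks(gs[first:])
    if len(peaks) == 0:
        return 0.0
    best = 0.0
    for p in first + peaks:
        valley = gs[first:p + 1].min()
        best = max(best, gs[p] - valley)
    return float(best)


# ---------------------------------------------------------------------------
# energy / heat-capacity scans


def heat_capacity_scan(series: pd.DataFrame) -> pd.DataFrame:
    """c_V*(T*) from finite differences of u*(T*), per density.

    ``series`` needs columns rho_star, T_star, u_star (and optionally
    u_var_total, n_particles for the fluctuation estimate).  Central
    differences at interior temperatures, one-sided at the endpoints.
    """
    req = {"rho_star", "T_star", "u_star"}
    if not req.issubset(series.columns):
        raise ValueError(f"series must have columns {sorted(req)}")
    out = []
    for rho, grp in series.groupby("rho_star"):
        grp = grp.sort_values("T_star")
        t = grp["T_star"].to_numpy()
        u = grp["u_star"].to_numpy()
        if len(t) < 3:
            raise ValueError("need at least 3 temperatures per density")
        if np.any(np.diff(t) <= 0):
            raise ValueError("duplicate temperatures in scan")
        cv = np.gradient(u, t)  # central interior, one-sided ends
        rec = pd.DataFrame({"rho_star": rho, "T_star": t, "u_star": u,
                            "c_v_star": cv})
        if "u_var_total" in grp.columns and "n_particles" in grp.columns:
            # fluctuation route: Var(U_total) / (N kB^2 T^2), reduced
            rec["c_v_star_fluct"] = (
                grp["u_var_total"].to_numpy()
                / (grp["n_particles"].to_numpy() * t ** 2)
            )
        out.append(rec)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# phase classification


def _cell_counts(pos: np.ndarray, box: np.ndarray, n_cells: np.ndarray):
    idx = np.floor(pos / box * n_cells).astype(np.int64)
    idx = np.clip(idx, 0, n_cells - 1)
    flat = (idx[:, 0] * n_cells[1] + idx[:, 1]) * n_cells[2] + idx[:, 2]
    return np.bincount(flat, minlength=int(np.prod(n_cells)))


def _bimodality(counts: np.ndarray):
    """(is_bimodal, valley_ratio, threshold) from a cell-occupancy sample.

    Histogram the per-cell particle counts, lightly smooth, and look for
    two modes separated by a persistent minimum.  valley_ratio is
    valley_height / smaller_mode_height (lower = cleaner separation).
    """
    top = int(counts.max())
    if top < 2:
        return False, np.inf, 0.0
    hist = np.bincount(counts, minlength=top + 1).astype(float)
    kernel = np.array([0.25, 0.5, 0.25])
    hs = np.convolve(hist, kernel, mode="same")
    # zero-pad so modes at the histogram edges (empty cells, top bin) count
    peaks, _ = signal.find_peaks(np.concatenate([[0.0], hs, [0.0]]))
    peaks = peaks - 1
    if len(peaks) < 2:
        return False, np.inf, 0.0
    order = np.argsort(hs[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    if p2 - p1 < 2:
        return False, np.inf, 0.0
    valley_pos = p1 + int(np.argmin(hs[p1:p2 + 1]))
    valley = hs[valley_pos]
    smaller = min(hs[p1], hs[p2])
    if smaller <= 0:
        return False, np.inf, 0.0
    ratio = valley / smaller
    return bool(ratio <= BIMODAL_VALLEY_RATIO), float(ratio), float(valley_pos)


def classify_phase(frames, box, units: UnitSystem = UnitSystem(),
                   cell_edge_reduced: float = DENSITY_CELL_EDGE_REDUCED,
                   g_table: pd.DataFrame | None = None) -> PhaseLabel:
    """Label production frames homogeneous vs (clear/blurred) coexistence.

    Coexistence requires either a bimodal local-density histogram in at
    least :data:`BIMODALITY_FRAME_FRACTION` of the frames, or an RDF second
    peak with prominence >= :data:`RDF_SECOND_PEAK_PROMINENCE`.  The
    clear/blur sub-label comes from the pooled histogram's valley depth.
    """
    frames = list(frames)
    if len(frames) < 5:
        raise ValueError("need at least 5 production frames")
    box = np.asarray(box, dtype=float)
    edge = cell_edge_reduced * units.sigma_ref
    n_cells = np.maximum(2, np.round(box / edge).astype(int))
    per_frame = [_cell_counts(np.mod(p, box), box, n_cells) for p in frames]
    votes = [_bimodality(c)[0] for c in per_frame]
    pooled = np.concatenate(per_frame)
    bimodal_pooled, ratio, _ = _bimodality(pooled)
    frac = float(np.mean(votes))
    bimodal = bimodal_pooled and frac >= BIMODALITY_FRAME_FRACTION

    if g_table is None:
        r_max = 0.45 * float(box.min())
        g_table = rdf(frames, box, r_max, n_bins=max(40, int(r_max / 0.03)))
    sp = second_peak_score(g_table)

    if not bimodal and sp < RDF_SECOND_PEAK_PROMINENCE:
        return PhaseLabel("homogeneous-fluid", "none", sp, frac)
    category = ("coexistence-clear"
                if (bimodal and ratio <= CLEAR_VALLEY_RATIO)
                else "coexistence-blur")
    m_edge = MORPHOLOGY_CELL_EDGE_REDUCED * units.sigma_ref
    m_cells = np.maximum(2, np.round(box / m_edge).astype(int))
    mean_grid = mean_density_grid(frames, box, m_cells)
    try:
        morph = classify_morphology(mean_grid)
    except ValueError:
        # weak two-mode structure on the mean grid: split at mid-range
        thr = 0.5 * (float(mean_grid.max()) + float(mean_grid.min()))
        morph = classify_morphology(mean_grid, threshold=thr)
    return PhaseLabel(category, morph, sp, frac)


# ---------------------------------------------------------------------------
# morphology


def mean_density_grid(frames, box, n_cells) -> np.ndarray:
    """Time-averaged coarse occupancy grid (particles per cell)."""
    box = np.asarray(box, dtype=float)
    n_cells = np.asarray(n_cells, dtype=int)
    acc = np.zeros(int(np.prod(n_cells)))
    for p in frames:
        acc += _cell_counts(np.mod(p, box), box, n_cells)
    return (acc / len(frames)).reshape(tuple(n_cells))


def _periodic_label(mask: np.ndarray):
    """Connected-component labels with periodic wrap (6-connectivity)."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return labels, 0
    # union-find merge across the three periodic faces
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, -1, axis=axis)
        both = (lo > 0) & (hi > 0)
        for x, y in zip(lo[both].ravel(), hi[both].ravel()):
            union(int(x), int(y))
    remap = np.array([find(x) for x in range(n + 1)])
    labels = remap[labels]
    ids = np.unique(labels[labels > 0])
    return labels, len(ids)


def _spanning_axes(component_mask: np.ndarray) -> int:
    """Number of periodic axes the component spans (occupies every layer)."""
    count = 0
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        if np.all(component_mask.any(axis=other)):
            count += 1
    return count


def classify_morphology(mean_grid: np.ndarray, threshold: float | None = None) -> str:
    """Shape of the minority phase on a time-averaged density grid.

    Threshold at the valley between the two occupancy modes (or an
    explicit ``threshold``), label the minority phase with periodic
    connectivity, and map the largest component's spanning count to
    sphere (0) / cylinder (1) / slab (>=2); a dense minority gives droplet
    variants, a dilute minority bubbles.
    """
    if threshold is None:
        flat = np.rint(mean_grid.ravel()).astype(int)
        ok, _, valley = _bimodality(np.maximum(flat, 0))
        if not ok:
            raise ValueError(
                "no two-mode density structure; run classify_phase first"
            )
        threshold = valley
    dense = mean_grid > threshold
    minority_dense = dense.sum() <= dense.size / 2
    minority = dense if minority_dense else ~dense
    labels, n = _periodic_label(minority)
    if n == 0:
        raise ValueError("empty minority phase after thresholding")
    ids, sizes = np.unique(labels[labels > 0], return_counts=True)
    main = ids[np.argmax(sizes)]
    span = _spanning_axes(labels == main)
    shape = {0: "sphere", 1: "cylinder"}.get(span, "slab")
    if shape == "slab":
        return "slab"
    return f"{shape}-droplet" if minority_dense else f"{shape}-bubble"


# ---------------------------------------------------------------------------
# state-point scans (driver-level convenience)


def observables_to_reduced(obs: pd.DataFrame, rho_star: float,
                           units: UnitSystem) -> dict:
    """Summarize a production observable series into one state-point row."""
    prod = obs[obs["production"]] if "production" in obs.columns else obs
    u = prod["u_total"].to_numpy() / units.epsilon_ref
    t = prod["T"].to_numpy() * KB / units.epsilon_ref
    n_eff = max(len(u), 1)
    return dict(
        rho_star=rho_star,
        T_star_mean=float(t.mean()),
        u_star=float(u.mean()),
        u_star_se=float(u.std(ddof=1) / np.sqrt(n_eff)) if n_eff > 1 else 0.0,
        frames=int(n_eff),
    )
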