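"""Phagocytosis quantification from two-channel time-lapses.

Microglia carry a red cytoplasmic reporter; nucleic-acid debris released by
dying cells is stained green (SYTOX).  Per frame the analysis thresholds
both channels (Huang's fuzzy-entropy method for the dim, heavy-tailed cell
channel; IsoData intermeans for the punctate particle channel), books every
green particle as inside or outside a cell (strict majority-overlap
containment), and computes:

* ``phago_index`` — ``100 x (SYTOX area inside microglia / total SYTOX
  area) / number of microglia`` in the field;
* ``phagocytosing_pct`` — percentage of microglia containing at least one
  *confirmed* particle;
* ``delta_sytox`` — change in total SYTOX area between two named frames
  (cell-death progression).

Engulfment confirmation follows the time-lapse criteria: a particle is
confirmed when it (a) moves together with its host cell and (b) shrinks
over the observation window.  The third criterion used by human observers —
visible phagosome pouches — is inherently visual; records carry a
``needs_review`` flag instead of a fake automation of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import as_label_mask

__all__ = [
    "max_project", "huang_threshold", "isodata_threshold", "auto_threshold",
    "assign_containment", "track_particles", "confirm_engulfment",
    "phago_index", "phagocytosing_pct", "delta_sytox", "PhagoReport",
    "analyse_timelapse",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def max_project(zstack) -> np.ndarray:
    """Per-pixel maximum over the z planes of a stack."""
    planes = [np.asarray(p, dtype=float) for p in zstack]
    if not planes:
        raise ValueError("empty z-stack")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("z planes differ in shape")
    return np.maximum.reduce(planes)


# ---------------------------------------------------------------------------
# automatic thresholds (256-bin histogram algorithms)

def _histogram(image: np.ndarray, n_bins: int = 256):
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise ValueError("constant image: no threshold exists")
    counts, edges = np.histogram(image.ravel(), bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def isodata_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """IsoData (Ridler–Calvard) intermeans threshold.

    Iterates ``t <- (mean below t + mean above t) / 2`` on a 256-bin
    histogram until the fixed point; returns the threshold in intensity
    units.  Foreground is intensity strictly above the threshold.  The
    iteration starts at the midpoint of the grey-level range: on images
    dominated by a background mode this converges to the between-modes fixed
    point rather than a spurious fixed point inside the background noise.
    """
    counts, centers = _histogram(image, n_bins)
    t = float((centers[0] + centers[-1]) / 2.0)
    for _ in range(500):
        below = centers <= t
        w0 = counts[below].sum()
        w1 = counts[~below].sum()
        if w0 == 0 or w1 == 0:
            break
        m0 = (counts[below] * centers[below]).sum() / w0
        m1 = (counts[~below] * centers[~below]).sum() / w1
        t_new = (m0 + m1) / 2.0
        if abs(t_new - t) < 1e-10:
            t = t_new
            break
        t = t_new
    return float(t)


def huang_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Huang's fuzzy-entropy threshold.

    For every candidate threshold the image is fuzzily partitioned around
    the below/above class means; membership of grey level ``g`` in its class
    is ``1 / (1 + |g - mu| / C)`` with ``C`` the grey-level range.  The
    threshold minimising the total Shannon entropy of the memberships is
    returned (in intensity units; foreground is strictly above it).
    """
    counts, centers = _histogram(image, n_bins)
    c_range = centers[-1] - centers[0]
    cum_w = np.cumsum(counts)
    cum_wx = np.cumsum(counts * centers)
    total_w, total_wx = cum_w[-1], cum_wx[-1]

    best_t, best_s = centers[0], np.inf
    for i in range(len(centers) - 1):
        w0 = cum_w[i]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cum_wx[i] / w0
        mu1 = (total_wx - cum_wx[i]) / w1
        mu = np.where(np.arange(len(centers)) <= i, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(centers - mu) / c_range)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -(u * np.log(u) + (1 - u) * np.log(1 - u))
        h = np.where((u <= 0) | (u >= 1), 0.0, h)
        s = float((counts * h).sum())
        if s < best_s:
            best_s, best_t = s, centers[i]
    return float(best_t)


def auto_threshold(image: np.ndarray, method: str = "huang") -> np.ndarray:
    """Binarize with a named histogram algorithm; foreground is above t."""
    image = np.asarray(image, dtype=float)
    if method == "huang":
        t = huang_threshold(image)
    elif method == "isodata":
        t = isodata_threshold(image)
    else:
        raise ValueError(f"unknown threshold method {method!r}; "
                         "expected 'huang' or 'isodata'")
    return image > t


# ---------------------------------------------------------------------------
# particle bookkeeping

def assign_containment(cell_mask: np.ndarray, particle_mask: np.ndarray,
                       pixel_size_um: float, frame_index: int = 0,
                       ) -> pd.DataFrame:
    """Book every particle as inside or outside a cell, one frame.

    ``particle_mask`` may be binary (particles are then its 8-connected
    components) or already labelled.  A particle's host is the cell covering
    strictly more than half of its area; exactly half or less means no host
    (``host_cell_id = 0``).
    """
    cell_mask = as_label_mask(cell_mask)
    particle_mask = np.asarray(particle_mask)
    if particle_mask.dtype == bool or particle_mask.max() <= 1:
        particle_mask, _ = ndi.label(particle_mask.astype(bool),
                                     structure=_STRUCT8)
    particle_mask = as_label_mask(particle_mask)
    if cell_mask.shape != particle_mask.shape:
        raise ValueError("cell and particle masks must share a shape")

    px2 = pixel_size_um ** 2
    rows = []
    for pid in np.unique(particle_mask):
        if pid == 0:
            continue
        sel = particle_mask == pid
        area_px = int(sel.sum())
        under = cell_mask[sel]
        host = 0
        inside_px = 0
        vals, cnts = np.unique(under[under > 0], return_counts=True)
        if len(vals):
            best = int(np.argmax(cnts))
            if cnts[best] > 0.5 * area_px:  # strict majority
                host = int(vals[best])
                inside_px = int(cnts[best])
        com = np.argwhere(sel).mean(axis=0)
        rows.append(dict(
            particle_id=int(pid), frame_index=int(frame_index),
            area_um2=area_px * px2,
            centroid_row=float(com[0]), centroid_col=float(com[1]),
            host_cell_id=host,
            inside_area_um2=(area_px * px2 if host else 0.0),
            needs_review=bool(host),  # phagosome-pouch check stays with a human
        ))
    return pd.DataFrame(rows, columns=[
        "particle_id", "frame_index", "area_um2", "centroid_row",
        "centroid_col", "host_cell_id", "inside_area_um2", "needs_review"])


def track_particles(frames: list[pd.DataFrame],
                    pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Link per-frame particle records into tracks by nearest centroid.

    Greedy frame-to-frame linking; a link is accepted when the centroid step
    (pixels) is at most one particle diameter (computed from the earlier
    frame's area via ``pixel_size_um``).  Returns the concatenated records
    with a ``track_id`` column.
    """
    if not frames:
        return pd.DataFrame()
    out = []
    prev = frames[0].copy()
    prev["track_id"] = np.arange(1, len(prev) + 1)
    next_track = len(prev) + 1
    out.append(prev)
    for t in range(1, len(frames)):
        cur = frames[t].copy()
        cur["track_id"] = 0
        links = []
        for i, row in cur.iterrows():
            d = np.hypot(prev["centroid_row"] - row.centroid_row,
                         prev["centroid_col"] - row.centroid_col).to_numpy()
            j = int(np.argmin(d))
            # gate: step at most one particle diameter (floor of 2 px for
            # single-pixel particles)
            diam_px = (2.0 * float(np.sqrt(prev["area_um2"].iloc[j] / np.pi))
                       / pixel_size_um)
            if d[j] <= max(diam_px, 2.0):
                links.append((float(d[j]), i, int(prev["track_id"].iloc[j])))
        links.sort()
        used = set()
        for dist, i, tid in links:
            if tid in used or cur.at[i, "track_id"] != 0:
                continue
            cur.at[i, "track_id"] = tid
            used.add(tid)
        for i in cur.index[cur["track_id"] == 0]:
            cur.at[i, "track_id"] = next_track
            next_track += 1
        out.append(cur)
        prev = cur
    return pd.concat(out, ignore_index=True)


def confirm_engulfment(tracked: pd.DataFrame,
                       cell_centroids: dict[int, dict[int, tuple[float, float]]],
                       min_shrink: float = 0.1,
                       co_move_tol_px: float = 3.0) -> pd.DataFrame:
    """Flag tracked particles whose behaviour confirms engulfment.

    A particle track is confirmed when, over at least three frames with a
    host cell: (a) its frame-to-frame displacement matches its host's within
    ``co_move_tol_px`` pixels per frame, and (b) its area shrinks by at
    least ``min_shrink`` (fraction) across the window.  Tracks with fewer
    than three hosted frames are left unconfirmed and flagged
    ``insufficient_data``.

    ``cell_centroids`` maps frame index -> {cell id: (row, col)}.
    """
    if not 0 <= min_shrink < 1:
        raise ValueError("min_shrink must lie in [0, 1)")
    results = []
    for tid, grp in tracked.groupby("track_id"):
        grp = grp.sort_values("frame_index")
        hosted = grp[grp["host_cell_id"] > 0]
        rec = dict(track_id=int(tid), confirmed=False,
                   insufficient_data=False, co_movement_ok=False,
                   shrinkage=np.nan,
                   host_cell_id=int(hosted["host_cell_id"].iloc[0])
                   if len(hosted) else 0)
        if len(hosted) < 3 or hosted["host_cell_id"].nunique() != 1:
            rec["insufficient_data"] = True
            results.append(rec)
            continue
        host = int(hosted["host_cell_id"].iloc[0])
        co_ok = True
        fr = hosted["frame_index"].to_numpy()
        pr = hosted["centroid_row"].to_numpy()
        pc = hosted["centroid_col"].to_numpy()
        for a in range(len(fr) - 1):
            f0, f1 = int(fr[a]), int(fr[a + 1])
            if f0 not in cell_centroids or f1 not in cell_centroids:
                co_ok = False
                break
            if host not in cell_centroids[f0] or host not in cell_centroids[f1]:
                co_ok = False
                break
            h0 = np.array(cell_centroids[f0][host])
            h1 = np.array(cell_centroids[f1][host])
            p_step = np.array([pr[a + 1] - pr[a], pc[a + 1] - pc[a]])
            mismatch = float(np.linalg.norm(p_step - (h1 - h0)))
            if mismatch > co_move_tol_px * (f1 - f0):
                co_ok = False
                break
        a0 = float(hosted["area_um2"].iloc[0])
        a1 = float(hosted["area_um2"].iloc[-1])
        shrink = (a0 - a1) / a0 if a0 > 0 else 0.0
        rec["co_movement_ok"] = co_ok
        rec["shrinkage"] = shrink
        rec["confirmed"] = bool(co_ok and shrink >= min_shrink)
        results.append(rec)
    return pd.DataFrame(results, columns=[
        "track_id", "host_cell_id", "confirmed", "co_movement_ok",
        "shrinkage", "insufficient_data"])


# ---------------------------------------------------------------------------
# summary statistics

def phago_index(sytox_area_inside: float, sytox_area_total: float,
                n_microglia: int) -> float:
    """``100 x (SYTOX area inside / total SYTOX area) / n microglia``."""
    if n_microglia < 1:
        raise ValueError("phago_index needs at least one microglia")
    if sytox_area_total <= 0:
        raise ValueError("total SYTOX area is zero: index undefined")
    if not 0 <= sytox_area_inside <= sytox_area_total:
        raise ValueError("inside area must lie in [0, total area]")
    return 100.0 * (sytox_area_inside / sytox_area_total) / n_microglia


def phagocytosing_pct(confirmed_per_cell: dict[int, bool] | pd.Series) -> float:
    """Percentage of microglia with at least one confirmed particle."""
    flags = pd.Series(confirmed_per_cell)
    if len(flags) == 0:
        raise ValueError("needs at least one microglia")
    return 100.0 * float(flags.astype(bool).mean())


def delta_sytox(area_t_late: float, area_t_early: float) -> float:
    """SYTOX area change between two frames (late - early, unclamped)."""
    return float(area_t_late) - float(area_t_early)


# ---------------------------------------------------------------------------
# per-frame report

@dataclass
class PhagoReport:
    frame_index: int
    sytox_area_inside: float
    sytox_area_total: float
    n_microglia: int
    phago_index: float
    n_phagocytosing: int
    phagocytosing_pct: float


def analyse_timelapse(cell_masks: list[np.ndarray],
                      particle_masks: list[np.ndarray],
                      pixel_size_um: float,
                      min_shrink: float = 0.1,
                      co_move_tol_px: float = 3.0,
                      ):
    """Full bookkeeping over a time-lapse of cell + particle masks.

    Returns ``(per_frame_particles, confirmations, reports)``: the tracked
    particle table, per-track confirmation flags, and one
    :class:`PhagoReport` per frame (confirmation counts refer to the whole
    lapse, areas to the frame).
    """
    if len(cell_masks) != len(particle_masks):
        raise ValueError("need one particle mask per cell mask")
    frames = [
        assign_containment(cm, pm, pixel_size_um, frame_index=t)
        for t, (cm, pm) in enumerate(zip(cell_masks, particle_masks))
    ]
    tracked = track_particles(frames, pixel_size_um=pixel_size_um)
    centroids: dict[int, dict[int, tuple[float, float]]] = {}
    for t, cm in enumerate(cell_masks):
        cm = as_label_mask(cm)
        centroids[t] = {
            int(l): tuple(np.argwhere(cm == l).mean(axis=0))
            for l in np.unique(cm) if l > 0
        }
    conf = confirm_engulfment(tracked, centroids, min_shrink=min_shrink,
                              co_move_tol_px=co_move_tol_px)
    confirmed_hosts = set(
        conf.loc[conf["confirmed"], "host_cell_id"].astype(int))

    reports = []
    for t, frame in enumerate(frames):
        total = float(frame["area_um2"].sum())
        inside = float(frame["inside_area_um2"].sum())
        cells = [int(l) for l in np.unique(as_label_mask(cell_masks[t]))
                 if l > 0]
        n_cells = len(cells)
        n_phago = sum(1 for c in cells if c in confirmed_hosts)
        reports.append(PhagoReport(
            frame_index=t,
            sytox_area_inside=inside,
            sytox_area_total=total,
            n_microglia=n_cells,
            phago_index=(phago_index(inside, total, n_cells)
                         if total > 0 and n_cells else float("nan")),
            n_phagocytosing=n_phago,
            phagocytosing_pct=(phagocytosing_pct(
                {c: c in confirmed_hosts for c in cells}) if cells
                else float("nan")),
        ))
    return tracked, conf, reports
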