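"""Fiducial drift correction for 3D tissue migration assays.

A bioengineered tissue construct drifts rigidly under the objective during
time-lapse imaging.  Landmark ("fiducial") tracks belonging to the construct
move together; they are identified by the cosine similarity of their step
series (threshold 0.95), their mean start-anchored trajectory is taken as
the construct's drift path, and that path is subtracted from the cell
trajectories before motility features are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import Track, TrackSet, fill_gaps

logger = logging.getLogger(__name__)


@dataclass
class DriftEstimate:
    """The correlated fiducial set and the drift path it defines.

    drift_path[t] is the members' mean displacement from their frame-0
    positions (start-anchored averaging, so spatially dispersed fiducials do
    not bias the path); drift_frames are the covered frame indices.
    """

    member_ids: list[str]
    similarity: np.ndarray
    fiducial_ids: list[str]
    threshold: float
    drift_path: np.ndarray
    drift_frames: np.ndarray


def _common_frame_positions(fiducials: TrackSet) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    """Gap-fill fiducials, intersect their frame ranges, and return positions
    over the common range."""
    filled = []
    for t in fiducials:
        f = fill_gaps(t)
        if f is None:
            logger.info("fiducial %s excluded: frame gap > 2", t.track_id)
            continue
        filled.append(f)
    if len(filled) < 2:
        raise ValueError("need at least 2 gap-free fiducial tracks")
    start = max(int(t.frames[0]) for t in filled)
    stop = min(int(t.frames[-1]) for t in filled)
    if stop - start + 1 < 3:
        raise ValueError("fiducials share no common frame range of ≥ 3 frames")
    frames = np.arange(start, stop + 1)
    positions = [
        t.positions[(t.frames >= start) & (t.frames <= stop)] for t in filled
    ]
    return frames, positions, [t.track_id for t in filled]


def pairwise_track_similarity(fiducials: TrackSet) -> tuple[np.ndarray, list[str]]:
    """Cosine similarity between fiducial step series over their common
    frame range.

    Each track's step vectors are flattened into one vector; the similarity
    is scale-invariant, so fiducials that move along the same path at
    different amplitudes still correlate at 1.  Stationary fiducials
    (zero-norm step series) get NaN similarity to every partner (flagged).
    Returns (matrix, track ids in matrix order).
    """
    _, positions, ids = _common_frame_positions(fiducials)
    vecs = np.stack([np.diff(p, axis=0).ravel() for p in positions])
    norms = np.linalg.norm(vecs, axis=1)
    sim = np.full((len(ids), len(ids)), np.nan)
    ok = norms > 0
    if not ok.all():
        logger.warning(
            "stationary fiducial(s) %s: similarity undefined",
            [i for i, o in zip(ids, ok) if not o],
        )
    nv = vecs[ok] / norms[ok, None]
    sub = nv @ nv.T
    idx = np.flatnonzero(ok)
    sim[np.ix_(idx, idx)] = sub
    np.fill_diagonal(sim, 1.0)
    return sim, ids


def estimate_drift(fiducials: TrackSet, threshold: float = 0.95) -> DriftEstimate:
    """Select the correlated fiducial set and average its start-anchored
    trajectories into the drift path.

    Fiducials form a graph with edges where cosine similarity ≥ threshold;
    the member set is the largest connected component with ≥ 2 members
    (ties broken by higher mean internal similarity).  drift_path[t] is the
    members' mean (position[t] − position[0]) over the common frame range.
    """
    frames, positions, ids = _common_frame_positions(fiducials)
    sim, _ = pairwise_track_similarity(fiducials)
    adj = np.where(np.isnan(sim), -2.0, sim) >= threshold
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    best, best_key = None, None
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) < 2:
            continue
        internal = sim[np.ix_(members, members)]
        mean_sim = float(np.nanmean(internal[np.triu_indices(len(members), k=1)]))
        key = (len(members), mean_sim)
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best is None:
        raise ValueError(
            f"no correlated fiducial set at threshold {threshold}: "
            "no connected component of size ≥ 2"
        )
    anchored = np.stack([positions[i] - positions[i][0] for i in best])
    drift_path = anchored.mean(axis=0)
    return DriftEstimate(
        member_ids=[ids[i] for i in best],
        similarity=sim,
        fiducial_ids=ids,
        threshold=threshold,
        drift_path=drift_path,
        drift_frames=frames,
    )


def apply_drift_correction(cells: TrackSet, d: DriftEstimate) -> TrackSet:
    """Subtract the drift path from every cell position.

    Every cell frame must fall inside the drift path's frame range;
    corrected position[t] = position[t] − drift_path[t].
    """
    lo, hi = int(d.drift_frames[0]), int(d.drift_frames[-1])
    corrected: list[Track] = []
    for t in cells:
        if t.frames[0] < lo or t.frames[-1] > hi:
            raise ValueError(
                f"track {t.track_id!r} spans frames [{t.frames[0]}, {t.frames[-1]}] "
                f"outside drift range [{lo}, {hi}]"
            )
        offs = d.drift_path[t.frames - lo]
        corrected.append(replace(t, positions=t.positions - offs))
    return TrackSet(
        tracks=corrected,
        frame_interval=cells.frame_interval,
        field_bounds=cells.field_bounds,
        meta={**cells.meta, "drift_members": list(d.member_ids),
              "drift_threshold": d.threshold},
    )
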