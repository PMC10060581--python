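"""Synthetic probe and montage geometry.

One bilateral fNIRS probe: per hemisphere a 3x3 optode grid (alternating
sources and detectors) yields 12 nearest-neighbour source-detector channels;
both hemispheres together give 8 sources, 10 detectors and 24 channels.
Optodes sit on a 10 cm scalp sphere; the grid pitch is jittered within the
published inter-optode range (2.16-3.26 cm) to emulate cap-fit variation.

EEG electrode positions are a fixed synthetic unit-sphere montage covering
every label used by the scalp ROI groupings plus the 24 boundary labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rois import ANALYSIS_ELECTRODES, BOUNDARY_ELECTRODES, EEG_ROI_ELECTRODES

HEAD_RADIUS_CM = 10.0
CHANNEL_DISTANCE_RANGE = (2.16, 3.26)


@dataclass(frozen=True)
class ProbeGeometry:
    """Optode/electrode geometry of one recording session.

    Positions are 3-D coordinates in cm on a scalp sphere (fNIRS optodes)
    or unit-sphere coordinates keyed by electrode label (EEG).
    """

    source_positions: np.ndarray  # (8, 3) cm
    detector_positions: np.ndarray  # (10, 3) cm
    channel_pairs: tuple[tuple[int, int], ...]  # (source idx, detector idx)
    electrode_positions: dict[str, np.ndarray] = field(repr=False)
    head_radius: float = HEAD_RADIUS_CM

    @property
    def n_channels(self) -> int:
        return len(self.channel_pairs)

    @property
    def channel_distance(self) -> np.ndarray:
        """Euclidean source-detector distance per channel (cm)."""
        s = self.source_positions[[p[0] for p in self.channel_pairs]]
        d = self.detector_positions[[p[1] for p in self.channel_pairs]]
        return np.linalg.norm(s - d, axis=1)

    @property
    def channel_midpoints(self) -> np.ndarray:
        s = self.source_positions[[p[0] for p in self.channel_pairs]]
        d = self.detector_positions[[p[1] for p in self.channel_pairs]]
        return (s + d) / 2.0


def _sph(theta_deg: float, phi_deg: float, radius: float = 1.0) -> np.ndarray:
    """Point on a sphere; theta = polar angle from vertex, phi = azimuth
    (90 deg = front, 0 = right ear, 180 = left ear, 270 = back)."""
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return radius * np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )


def _tangent_basis(center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = center / np.linalg.norm(center)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(c @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, c)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(c, t1)
    return t1, t2


def _project_patch(center: np.ndarray, uv: np.ndarray, radius: float) -> np.ndarray:
    """Map planar patch coordinates (cm) onto the sphere via the exponential
    map at ``center``; arc lengths along great circles are preserved."""
    c = center / np.linalg.norm(center)
    t1, t2 = _tangent_basis(c)
    d = np.linalg.norm(uv, axis=1)
    phi = np.arctan2(uv[:, 1], uv[:, 0])
    d = np.where(d == 0, 1e-12, d)
    direction = np.cos(phi)[:, None] * t1 + np.sin(phi)[:, None] * t2
    ang = d / radius
    pts = np.cos(ang)[:, None] * c + np.sin(ang)[:, None] * direction
    return pts * radius


def _hemisphere_grid(rng: np.random.Generator, center: np.ndarray):
    """3x3 alternating optode grid; even parity = detector (5), odd = source
    (4); the 12 grid edges are the source-detector channels."""
    pitch = rng.uniform(2.6, 3.0)
    jitter = rng.uniform(-0.1, 0.1, size=(9, 2))
    uv = np.array([[i - 1.0, j - 1.0] for i in range(3) for j in range(3)])
    uv = uv * pitch + jitter
    pts = _project_patch(center, uv, HEAD_RADIUS_CM)
    is_detector = [((k // 3) + (k % 3)) % 2 == 0 for k in range(9)]
    sources = [k for k in range(9) if not is_detector[k]]
    detectors = [k for k in range(9) if is_detector[k]]
    edges = []
    for i in range(3):
        for j in range(3):
            k = i * 3 + j
            if j < 2:
                edges.append((k, k + 1))
            if i < 2:
                edges.append((k, k + 3))
    pairs = []
    for a, b in edges:
        s, d = (a, b) if not is_detector[a] else (b, a)
        pairs.append((sources.index(s), detectors.index(d)))
    return pts[sources], pts[detectors], pairs


#: nominal ROI centre directions (polar from vertex, azimuth) for the
#: synthetic montage; boundary electrodes ring the rim at theta=85.
_EEG_ROI_CENTERS = {
    "left frontal": (45.0, 130.0),
    "right frontal": (45.0, 50.0),
    "left central": (32.0, 180.0),
    "right central": (32.0, 0.0),
    "left parietal": (45.0, 230.0),
    "right parietal": (45.0, 310.0),
    "left occipital": (62.0, 250.0),
    "right occipital": (62.0, 290.0),
}


def _electrode_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for roi, labels in EEG_ROI_ELECTRODES.items():
        th0, ph0 = _EEG_ROI_CENTERS[roi]
        n = len(labels)
        for k, lab in enumerate(labels):
            # deterministic ring layout around the ROI centre
            ang = 2 * np.pi * k / n
            r = 8.0 if k else 0.0  # degrees of angular spread
            pos[lab] = _sph(th0 + r * np.sin(ang), ph0 + r * np.cos(ang) * 1.6)
    for k, lab in enumerate(BOUNDARY_ELECTRODES):
        pos[lab] = _sph(85.0, 360.0 * k / len(BOUNDARY_ELECTRODES))
    return pos


def generate_geometry(seed: int) -> ProbeGeometry:
    """Generate a bilateral 8-source/10-detector/24-channel probe geometry.

    Deterministic for a fixed seed; the grid pitch and per-optode jitter are
    chosen so every source-detector distance stays inside the published
    2.16-3.26 cm range.
    """
    rng = np.random.default_rng(seed)
    left_center = _sph(42.0, 205.0, HEAD_RADIUS_CM)
    right_center = _sph(42.0, 335.0, HEAD_RADIUS_CM)
    ls, ld, lp = _hemisphere_grid(rng, left_center)
    rs, rd, rp = _hemisphere_grid(rng, right_center)
    sources = np.vstack([ls, rs])
    detectors = np.vstack([ld, rd])
    pairs = [*lp] + [(s + 4, d + 5) for s, d in rp]
    geom = ProbeGeometry(
        source_positions=sources,
        detector_positions=detectors,
        channel_pairs=tuple(pairs),
        electrode_positions=_electrode_positions(),
    )
    dist = geom.channel_distance
    lo, hi = CHANNEL_DISTANCE_RANGE
    if dist.min() < lo or dist.max() > hi:  # pragma: no cover - guard
        raise AssertionError("channel distances outside printed range")
    return geom


__all__ = [
    "ProbeGeometry",
    "generate_geometry",
    "HEAD_RADIUS_CM",
    "CHANNEL_DISTANCE_RANGE",
    "ANALYSIS_ELECTRODES",
    "BOUNDARY_ELECTRODES",
]
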