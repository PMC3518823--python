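"""Synthetic streamline phantoms.

The generators produce parametric polylines sampled at a fixed number of
points (200 by default), in millimeters on a roughly 100 mm scene scale so
that clustering thresholds of 1–20 mm behave as they do on brain-scale
tractographies.  Three bundle families are provided:

* a *pencil of helices* sharing a start point, with linearly varying pitch;
* a *divergent fan of rays* on a sinusoidally corrugated sheet;
* the same fan with additional sinusoidal lateral bending whose amplitude
  varies across members.

``three_bundle_phantom`` arranges one bundle of each family (450
streamlines total) so that the helix pencil and the bent fan run close
together — they merge into a single cluster at a coarse threshold around
8 mm — while the plain corrugated fan stays well separated, and all three
are cleanly separable at a fine threshold of ~1 mm.

``dense_phantom`` is a larger variant with *nonuniformly* distributed
member parameters (beta-distributed rather than evenly spaced).  It mimics
the uneven streamline density of real tractographies, where random
subsampling overrepresents dense regions — the regime in which centroid
summaries outperform equal-sized random subsets.

All generators are deterministic given their arguments and seed.
"""

from __future__ import annotations

import numpy as np

from .streamlines import Tractography

__all__ = [
    "helix_pencil",
    "corrugated_rays",
    "bent_corrugated_rays",
    "three_bundle_phantom",
    "dense_phantom",
    "parallel_line_grid",
    "truncate_copies",
]

#: default samples per generated path
POINTS_PER_PATH = 200


def _check_range(name: str, rng_pair, n: int) -> None:
    lo, hi = rng_pair
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError(f"{name} must be finite, got {rng_pair}")
    if n > 1 and lo == hi:
        raise ValueError(f"{name} is degenerate ({lo}, {hi}) but n={n} > 1")


def _spread_values(lo: float, hi: float, n: int) -> np.ndarray:
    """n values linearly spaced over [lo, hi]; the midpoint when n == 1."""
    if n == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, n)


def helix_pencil(n: int, pitch_range: tuple[float, float] = (4.5, 6.0),
                 radius: float = 5.0, turns: float = 2.0,
                 points: int = POINTS_PER_PATH, seed: int = 0) -> Tractography:
    """A pencil of helices on a common cylinder, all starting at the same
    point, with pitch varying linearly across members.

    Member k follows ``(r cos t, r sin t, p_k t)`` for t in [0, 2*pi*turns];
    the shared start point is ``(radius, 0, 0)``.  *seed* is accepted for
    interface uniformity; the recipe is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_range("pitch_range", pitch_range, n)
    pitches = _spread_values(pitch_range[0], pitch_range[1], n)
    tau = np.linspace(0.0, 2.0 * np.pi * turns, points)
    streamlines = []
    for p in pitches:
        path = np.column_stack([radius * np.cos(tau),
                                radius * np.sin(tau),
                                p * tau])
        streamlines.append(path)
    return Tractography(streamlines)


def _ray_fan(angles: np.ndarray, bend_amps: np.ndarray,
             corrugation_amp: float, corrugation_freq: float,
             length: float, points: int) -> list[np.ndarray]:
    """Rays from the origin in the (u, v) sheet plane; corrugation is the
    out-of-sheet w-height, lateral bending displaces within the sheet."""
    t = np.linspace(0.0, length, points)
    w = corrugation_amp * np.sin(2.0 * np.pi * corrugation_freq * t)
    bend_profile = np.sin(2.0 * np.pi * t / length)
    out = []
    for phi, b in zip(angles, bend_amps):
        u = t * np.cos(phi) - b * bend_profile * np.sin(phi)
        v = t * np.sin(phi) + b * bend_profile * np.cos(phi)
        out.append(np.column_stack([u, v, w]))
    return out


def corrugated_rays(n: int, spread_angle: float = 0.7,
                    corrugation_amp: float = 2.0,
                    corrugation_freq: float = 0.03,
                    length: float = 90.0,
                    points: int = POINTS_PER_PATH, seed: int = 0) -> Tractography:
    """A divergent fan of rays on a sinusoidally corrugated sheet.

    Ray directions are spread linearly over ``spread_angle`` (radians)
    about the sheet's u-axis; the sheet height is
    ``corrugation_amp * sin(2*pi*corrugation_freq * t)`` with t the
    in-sheet distance along the ray (mm).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 1 and spread_angle == 0.0:
        raise ValueError("spread_angle is degenerate but n > 1")
    angles = _spread_values(-spread_angle / 2.0, spread_angle / 2.0, n)
    rays = _ray_fan(angles, np.zeros(n), corrugation_amp, corrugation_freq,
                    length, points)
    return Tractography(rays)


def bent_corrugated_rays(n: int, spread_angle: float = 0.35,
                         corrugation_amp: float = 1.5,
                         corrugation_freq: float = 0.03,
                         bend_amp_range: tuple[float, float] = (0.0, 6.0),
                         length: float = 70.0,
                         points: int = POINTS_PER_PATH,
                         seed: int = 0) -> Tractography:
    """Corrugated-sheet rays with sinusoidal lateral bending whose
    amplitude varies linearly over ``bend_amp_range`` across members."""
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_range("bend_amp_range", bend_amp_range, n)
    angles = _spread_values(-spread_angle / 2.0, spread_angle / 2.0, n)
    bends = _spread_values(bend_amp_range[0], bend_amp_range[1], n)
    rays = _ray_fan(angles, bends, corrugation_amp, corrugation_freq,
                    length, points)
    return Tractography(rays)


def _assemble_three_bundles(helix: Tractography, bent: Tractography,
                            plain: Tractography) -> tuple[Tractography, np.ndarray]:
    """Place the three bundles in a shared frame: helix around the z-axis at
    the origin, bent rays rotated to run up the helix axis, plain rays
    translated well away; labels 0/1/2 in that order."""
    streamlines = [s.copy() for s in helix.streamlines]
    for s in bent.streamlines:
        # local (u, v, w) -> world (w, v, u): rays climb +z through the helix
        placed = np.column_stack([s[:, 2], s[:, 1], s[:, 0]])
        placed += np.array([0.0, 0.0, -2.0])
        streamlines.append(placed)
    for s in plain.streamlines:
        streamlines.append(s + np.array([35.0, -45.0, 0.0]))
    labels = np.repeat([0, 1, 2], [len(helix), len(bent), len(plain)])
    return Tractography(streamlines), labels


def three_bundle_phantom(seed: int = 0, n_per_bundle: int = 150,
                         points: int = POINTS_PER_PATH
                         ) -> tuple[Tractography, np.ndarray]:
    """The canonical three-bundle scene: helix pencil (label 0), bent
    corrugated rays (label 1) hugging the helix axis, and a plain
    corrugated fan (label 2) placed ~45 mm away.

    Returns the concatenated tractography (ids 1..3*n_per_bundle, bundle
    blocks in label order) and the per-streamline ground-truth labels.
    At a 1 mm threshold the three bundles separate cleanly; around 8 mm the
    helix and bent-ray bundles merge while the plain fan stays apart.
    """
    helix = helix_pencil(n_per_bundle, points=points, seed=seed)
    bent = bent_corrugated_rays(n_per_bundle, points=points, seed=seed)
    plain = corrugated_rays(n_per_bundle, points=points, seed=seed)
    return _assemble_three_bundles(helix, bent, plain)


def dense_phantom(seed: int = 0, n_per_bundle: int = 250,
                  points: int = POINTS_PER_PATH
                  ) -> tuple[Tractography, np.ndarray]:
    """A denser, broader three-bundle scene with nonuniform member density.

    Member parameters (helix pitch, ray angle, bend amplitude) are drawn
    from beta distributions over widened ranges, so each bundle has a dense
    core and sparse fringes — the density profile that makes random
    subsampling a poor summary of a tractography.
    """
    rng = np.random.default_rng(seed)

    pitches = 2.0 + 6.0 * rng.beta(4.0, 1.5, size=n_per_bundle)
    tau = np.linspace(0.0, 4.0 * np.pi, points)
    helix_sl = [np.column_stack([6.0 * np.cos(tau), 6.0 * np.sin(tau), p * tau])
                for p in np.sort(pitches)]
    helix = Tractography(helix_sl)

    bent_angles = -0.5 + 1.0 * rng.beta(2.0, 2.0, size=n_per_bundle)
    bend_amps = 20.0 * rng.beta(1.5, 4.0, size=n_per_bundle)
    bent = Tractography(_ray_fan(bent_angles, bend_amps, 1.5, 0.03, 70.0, points))

    plain_angles = -0.75 + 1.5 * rng.beta(4.0, 1.5, size=n_per_bundle)
    plain = Tractography(_ray_fan(plain_angles, np.zeros(n_per_bundle),
                                  2.0, 0.03, 90.0, points))

    return _assemble_three_bundles(helix, bent, plain)


def parallel_line_grid(count: int, spacing: float = 1.0,
                       phase_offset: float = 0.0, length: float = 100.0,
                       points: int = POINTS_PER_PATH) -> Tractography:
    """Straight parallel lines along x, line j at ``y = phase_offset +
    j*spacing``; the degenerate best/worst-case dataset for studying how a
    threshold partitions a homogeneous sheet into consecutive runs."""
    if count < 2:
        raise ValueError("count must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    x = np.linspace(0.0, length, points)
    lines = []
    for j in range(count):
        y = phase_offset + j * spacing
        lines.append(np.column_stack([x, np.full(points, y), np.zeros(points)]))
    return Tractography(lines)


def truncate_copies(t: Tractography, fraction_range: tuple[float, float] = (0.25, 0.75),
                    per_streamline: int = 1, seed: int = 0) -> Tractography:
    """Short-fragment phantom: for each source streamline emit copies
    clipped to random arc-length sub-intervals.

    Each copy keeps a fraction drawn uniformly from ``fraction_range``
    (must lie in (0, 1]) of the source's arc length, starting at a random
    offset, re-interpolated to a proportional number of points.  Fresh ids
    1..N are assigned.
    """
    lo, hi = fraction_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for s in t.streamlines:
        seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        total = cum[-1]
        for _ in range(per_streamline):
            f = rng.uniform(lo, hi)
            start = rng.uniform(0.0, 1.0 - f) if f < 1.0 else 0.0
            npts = max(2, int(round(f * len(s))))
            targets = np.linspace(start * total, (start + f) * total, npts)
            piece = np.column_stack([np.interp(targets, cum, s[:, d])
                                     for d in range(3)])
            out.append(piece)
    return Tractography(out)
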