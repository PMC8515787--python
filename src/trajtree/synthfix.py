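"""Synthetic labeled trajectory collections with known ground truth.

The generator emulates a formic-acid molecule solvated by a small water
cluster — the archetypal system for studying acid-to-water proton
transfer — producing both unreactive excursions (the acid O–H stretches
to ~1.3 Å and relaxes) and reactive paths (the proton transfers to the
nearest water, forming a triply coordinated hydronium oxygen, whose
identity then hops to a distant water so that s(r) exceeds the product
bound).  The hops are scripted kinematics, not dynamics: the analysis
pipeline, not an MD engine, is what these fixtures exercise.

The recoverable ground truth is geometric: two waters sit outside the
solvation ring, and the O–O distance between them is drawn below the
planted threshold for reactive paths and above it for unreactive ones,
as a rigid displacement of the outer water.  Random rigid orientations
of both outlier waters scramble all hydrogen-involving distances, so
exactly one entry of the index-invariant matrix — the planted feature —
separates the classes cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .invrep import FeatureLabel
from .trajio import Frame, PathRecord, write_manifest

__all__ = ["FixtureSpec", "template_cluster", "generate_paths", "auto_planted_feature"]

# Formic acid internal geometry (Å): planar HCOOH with standard bond
# lengths; atom order C, O(carbonyl), O(hydroxyl), H(formyl), H(acid).
_CO_DOUBLE = 1.22
_CO_SINGLE = 1.34
_OH_ACID = 0.97
_CH = 1.09
# Rigid water: O–H 0.96 Å, H–O–H 104.5 deg.
_OH_WATER = 0.96
_HOH_DEG = 104.5

_RING_RADIUS = 3.8
_OUTLIER_RADIUS = 5.2  # radius of the inner outlier water ("partner")
_OUTLIER_ANGLE = 225.0  # deg; sector free of ring waters and acid atoms


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic collection.

    ``planted_feature`` defaults to the O–O pair this generator plants
    (``auto_planted_feature``); passing any other label is rejected
    because no other pair carries a clean class signal.
    """

    n_waters: int = 6
    n_paths: int = 40
    frac_reactive: float = 0.5
    planted_feature: FeatureLabel | None = None
    planted_threshold: float = 3.0  # Å
    jitter_sigma: float = 0.02  # Å, per coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_paths < 2:
            raise ValueError("need at least two paths")
        if not 0.0 <= self.frac_reactive <= 1.0:
            raise ValueError("frac_reactive must be in [0, 1]")
        if self.n_waters < 3:
            raise ValueError("the planted-pair construction needs >= 3 waters")
        auto = auto_planted_feature(self.n_waters)
        if self.planted_feature is None:
            self.planted_feature = auto
        elif str(self.planted_feature) != str(auto):
            raise ValueError(
                f"this generator plants {auto}; cannot plant {self.planted_feature}"
            )

    @property
    def n_reactive(self) -> int:
        return int(round(self.frac_reactive * self.n_paths))


def auto_planted_feature(n_waters: int) -> FeatureLabel:
    """The planted entry: the farthest oxygen's distance to its nearest
    *other* oxygen.

    With 2 acid + ``n_waters`` water oxygens, the outer outlier water is
    always the farthest oxygen from the reference carbon (row rank
    n_waters + 1).  Column rank 0 of its own element group is its
    self-distance (0), so its partner — always its nearest other
    oxygen — sits at column rank 1.
    """
    return FeatureLabel("O", n_waters + 1, "O", 1)


def _acid_atoms() -> tuple[list[str], np.ndarray]:
    ang120 = math.radians(120.0)
    c = np.zeros(3)
    o_carbonyl = _CO_DOUBLE * np.array([math.cos(ang120), math.sin(ang120), 0.0])
    o_hydroxyl = np.array([_CO_SINGLE, 0.0, 0.0])
    ang240 = math.radians(240.0)
    h_formyl = _CH * np.array([math.cos(ang240), math.sin(ang240), 0.0])
    # acid H on the hydroxyl O, trans to the carbonyl O (C-O-H ~106 deg)
    h_acid = o_hydroxyl + _OH_ACID * np.array(
        [math.cos(math.radians(74.0)), -math.sin(math.radians(74.0)), 0.0]
    )
    coords = np.vstack([c, o_carbonyl, o_hydroxyl, h_formyl, h_acid])
    return ["C", "O", "O", "H", "H"], coords


def _water_at(o_pos: np.ndarray, inward: np.ndarray) -> np.ndarray:
    """Rigid water with its H–O–H bisector along ``inward`` (unit vector),
    hydrogens tilted out of the bisector plane along ±z-like axis."""
    inward = inward / np.linalg.norm(inward)
    # axis perpendicular to inward, preferring global z
    z = np.array([0.0, 0.0, 1.0])
    perp = z - z.dot(inward) * inward
    if np.linalg.norm(perp) < 1e-8:
        perp = np.array([1.0, 0.0, 0.0]) - inward[0] * inward
    perp = perp / np.linalg.norm(perp)
    half = math.radians(_HOH_DEG / 2.0)
    h1 = o_pos + _OH_WATER * (math.cos(half) * inward + math.sin(half) * perp)
    h2 = o_pos + _OH_WATER * (math.cos(half) * inward - math.sin(half) * perp)
    return np.vstack([o_pos, h1, h2])


def template_cluster(n_waters: int) -> Frame:
    """Deterministic idealized cluster: planar HCOOH ringed by rigid waters.

    Water oxygens sit on a circle of radius 3.8 Å in the molecular
    plane, hydrogens pointing inward; no intermolecular atom pair comes
    closer than 1.5 Å.
    """
    if n_waters < 1:
        raise ValueError("need at least one water")
    elements, coords = _acid_atoms()
    blocks = [coords]
    for k in range(n_waters):
        theta = math.radians(90.0 + 360.0 * k / n_waters)
        o_pos = _RING_RADIUS * np.array([math.cos(theta), math.sin(theta), 0.0])
        blocks.append(_water_at(o_pos, -o_pos))
        elements.extend(["O", "H", "H"])
    return Frame(elements=tuple(elements), coords=np.vstack(blocks), time_index=0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _base_geometry(spec: FixtureSpec, rng: np.random.Generator, reactive: bool):
    """Per-path cluster: acid + ring waters + the planted outlier pair.

    Returns (elements, coords, metadata) where coords hold the resting
    (protonated) configuration before any scripted motion.
    """
    elements, acid = _acid_atoms()
    n_ring = spec.n_waters - 2
    blocks = [acid]
    for k in range(n_ring):
        theta = math.radians(90.0 + 360.0 * k / n_ring)
        r = _RING_RADIUS + rng.uniform(-0.15, 0.15)
        theta += math.radians(rng.uniform(-4.0, 4.0))
        z = rng.uniform(-0.2, 0.2)
        o_pos = np.array([r * math.cos(theta), r * math.sin(theta), z])
        water = _water_at(o_pos, -o_pos)
        # small random tilt of the whole water about its oxygen
        tilt = _small_rotation(rng, 10.0)
        water = o_pos + (water - o_pos) @ tilt.T
        blocks.append(water)
        elements.extend(["O", "H", "H"])
    # inner outlier water ("partner", A): placed at a class-independent,
    # broadly distributed distance from the ring water nearest its
    # sector, so A's nearest-other-oxygen distance straddles the planted
    # threshold in both classes and carries no clean class signal
    theta_a = math.radians(_OUTLIER_ANGLE + rng.uniform(-9.0, 9.0))
    r_a = _OUTLIER_RADIUS + rng.uniform(-0.6, 0.6)
    target = np.array(
        [r_a * math.cos(theta_a), r_a * math.sin(theta_a), rng.uniform(-0.2, 0.2)]
    )
    ring_o = np.array([blocks[1 + k][0] for k in range(n_ring)])
    anchor = ring_o[int(np.argmin(np.linalg.norm(ring_o - target, axis=1)))]
    v = (target - anchor) / np.linalg.norm(target - anchor)
    a_dist = rng.uniform(2.4, 3.6)
    o_a = anchor + a_dist * v
    water_a = _water_at(o_a, -o_a)
    water_a = o_a + (water_a - o_a) @ _random_rotation(rng).T
    blocks.append(water_a)
    elements.extend(["O", "H", "H"])
    # outer outlier water (B), beyond A at the class-dependent planted
    # distance: the recoverable ground truth.  The placement direction
    # gets a large out-of-plane tilt and a small azimuthal wobble so
    # that B's absolute position (hence every *other* distance touching
    # B) varies strongly within each class, while |O_A - O_B| is exact.
    margin = 0.25, 0.55
    if reactive:
        d = spec.planted_threshold - rng.uniform(*margin)
    else:
        d = spec.planted_threshold + rng.uniform(*margin)
    u = o_a / np.linalg.norm(o_a)
    phi = math.radians(rng.choice([-1.0, 1.0]) * rng.uniform(0.0, 55.0))
    azim = math.radians(rng.uniform(-3.0, 3.0))
    u = _rotz(azim) @ _rot_about(np.cross([0.0, 0.0, 1.0], u), phi) @ u
    o_b = o_a + d * u
    water_b = _water_at(o_b, -u)
    water_b = o_b + (water_b - o_b) @ _random_rotation(rng).T
    blocks.append(water_b)
    elements.extend(["O", "H", "H"])
    coords = np.vstack(blocks)
    meta = {
        "acid_O_hydroxyl": 2,
        "acid_H": 4,
        "o_b_index": 5 + 3 * (spec.n_waters - 1),
        "planted_distance": d,
    }
    return elements, coords, meta


def _rot_about(axis: np.ndarray, ang: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)


def _rotz(ang: float) -> np.ndarray:
    return _rot_about(np.array([0.0, 0.0, 1.0]), ang)


def _small_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    ang = math.radians(rng.uniform(-max_deg, max_deg))
    return _rot_about(axis, ang)


# Scripted acid O–H stretch targets (Å); values inside (1.1, 1.25)
# populate the default selection window.
_UNREACTIVE_R = (0.97, 1.03, 1.12, 1.18, 1.24, 1.29, 1.23, 1.17, 1.11, 1.02, 0.97)
_REACTIVE_R = (0.97, 1.03, 1.12, 1.17, 1.23, 1.30, 1.38)


def _nearest_water_oxygen(coords: np.ndarray, n_waters: int, target: np.ndarray) -> int:
    o_idx = [5 + 3 * k for k in range(n_waters)]
    d = [np.linalg.norm(coords[i] - target) for i in o_idx]
    return o_idx[int(np.argmin(d))]


def _path_frames(spec: FixtureSpec, rng: np.random.Generator, reactive: bool) -> list[Frame]:
    elements, base, meta = _base_geometry(spec, rng, reactive)
    o2, h4 = meta["acid_O_hydroxyl"], meta["acid_H"]
    u_oh = (base[h4] - base[o2]) / np.linalg.norm(base[h4] - base[o2])
    schedule = _REACTIVE_R if reactive else _UNREACTIVE_R
    frames: list[Frame] = []

    def jittered() -> np.ndarray:
        return base + rng.normal(scale=spec.jitter_sigma, size=base.shape)

    for r in schedule:
        c = jittered()
        r_eff = r + rng.uniform(-0.008, 0.008)
        c[h4] = c[o2] + r_eff * u_oh  # exact stretched O–H distance
        frames.append(Frame(tuple(elements), c, time_index=len(frames)))

    if reactive:
        # proton transfer: acid H becomes the third hydrogen of the
        # nearest water oxygen, forming the hydronium
        c = jittered()
        ow1 = _nearest_water_oxygen(c, spec.n_waters, c[o2])
        toward_acid = (c[o2] - c[ow1]) / np.linalg.norm(c[o2] - c[ow1])
        lift = np.array([0.0, 0.0, 1.0])
        direction = math.cos(math.radians(40.0)) * toward_acid + math.sin(
            math.radians(40.0)
        ) * lift
        direction /= np.linalg.norm(direction)
        c[h4] = c[ow1] + _OH_ACID * direction
        frames.append(Frame(tuple(elements), c, time_index=len(frames)))
        # identity hop: the hydronium jumps to the far outlier water,
        # producing the discontinuous rise of s(r) past the B bound
        for _ in range(2):
            c = jittered()
            ob = meta["o_b_index"]
            u_back = (c[5 + 3 * (spec.n_waters - 2)] - c[ob])
            u_back /= np.linalg.norm(u_back)
            c[h4] = c[ob] + _OH_ACID * u_back
            frames.append(Frame(tuple(elements), c, time_index=len(frames)))
    return frames


def _label_schedule(n_paths: int, n_reactive: int) -> list[bool]:
    """Spread the reactive paths evenly across generation order so every
    time block sees both classes."""
    if n_paths == 0:
        return []
    flags = []
    acc = 0
    frac = n_reactive / n_paths
    for i in range(n_paths):
        nxt = int(math.floor((i + 1) * frac + 1e-12))
        flags.append(nxt > acc)
        acc = nxt
    return flags


def generate_paths(spec: FixtureSpec, out_dir=None) -> list[PathRecord]:
    """Generate the labeled collection; optionally write XYZ + manifest.

    Reactive/unreactive counts are exact (``round(frac_reactive *
    n_paths)``), reactive paths end in state B with a discontinuous
    hydronium-identity jump, unreactive paths return to state A, and
    every path carries the planted geometric signature appropriate to
    its class.  Deterministic given ``spec.seed``.
    """
    flags = _label_schedule(spec.n_paths, spec.n_reactive)
    records: list[PathRecord] = []
    for i, reactive in enumerate(flags):
        rng = np.random.default_rng([spec.seed, i])
        frames = _path_frames(spec, rng, reactive)
        records.append(
            PathRecord(
                frames=frames,
                label="reactive" if reactive else "unreactive",
                path_id=f"path{i:04d}",
                generation_order=i,
            )
        )
    if out_dir is not None:
        write_manifest(records, Path(out_dir))
    return records


def default_colvar_config(n_waters: int):
    """The ColvarConfig matching this generator's atom layout."""
    from .colvar import ColvarConfig

    n_atoms = 5 + 3 * n_waters
    acid_o = {1, 2}
    reactive_h = {4} | {
        i for w in range(n_waters) for i in (6 + 3 * w, 7 + 3 * w)
    }
    assert max(reactive_h) < n_atoms
    return ColvarConfig(
        acid_oxygen_indices=frozenset(acid_o),
        reactive_hydrogen_indices=frozenset(reactive_h),
        stateA_bound=1.07 if n_waters >= 6 else 1.05,
    )
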