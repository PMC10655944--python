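"""Synthetic landmark datasets with the study's statistical structure.

The generator emulates a museum series of crania photographed in three views:
four karyotypic blocks of unequal size distributed along a short linear
transect, block-specific mean-shape displacements, male-biased size dimorphism
plus a sex shape effect, independent digitisation noise, bilateral asymmetry
noise on paired landmarks, and an arbitrary similarity transform (scale,
rotation, translation) per photographed configuration.

Shape effects are constructed in the tangent space at a deterministic
template: random displacement fields are projected to be orthogonal to the
translation, rotation and scaling directions (so they are genuine shape
effects) and, for the bilaterally paired views, onto the symmetric subspace
(so they survive symmetrization).  Ground truth — displacement fields, true
sizes, assignments — is returned alongside the dataset for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_tps import (
    BLOCK_KARYOTYPES,
    LandmarkConfiguration,
    MorphometricDataset,
    PairMap,
    SpecimenRecord,
)

BLOCKS = ("A", "B", "C", "D")

#: Mechanistic map from karyotype to the rearrangement states of chromosomal
#: pairs 1 and 2.  2n counts up from 54 (both pairs fused, MM/MM) to 58 (both
#: fissioned, AA/AA); each acrocentric homolog adds one to 2n.  The 55a/55b
#: and 56a/56b variants differ in which pair carries the rearrangement.
KARYOTYPE_PAIR_STATES: Mapping[str, tuple[str, str]] = {
    "54A": ("MM", "MM"),
    "54C": ("MM", "MM"),
    "55a": ("MM", "MA"),
    "55b": ("MA", "MM"),
    "56a": ("MM", "AA"),
    "56b": ("AA", "MM"),
    "57": ("MA", "AA"),
    "58": ("AA", "AA"),
}

#: Empirical karyotype composition of each block in the reference collection
#: (counts per karyotype); used as default sampling weights.
BLOCK_KARYOTYPE_COUNTS: Mapping[str, Mapping[str, int]] = {
    "A": {"54A": 19, "55a": 6},
    "B": {"58": 17},
    "C": {"54C": 18},
    "D": {"55b": 5, "56b": 24},
}


@dataclass
class SimulationParams:
    """Knobs of the synthetic-data generator.

    Defaults reproduce the reference study conditions: 89 specimens in blocks
    of 25/17/18/29, 52 females / 37 males, 29/30/21 landmarks per view, 18
    localities on a 78 km transect.  Effect sizes are in Procrustes-distance
    units (the template has unit centroid size): ``block_effect_size`` is
    the magnitude of each block's mean-shape displacement (the spacing of
    adjacent block means under the 'line' layout),
    ``karyotype_effect_size`` the magnitude of the karyotype-specific
    displacement scattered around the block mean (within-block karyotype
    divergence is roughly half the between-block divergence in the
    reference collection, hence the 0.03 default against 0.05),
    ``sex_shape_effect`` the male-female mean shape distance,
    ``sex_size_ratio`` the male/female mean centroid-size ratio, and
    ``landmark_noise`` the per-coordinate digitising SD.
    """

    n_per_block: tuple[int, int, int, int] = (25, 17, 18, 29)
    sex_ratio: float = 52 / 89
    k_per_view: tuple[int, int, int] = (29, 30, 21)
    block_effect_size: float = 0.05
    karyotype_effect_size: float = 0.03
    sex_shape_effect: float = 0.03
    sex_size_ratio: float = 1.1
    landmark_noise: float = 0.02
    asymmetry_noise: float = 0.01
    size_cv: float = 0.05
    base_size: float = 250.0
    n_localities: int = 18
    transect_length_km: float = 78.0
    clinal_component: float = 0.0
    block_layout: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_block):
            raise ValueError("n_per_block entries must all be >= 2")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for name in ("landmark_noise", "asymmetry_noise", "size_cv",
                     "block_effect_size", "karyotype_effect_size",
                     "sex_shape_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sex_size_ratio <= 0:
            raise ValueError("sex_size_ratio must be positive")
        if not 0.0 <= self.clinal_component <= 1.0:
            raise ValueError("clinal_component must be in [0, 1]")
        if self.block_layout not in ("line", "random"):
            raise ValueError("block_layout must be 'line' or 'random'")


@dataclass
class GroundTruth:
    """Generative truth emitted next to a simulated dataset."""

    template: dict[str, np.ndarray]                 # view -> k x 2
    block_displacement: dict[tuple[str, str], np.ndarray]  # (view, block)
    karyotype_displacement: dict[tuple[str, str], np.ndarray]  # (view, 2n)
    sex_displacement: dict[str, np.ndarray]         # view -> k x 2 (M - F)
    mean_shape: dict[tuple[str, str, str], np.ndarray]  # (block, sex, view)
    true_size: dict[str, float]                     # specimen -> pre-noise CS
    locality_km: dict[int, float]                   # locality -> position
    params: SimulationParams = field(repr=False, default=None)


def default_pair_map(k: int, view: str) -> PairMap:
    """Bilateral pairing used by the synthetic templates.

    Paired views put the first ``n_mid`` landmarks on the midline (n_mid = 5
    for odd k, 4 for even) and the rest in consecutive (left, right) pairs.
    The lateral view has no bilateral pairs: every landmark is a singleton.
    This layout is a property of the synthetic templates only — real data
    need the pairing that matches their landmark scheme.
    """
    if view == "lateral":
        return PairMap((), tuple(range(k)))
    n_mid = 5 if k % 2 else 4
    pairs = tuple((n_mid + 2 * t, n_mid + 2 * t + 1)
                  for t in range((k - n_mid) // 2))
    return PairMap(pairs, tuple(range(n_mid)))


def make_template(k: int, view: str) -> np.ndarray:
    """Deterministic cranium-like template: points on two nested arcs.

    Paired views are exactly symmetric about the y axis (midline landmarks at
    x = 0, pairs mirror-placed); the lateral view is an asymmetric profile.
    Centred, unit centroid size.
    """
    pm = default_pair_map(k, view)
    coords = np.zeros((k, 2))
    if view != "lateral":
        n_mid = len(pm.midline)
        for idx, m in enumerate(pm.midline):
            coords[m] = (0.0, 1.0 - 2.0 * idx / max(n_mid - 1, 1))
        n_pairs = len(pm.pairs)
        n_outer = (n_pairs + 1) // 2
        for t, (left, right) in enumerate(pm.pairs):
            if t < n_outer:
                frac = t / max(n_outer - 1, 1)
                a, b = 0.62, 0.95
            else:
                frac = (t - n_outer) / max(n_pairs - n_outer - 1, 1)
                a, b = 0.34, 0.70
            ang = np.pi * (0.12 + 0.76 * frac)
            x, y = a * np.sin(ang), b * np.cos(ang)
            coords[right] = (x, y)
            coords[left] = (-x, y)
    else:
        n_outer = (k + 1) // 2
        for i in range(n_outer):
            ang = np.pi * i / max(n_outer - 1, 1)
            coords[i] = (np.cos(ang), 0.55 * np.sin(ang))
        for i in range(k - n_outer):
            ang = np.pi * i / max(k - n_outer - 1, 1)
            coords[n_outer + i] = (0.6 * np.cos(ang),
                                   0.25 * np.sin(ang) - 0.12)
    coords -= coords.mean(axis=0)
    coords /= np.sqrt(np.sum(coords ** 2))
    return coords


def _nuisance_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of translation, scaling and rotation directions."""
    k = template.shape[0]
    ex = np.zeros((k, 2))
    ex[:, 0] = 1.0
    ey = np.zeros((k, 2))
    ey[:, 1] = 1.0
    scale_dir = template.copy()
    rot_dir = np.stack([-template[:, 1], template[:, 0]], axis=1)
    basis = np.stack([v.reshape(-1) for v in (ex, ey, scale_dir, rot_dir)])
    q, _ = np.linalg.qr(basis.T)
    return q


def _tangent_direction(rng: np.random.Generator, template: np.ndarray,
                       pair_map: PairMap, symmetric: bool) -> np.ndarray:
    """Random unit shape direction, nuisance-free (and symmetric if asked)."""
    k = template.shape[0]
    z = rng.standard_normal((k, 2))
    if symmetric and pair_map.pairs:
        z = 0.5 * (z + _reflect_field(z, pair_map))
    q = _nuisance_basis(template)
    v = z.reshape(-1)
    v = v - q @ (q.T @ v)
    v = v / np.linalg.norm(v)
    return v.reshape(k, 2)


def _reflect_field(field_k2: np.ndarray, pair_map: PairMap) -> np.ndarray:
    return (field_k2 * np.array([-1.0, 1.0]))[pair_map.permutation()]


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder)[: total - counts.sum()]:
        counts[idx] += 1
    return counts


def assign_pair_states(records: list[SpecimenRecord],
                       rng: np.random.Generator | None = None,
                       ) -> list[SpecimenRecord]:
    """Fill pair1/pair2 rearrangement states from each specimen's karyotype.

    The states follow mechanistically from the fission/fusion configuration
    of chromosomes 1 and 2 implied by the diploid number, so the assignment
    is deterministic; ``rng`` is accepted for interface symmetry with the
    other sampling steps but is not consumed.
    """
    out = []
    for r in records:
        p1, p2 = KARYOTYPE_PAIR_STATES[r.diploid_2n]
        out.append(SpecimenRecord(
            specimen_id=r.specimen_id, sex=r.sex, diploid_2n=r.diploid_2n,
            block=r.block, pair1=p1, pair2=p2, locality_id=r.locality_id,
            lat=r.lat, lon=r.lon,
        ))
    return out


#: Transect anchor in the study region (southern Brazilian coastal plain).
_TRANSECT_LAT = -30.35
_TRANSECT_LON0 = -51.05
_KM_PER_DEG = 111.195


def simulate_dataset(params: SimulationParams | None = None,
                     ) -> tuple[MorphometricDataset, GroundTruth]:
    """Draw one synthetic multi-view landmark dataset plus its ground truth.

    Per specimen and view the generative model is

        config = s · R(theta) · (template + block_disp + sex_disp
                                  + noise + asymmetry) + t

    with isotropic Gaussian landmark noise, antisymmetric noise restricted to
    paired landmarks, a lognormal size factor ``s`` whose male mean is
    ``sex_size_ratio`` times the female mean, uniform rotation and uniform
    translation.  With the default ``block_layout='random'`` each block gets
    an independent random displacement of magnitude ``block_effect_size``
    (block-structured variation with no geographic gradient); with ``'line'``
    the block means sit on a line in shape space at unit spacing, ordered
    A-D like the blocks on the transect.  ``clinal_component`` mixes the
    block displacement with a continuous transect-position effect along a
    shared direction (0 = purely block structured, 1 = purely clinal, which
    produces a true isolation-by-distance signal).  Karyotypes are drawn
    within block from the reference-collection composition, localities sit
    at evenly spaced points on the transect with blocks A-D occupying
    contiguous segments in order, and pair-1/pair-2 states follow from the
    karyotype.
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)
    views = ("dorsal", "ventral", "lateral")
    templates = {v: make_template(k, v) for v, k in zip(views, p.k_per_view)}
    pair_maps = {v: default_pair_map(k, v)
                 for v, k in zip(views, p.k_per_view)}

    block_centres = {b: c for b, c in zip(BLOCKS, (-1.5, -0.5, 0.5, 1.5))}
    # clinal_dir doubles as the block line direction under the 'line' layout
    clinal_dir = {v: _tangent_direction(rng, templates[v], pair_maps[v],
                                        symmetric=(v != "lateral"))
                  for v in views}
    sex_dir = {v: _tangent_direction(rng, templates[v], pair_maps[v],
                                     symmetric=(v != "lateral"))
               for v in views}
    block_disp: dict[tuple[str, str], np.ndarray] = {}
    for v in views:
        for b in BLOCKS:
            if p.block_layout == "line":
                disp = p.block_effect_size * block_centres[b] * clinal_dir[v]
            else:
                disp = p.block_effect_size * _tangent_direction(
                    rng, templates[v], pair_maps[v],
                    symmetric=(v != "lateral"),
                )
            block_disp[(v, b)] = disp
    karyo_disp: dict[tuple[str, str], np.ndarray] = {}
    for v in views:
        for kt in KARYOTYPE_PAIR_STATES:
            karyo_disp[(v, kt)] = (
                p.karyotype_effect_size * _tangent_direction(
                    rng, templates[v], pair_maps[v],
                    symmetric=(v != "lateral"),
                )
            )

    # specimen roster: blocks, karyotypes, sexes
    n_total = sum(p.n_per_block)
    blocks_per_specimen: list[str] = []
    karyotypes: list[str] = []
    for b, n_b in zip(BLOCKS, p.n_per_block):
        blocks_per_specimen.extend([b] * n_b)
        counts_map = BLOCK_KARYOTYPE_COUNTS[b]
        kts = list(counts_map)
        counts = _largest_remainder(
            n_b, np.array([counts_map[k] for k in kts], dtype=float)
        )
        karyo_pool = [k for k, c in zip(kts, counts) for _ in range(c)]
        karyotypes.extend(rng.permutation(karyo_pool).tolist())
    n_female = int(round(p.sex_ratio * n_total))
    sexes = np.array(["M"] * n_total, dtype=object)
    sexes[rng.choice(n_total, size=n_female, replace=False)] = "F"

    # localities: evenly spaced on the transect, contiguous block segments
    loc_counts = _largest_remainder(
        p.n_localities, np.asarray(p.n_per_block, dtype=float)
    )
    loc_counts = np.maximum(loc_counts, 1)
    while loc_counts.sum() > p.n_localities:
        loc_counts[np.argmax(loc_counts)] -= 1
    positions = (np.arange(p.n_localities) + 0.5) / p.n_localities \
        * p.transect_length_km
    locality_km = {i + 1: float(positions[i]) for i in range(p.n_localities)}
    block_locs: dict[str, list[int]] = {}
    start = 0
    for b, c in zip(BLOCKS, loc_counts):
        block_locs[b] = [start + i + 1 for i in range(int(c))]
        start += int(c)

    loc_assign: list[int] = []
    counter: dict[str, int] = {b: 0 for b in BLOCKS}
    for b in blocks_per_specimen:
        locs = block_locs[b]
        loc_assign.append(locs[counter[b] % len(locs)])
        counter[b] += 1

    width = len(str(n_total))
    records: list[SpecimenRecord] = []
    for i in range(n_total):
        loc = loc_assign[i]
        km = locality_km[loc]
        lon = _TRANSECT_LON0 + km / (_KM_PER_DEG
                                     * np.cos(np.radians(_TRANSECT_LAT)))
        records.append(SpecimenRecord(
            specimen_id=f"s{i + 1:0{width}d}",
            sex=str(sexes[i]),
            diploid_2n=karyotypes[i],
            block=blocks_per_specimen[i],
            locality_id=loc,
            lat=_TRANSECT_LAT,
            lon=lon,
        ))
    records = assign_pair_states(records, rng)

    # sizes: lognormal around the sex mean (female mean = base_size)
    log_sd = p.size_cv
    sex_mean = {"F": p.base_size, "M": p.base_size * p.sex_size_ratio}
    true_size: dict[str, float] = {}
    for r in records:
        mu = np.log(sex_mean[r.sex]) - 0.5 * log_sd ** 2
        true_size[r.specimen_id] = float(np.exp(rng.normal(mu, log_sd)))

    # configurations
    half = 0.5 * p.sex_shape_effect
    configurations: dict[tuple[str, str], LandmarkConfiguration] = {}
    mean_shape: dict[tuple[str, str, str], np.ndarray] = {}
    # block-level truth: block displacement plus the realised mixture of
    # karyotype displacements within the block; the clinal term varies
    # within block and is not part of the block-level mean
    for v in views:
        for b in BLOCKS:
            kts = [kt for kt, blk in zip(karyotypes, blocks_per_specimen)
                   if blk == b]
            karyo_mix = np.mean([karyo_disp[(v, kt)] for kt in kts], axis=0)
            for sex, sign in (("F", -1.0), ("M", 1.0)):
                mean_shape[(b, sex, v)] = (
                    templates[v]
                    + (1.0 - p.clinal_component)
                    * (block_disp[(v, b)] + karyo_mix)
                    + sign * half * sex_dir[v]
                )
    for r in records:
        c_pos = 3.0 * (locality_km[r.locality_id]
                       / p.transect_length_km) - 1.5
        sign = -1.0 if r.sex == "F" else 1.0
        gamma = p.clinal_component
        for v in views:
            shape = (templates[v]
                     + (1.0 - gamma) * (block_disp[(v, r.block)]
                                        + karyo_disp[(v, r.diploid_2n)])
                     + gamma * p.block_effect_size * c_pos * clinal_dir[v]
                     + sign * half * sex_dir[v])
            noise = rng.standard_normal(shape.shape) * p.landmark_noise
            shape = shape + noise
            pm = pair_maps[v]
            if p.asymmetry_noise > 0 and pm.pairs:
                z = rng.standard_normal(shape.shape) * p.asymmetry_noise
                shape = shape + 0.5 * (z - _reflect_field(z, pm))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rot = np.array([[np.cos(theta), np.sin(theta)],
                            [-np.sin(theta), np.cos(theta)]])
            t = rng.uniform(-p.base_size, p.base_size, size=2)
            coords = true_size[r.specimen_id] * (shape @ rot) + t
            configurations[(r.specimen_id, v)] = LandmarkConfiguration(
                r.specimen_id, v, coords
            )

    dataset = MorphometricDataset(
        configurations, {r.specimen_id: r for r in records}, pair_maps
    )
    truth = GroundTruth(
        template=templates,
        block_displacement=block_disp,
        karyotype_displacement=karyo_disp,
        sex_displacement={v: p.sex_shape_effect * sex_dir[v] for v in views},
        mean_shape=mean_shape,
        true_size=true_size,
        locality_km=locality_km,
        params=p,
    )
    return dataset, truth
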