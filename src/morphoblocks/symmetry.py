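"""Object-symmetry symmetrization of bilateral landmark configurations.

A cranium seen in dorsal or ventral view is a single symmetric structure:
every left-side landmark has a right-side counterpart and the remainder sit on
the sagittal midline.  The symmetric component of a configuration is the
average of the configuration and its mirror image with left/right labels
swapped, after superimposing the two; the discarded asymmetric remainder
carries fluctuating/directional asymmetry plus digitising error, which the
downstream analyses deliberately ignore.

Symmetrization here operates per specimen on raw configurations, before the
generalized Procrustes superimposition; the lateral view, having no bilateral
pairs, is left untouched.
"""

from __future__ import annotations

import numpy as np

from .io_tps import LandmarkConfiguration, PairMap
from .procrustes import center, centroid_size, optimal_rotation, to_preshape


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def _rebuild(config, coords: np.ndarray):
    if isinstance(config, LandmarkConfiguration):
        return LandmarkConfiguration(
            config.specimen_id, config.view, coords, scale=config.scale
        )
    return coords


def reflect_relabel(config, pair_map: PairMap):
    """Mirror a configuration and swap its left/right landmark labels.

    The reflection axis is the vertical (y) axis through the centroid:
    after centring, x -> -x; paired landmarks then exchange indices while
    midline landmarks keep theirs.  The original centroid position is
    restored.  Applying the operator twice is the identity, and a
    configuration that is perfectly symmetric about that axis is a fixed
    point.
    """
    coords = _as_coords(config)
    pair_map.validate_for(coords.shape[0])
    centroid = coords.mean(axis=0)
    mirrored = (coords - centroid) * np.array([-1.0, 1.0])
    mirrored = mirrored[pair_map.permutation()] + centroid
    return _rebuild(config, mirrored)


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def symmetrize(config, pair_map: PairMap):
    """Extract the symmetric component of a bilateral configuration.

    The reflected-relabelled copy is rotated into least-squares agreement
    with the original (both centred and scaled to unit centroid size —
    reflection preserves centroid size, so the scales match), and the two are
    averaged landmark-wise.  The average is then rotated by half the fitted
    angle, which makes it *exactly* invariant under :func:`reflect_relabel`,
    i.e. symmetric about the vertical axis; finally it is rescaled to the
    original centroid size and moved back to the original centroid.

    Idempotent: symmetrizing a symmetric configuration returns it unchanged
    (up to round-off), since the fitted rotation is then the identity.
    """
    coords = _as_coords(config)
    pair_map.validate_for(coords.shape[0])
    centroid = coords.mean(axis=0)
    cs = centroid_size(coords)
    x = to_preshape(coords)

    perm = pair_map.permutation()
    mirrored = (x * np.array([-1.0, 1.0]))[perm]
    rot = optimal_rotation(mirrored, x)
    theta = np.arctan2(rot[0, 1], rot[0, 0])
    sym = 0.5 * (x + mirrored @ rot)
    # Half-angle back-rotation: with T the reflect-relabel operator and R the
    # fitted rotation by theta, T(sym) = sym @ rot(-theta) identically, so
    # rotating sym by -theta/2 gives a T-fixed point.
    sym = sym @ _rotation_matrix(-theta / 2.0)

    sym_cs = centroid_size(sym)
    if sym_cs == 0.0:
        raise ValueError("degenerate configuration: symmetric component is "
                         "a single point")
    out = center(sym) * (cs / sym_cs) + centroid
    return _rebuild(config, out)


def symmetrize_dataset(dataset, views=("dorsal", "ventral")):
    """Return a copy of a dataset with the given views symmetrized.

    Views without a pair map, or with an empty pair list (e.g. lateral),
    pass through unchanged.
    """
    new_configs = {}
    for (sid, view), cfg in dataset.configurations.items():
        pm = dataset.pair_maps.get(view)
        if view in views and pm is not None and pm.pairs:
            new_configs[(sid, view)] = symmetrize(cfg, pm)
        else:
            new_configs[(sid, view)] = cfg
    return type(dataset)(new_configs, dict(dataset.records),
                         dict(dataset.pair_maps))
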