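import warnings

import numpy as np
import pytest

import rhizotrace as rt


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Segmentation legitimately warns on empty/degenerate inputs; keep the
    test output readable and assert warnings explicitly where they matter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_noiseless_scene(seed: int, model: rt.PlantModel | None = None):
    """A clean render (no noise/mesh/vignette) of one sampled plant."""
    geom = rt.sample_plant(model or rt.PlantModel(), seed)
    return rt.render_scene(geom, rng_seed=1000 + seed, noise_sd=0,
                           mesh_brightness=0, glint_fraction=0, vignette=0)


def recover_topology(scene, mask=None):
    """Skeletonize + trace a scene's mask (truth mask unless given)."""
    mask = mask or scene.truth_mask
    skel = rt.skeletonize_mask(mask)
    return rt.build_topology(skel, scene.seed_px, mask.scale, mask=mask)


@pytest.fixture(scope="session")
def noiseless_scenes():
    """Ten clean scenes shared by the architecture/global-trait tests."""
    return [make_noiseless_scene(seed) for seed in range(10)]


def gift_wrap_area(points_xy) -> float:
    """Independent hull oracle: Jarvis march (gift wrapping) + shoelace.

    At each hull vertex the next vertex is the point with the smallest
    positive turn from the incoming edge (ties broken toward the farthest
    point, which absorbs collinear runs); no call into qhull anywhere.
    """
    pts = np.unique(np.asarray(points_xy, float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
    hull = [start]
    prev_ang = np.pi / 2
    cur = start
    for _ in range(n + 1):
        rel = pts - pts[cur]
        dist = np.hypot(rel[:, 0], rel[:, 1])
        ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - prev_ang, 2 * np.pi)
        ang[dist == 0] = np.inf
        ang[np.isclose(ang, 0.0)] = 2 * np.pi  # never reverse along the edge
        nxt = int(np.lexsort((-dist, np.round(ang, 12)))[0])
        if nxt == start:
            break
        hull.append(nxt)
        prev_ang = np.arctan2(pts[nxt, 1] - pts[cur, 1],
                              pts[nxt, 0] - pts[cur, 0]) + np.pi
        cur = nxt
    v = pts[hull]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@pytest.fixture(scope="session")
def green_disk_image():
    """A green disk (radius 100 px) on a grey background, 0.01 cm/px."""
    px = np.full((300, 300, 3), 128, dtype=np.uint8)
    yy, xx = np.mgrid[:300, :300]
    disk = (yy - 150) ** 2 + (xx - 150) ** 2 <= 100 ** 2
    px[disk] = (60, 160, 70)
    return rt.CalibratedImage(px, scale=0.01), disk
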