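"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the library's own code paths: the flooding
oracle runs one BFS per seed and takes an explicit distance argmin; the
matching oracle enumerates every one-to-one assignment.
"""

from collections import deque
from itertools import permutations

import numpy as np
import pytest

import myelinseg as m

EIGHT_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def bfs_distance(start_mask, domain):
    """Single-source (multi-pixel) geodesic BFS distance over a domain."""
    dist = np.full(domain.shape, -1, dtype=int)
    q = deque()
    for r, c in zip(*np.nonzero(start_mask)):
        dist[r, c] = 0
        q.append((r, c))
    h, w = domain.shape
    while q:
        r, c = q.popleft()
        for dr, dc in EIGHT_NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and domain[rr, cc] and dist[rr, cc] < 0:
                dist[rr, cc] = dist[r, c] + 1
                q.append((rr, cc))
    return dist


def flooding_oracle(seeds, myelin_mask):
    """Assign each reachable domain pixel to the nearest seed (tie: lower label).

    Independent of the library: computes one full BFS distance field per seed
    and takes the argmin explicitly.
    """
    seeds = np.asarray(seeds)
    domain = np.asarray(myelin_mask, dtype=bool) | (seeds > 0)
    labels = sorted(int(l) for l in np.unique(seeds) if l > 0)
    out = seeds.copy()
    if not labels:
        return out
    dists = {l: bfs_distance(seeds == l, domain) for l in labels}
    todo = domain & (seeds == 0)
    for r, c in zip(*np.nonzero(todo)):
        best_l, best_d = 0, None
        for l in labels:
            d = dists[l][r, c]
            if d >= 0 and (best_d is None or d < best_d):
                best_l, best_d = l, d
        out[r, c] = best_l
    return out


def brute_force_match(target, prediction, threshold):
    """Best one-to-one assignment by (pair count, total IoU), enumerated."""
    t_labels = list(target.object_labels)
    p_labels = list(prediction.object_labels)
    ious = {}
    for tl in t_labels:
        tm = target.labels == tl
        for pl in p_labels:
            pm = prediction.labels == pl
            inter = np.logical_and(tm, pm).sum()
            if inter:
                v = inter / np.logical_or(tm, pm).sum()
                if v >= threshold:
                    ious[(int(tl), int(pl))] = v
    best = (0, 0.0, [])
    k = min(len(t_labels), len(p_labels))
    for size in range(k, -1, -1):
        from itertools import combinations
        for t_sub in combinations(t_labels, size):
            for p_perm in permutations(p_labels, size):
                pairs = [
                    (int(t), int(p), ious[(int(t), int(p))])
                    for t, p in zip(t_sub, p_perm)
                    if (int(t), int(p)) in ious
                ]
                if len(pairs) < size:
                    continue
                score = (len(pairs), sum(v for _, _, v in pairs))
                if score > best[:2]:
                    best = (*score, pairs)
        if best[0] == size and size > 0:
            break
    return best[0], best[2]


def point_in_polygon(px, py, vertices):
    """Even-odd ray casting, independent of matplotlib."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xcross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xcross:
                inside = not inside
    return inside


def random_instance_map(rng, shape=(32, 32), n_objects=4, kind=m.ComponentKind.FIBRE):
    """Disjoint random rectangles as a tiny instance map."""
    labels = np.zeros(shape, dtype=np.int64)
    lab = 1
    for _ in range(n_objects):
        for _ in range(20):
            h = rng.integers(3, 9)
            w = rng.integers(3, 9)
            r = rng.integers(0, shape[0] - h)
            c = rng.integers(0, shape[1] - w)
            if (labels[r : r + h, c : c + w] == 0).all():
                labels[r : r + h, c : c + w] = lab
                lab += 1
                break
    return m.InstanceMap(labels, kind, 1.0)


def annulus_probability_stack(shape=(40, 40), centre=(20, 20), r_in=8, r_out=13, gap=None):
    """Probability stack of one myelin annulus; optional gap cut through it."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - centre[0], cc - centre[1])
    ring = (d >= r_in) & (d <= r_out)
    if gap is not None:
        ring &= ~((np.abs(rr - centre[0]) <= gap / 2) & (cc >= centre[1]))
    inner = d < r_in
    stack = np.zeros((3, *shape))
    stack[0][ring] = 1.0
    stack[1][inner] = 1.0
    stack[2][~(ring | inner)] = 1.0
    return m.ProbabilityStack(stack, 1.0), ring, inner


@pytest.fixture(scope="session")
def small_phantom():
    return m.generate_phantom(m.PhantomSpec(image_size_px=256, n_fibres=10, seed=7))


@pytest.fixture(scope="session")
def object_model(small_phantom):
    """Object classifier trained on true object shapes (disks + crescents)."""
    from myelinseg.phantoms import gt_object_candidates

    return m.train_object_model(
        gt_object_candidates(small_phantom),
        small_phantom.image,
        m.object_scribbles(small_phantom),
        seed=0,
    )
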