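import numpy as np
import pytest

from netarch import FieldSpec


@pytest.fixture
def field():
    return FieldSpec(width=50.0, height=50.0, seed=0)


@pytest.fixture
def soax_fixture(tmp_path):
    """Two snakes crossing at one junction, pixel coordinates, with a
    header block and a trailing junction section."""
    text = (
        "# SOAX result\n"
        "# alpha 0.01\n"
        "0 0 10 10 0 500\n"
        "0 1 20 10 0 510\n"
        "0 2 30 10 0 490\n"
        "1 0 20 0 0 300\n"
        "1 1 20 10 0 310\n"
        "1 2 20 20 0 305\n"
        "#Junctions\n"
        "20 10 0\n"
    )
    p = tmp_path / "soax.txt"
    p.write_text(text)
    return p


def brute_force_nn(points: np.ndarray) -> np.ndarray:
    """O(N^2) all-pairs nearest-neighbour distances (test oracle)."""
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_fuse(coords: np.ndarray, threshold: float) -> np.ndarray:
    """Independent junction-fusion oracle: O(N^2) pairwise distances,
    depth-first connected components, member-weighted centroids, iterated
    to a fixed point.  Returns centroids sorted lexicographically."""
    coords = np.asarray(coords, dtype=float)
    weights = np.ones(len(coords))
    while True:
        n = len(coords)
        adj = [[] for _ in range(n)]
        any_edge = False
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(coords[i] - coords[j])) < threshold:
                    adj[i].append(j)
                    adj[j].append(i)
                    any_edge = True
        if not any_edge:
            break
        seen = [False] * n
        new_c, new_w = [], []
        for i in range(n):
            if seen[i]:
                continue
            stack, comp = [i], []
            seen[i] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            w = weights[comp]
            new_c.append(np.average(coords[comp], axis=0, weights=w))
            new_w.append(w.sum())
        coords, weights = np.array(new_c), np.array(new_w)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    return coords[order]
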