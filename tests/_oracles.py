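"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles with the slowest,
most transparent algorithm available (exhaustive enumeration, flood fill,
double loops, projected gradient), sharing no code with the implementation
it checks.
"""

from __future__ import annotations

import numpy as np

OFFSETS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

NEIGHBOURS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def glcm_bruteforce(lab: np.ndarray, distance: int = 1) -> np.ndarray:
    """Symmetric pooled GLCM by enumerating every voxel pair explicitly."""
    ng = int(lab.max())
    counts = np.zeros((ng, ng))
    shape = lab.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = lab[z, y, x]
                if a == 0:
                    continue
                for dz, dy, dx in OFFSETS_13:
                    zz, yy, xx = z + dz * distance, y + dy * distance, x + dx * distance
                    if 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]:
                        b = lab[zz, yy, xx]
                        if b > 0:
                            counts[a - 1, b - 1] += 1
                            counts[b - 1, a - 1] += 1
    return counts / counts.sum()


def glszm_zones_bruteforce(lab: np.ndarray) -> dict[tuple[int, int], int]:
    """Zones by explicit 26-connected flood fill."""
    shape = lab.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if lab[z, y, x] == 0 or seen[z, y, x]:
                    continue
                level = lab[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in NEIGHBOURS_26:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= nz < shape[0]
                            and 0 <= ny < shape[1]
                            and 0 <= nx < shape[2]
                            and not seen[nz, ny, nx]
                            and lab[nz, ny, nx] == level
                        ):
                            seen[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                key = (int(level), size)
                zones[key] = zones.get(key, 0) + 1
    return zones


def ngtdm_bruteforce(lab: np.ndarray, require_full: bool = False):
    """Per-level (n_i, p_i, s_i) by per-voxel neighbour enumeration."""
    shape = lab.shape
    ng = int(lab.max())
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = lab[z, y, x]
                if a == 0:
                    continue
                nb = []
                for dz, dy, dx in NEIGHBOURS_26:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                        if lab[nz, ny, nx] > 0:
                            nb.append(lab[nz, ny, nx])
                if require_full and len(nb) < 26:
                    continue
                if not nb:
                    continue
                n_i[a - 1] += 1
                s_i[a - 1] += abs(a - np.mean(nb))
    p_i = n_i / n_i.sum() if n_i.sum() else n_i
    return n_i, p_i, s_i


def auc_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney probability by O(n^2) pairwise comparison."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def delong_components_bruteforce(scores: np.ndarray, labels: np.ndarray):
    """Placement values and AUC variance by explicit double loops."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v10 = np.array(
        [np.mean([1.0 if a > b else (0.5 if a == b else 0.0) for b in neg]) for a in pos]
    )
    v01 = np.array(
        [np.mean([1.0 if a > b else (0.5 if a == b else 0.0) for a in pos]) for b in neg]
    )
    auc = v10.mean()
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return auc, var, v10, v01


def lasso_objective(x, y, beta, b0, lam, family="binomial") -> float:
    eta = b0 + x @ beta
    if family == "binomial":
        loss = np.mean(np.log1p(np.exp(eta)) - y * eta)
    else:
        loss = 0.5 * np.mean((y - eta) ** 2)
    return loss + lam * np.sum(np.abs(beta))


def lasso_proximal_gradient(
    x, y, lam, family="binomial", iters=200_000, step=None
):
    """Independent ISTA solver of the same penalized objective."""
    n, p = x.shape
    beta = np.zeros(p)
    b0 = 0.0
    if step is None:
        lip = np.linalg.norm(x, 2) ** 2 / n
        lip = lip / 4 if family == "binomial" else lip
        step = 1.0 / (lip + 1.0)
    for _ in range(iters):
        eta = b0 + x @ beta
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = x.T @ (mu - y) / n
            g0 = np.mean(mu - y)
        else:
            grad = -x.T @ (y - eta) / n
            g0 = -np.mean(y - eta)
        beta_new = beta - step * grad
        beta_new = np.sign(beta_new) * np.maximum(np.abs(beta_new) - step * lam, 0.0)
        b0_new = b0 - step * g0
        if max(np.max(np.abs(beta_new - beta)), abs(b0_new - b0)) < 1e-12:
            beta, b0 = beta_new, b0_new
            break
        beta, b0 = beta_new, b0_new
    return beta, b0
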