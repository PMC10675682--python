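"""Gyration-tensor shape analysis of aggregate cores and whole aggregates.

The gyration tensor of a set of (unit-mass) beads is
S = (1/N) sum_i (r_i - r_mean)(r_i - r_mean)^T; its ordered eigenvalues
lambda_1^2 <= lambda_2^2 <= lambda_3^2 are the squared principal size
parameters, and their sum is the squared radius of gyration.  A sphere has
three comparable eigenvalues; a rod of growing length has two flat small
components and lambda_3^2 growing with the length squared — the signature
used to separate spherical micelles from cylindrical associates.

"Diagonal components" are reported in the principal frame (eigenvalues) by
default, because lab-frame diagonals are basis-dependent and average
poorly over an isotropic ensemble; ``mode="diagonal"`` returns the
lab-frame diagonal instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .aggregates import Aggregate, AggregateSet
from .builder import Configuration

__all__ = ["GyrationResult", "unwrap", "gyration", "shape_vs_size", "fit_scaling_exponent"]


@dataclass
class GyrationResult:
    """Ordered squared size parameters of one aggregate subset."""

    lambda_sq: tuple[float, float, float]  # ascending
    subset: str  # "core" (B beads) or "whole" (A+B)
    A_S: int = 0

    @property
    def rg_sq(self) -> float:
        return float(sum(self.lambda_sq))

    @property
    def asphericity(self) -> float:
        """lambda_3^2 - (lambda_1^2 + lambda_2^2)/2; zero for a sphere."""
        l1, l2, l3 = self.lambda_sq
        return l3 - 0.5 * (l1 + l2)


def unwrap(
    positions: np.ndarray,
    geometry,
    cutoff: float = 1.0,
    bonds: np.ndarray | None = None,
) -> np.ndarray:
    """Make one aggregate's coordinates continuous across periodic boundaries.

    Beads are traversed over their contact network (pairs closer than
    ``cutoff`` under minimum image, optionally augmented with bond edges);
    each newly reached bead is placed at the minimum-image position
    relative to its already-unwrapped neighbour.  The result is unique up
    to a global translation.  Aggregates spanning more than half the box
    in a periodic direction are flagged with a warning (the unwrap is
    ambiguous there).
    """
    pos = np.asarray(positions, dtype=float).copy()
    n = len(pos)
    if n <= 1:
        return pos
    L = np.array([geometry.Lx, geometry.Ly, geometry.Lz])
    periodic = np.array(geometry.periodic)

    def min_image(dr):
        for ax in range(3):
            if periodic[ax]:
                dr[ax] -= L[ax] * np.round(dr[ax] / L[ax])
        return dr

    # neighbour graph in wrapped coordinates (shift to a non-negative box)
    shifted = pos + L / 2.0
    box = L.copy().astype(float)
    for ax in range(3):
        if periodic[ax]:
            shifted[:, ax] = np.mod(shifted[:, ax], box[ax])
        else:
            box[ax] = 8.0 * (abs(shifted[:, ax]).max() + L[ax])
            shifted[:, ax] = np.mod(shifted[:, ax], box[ax])
    tree = cKDTree(shifted, boxsize=box)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for i, j in tree.query_pairs(cutoff, output_type="ndarray"):
        neigh[i].append(int(j))
        neigh[j].append(int(i))
    if bonds is not None:
        for i, j in bonds:
            neigh[int(i)].append(int(j))
            neigh[int(j)].append(int(i))

    out = np.empty_like(pos)
    seen = np.zeros(n, dtype=bool)
    for root in range(n):
        if seen[root]:
            continue
        out[root] = pos[root]
        seen[root] = True
        stack = [root]
        while stack:
            i = stack.pop()
            for j in neigh[i]:
                if not seen[j]:
                    dr = min_image(pos[j] - pos[i])
                    out[j] = out[i] + dr
                    seen[j] = True
                    stack.append(j)
    span = out.max(axis=0) - out.min(axis=0)
    for ax in range(3):
        if periodic[ax] and span[ax] > L[ax] / 2.0:
            warnings.warn(
                f"aggregate spans more than half the box along axis {ax}; "
                "unwrapped coordinates are ambiguous",
                stacklevel=2,
            )
    return out


def gyration(positions: np.ndarray, mode: str = "eigen") -> np.ndarray:
    """Squared size parameters of a point set (already unwrapped).

    ``mode="eigen"`` (default) returns the ordered eigenvalues of the
    gyration tensor; ``mode="diagonal"`` the sorted lab-frame diagonal.
    A single bead gives (0, 0, 0); two beads at distance d give
    (0, 0, d^2/4).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(pos) == 0:
        raise ValueError("need at least one bead")
    centred = pos - pos.mean(axis=0)
    S = centred.T @ centred / len(pos)
    if mode == "eigen":
        vals = np.linalg.eigvalsh(S)
        return np.clip(np.sort(vals), 0.0, None)
    if mode == "diagonal":
        return np.sort(np.diag(S))
    raise ValueError(f"unknown gyration mode {mode!r}")


def aggregate_gyration(
    config: Configuration,
    agg: Aggregate,
    subset: str = "core",
    mode: str = "eigen",
    cutoff: float = 1.0,
) -> GyrationResult:
    """Gyration of one aggregate's core (B beads) or whole body (A+B)."""
    mask = np.isin(config.chain_id, list(agg.chains))
    if subset == "core":
        mask &= config.species == "B"
    elif subset != "whole":
        raise ValueError("subset must be 'core' or 'whole'")
    pos = unwrap(config.positions[mask], config.geometry, cutoff=cutoff)
    lam = gyration(pos, mode=mode)
    return GyrationResult(lambda_sq=tuple(lam), subset=subset, A_S=agg.A_S)


def shape_vs_size(
    frames: list[Configuration],
    aggsets: list[AggregateSet],
    subset: str = "core",
    mode: str = "eigen",
    fit_window: tuple[int, int] | None = None,
) -> dict:
    """Average squared size parameters binned by association number.

    Pools all aggregates of all frames; returns a dict with the sorted
    unique sizes ``A_S``, the (n_sizes, 3) matrix of mean lambda_i^2, the
    per-size aggregate counts, and (when two or more sizes are available)
    the scaling exponents a from lambda_i ∝ A_S^a fitted by least squares
    on log–log over ``fit_window`` (inclusive A_S range; default all
    sizes), plus the exponent of the radius of gyration.
    """
    if len(frames) != len(aggsets):
        raise ValueError("one aggregate set per frame required")
    acc: dict[int, list[np.ndarray]] = {}
    for cfg, aggset in zip(frames, aggsets):
        for agg in aggset:
            res = aggregate_gyration(cfg, agg, subset=subset, mode=mode)
            acc.setdefault(agg.A_S, []).append(np.array(res.lambda_sq))
    sizes = np.array(sorted(acc), dtype=np.int64)
    mean_lam = np.array([np.mean(acc[s], axis=0) for s in sizes])
    counts = np.array([len(acc[s]) for s in sizes], dtype=np.int64)
    out = {"A_S": sizes, "lambda_sq": mean_lam, "counts": counts, "subset": subset}
    lo, hi = fit_window if fit_window else (int(sizes.min()), int(sizes.max()))
    sel = (sizes >= lo) & (sizes <= hi) & (sizes > 0)
    if sel.sum() >= 2:
        out["exponents"] = np.array(
            [
                fit_scaling_exponent(sizes[sel], mean_lam[sel, i])
                for i in range(3)
            ]
        )
        out["rg_exponent"] = fit_scaling_exponent(sizes[sel], mean_lam[sel].sum(axis=1))
    return out


def fit_scaling_exponent(sizes: np.ndarray, lambda_sq: np.ndarray) -> float:
    """Exponent a of lambda ∝ A_S^a from a log–log least-squares fit.

    ``lambda_sq`` are squared sizes, so the fitted slope of
    log(lambda_sq) vs log(A_S) is halved.  Compact homogeneous objects
    (filled spheres) give a = 1/3; rods of fixed diameter give a → 1 for
    the long axis.
    """
    sizes = np.asarray(sizes, dtype=float)
    lam = np.asarray(lambda_sq, dtype=float)
    ok = (sizes > 0) & (lam > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive points to fit an exponent")
    slope = np.polyfit(np.log(sizes[ok]), np.log(lam[ok]), 1)[0]
    return float(slope / 2.0)
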