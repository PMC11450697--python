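"""Cluster-based permutation Spearman correlation on time-frequency maps.

For n subjects each contributing a scalar predictor (pre-stimulation
endogenous-exogenous frequency difference) and a (frequency x time) response
map (percent-change connectivity), Spearman's rho is computed per cell.
Cells with p < alpha are clustered by orthogonal spectro-temporal adjacency,
separately for positive and negative rho; each cluster's mass is the sum of
|rho| over its cells.  The null distribution of the maximum cluster mass is
built by permuting the subject order of the predictor, and observed
clusters whose mass exceeds the null's 97.5th percentile are flagged
significant (two-sided test at family-wise alpha 0.05).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

CLUSTER_ALPHA = 0.05
NULL_PERCENTILE = 97.5
DEFAULT_N_PERM = 1000

#: orthogonal (4-neighbour) adjacency in the (frequency, time) grid
ORTHOGONAL = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p from the t
    approximation on n - 2 degrees of freedom; ties get average ranks.

    Raises on constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need n >= 4 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def _rho_p_from_ranks(
    rx: np.ndarray, ry_centered: np.ndarray, ry_norm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman over cells.

    rx : (n,) ranks of the predictor; ry_centered : (n, cells) centered
    ranks of the responses; ry_norm : (cells,) their norms.  Returns
    (rho, p) per cell, NaN where a response is constant.
    """
    n = len(rx)
    cx = rx - rx.mean()
    nx = np.linalg.norm(cx)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (cx @ ry_centered) / (nx * ry_norm)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p


def correlation_map(
    diffs: np.ndarray,
    maps: np.ndarray,
    subject_ids: list | None = None,
    map_ids: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Spearman correlation between a subject vector and subject
    maps.

    diffs : (n,); maps : (n, F, T).  Subjects with a non-finite predictor
    or any non-finite map (that subject's whole map) are dropped pairwise;
    fewer than 4 complete subjects is an error.  When both id lists are
    given they must agree element-wise (misalignment guard).

    Returns (rho, p) arrays of shape (F, T); cells where the response is
    constant across subjects are NaN-flagged.
    """
    diffs = np.asarray(diffs, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != len(diffs):
        raise ValueError("diffs and maps disagree on subject count")
    if subject_ids is not None and map_ids is not None:
        if list(subject_ids) != list(map_ids):
            raise ValueError("subject order differs between diffs and maps")
    complete = np.isfinite(diffs) & np.isfinite(maps).all(axis=(1, 2))
    if complete.sum() < 4:
        raise ValueError(f"only {int(complete.sum())} complete subjects; need >= 4")
    d = diffs[complete]
    m = maps[complete]
    if np.ptp(d) == 0:
        raise ValueError("constant predictor: rank correlation undefined")
    n, nf, nt = m.shape
    flat = m.reshape(n, nf * nt)
    ry = _rank(flat, axis=0)
    ryc = ry - ry.mean(axis=0)
    ryn = np.linalg.norm(ryc, axis=0)
    ryn[ryn == 0] = np.nan  # constant response cell -> undefined
    rho, p = _rho_p_from_ranks(_rank(d), ryc, ryn)
    return rho.reshape(nf, nt), p.reshape(nf, nt)


@dataclass
class Cluster:
    sign: str  # "positive" | "negative"
    cells: list[tuple[int, int]]
    mass: float
    p_perm: float | None = None
    significant: bool | None = None

    def to_dict(self) -> dict:
        return {
            "sign": self.sign,
            "cells": [list(c) for c in self.cells],
            "mass": self.mass,
            "p_perm": self.p_perm,
            "significant": self.significant,
        }


@dataclass
class ClusterResult:
    """Observed clusters plus the permutation null they were tested against."""

    clusters: list[Cluster]
    null_max_mass: np.ndarray
    null_quantile: float
    n_perm: int
    seed: int | None
    alpha: float = CLUSTER_ALPHA
    percentile: float = NULL_PERCENTILE
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "clusters": [c.to_dict() for c in self.clusters],
            "null_quantile": self.null_quantile,
            "null_mean": float(self.null_max_mass.mean()) if len(self.null_max_mass) else 0.0,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha": self.alpha,
            "percentile": self.percentile,
            "meta": self.meta,
        }


def form_clusters(
    p_map: np.ndarray,
    rho_map: np.ndarray,
    alpha: float = CLUSTER_ALPHA,
    structure: np.ndarray = ORTHOGONAL,
) -> list[Cluster]:
    """Partition supra-threshold cells (p < alpha) into connected
    components under orthogonal adjacency, separately per sign of rho;
    cluster mass = sum of |rho| over member cells."""
    p_map = np.asarray(p_map, dtype=float)
    rho_map = np.asarray(rho_map, dtype=float)
    if p_map.shape != rho_map.shape:
        raise ValueError("p and rho maps must share a grid")
    supra = np.isfinite(p_map) & (p_map < alpha)
    clusters: list[Cluster] = []
    for sign, mask in (
        ("positive", supra & (rho_map > 0)),
        ("negative", supra & (rho_map < 0)),
    ):
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            cells = np.argwhere(labels == lab)
            mass = float(np.abs(rho_map[labels == lab]).sum())
            clusters.append(Cluster(sign, [tuple(map(int, c)) for c in cells], mass))
    return clusters


def _max_mass(p_map: np.ndarray, rho_map: np.ndarray, alpha: float,
              structure: np.ndarray) -> float:
    cl = form_clusters(p_map, rho_map, alpha, structure)
    return max((c.mass for c in cl), default=0.0)


def permutation_test(
    diffs: np.ndarray,
    maps: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = CLUSTER_ALPHA,
    percentile: float = NULL_PERCENTILE,
    subject_ids: list | None = None,
    map_ids: list | None = None,
) -> ClusterResult:
    """Cluster-based permutation test of the subject-level correlation.

    Each iteration permutes the subject order of ``diffs`` (maps fixed),
    recomputes the full rho/p map and its clusters, and records the maximum
    cluster mass (0 when no cell is supra-threshold).  Observed clusters are
    significant when their mass strictly exceeds the ``percentile`` of that
    max-mass null; an exact-style permutation p, (1 + #{null >= obs}) /
    (1 + n_perm), is reported alongside.  When n! <= n_perm every distinct
    permutation is used exactly once (sampling without replacement).
    Fully reproducible from ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    diffs = np.asarray(diffs, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if subject_ids is not None and map_ids is not None:
        if list(subject_ids) != list(map_ids):
            raise ValueError("subject order differs between diffs and maps")
    complete = np.isfinite(diffs) & np.isfinite(maps).all(axis=(1, 2))
    if complete.sum() < 4:
        raise ValueError(f"only {int(complete.sum())} complete subjects; need >= 4")
    d = diffs[complete]
    m = maps[complete]
    n, nf, nt = m.shape

    # shared rank precomputation: permuting subjects permutes d's ranks only
    flat = m.reshape(n, nf * nt)
    ry = _rank(flat, axis=0)
    ryc = ry - ry.mean(axis=0)
    ryn = np.linalg.norm(ryc, axis=0)
    ryn[ryn == 0] = np.nan
    rd = _rank(d)

    rho, p = _rho_p_from_ranks(rd, ryc, ryn)
    rho, p = rho.reshape(nf, nt), p.reshape(nf, nt)
    observed = form_clusters(p, rho, alpha)

    rng = np.random.default_rng(seed)
    if n <= 20 and math.factorial(n) <= n_perm:
        perms = list(itertools.permutations(range(n)))
        order = rng.permutation(len(perms))
        perm_iter = (np.array(perms[k]) for k in order)
        n_used = len(perms)
    else:
        perm_iter = (rng.permutation(n) for _ in range(n_perm))
        n_used = n_perm

    null = np.empty(n_used)
    for it, perm in enumerate(perm_iter):
        r, q = _rho_p_from_ranks(rd[perm], ryc, ryn)
        null[it] = _max_mass(
            q.reshape(nf, nt), r.reshape(nf, nt), alpha, ORTHOGONAL
        )

    thresh = float(np.percentile(null, percentile))
    for c in observed:
        c.significant = bool(c.mass > thresh)
        c.p_perm = float((1 + int((null >= c.mass).sum())) / (1 + n_used))
    return ClusterResult(
        clusters=observed, null_max_mass=null, null_quantile=thresh,
        n_perm=n_used, seed=seed, alpha=alpha, percentile=percentile,
        meta={"n_subjects": int(n), "grid": [int(nf), int(nt)]},
    )
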