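"""Single-unit isolation quality and long-term waveform stability.

Cluster separation in principal-component space is graded with two scalar
indices: J3 = J2/J1, where J1 is the pooled within-cluster scatter and J2 the
between-cluster scatter (high J3 = compact, well separated), and the
Davies-Bouldin index DB = (1/K) sum_k max_{j != k} (s_k + s_j) / d(m_k, m_j)
(low DB = well separated).  Long-term stability across behavioural sessions is
graded by the Pearson correlation between session-mean waveform templates;
only units with every consecutive-session correlation above 0.97 are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClusterQuality",
    "StabilityResult",
    "UnitQuality",
    "cluster_quality",
    "pc_project",
    "template_stability",
    "stability_gate",
]

R_THRESHOLD_DEFAULT = 0.97


@dataclass(frozen=True)
class ClusterQuality:
    j3: float          # +inf when within-cluster scatter is exactly zero
    db: float
    flag: str | None = None


@dataclass(frozen=True)
class StabilityResult:
    unit_id: str
    template_r: tuple            # consecutive session-pair correlations
    session_pairs: tuple
    stable: bool
    threshold: float
    reason: str | None = None


@dataclass(frozen=True)
class UnitQuality:
    unit_id: str
    j3: float | None = None
    db: float | None = None
    stability: StabilityResult | None = None

    @property
    def stable(self) -> bool:
        return bool(self.stability and self.stability.stable)


def cluster_quality(clusters: Sequence[np.ndarray]) -> ClusterQuality:
    """J3 and Davies-Bouldin indices for point sets in a shared space."""
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    arrs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in clusters]
    dim = arrs[0].shape[1]
    if any(a.shape[0] < 1 or a.shape[1] != dim for a in arrs):
        raise ValueError("clusters must be non-empty and share a dimension")

    centroids = np.array([a.mean(axis=0) for a in arrs])
    sizes = np.array([a.shape[0] for a in arrs])
    grand = (centroids * sizes[:, None]).sum(axis=0) / sizes.sum()

    j1 = sum(((a - c) ** 2).sum() for a, c in zip(arrs, centroids))
    j2 = float((sizes * ((centroids - grand) ** 2).sum(axis=1)).sum())
    j3 = np.inf if j1 == 0 else j2 / j1

    # mean distance of each cluster's points to its centroid
    s = np.array([np.linalg.norm(a - c, axis=1).mean() for a, c in zip(arrs, centroids)])
    k = len(arrs)
    ratios = np.full((k, k), -np.inf)
    flag = None
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            if d == 0:
                return ClusterQuality(float(j3), float("nan"), flag="coincident_centroids")
            ratios[i, j] = (s[i] + s[j]) / d
    db = float(ratios.max(axis=1).mean())
    return ClusterQuality(float(j3), db, flag)


def pc_project(snippets: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Project waveform snippets onto the top principal components.

    The projection uses the covariance of the pooled snippets (rows = spikes);
    sorter conventions vary, top-2 PCs of the pooled covariance is used here.
    """
    x = np.asarray(snippets, dtype=float)
    if x.ndim != 2:
        raise ValueError("snippets must be a 2-D (n_spikes, n_samples) matrix")
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return xc @ vt[:n_components].T


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    return float(np.dot(a, b) / (na * nb))


def template_stability(waveforms: Mapping[str, np.ndarray], unit_id: str = "",
                       threshold: float = R_THRESHOLD_DEFAULT) -> StabilityResult:
    """Pearson correlations of session-mean templates across consecutive sessions.

    ``waveforms`` maps session label -> snippet matrix (n_spikes, n_samples) or
    a 1-D template; sessions are taken in mapping order.  A unit is stable iff
    every consecutive-pair correlation exceeds ``threshold``.  A zero-variance
    template makes the correlation undefined; the unit is then unstable with
    reason ``zero_variance_template``.
    """
    sessions = list(waveforms)
    if len(sessions) < 2:
        raise ValueError("need templates from >= 2 sessions")
    templates = []
    for sess in sessions:
        w = np.asarray(waveforms[sess], dtype=float)
        templates.append(w.mean(axis=0) if w.ndim == 2 else w)
    length = templates[0].size
    if any(t.size != length for t in templates):
        raise ValueError("templates must have equal length")

    rs, pairs = [], []
    for a, b, sa, sb in zip(templates, templates[1:], sessions, sessions[1:]):
        r = _pearson(a, b)
        if r is None:
            return StabilityResult(unit_id, tuple(rs), tuple(pairs), False,
                                   threshold, reason="zero_variance_template")
        rs.append(r)
        pairs.append((sa, sb))
    stable = all(r > threshold for r in rs)
    return StabilityResult(unit_id, tuple(rs), tuple(pairs), stable, threshold,
                           None if stable else "template_r_below_threshold")


def stability_gate(results: Sequence[StabilityResult]) -> list[StabilityResult]:
    """Keep only stable units; idempotent by construction."""
    return [r for r in results if r.stable]
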