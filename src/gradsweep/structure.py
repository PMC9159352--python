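"""Population-structure utilities: LD decay, LD pruning, PCA, NJ tree.

LD is measured as the squared correlation r^2 between phased haplotype
columns.  Pruning is the greedy sliding-window procedure: within each window
the later site (by position) of any pair with r^2 >= the bound is dropped.
PCA uses frequency-scaled dosages (each site centred by 2*p and divided by
sqrt(2*p*(1-p))), the standard scaling for population-genetic PCA.  The
neighbour-joining tree is built from allele-sharing distances (1 - IBS).
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, HaplotypePanel


def hap_r2(hap_i: np.ndarray, hap_j: np.ndarray) -> float:
    """r^2 between two phased binary sites: D^2 / (p_i q_i p_j q_j)."""
    hi = np.asarray(hap_i, dtype=float)
    hj = np.asarray(hap_j, dtype=float)
    if hi.shape != hj.shape or hi.ndim != 1 or len(hi) < 2:
        raise ValueError("need two equal-length vectors of >= 2 haplotypes")
    p_i = hi.mean()
    p_j = hj.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise ValueError("r^2 undefined for a monomorphic site")
    d = (hi * hj).mean() - p_i * p_j
    return float(d * d / (p_i * (1 - p_i) * p_j * (1 - p_j)))


def ld_decay(
    panel: HaplotypePanel,
    max_dist: int = 300_000,
    bin_width: int = 10_000,
) -> pd.DataFrame:
    """Mean r^2 per distance bin over all SNP pairs within ``max_dist`` bp.

    Monomorphic sites contribute no pairs.  Empty bins are absent from the
    output rather than reported as zero.
    """
    h = panel.haplotypes.astype(float)
    pos = panel.positions
    freq = h.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_sites = panel.n_sites
    for i in range(n_sites):
        if not poly[i]:
            continue
        j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
        for j in range(i + 1, j_hi):
            if not poly[j]:
                continue
            r2 = hap_r2(h[:, i], h[:, j])
            b = int((pos[j] - pos[i]) // bin_width)
            sums[b] = sums.get(b, 0.0) + r2
            counts[b] = counts.get(b, 0) + 1
    rows = [
        {
            "bin_start": b * bin_width,
            "bin_end": (b + 1) * bin_width,
            "mean_r2": sums[b] / counts[b],
            "n_pairs": counts[b],
        }
        for b in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])


def ld_prune(
    panel: HaplotypePanel,
    r2_max: float = 0.2,
    window_sites: int = 50,
    step_sites: int = 5,
) -> np.ndarray:
    """Greedy sliding-window LD prune; returns retained site indices.

    Within each window, pairs are scanned in position order and the later
    site of any pair with r^2 >= ``r2_max`` is dropped (on a position tie
    the site with the larger alt frequency is kept).  Deterministic given
    the site order.
    """
    h = panel.haplotypes.astype(float)
    freq = h.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    n = panel.n_sites
    keep = np.ones(n, dtype=bool)
    for start in range(0, max(n - 1, 1), step_sites):
        stop = min(start + window_sites, n)
        idx = [k for k in range(start, stop) if keep[k] and poly[k]]
        for ai in range(len(idx)):
            i = idx[ai]
            if not keep[i]:
                continue
            for bi in range(ai + 1, len(idx)):
                j = idx[bi]
                if not keep[j]:
                    continue
                if hap_r2(h[:, i], h[:, j]) >= r2_max:
                    drop = j if panel.positions[j] != panel.positions[i] else (
                        i if freq[i] <= freq[j] else j
                    )
                    keep[drop] = False
        if stop >= n:
            break
    return np.flatnonzero(keep)


def pca(
    matrix: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of frequency-scaled dosages.

    Returns (coordinates, variance_fractions): sample coordinates are the
    covariance eigenvectors scaled by sqrt(eigenvalue); variance fractions
    are eigenvalues over the covariance trace.  Monomorphic sites are
    dropped before scaling; the dosage matrix must be complete.
    """
    d = matrix.dosage.astype(float)
    if np.any(matrix.dosage == MISSING):
        raise ValueError("PCA requires a complete dosage matrix")
    p_hat = d.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    d = d[:, poly]
    p_hat = p_hat[poly]
    if d.shape[1] == 0:
        raise ValueError("no polymorphic sites")
    x = (d - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    frac = eigval / eigval.sum()
    return coords, frac[:k]


def ibs_distance(matrix: GenotypeMatrix) -> np.ndarray:
    """Allele-sharing distance 1 - IBS between all sample pairs.

    IBS per site for dosages d_i, d_j is 1 - |d_i - d_j| / 2; the distance
    is its complement averaged over sites.
    """
    d = matrix.dosage.astype(float)
    if np.any(matrix.dosage == MISSING):
        raise ValueError("IBS distance requires a complete dosage matrix")
    n = matrix.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        dist[i] = np.abs(d - d[i]).mean(axis=1) / 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbour joining; returns a newick string."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dist = np.asarray(dist, dtype=float)
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if dist.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    tree = nj(DistanceMatrix(dist, ids=list(labels)))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
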