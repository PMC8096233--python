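"""Ensemble-comparison metrics: distance maps, dihedral KLD, tail PCA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InputError, SpecificationError
from .core import Trajectory, kabsch

# ---------------------------------------------------------------------------
# inter-residue distances


def mean_distance_map(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Time-averaged pairwise distance matrix over the selected beads/Cα."""
    sel = np.asarray(selection, dtype=int)
    if sel.size < 2:
        raise InputError("need at least 2 residues for a distance map")
    x = traj.coords[:, sel]                               # (F, n, 3)
    diff = x[:, :, None, :] - x[:, None, :, :]
    return np.linalg.norm(diff, axis=3).mean(axis=0)


def compactness(dist_map: np.ndarray, min_separation: int = 10) -> float:
    """Mean long-range distance (|i - j| >= min_separation); smaller = more
    compact."""
    n = dist_map.shape[0]
    i, j = np.triu_indices(n, k=min_separation)
    if i.size == 0:
        raise InputError("no residue pairs at the requested separation")
    return float(dist_map[i, j].mean())


# ---------------------------------------------------------------------------
# dihedral distributions


def pseudo_dihedrals(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Pseudo-torsions (deg) over each 4 consecutive selected beads.

    Returns (frames, n_selected - 3).  For all-atom input pass backbone
    atoms in φ/ψ order instead.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 4:
        raise InputError("need at least 4 beads for a dihedral")
    x = traj.coords[:, sel]
    b1 = x[:, 1:-2] - x[:, :-3]
    b2 = x[:, 2:-1] - x[:, 1:-2]
    b3 = x[:, 3:] - x[:, 2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=2, keepdims=True))
    xcomp = np.sum(n1 * n2, axis=2)
    ycomp = np.sum(m1 * n2, axis=2)
    return np.degrees(np.arctan2(ycomp, xcomp))


def histogram_kld(a: np.ndarray, b: np.ndarray, bins: int = 60,
                  pseudo_count: float = 0.5) -> float:
    """KLD(A||B) in nats between binned angle samples on [-180, 180).

    Histograms are regularized with a per-bin pseudo-count so empty bins in
    B stay finite; identical samples give exactly 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InputError("empty sample set")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    pa = np.histogram(np.mod(a + 180.0, 360.0) - 180.0, bins=edges)[0] + pseudo_count
    pb = np.histogram(np.mod(b + 180.0, 360.0) - 180.0, bins=edges)[0] + pseudo_count
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.sum(pa * np.log(pa / pb)))


def jensen_shannon(a: np.ndarray, b: np.ndarray, bins: int = 60,
                   pseudo_count: float = 0.5) -> float:
    """Symmetrized alternative: 0.5*KLD(A||M) + 0.5*KLD(B||M)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    edges = np.linspace(-180.0, 180.0, bins + 1)
    pa = np.histogram(np.mod(a + 180.0, 360.0) - 180.0, bins=edges)[0] + pseudo_count
    pb = np.histogram(np.mod(b + 180.0, 360.0) - 180.0, bins=edges)[0] + pseudo_count
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    m = 0.5 * (pa + pb)
    return float(0.5 * np.sum(pa * np.log(pa / m)) + 0.5 * np.sum(pb * np.log(pb / m)))


def dihedral_kld(
    ens_a: list[np.ndarray],
    ens_b: list[np.ndarray],
    bins: int = 60,
    pseudo_count: float = 0.5,
    n_permutations: int = 1000,
    seed: int = 0,
    min_samples: int = 100,
) -> pd.DataFrame:
    """Per-coordinate KLD(A||B) with a permutation p-value.

    ``ens_a`` / ``ens_b`` are lists of replicate-run sample arrays, each of
    shape (samples, n_coords); the divergence is computed on the pooled
    samples and the null is built by permuting replicate-run labels between
    the two ensembles (>= ca. 1000 permutations, seeded).
    """
    if not ens_a or not ens_b:
        raise InputError("both ensembles need at least one replicate run")
    a_pool = np.concatenate([np.atleast_2d(r) for r in ens_a], axis=0)
    b_pool = np.concatenate([np.atleast_2d(r) for r in ens_b], axis=0)
    if a_pool.shape[1] != b_pool.shape[1]:
        raise InputError("ensembles must share the coordinate dimension")
    if a_pool.shape[0] < min_samples or b_pool.shape[0] < min_samples:
        raise InputError(f"need >= {min_samples} samples per ensemble")

    n_coords = a_pool.shape[1]
    observed = np.array([
        histogram_kld(a_pool[:, c], b_pool[:, c], bins, pseudo_count)
        for c in range(n_coords)
    ])

    runs = [np.atleast_2d(r) for r in ens_a] + [np.atleast_2d(r) for r in ens_b]
    n_a = len(ens_a)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_coords)
    for _ in range(n_permutations):
        order = rng.permutation(len(runs))
        pa = np.concatenate([runs[i] for i in order[:n_a]], axis=0)
        pb = np.concatenate([runs[i] for i in order[n_a:]], axis=0)
        for c in range(n_coords):
            stat = histogram_kld(pa[:, c], pb[:, c], bins, pseudo_count)
            if stat >= observed[c]:
                exceed[c] += 1
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    return pd.DataFrame({"coord": np.arange(n_coords), "kld": observed,
                         "p_value": pvals})


# ---------------------------------------------------------------------------
# tail PCA


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, >= 0
    eigenvectors: np.ndarray         # columns, orthonormal, 3n x 3n
    variance_fractions: np.ndarray
    projections: dict[str, np.ndarray]   # species -> (frames, 2) PC1/PC2
    mean: np.ndarray                 # flattened mean conformation


def superpose_to_reference(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch-fit each frame of (F, n, 3) onto a fixed reference (n, 3)."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, t = kabsch(coords[f], reference)
        out[f] = coords[f] @ rot + t
    return out


def pca_tails(ensembles: list[tuple[str, np.ndarray]]) -> PCAResult:
    """PCA of pooled tail-Cα coordinates across species.

    Each entry is (species, coords) with coords of shape (frames, n_res, 3)
    already superposed on the tail only.  The pooled 3n x 3n covariance is
    eigendecomposed; per-species projections onto PC1/PC2 are returned.
    Sign convention: PC1 is oriented so that the most extended conformation
    in the pool (largest end-to-end distance) projects negative.
    """
    if not ensembles:
        raise InputError("no ensembles given")
    flats, labels, ends = [], [], []
    for species, coords in ensembles:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InputError("each ensemble needs shape (frames, residues, 3)")
        flats.append(coords.reshape(coords.shape[0], -1))
        labels.extend([species] * coords.shape[0])
        ends.append(np.linalg.norm(coords[:, -1] - coords[:, 0], axis=1))
    x = np.concatenate(flats, axis=0)
    if x.shape[0] < 2:
        raise InputError("need at least 2 pooled frames")
    end_to_end = np.concatenate(ends)

    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]

    proj_all = xc @ v[:, :2]
    most_extended = int(np.argmax(end_to_end))
    if proj_all[most_extended, 0] > 0:
        v[:, 0] = -v[:, 0]
        proj_all[:, 0] = -proj_all[:, 0]

    projections = {}
    labels = np.array(labels)
    for species in dict.fromkeys(labels):          # preserve input order
        projections[species] = proj_all[labels == species]
    total = w.sum()
    fractions = w / total if total > 0 else np.zeros_like(w)
    return PCAResult(eigenvalues=w, eigenvectors=v,
                     variance_fractions=fractions,
                     projections=projections, mean=mean)
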